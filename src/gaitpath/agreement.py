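"""Method-agreement statistics for comparing two gait-measurement systems.

The battery applied per parameter when validating a candidate system (e.g.
an RGB-D pipeline) against a reference (e.g. marker-based optoelectronic
gait analysis):

* Kolmogorov-Smirnov normality gate (summaries switch to median/quartile
  when normality fails);
* paired Wilcoxon signed-rank test (difference between systems), with
  effect size r = |Z| / sqrt(n);
* Spearman rank correlation (exact permutation p for n <= 9);
* ICC(2,1) — two-way random effects, absolute agreement, single measure;
* Bland-Altman limits of agreement, mean difference +/- 1.96 SD;
* mean percentage error ACC% = |REF - CUR| / |REF| x 100;
* Spearman correlation of each parameter against TUG times.

Sign conventions: differences are candidate - reference, so a positive
Bland-Altman mean difference means the candidate system overestimates.  No
multiple-testing correction is applied (per-parameter p < 0.05); this is
recorded in the report metadata.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSampleError, InsufficientDataError, ValidationError

#: largest n for which the Spearman p-value is computed by exact permutation
_SPEARMAN_EXACT_N = 9


@dataclass
class PairedSample:
    """Aligned per-trial(-and-side) values from two measurement systems."""

    parameter_name: str
    values_ref: np.ndarray
    values_cur: np.ndarray

    def __post_init__(self) -> None:
        self.values_ref = np.asarray(self.values_ref, dtype=float)
        self.values_cur = np.asarray(self.values_cur, dtype=float)
        if self.values_ref.shape != self.values_cur.shape or self.values_ref.ndim != 1:
            raise ValidationError("paired sample requires two equal-length 1-D vectors")
        if self.values_ref.size < 3:
            raise InsufficientDataError("paired tests need at least 3 pairs")

    @property
    def n(self) -> int:
        return int(self.values_ref.size)

    @property
    def diffs(self) -> np.ndarray:
        return self.values_cur - self.values_ref


@dataclass
class ParameterAgreement:
    """The full per-parameter comparison record."""

    parameter_name: str
    n: int
    normality_p: float
    wilcoxon_p: float
    effect_size_r: float
    spearman_rho: float
    spearman_p: float
    icc: float
    acc_pct: float
    ba_mean_diff: float
    ba_loa_low: float
    ba_loa_high: float
    n_outside_loa: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# individual statistics
# ---------------------------------------------------------------------------

def normality_check(x: np.ndarray) -> float:
    """One-sample KS p-value against a normal with the sample's mean/SD.

    Used as a gate: downstream summaries switch to median and quartile when
    p < 0.05.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("normality check needs n >= 3")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateSampleError("constant sample: normality undefined")
    return float(stats.kstest(x, "norm", args=(float(np.mean(x)), sd)).pvalue)


def wilcoxon_paired(s: PairedSample) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test: (two-sided p, effect size r).

    The exact null distribution is used for n <= 25 when no zero
    differences or ties in |d| intervene; otherwise the normal
    approximation with Pratt zero handling (zeros ranked then dropped).
    The effect size is r = |Z| / sqrt(n) from the approximation's Z.
    """
    d = s.diffs
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p=1, r=0", stacklevel=2)
        return 1.0, 0.0
    if nz.size < 5:
        raise InsufficientDataError("Wilcoxon needs >= 5 non-zero differences")
    has_zeros = nz.size < d.size
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (s.n <= 25 and not has_zeros and not has_ties) else "approx"
    res = stats.wilcoxon(
        s.values_cur, s.values_ref, zero_method="pratt", method=method, correction=False
    )
    p = float(res.pvalue)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_z = stats.wilcoxon(
            s.values_cur, s.values_ref, zero_method="pratt", method="approx", correction=False
        )
    r = abs(float(res_z.zstatistic)) / math.sqrt(s.n)
    return p, r


def _rankdata(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    p-value by exact permutation of the y-ranks for n <= 9, by the
    t-approximation otherwise.  Constant input yields (nan, nan) with a
    warning (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InsufficientDataError("spearman needs two equal-length vectors of n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    n = x.size
    rx, ry = _rankdata(x), _rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= _SPEARMAN_EXACT_N:
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pyc = perms - perms.mean(axis=1, keepdims=True)
        num = pyc @ rxc
        den = np.sqrt((pyc**2).sum(axis=1) * (rxc**2).sum())
        rho_perm = num / den
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def icc_absolute(s: PairedSample) -> tuple[float, list[str]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares of the n x 2
    subjects-by-systems table:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Negative estimates are clamped to 0 and flagged; zero between-subject
    variance is flagged degenerate.
    """
    if s.n < 5:
        raise InsufficientDataError("ICC needs >= 5 pairs")
    data = np.column_stack([s.values_ref, s.values_cur])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    flags: list[str] = []
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= mse or denom <= 0:
        flags.append("degenerate_between_subject_variance")
    if denom == 0:
        return 0.0, flags + ["icc_undefined"]
    icc = (msr - mse) / denom
    if icc < 0:
        flags.append("negative_icc_clamped")
        icc = 0.0
    return float(min(icc, 1.0)), flags


def bland_altman(s: PairedSample) -> tuple[float, float, float, int]:
    """Bland-Altman agreement: (mean diff, LoA low, LoA high, n outside).

    Differences are candidate - reference; limits of agreement are the mean
    difference +/- 1.96 x sample SD (ddof=1), the conventional 95% band.
    """
    d = s.diffs
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    outside = int(np.sum((d < lo) | (d > hi)))
    return mean, lo, hi, outside


def bland_altman_plot_data(s: PairedSample) -> pd.DataFrame:
    """Per-pair (mean of pair, difference) table for a Bland-Altman plot."""
    return pd.DataFrame(
        {
            "pair_mean": 0.5 * (s.values_ref + s.values_cur),
            "difference": s.diffs,
        }
    )


def accuracy_pct(s: PairedSample) -> float:
    """Mean percentage measurement error |REF - CUR| / |REF| x 100.

    Pairs with a zero reference value are excluded with a warning.
    """
    ref, cur = s.values_ref, s.values_cur
    ok = ref != 0
    if not np.all(ok):
        warnings.warn(
            f"{int(np.sum(~ok))} pair(s) with zero reference value excluded from ACC%",
            stacklevel=2,
        )
    if not np.any(ok):
        raise DegenerateSampleError("all reference values are zero: ACC% undefined")
    return float(np.mean(np.abs(ref[ok] - cur[ok]) / np.abs(ref[ok])) * 100.0)


def tug_correlation(params: pd.DataFrame, tug: pd.Series | np.ndarray) -> pd.DataFrame:
    """Spearman correlation of each parameter column against TUG times.

    Subjects with missing TUG are excluded with a warning.  Expected signs
    in impaired gait: negative for step length, velocity and cadence (slower
    subjects take longer TUG), positive for stance and double support.
    """
    tug = pd.Series(np.asarray(tug, dtype=float), index=params.index)
    ok = tug.notna()
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} subject(s) without TUG excluded", stacklevel=2)
    if int(ok.sum()) < 3:
        raise InsufficientDataError("TUG correlation needs >= 3 subjects with TUG")
    rows = []
    for col in params.columns:
        rho, p = spearman(params.loc[ok, col].to_numpy(), tug[ok].to_numpy())
        rows.append({"parameter": col, "rho": rho, "p": p})
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Per-parameter agreement battery for two aligned parameter tables."""

    parameters: dict[str, ParameterAgreement]
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.to_dict() for p in self.parameters.values()]).set_index(
            "parameter_name"
        )

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "parameters": {k: v.to_dict() for k, v in self.parameters.items()},
        }


def compare_parameter(s: PairedSample) -> ParameterAgreement:
    """Run the full battery on one paired parameter sample."""
    flags: list[str] = []
    try:
        norm_p = normality_check(np.concatenate([s.values_ref, s.values_cur]))
    except DegenerateSampleError:
        norm_p = float("nan")
        flags.append("degenerate_normality_sample")
    if not math.isnan(norm_p) and norm_p < 0.05:
        flags.append("non_normal_median_summary")
    wil_p, r = wilcoxon_paired(s)
    rho, sp_p = spearman(s.values_ref, s.values_cur)
    icc, icc_flags = icc_absolute(s)
    mean_d, lo, hi, n_out = bland_altman(s)
    acc = accuracy_pct(s)
    return ParameterAgreement(
        parameter_name=s.parameter_name,
        n=s.n,
        normality_p=norm_p,
        wilcoxon_p=wil_p,
        effect_size_r=r,
        spearman_rho=rho,
        spearman_p=sp_p,
        icc=icc,
        acc_pct=acc,
        ba_mean_diff=mean_d,
        ba_loa_low=lo,
        ba_loa_high=hi,
        n_outside_loa=n_out,
        flags=flags + icc_flags,
    )


def compare_systems(
    ref: pd.DataFrame, cur: pd.DataFrame, tug: pd.Series | None = None
) -> AgreementReport:
    """Compare two aligned parameter tables column by column.

    Rows must pair by trial(-and-side); columns are parameters.  An optional
    TUG series adds per-parameter TUG correlations to the metadata.
    """
    if list(ref.columns) != list(cur.columns) or len(ref) != len(cur):
        raise ValidationError("parameter tables must share columns and row count to pair")
    report = AgreementReport(
        parameters={},
        metadata={
            "icc_form": "ICC(2,1) two-way random, absolute agreement, single measure",
            "wilcoxon_zeros": "pratt",
            "ba_sign": "candidate - reference",
            "multiple_testing": "none (per-parameter p < 0.05)",
        },
    )
    for col in ref.columns:
        s = PairedSample(col, ref[col].to_numpy(), cur[col].to_numpy())
        report.parameters[col] = compare_parameter(s)
    if tug is not None:
        report.metadata["tug_correlation"] = tug_correlation(cur, tug).to_dict(orient="index")
    return report
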