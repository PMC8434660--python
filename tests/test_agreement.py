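"""Agreement-statistics battery vs brute-force and library oracles."""

import numpy as np
import pandas as pd
import pytest

from gaitpath import PairedSample, compare_systems
from gaitpath.agreement import (
    accuracy_pct,
    bland_altman,
    bland_altman_plot_data,
    icc_absolute,
    normality_check,
    spearman,
    tug_correlation,
    wilcoxon_paired,
)
from gaitpath.errors import DegenerateSampleError, InsufficientDataError, ValidationError

from oracles import (
    icc21_mean_squares,
    spearman_exhaustive,
    spearman_permutation_p,
    wilcoxon_exact_enumeration,
)


# -- normality --------------------------------------------------------------

def test_normality_accepts_normal_sample(rng):
    x = rng.normal(0, 1, 1000)
    assert normality_check(x) > 0.05


def test_normality_rejects_exponential_sample(rng):
    x = rng.exponential(1.0, 1000)
    assert normality_check(x) < 0.05


def test_normality_preconditions():
    with pytest.raises(InsufficientDataError):
        normality_check([1.0, 2.0])
    with pytest.raises(DegenerateSampleError):
        normality_check([3.0, 3.0, 3.0, 3.0])


# -- wilcoxon ---------------------------------------------------------------

def test_wilcoxon_identical_vectors():
    s = PairedSample("p", [1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5])
    with pytest.warns(UserWarning, match="zero"):
        p, r = wilcoxon_paired(s)
    assert p == 1.0 and r == 0.0


def test_wilcoxon_all_positive_n10_exact():
    ref = np.zeros(10)
    cur = np.arange(1.0, 11.0)
    p, r = wilcoxon_paired(PairedSample("p", ref, cur))
    assert p == pytest.approx(2 / 1024, abs=1e-12)
    assert r > 0.8  # maximal one-directional shift


@pytest.mark.parametrize("seed", range(5))
def test_wilcoxon_matches_sign_enumeration(seed):
    rng = np.random.default_rng(500 + seed)
    n = int(rng.integers(6, 13))
    # distinct non-zero differences keep the exact regime
    d = rng.choice(np.arange(1, 40), size=n, replace=False) * rng.choice([-1.0, 1.0], n) / 10
    ref = rng.normal(0, 1, n)
    cur = ref + d
    p, _ = wilcoxon_paired(PairedSample("p", ref, cur))
    assert p == pytest.approx(wilcoxon_exact_enumeration(d), abs=1e-10)


def test_wilcoxon_too_few_nonzero():
    s = PairedSample("p", [1.0, 2, 3, 4, 5], [1.1, 2, 3, 4, 5])
    with pytest.raises(InsufficientDataError):
        wilcoxon_paired(s)


# -- spearman ---------------------------------------------------------------

def test_spearman_perfect_monotone():
    x = np.array([1.0, 2, 3, 5, 8])
    assert spearman(x, x**3)[0] == pytest.approx(1.0)
    assert spearman(x, -x)[0] == pytest.approx(-1.0)


def test_spearman_constant_flagged():
    with pytest.warns(UserWarning, match="constant"):
        rho, p = spearman([1.0, 1, 1, 1], [1.0, 2, 3, 4])
    assert np.isnan(rho) and np.isnan(p)


@pytest.mark.parametrize("seed", range(4))
def test_spearman_matches_exhaustive_ranks(seed):
    rng = np.random.default_rng(600 + seed)
    x = rng.normal(0, 1, 8)
    y = rng.normal(0, 1, 8) + 0.5 * x
    rho, p = spearman(x, y)
    assert rho == pytest.approx(spearman_exhaustive(x, y), abs=1e-10)


def test_spearman_exact_permutation_p_small_n(rng):
    x = rng.normal(0, 1, 6)
    y = rng.normal(0, 1, 6)
    _, p = spearman(x, y)
    assert p == pytest.approx(spearman_permutation_p(list(x), list(y)), abs=1e-10)


# -- ICC --------------------------------------------------------------------

def test_icc_identical_is_one():
    v = np.array([1.0, 2, 3, 4, 5, 6])
    icc, flags = icc_absolute(PairedSample("p", v, v))
    assert icc == pytest.approx(1.0)


def test_icc_independent_noise_near_zero(rng):
    ref = rng.normal(0, 1, 60)
    cur = rng.normal(0, 1, 60)  # no shared subject effect at matched scale
    icc, _ = icc_absolute(PairedSample("p", ref, cur))
    assert icc < 0.3


def test_icc_matches_hand_mean_squares():
    ref = [9.0, 10.5, 12.0, 8.0, 14.5, 11.0]
    cur = [9.4, 10.2, 12.6, 8.4, 14.0, 11.5]
    icc, _ = icc_absolute(PairedSample("p", ref, cur))
    assert icc == pytest.approx(icc21_mean_squares(ref, cur), abs=1e-10)


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(77)
    subj = rng.normal(10, 2, 12)
    ref = subj + rng.normal(0, 0.5, 12)
    cur = subj + 0.3 + rng.normal(0, 0.5, 12)
    icc, _ = icc_absolute(PairedSample("p", ref, cur))
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(12), 2),
            "rater": ["ref", "cur"] * 12,
            "score": np.column_stack([ref, cur]).ravel(),
        }
    )
    table = pg.intraclass_corr(data=df, targets="subject", raters="rater", ratings="score")
    # two-way random, absolute agreement, single measure; labeled ICC2 or ICC(A,1)
    sel = table["Type"].isin(["ICC2", "ICC(A,1)"])
    icc2 = float(table.loc[sel, "ICC"].iloc[0])
    assert icc == pytest.approx(icc2, abs=1e-8)


# -- Bland-Altman -----------------------------------------------------------

def test_bland_altman_identical():
    v = np.arange(5.0)
    assert bland_altman(PairedSample("p", v, v)) == (0.0, 0.0, 0.0, 0)


def test_bland_altman_unit_sd():
    ref = np.zeros(3)
    cur = np.array([-1.0, 0.0, 1.0])
    mean, lo, hi, n_out = bland_altman(PairedSample("p", ref, cur))
    assert mean == pytest.approx(0.0)
    assert lo == pytest.approx(-1.96)
    assert hi == pytest.approx(1.96)
    assert n_out == 0


def test_bland_altman_coverage_95pct(rng):
    """LoA from n=22 normal differences contain ~95% of them on average."""
    inside = []
    for _ in range(1000):
        ref = rng.normal(0, 1, 22)
        cur = ref + rng.normal(0.1, 0.3, 22)
        _, lo, hi, n_out = bland_altman(PairedSample("p", ref, cur))
        inside.append(1 - n_out / 22)
    assert np.mean(inside) == pytest.approx(0.95, abs=0.02)


def test_bland_altman_plot_data():
    s = PairedSample("p", [1.0, 2.0, 3.0], [1.5, 2.5, 2.5])
    df = bland_altman_plot_data(s)
    np.testing.assert_allclose(df["pair_mean"], [1.25, 2.25, 2.75])
    np.testing.assert_allclose(df["difference"], [0.5, 0.5, -0.5])


# -- ACC% -------------------------------------------------------------------

def test_accuracy_pct_examples():
    assert accuracy_pct(PairedSample("p", [1.0, 2, 3], [1.0, 2, 3])) == 0.0
    assert accuracy_pct(PairedSample("p", [1.0, 1, 1], [0.9, 0.9, 0.9])) == pytest.approx(10.0)
    assert accuracy_pct(PairedSample("p", [2.0, 4.0, 2.0, 4.0], [1.0, 5.0, 1.0, 5.0])) == pytest.approx(37.5)


def test_accuracy_pct_zero_reference_excluded():
    with pytest.warns(UserWarning, match="zero reference"):
        acc = accuracy_pct(PairedSample("p", [0.0, 1.0, 1.0], [5.0, 0.9, 1.1]))
    assert acc == pytest.approx(10.0)


# -- TUG --------------------------------------------------------------------

def test_tug_perfect_inverse():
    params = pd.DataFrame({"velocity": [1.2, 1.0, 0.8, 0.5]})
    tug = [8.0, 10.0, 14.0, 25.0]
    out = tug_correlation(params, tug)
    assert out.loc["velocity", "rho"] == pytest.approx(-1.0)


def test_tug_synthetic_cohort(rng):
    vel = rng.uniform(0.3, 1.3, 12)
    tug = 10.0 / vel + rng.normal(0, 0.8, 12)
    params = pd.DataFrame({"mean_velocity": vel})
    out = tug_correlation(params, tug)
    assert out.loc["mean_velocity", "rho"] < -0.7


def test_tug_needs_three_subjects():
    with pytest.raises(InsufficientDataError):
        tug_correlation(pd.DataFrame({"v": [1.0, 2.0]}), [10.0, 12.0])


def test_tug_missing_excluded(rng):
    params = pd.DataFrame({"v": [1.0, 0.8, 0.6, 0.4]})
    with pytest.warns(UserWarning, match="without TUG"):
        out = tug_correlation(params, [10.0, 12.0, np.nan, 20.0])
    assert out.loc["v", "rho"] == pytest.approx(-1.0)


# -- report -----------------------------------------------------------------

def _two_system_tables(rng, sigma, n=22):
    subj = rng.normal(0, 1, n)
    ref = pd.DataFrame(
        {"step_length_m": 0.45 + 0.1 * subj, "cadence_spm": 95 + 15 * subj}
    )
    cur = ref + rng.normal(0, sigma, ref.shape) * [0.1, 15]
    return ref, cur


def test_compare_systems_report_structure(rng):
    ref, cur = _two_system_tables(rng, 0.2)
    report = compare_systems(ref, cur)
    frame = report.to_frame()
    assert set(frame.index) == {"step_length_m", "cadence_spm"}
    for col in ("wilcoxon_p", "spearman_rho", "icc", "acc_pct", "ba_mean_diff"):
        assert col in frame.columns
    row = report.parameters["step_length_m"]
    assert row.ba_loa_low <= row.ba_mean_diff <= row.ba_loa_high
    assert -1 <= row.spearman_rho <= 1
    assert 0 <= row.icc <= 1


def test_compare_systems_requires_alignment(rng):
    ref, cur = _two_system_tables(rng, 0.2)
    with pytest.raises(ValidationError):
        compare_systems(ref, cur.iloc[:-1])


def test_agreement_degrades_monotonically_with_noise(rng):
    """More candidate noise: ICC and Spearman fall, ACC% rises."""
    iccs, rhos, accs = [], [], []
    for sigma in (0.05, 0.4, 1.5):
        ref, cur = _two_system_tables(np.random.default_rng(99), sigma)
        rep = compare_systems(ref, cur).parameters["step_length_m"]
        iccs.append(rep.icc)
        rhos.append(rep.spearman_rho)
        accs.append(rep.acc_pct)
    assert iccs[0] > iccs[1] > iccs[2]
    assert rhos[0] > rhos[1] > rhos[2]
    assert accs[0] < accs[1] < accs[2]


def test_report_deterministic(rng):
    ref, cur = _two_system_tables(rng, 0.3)
    a = compare_systems(ref, cur).to_dict()
    b = compare_systems(ref, cur).to_dict()
    assert a == b
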