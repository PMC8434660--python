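"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written as plainly as possible (python loops, explicit
sums) and must stay independent of the library code paths it checks.
"""

from itertools import permutations, product

import numpy as np


# ---------------------------------------------------------------------------
# segmentation oracle: frame-by-frame threshold labeling + run merging
# ---------------------------------------------------------------------------

def brute_force_binarize(z, threshold, min_run):
    """Reference stationary(0)/moving(1) labeler.

    Frame k is moving iff |z[k]-z[k-1]| >= threshold; frame 0 copies frame
    1's label.  Then, repeatedly, the shortest interior run below min_run
    is flipped (ties: moving runs first, then leftmost).
    """
    n = len(z)
    labels = [0] * n
    for k in range(1, n):
        labels[k] = 1 if abs(z[k] - z[k - 1]) >= threshold else 0
    labels[0] = labels[1]

    def runs(lab):
        out = []
        start = 0
        for k in range(1, n + 1):
            if k == n or lab[k] != lab[start]:
                out.append((start, k, lab[start]))
                start = k
        return out

    while True:
        rs = runs(labels)
        short = [
            (stop - start, -val, start, stop)
            for (start, stop, val) in rs
            if start > 0 and stop < n and stop - start < min_run
        ]
        if not short:
            break
        _, negval, start, stop = min(short)
        for k in range(start, stop):
            labels[k] = 1 - (-negval)
    return labels


def brute_force_held(z, labels):
    """Stationary-hold: within each stationary run, z is the run's first value."""
    held = list(z)
    k = 0
    n = len(z)
    while k < n:
        if labels[k] == 0:
            j = k
            while j < n and labels[j] == 0:
                held[j] = z[k]
                j += 1
            k = j
        else:
            k += 1
    return held


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def wilcoxon_exact_enumeration(diffs):
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns.

    Requires no zero differences and no tied |d| (the exact-distribution
    regime).  Two-sided p = min(1, 2 * min(P(T+ <= t), P(T+ >= t))).
    """
    d = list(diffs)
    n = len(d)
    assert all(x != 0 for x in d) and len({abs(x) for x in d}) == n
    order = sorted(range(n), key=lambda i: abs(d[i]))
    ranks = [0] * n
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    t_plus = sum(ranks[i] for i in range(n) if d[i] > 0)
    le = ge = 0
    for signs in product((0, 1), repeat=n):
        t = sum(r for s, r in zip(signs, ranks) if s)
        le += t <= t_plus
        ge += t >= t_plus
    total = 2 ** n
    return min(1.0, 2.0 * min(le / total, ge / total))


def spearman_exhaustive(x, y):
    """Rank correlation from explicit average ranks and Pearson sums."""
    def avg_ranks(v):
        n = len(v)
        ranks = [0.0] * n
        order = sorted(range(n), key=lambda i: v[i])
        k = 0
        while k < n:
            j = k
            while j + 1 < n and v[order[j + 1]] == v[order[k]]:
                j += 1
            mean_rank = (k + j) / 2 + 1
            for m in range(k, j + 1):
                ranks[order[m]] = mean_rank
            k = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def spearman_permutation_p(x, y):
    """Exact two-sided permutation p for the rank correlation (small n)."""
    rho_obs = abs(spearman_exhaustive(x, y))
    count = total = 0
    for perm in permutations(y):
        total += 1
        if abs(spearman_exhaustive(x, perm)) >= rho_obs - 1e-12:
            count += 1
    return count / total


def icc21_mean_squares(ref, cur):
    """ICC(2,1) from explicitly written two-way ANOVA sums of squares."""
    n = len(ref)
    k = 2
    data = [[ref[i], cur[i]] for i in range(n)]
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((data[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def random_ankle_fixture(rng, n_frames):
    """A random gait-like depth series mixing holds, ramps and noise."""
    z = []
    depth = float(rng.uniform(2.0, 5.0))
    while len(z) < n_frames:
        kind = rng.integers(0, 3)
        length = int(rng.integers(1, 12))
        if kind == 0:          # hold
            z.extend([depth] * length)
        elif kind == 1:        # ramp toward sensor
            step = float(rng.uniform(0.005, 0.08))
            for _ in range(length):
                depth -= step
                z.append(depth)
        else:                  # jitter around current depth
            z.extend((depth + rng.normal(0, 0.004, length)).tolist())
    return np.array(z[:n_frames])
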