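"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: exhaustive enumeration
for the nonparametric tests, direct ECDF evaluation for KS, quadratic-time
window scans for the local-range map, and textbook sums of squares for the
balanced two-way ANOVA.
"""

import itertools

import numpy as np
from scipy.stats import rankdata


def signed_rank_exact_p(day0, day4):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    diffs = np.asarray(day4, float) - np.asarray(day0, float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    ranks = rankdata(np.abs(diffs))
    w_plus_obs = ranks[diffs > 0].sum()
    dist = np.array(
        [np.dot(signs, ranks) for signs in itertools.product([0, 1], repeat=n)]
    )
    p_le = np.mean(dist <= w_plus_obs)
    p_ge = np.mean(dist >= w_plus_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def rank_sum_exact_p(a, b):
    """Exact two-sided rank-sum p by enumerating all rank assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    obs = ranks[: a.size].sum()
    dist = np.array([sum(c) for c in itertools.combinations(ranks, a.size)])
    p_le = np.mean(dist <= obs)
    p_ge = np.mean(dist >= obs)
    return min(1.0, 2 * min(p_le, p_ge))


def ks_statistic_exhaustive(a, b):
    """sup |ECDF_a - ECDF_b| evaluated at every pooled point."""
    a, b = np.sort(a), np.sort(b)
    d = 0.0
    for x in np.concatenate([a, b]):
        d = max(d, abs(np.mean(a <= x) - np.mean(b <= x)))
    return d


def brute_force_local_range(image, s, shape="square"):
    """Exhaustive per-pixel max - min over the (truncated) window."""
    h, w = image.shape
    r = s // 2
    out = np.empty_like(image, dtype=float)
    if shape == "disk":
        dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
        mask = dy**2 + dx**2 <= r**2
    for i in range(h):
        for j in range(w):
            y0, y1 = max(0, i - r), min(h, i + r + 1)
            x0, x1 = max(0, j - r), min(w, j + r + 1)
            win = image[y0:y1, x0:x1]
            if shape == "disk":
                sub = mask[r - (i - y0) : r + (y1 - i), r - (j - x0) : r + (x1 - j)]
                win = win[sub]
            out[i, j] = win.max() - win.min()
    return out


def anova_2x2_hand(y):
    """Textbook balanced two-way ANOVA F statistics; y[a][b] = replicates."""
    y = np.asarray(y, float)  # shape (2, 2, n)
    n = y.shape[2]
    grand = y.mean()
    ss_a = 2 * n * ((y.mean(axis=(1, 2)) - grand) ** 2).sum()
    ss_b = 2 * n * ((y.mean(axis=(0, 2)) - grand) ** 2).sum()
    cell = y.mean(axis=2)
    ss_ab = n * (
        (cell - y.mean(axis=(1, 2))[:, None] - y.mean(axis=(0, 2))[None, :] + grand) ** 2
    ).sum()
    ss_e = ((y - cell[:, :, None]) ** 2).sum()
    df_e = 4 * (n - 1)
    return {
        "group": ss_a / (ss_e / df_e),
        "time": ss_b / (ss_e / df_e),
        "group:time": ss_ab / (ss_e / df_e),
    }
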