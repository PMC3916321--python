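"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the vectorized code paths of the package: ranking
uses scipy directly per series, neighborhoods are gathered by explicit
triple loops, and Kendall's W is evaluated from its definition.
"""

import itertools

import numpy as np
from scipy.stats import rankdata, spearmanr


def naive_kendall_w(ranks):
    """Direct evaluation of W = 12*S / (k^2 (n^3 - n))."""
    ranks = np.asarray(ranks, float)
    n, k = ranks.shape
    row_sums = ranks.sum(axis=1)
    s = ((row_sums - k * (n + 1) / 2.0) ** 2).sum()
    return min(1.0, 12.0 * s / (k * k * (n**3 - n)))


def naive_reho(data, mask, offsets):
    """Triple-loop ReHo map: gather in-mask neighbors, rank, evaluate W."""
    out = np.zeros(mask.shape)
    shape = mask.shape
    for i, j, k in itertools.product(*map(range, shape)):
        if not mask[i, j, k]:
            continue
        series = [data[i, j, k]]
        for dx, dy, dz in offsets:
            x, y, z = i + dx, j + dy, k + dz
            if (
                0 <= x < shape[0]
                and 0 <= y < shape[1]
                and 0 <= z < shape[2]
                and mask[x, y, z]
            ):
                series.append(data[x, y, z])
        if len(series) < 2:
            continue
        ranks = np.stack([rankdata(s) for s in series], axis=1)
        out[i, j, k] = naive_kendall_w(ranks)
    return out


def mean_pairwise_spearman(series_matrix):
    """Average Spearman rho over all pairs of columns (brute force)."""
    k = series_matrix.shape[1]
    rhos = [
        spearmanr(series_matrix[:, a], series_matrix[:, b]).statistic
        for a, b in itertools.combinations(range(k), 2)
    ]
    return float(np.mean(rhos))
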