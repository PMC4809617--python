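"""Naive from-definition implementations used as independent oracles.

Everything here is written with plain Python loops directly from the
statistic definitions, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def pairwise_pi(mat) -> float:
    """Mean number of pairwise differences (loop over all pairs)."""
    mat = np.asarray(mat)
    n = mat.shape[0]
    total = 0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(mat[i] != mat[j]))
            npairs += 1
    return total / npairs if npairs else 0.0


def tajimas_d_raw(mat) -> float:
    mat = np.asarray(mat)
    n, S = mat.shape
    if S == 0:
        return 0.0
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return 0.0
    return (pairwise_pi(mat) - S / a1) / math.sqrt(var)


def folded_sfs(mat, n_bins) -> np.ndarray:
    mat = np.asarray(mat)
    n = mat.shape[0]
    counts = np.zeros(n_bins)
    for j in range(mat.shape[1]):
        d = int(mat[:, j].sum())
        minor = min(d, n - d)
        if minor >= 1:
            counts[minor - 1] += 1
    s = counts.sum()
    return counts / s if s else counts


def bet_histogram(positions, n_sites_in_subregion, intervals) -> np.ndarray:
    """Gap histogram: 16 bins of width 20 starting at 0, last open;
    gaps between consecutive sites within each contiguous interval,
    counts divided by the subregion site count."""
    counts = np.zeros(16)
    for (a, b) in intervals:
        pos = sorted(p for p in positions if a <= p < b)
        for k in range(len(pos) - 1):
            gap = pos[k + 1] - pos[k]
            idx = min(int(gap // 20), 15)
            counts[idx] += 1
    if n_sites_in_subregion == 0:
        return counts
    return counts / n_sites_in_subregion


def ibs_histogram(mat, positions, intervals) -> np.ndarray:
    """IBS tract lengths for every haplotype pair, every interval.
    30 bins with starts i*5000/29, last open-ended."""
    mat = np.asarray(mat)
    n = mat.shape[0]
    edges = [i * 5000.0 / 29 for i in range(30)]

    def bin_of(length):
        k = 0
        for idx in range(30):
            if length >= edges[idx]:
                k = idx
        return k

    counts = np.zeros(30)
    total = 0
    for (a, b) in intervals:
        cols = [j for j, p in enumerate(positions) if a <= p < b]
        for i in range(n):
            for j in range(i + 1, n):
                mism = [positions[c] for c in cols if mat[i, c] != mat[j, c]]
                if not mism:
                    tracts = [b - a]
                else:
                    tracts = [mism[0] - a]
                    for k in range(len(mism) - 1):
                        tracts.append(mism[k + 1] - mism[k] - 1)
                    tracts.append(b - mism[-1] - 1)
                for t in tracts:
                    counts[bin_of(t)] += 1
                    total += 1
    return counts / total if total else counts


def ld_histogram(mat, positions, close_intervals, other_intervals,
                 same_subregion) -> np.ndarray:
    """D_AB histogram between close-subregion sites and other-subregion
    sites (site pairs i<j when the two subregions coincide)."""
    mat = np.asarray(mat)
    n = mat.shape[0]
    close = [j for j, p in enumerate(positions)
             if any(a <= p < b for a, b in close_intervals)]
    other = [j for j, p in enumerate(positions)
             if any(a <= p < b for a, b in other_intervals)]
    if same_subregion:
        pairs = [(close[i], close[j]) for i in range(len(close))
                 for j in range(i + 1, len(close))]
    else:
        pairs = [(c, o) for c in close for o in other]
    if not pairs:
        return np.zeros(16)
    width = 0.25 / 14
    counts = np.zeros(16)
    for (ca, cb) in pairs:
        pa = mat[:, ca].sum() / n
        pb = mat[:, cb].sum() / n
        pab = np.sum((mat[:, ca] == 1) & (mat[:, cb] == 1)) / n
        d = pab - pa * pb
        if d < -0.05:
            k = 0
        elif d >= 0.2:
            k = 15
        else:
            k = 1 + int((d + 0.05) / width)
            k = min(k, 14)
        counts[k] += 1
    return counts / counts.sum()


def h_stats(mat) -> tuple[float, float, float]:
    mat = np.asarray(mat)
    if mat.shape[1] == 0:
        return 1.0, 1.0, 0.0
    freqs = Counter(tuple(row) for row in mat)
    p = sorted((c / mat.shape[0] for c in freqs.values()), reverse=True)
    h1 = sum(x * x for x in p)
    h12 = (p[0] + p[1]) ** 2 + sum(x * x for x in p[2:]) if len(p) > 1 else h1
    h2 = h1 - p[0] ** 2
    return h1, h12, h2


def watterson_expected_s(n, theta) -> float:
    return theta * sum(1.0 / i for i in range(1, n))


def random_region(rng, n, S, region_len=1000):
    """A random region whose every column is segregating."""
    from demosel.simdata import HaplotypeRegion

    positions = np.sort(rng.choice(region_len, size=S, replace=False))
    mat = np.zeros((n, S), dtype=np.uint8)
    for j in range(S):
        d = int(rng.integers(1, n))
        rows = rng.choice(n, size=d, replace=False)
        mat[rows, j] = 1
    return HaplotypeRegion(mat, positions, region_len)
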