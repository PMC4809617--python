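"""The 345-statistic featurizer.

Each region of length L is divided into three subregions centred on the
(potentially) selected site: *close* [0.4L, 0.6L), *mid* [0.2L, 0.4L) u
[0.6L, 0.8L) and *far* [0, 0.2L) u [0.8L, L).  Within each subregion the
following statistics are computed, every one normalized into [0, 1]:

* S: segregating sites, truncated at S_max = 5000 and divided by S_max;
* Tajima's D with the standard (1989) variance estimator, mapped through
  clamp((D + 3) / 6, 0, 1);
* folded site frequency spectrum: eta_i = number of sites whose minor
  allele occurs i times, i = 1..n//2, normalized to sum to 1 (50 bins at
  n = 100);
* BET, the distribution of lengths between consecutive segregating
  sites: 16 bins starting at 0, 20, ..., 300 (last bin open-ended),
  counts divided by S;
* IBS, the identity-by-state tract length distribution over all
  haplotype pairs: 30 bins with starts equally spaced from 0 to 5000
  (last bin open-ended), normalized by the tract count;
* LD, the distribution of D_AB = p_AB - p_A * p_B between one site in
  the close subregion and one site in the given subregion: 16 bins --
  (-inf, -0.05), 14 equal bins spanning [-0.05, 0.2), and [0.2, inf) --
  normalized by the pair count.

H1, H12 and H2 haplotype-homozygosity statistics are computed over the
close subregion only.  Total: 3*(1 + 1 + 50 + 16 + 30 + 16) + 3 = 345.

Conventions for degenerate inputs (chosen for boundedness/continuity):
raw Tajima's D is 0 when S = 0 (normalized value 0.5); SFS, BET and LD
blocks are all-zero when undefined; identical haplotype pairs contribute
full-subregion-length IBS tracts, so the IBS block is defined whenever
n >= 2; the H statistics are (1, 1, 0) when the close subregion has no
segregating sites.

For regions carrying a missing mask, sites with fewer than n non-missing
calls are dropped, per-site counts use the first n non-missing calls,
and pairwise statistics (pi, IBS, LD) use pairwise-complete observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

S_MAX = 5000.0
D_MIN, D_MAX = -3.0, 3.0
N_BET_BINS = 16
N_IBS_BINS = 30
N_LD_BINS = 16

BET_EDGES = np.append(np.arange(N_BET_BINS) * 20.0, np.inf)
IBS_EDGES = np.append(np.arange(N_IBS_BINS) * (5000.0 / (N_IBS_BINS - 1)), np.inf)
LD_EDGES = np.concatenate([[-np.inf, -0.05],
                           -0.05 + (0.25 / 14.0) * np.arange(1, 14),
                           [0.2, np.inf]])

SUBREGIONS = ("close", "mid", "far")


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class SubregionLayout:
    """bp intervals (half-open) of the close/mid/far subregions."""

    region_len: int

    def intervals(self, name: str) -> list[tuple[int, int]]:
        L = self.region_len
        cut = [0, round(0.2 * L), round(0.4 * L), round(0.6 * L),
               round(0.8 * L), L]
        if name == "close":
            return [(cut[2], cut[3])]
        if name == "mid":
            return [(cut[1], cut[2]), (cut[3], cut[4])]
        if name == "far":
            return [(cut[0], cut[1]), (cut[4], cut[5])]
        raise LayoutError(f"unknown subregion {name!r}")


def _interval_site_slice(positions: np.ndarray, a: int, b: int) -> slice:
    lo = int(np.searchsorted(positions, a, side="left"))
    hi = int(np.searchsorted(positions, b, side="left"))
    return slice(lo, hi)


def _subregion_cols(region, name: str) -> list[slice]:
    layout = SubregionLayout(region.region_len)
    return [_interval_site_slice(region.positions, a, b)
            for a, b in layout.intervals(name)]


def _site_counts(region, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(derived count, called count) per site, honouring the missing mask
    and the first-n-non-missing downsampling rule."""
    n = region.n
    sub = region.alleles[:, cols]
    if region.missing is None:
        return sub.sum(axis=0).astype(np.int64), np.full(sub.shape[1], n)
    miss = region.missing[:, cols]
    d = np.zeros(sub.shape[1], dtype=np.int64)
    m = np.zeros(sub.shape[1], dtype=np.int64)
    for j in range(sub.shape[1]):
        called = np.flatnonzero(~miss[:, j])[:n]
        d[j] = int(sub[called, j].sum())
        m[j] = len(called)
    return d, m


def _usable_sites(region, name: str) -> np.ndarray:
    """Column indices of usable segregating sites in a subregion (sites
    with insufficient non-missing calls dropped)."""
    idx = np.concatenate([np.arange(s.start, s.stop)
                          for s in _subregion_cols(region, name)])
    if region.missing is not None and idx.size:
        called = (~region.missing[:, idx]).sum(axis=0)
        idx = idx[called >= region.n]
    return idx.astype(np.int64)


def seg_sites_stat(region, subregion: str) -> float:
    """min(S, 5000)/5000 for the subregion."""
    S = _usable_sites(region, subregion).size
    return min(S, S_MAX) / S_MAX


@lru_cache(maxsize=64)
def _tajima_constants(n: int):
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def _pairwise_pi(region, idx: np.ndarray) -> float:
    """Mean pairwise difference count over the given sites."""
    if idx.size == 0:
        return 0.0
    if region.missing is None:
        n = region.n
        d = region.alleles[:, idx].sum(axis=0).astype(float)
        return float(np.sum(2.0 * d * (n - d)) / (n * (n - 1)))
    # pairwise-complete: per site, diffs among called samples
    total = 0.0
    for j in idx:
        called = ~region.missing[:, j]
        m = int(called.sum())
        if m < 2:
            continue
        d = int(region.alleles[called, j].sum())
        total += 2.0 * d * (m - d) / (m * (m - 1))
    return total


def tajimas_d(region, subregion: str, *, raw: bool = False) -> float:
    """Tajima's D over the subregion, normalized to [0,1] unless raw."""
    if region.n < 2:
        raise LayoutError("Tajima's D needs n >= 2")
    idx = _usable_sites(region, subregion)
    S = idx.size
    if S == 0:
        D = 0.0
    else:
        a1, e1, e2 = _tajima_constants(region.n)
        var = e1 * S + e2 * S * (S - 1)
        pi = _pairwise_pi(region, idx)
        D = (pi - S / a1) / np.sqrt(var) if var > 0 else 0.0
    if raw:
        return float(D)
    return float(np.clip((D - D_MIN) / (D_MAX - D_MIN), 0.0, 1.0))


def folded_sfs(region, subregion: str, n_bins: int | None = None) -> np.ndarray:
    """Normalized folded SFS (bins i = 1..n//2); all-zero when S = 0."""
    n_bins = n_bins if n_bins is not None else region.n // 2
    idx = _usable_sites(region, subregion)
    out = np.zeros(n_bins)
    if idx.size == 0:
        return out
    d, m = _site_counts(region, idx)
    minor = np.minimum(d, m - d)
    minor = minor[(minor >= 1)]
    if minor.size == 0:
        return out
    counts = np.bincount(np.minimum(minor, n_bins), minlength=n_bins + 1)[1:]
    return counts / counts.sum()


def bet_distribution(region, subregion: str) -> np.ndarray:
    """Distribution of distances between consecutive segregating sites,
    counted per contiguous bp interval of the subregion; counts divided by
    the subregion's segregating-site count S (so the block sums to
    (S-1)/S for a single-interval subregion)."""
    out = np.zeros(N_BET_BINS)
    S_total = 0
    counts = np.zeros(N_BET_BINS)
    for sl in _subregion_cols(region, subregion):
        idx = np.arange(sl.start, sl.stop)
        if region.missing is not None and idx.size:
            called = (~region.missing[:, idx]).sum(axis=0)
            idx = idx[called >= region.n]
        S_total += idx.size
        if idx.size >= 2:
            gaps = np.diff(region.positions[idx]).astype(float)
            counts += np.histogram(gaps, bins=BET_EDGES)[0]
    if S_total == 0:
        return out
    return counts / S_total


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = np.triu_indices(n, k=1)
    return ia, ib


def _ibs_accumulate(diff_pos: np.ndarray, pair_of: np.ndarray, n_pairs: int,
                    a: int, b: int, counts: np.ndarray) -> int:
    """Histogram IBS tract lengths for one interval [a, b) given, per pair,
    the sorted positions where the pair differs.  Returns the tract count."""
    total = 0
    if diff_pos.size == 0:
        counts[np.searchsorted(IBS_EDGES, b - a, side="right") - 1] += n_pairs
        return n_pairs
    # boundaries between pairs in the flattened (pair-major) arrays
    first = np.flatnonzero(np.r_[True, pair_of[1:] != pair_of[:-1]])
    last = np.r_[first[1:] - 1, diff_pos.size - 1]
    n_with = first.size
    # interior tracts between consecutive mismatches of the same pair
    interior_mask = np.ones(diff_pos.size, bool)
    interior_mask[first] = False
    if interior_mask.any():
        prev = np.flatnonzero(interior_mask) - 1
        lens = diff_pos[interior_mask] - diff_pos[prev] - 1
        counts += np.histogram(lens, bins=IBS_EDGES)[0]
        total += lens.size
    lead = diff_pos[first] - a
    trail = b - diff_pos[last] - 1
    counts += np.histogram(lead, bins=IBS_EDGES)[0]
    counts += np.histogram(trail, bins=IBS_EDGES)[0]
    total += 2 * n_with
    n_without = n_pairs - n_with
    if n_without:
        counts[np.searchsorted(IBS_EDGES, b - a, side="right") - 1] += n_without
        total += n_without
    return total


def ibs_distribution(region, subregion: str) -> np.ndarray:
    """IBS tract length distribution pooled over all haplotype pairs.

    Tracts are maximal runs identical at every (usable) segregating site,
    delimited exclusively by mismatch sites and by the bp boundaries of
    each contiguous interval of the subregion.
    """
    n = region.n
    counts = np.zeros(N_IBS_BINS)
    total = 0
    ia, ib = _pair_indices(n)
    for sl, (a, b) in zip(_subregion_cols(region, subregion),
                          SubregionLayout(region.region_len).intervals(subregion)):
        idx = np.arange(sl.start, sl.stop)
        if region.missing is not None and idx.size:
            called = (~region.missing[:, idx]).sum(axis=0)
            idx = idx[called >= region.n]
        G = region.alleles[:, idx]
        D = G[ia] != G[ib]
        if region.missing is not None and idx.size:
            Mk = region.missing[:, idx]
            D &= ~(Mk[ia] | Mk[ib])  # pairwise-complete mismatches only
        prow, pcol = np.nonzero(D)
        total += _ibs_accumulate(region.positions[idx][pcol], prow,
                                 len(ia), a, b, counts)
    if total == 0:
        return counts
    return counts / total


def ld_distribution(region, subregion: str, *, pair_cap: int = 100_000,
                    pair_cap_seed: int = 0) -> np.ndarray:
    """Distribution of D_AB between close-subregion sites and sites of the
    given subregion (derived-allele coding); all-zero when no pairs."""
    close_idx = _usable_sites(region, "close")
    other_idx = _usable_sites(region, subregion)
    out = np.zeros(N_LD_BINS)
    if close_idx.size == 0 or other_idx.size == 0:
        return out
    if subregion == "close":
        ia, ib = np.triu_indices(close_idx.size, k=1)
        pairs_a, pairs_b = close_idx[ia], close_idx[ib]
    else:
        pairs_a = np.repeat(close_idx, other_idx.size)
        pairs_b = np.tile(other_idx, close_idx.size)
    if pairs_a.size == 0:
        return out
    if pairs_a.size > pair_cap:
        sel = np.random.default_rng(pair_cap_seed).choice(
            pairs_a.size, size=pair_cap, replace=False)
        pairs_a, pairs_b = pairs_a[sel], pairs_b[sel]
    X = region.alleles
    if region.missing is None:
        n = region.n
        pA = X[:, pairs_a].sum(axis=0) / n
        pB = X[:, pairs_b].sum(axis=0) / n
        pAB = (X[:, pairs_a] & X[:, pairs_b]).sum(axis=0) / n
        d = pAB - pA * pB
    else:
        d = np.empty(pairs_a.size)
        for k in range(pairs_a.size):
            called = ~(region.missing[:, pairs_a[k]]
                       | region.missing[:, pairs_b[k]])
            m = int(called.sum())
            if m == 0:
                d[k] = 0.0
                continue
            xa = X[called, pairs_a[k]]
            xb = X[called, pairs_b[k]]
            d[k] = (xa & xb).sum() / m - (xa.sum() / m) * (xb.sum() / m)
    counts = np.histogram(d, bins=LD_EDGES)[0]
    return counts / counts.sum()


def h_statistics(region) -> tuple[float, float, float]:
    """Garud's H1, H12, H2 over close-subregion haplotypes.

    With sorted haplotype class frequencies p1 >= p2 >= ...:
    H1 = sum p_i^2, H12 = (p1 + p2)^2 + sum_{i>=3} p_i^2, H2 = H1 - p1^2.
    Returns (1, 1, 0) when the close subregion has no segregating sites.
    """
    idx = _usable_sites(region, "close")
    if idx.size == 0:
        return 1.0, 1.0, 0.0
    G = region.alleles[:, idx]
    if region.missing is not None:
        complete = ~region.missing[:, idx].any(axis=1)
        G = G[complete]
        if G.shape[0] == 0:
            return 1.0, 1.0, 0.0
    _, counts = np.unique(G, axis=0, return_counts=True)
    p = np.sort(counts / G.shape[0])[::-1]
    h1 = float(np.sum(p**2))
    if p.size >= 2:
        h12 = float((p[0] + p[1])**2 + np.sum(p[2:]**2))
    else:
        h12 = h1
    h2 = h1 - float(p[0]**2)
    return h1, h12, h2


@lru_cache(maxsize=8)
def feature_names(n: int = 100) -> tuple[str, ...]:
    names: list[str] = []
    for sub in SUBREGIONS:
        names.append(f"S_{sub}")
        names.append(f"D_{sub}")
        names.extend(f"SFS_{sub}_{i}" for i in range(1, n // 2 + 1))
        names.extend(f"BET_{sub}_{j}" for j in range(1, N_BET_BINS + 1))
        names.extend(f"IBS_{sub}_{m}" for m in range(1, N_IBS_BINS + 1))
        names.extend(f"LD_{sub}_{j}" for j in range(1, N_LD_BINS + 1))
    names.extend(["H1", "H12", "H2"])
    return tuple(names)


def feature_blocks(n: int = 100) -> dict[str, np.ndarray]:
    """Index arrays of each statistic family within the feature vector."""
    names = feature_names(n)
    out: dict[str, np.ndarray] = {}
    for fam in ("S", "D", "SFS", "BET", "IBS", "LD"):
        out[fam] = np.array([i for i, nm in enumerate(names)
                             if nm.split("_")[0] == fam])
    out["H"] = np.array([i for i, nm in enumerate(names)
                         if nm in ("H1", "H12", "H2")])
    return out


def featurize(region, *, expected_n: int = 100, pair_cap: int = 100_000,
              pair_cap_seed: int = 0) -> np.ndarray:
    """Fixed-order feature vector (length 345 at n = 100)."""
    if region.missing is None and region.n != expected_n:
        raise LayoutError(
            f"region has n={region.n}, featurizer configured for "
            f"n={expected_n}; pass expected_n to reconfigure")
    parts: list[np.ndarray] = []
    for sub in SUBREGIONS:
        parts.append(np.array([seg_sites_stat(region, sub),
                               tajimas_d(region, sub)]))
        parts.append(folded_sfs(region, sub, n_bins=expected_n // 2))
        parts.append(bet_distribution(region, sub))
        parts.append(ibs_distribution(region, sub))
        parts.append(ld_distribution(region, sub, pair_cap=pair_cap,
                                     pair_cap_seed=pair_cap_seed))
    parts.append(np.array(h_statistics(region)))
    vec = np.concatenate(parts)
    return np.clip(vec, 0.0, 1.0)


def featurize_many(regions, *, expected_n: int = 100, **kw) -> np.ndarray:
    return np.vstack([featurize(r, expected_n=expected_n, **kw)
                      for r in regions])
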