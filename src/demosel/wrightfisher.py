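"""Rescaled forward Wright-Fisher simulation of haplotype regions.

The population is a set of M haploid sequences evolving in discrete
generations (multinomial reproduction).  Using M = 2N haploid sequences
reproduces the coalescent scaling conventions of ms/msms: pairwise
coalescence time is M generations, theta = 4*N*mu*L = 2*M*u where u is the
per-sequence per-generation mutation rate, and one "coalescent unit" of
time equals 4*N_ref = 2*M_ref generations.

Rescaling by a factor Q divides the population size by Q and multiplies
mu, r and s by Q, which preserves the compound parameters theta, rho and
2Ns that the summary statistics depend on.

Selection models (single biallelic selected site):

* directional (hard/soft sweeps): parents are sampled with probability
  proportional to fitness, 1+s for carriers of the beneficial allele and
  1 otherwise;
* balancing: heterozygote advantage -- mating pairs are sampled at random
  and accepted with probability proportional to the fitness of the
  genotype they form at the selected site (1+s if the two gametes differ,
  1 otherwise).

Recombination is a single crossover per meiosis occurring with
probability r*L; mutation follows the infinite-sites model at rate u per
sequence per generation (new sites at integer bp positions).

Haplotypes are bit-packed (64 segregating sites per uint64 word), which
makes a generation essentially a word-copy per offspring.  Columns are
kept unsorted; a crossover applies a per-column position mask built once
per recombination event.  Bits at column indices >= S are maintained as
zero everywhere.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_RETRIES_EXHAUSTED = 1
STATUS_CAPACITY = 2

NEUTRAL = 0
DIRECTIONAL = 1
BALANCING = 2

_ONE = np.uint64(1)
_DEBRUIJN = np.uint64(0x03F79D71B4CB0A89)
_DB_SHIFT = np.uint64(58)
# index of the lowest set bit: table[(lsb * _DEBRUIJN) >> 58]
_DB_TABLE = np.zeros(64, np.int64)
for _b in range(64):
    _DB_TABLE[(((1 << _b) * 0x03F79D71B4CB0A89) % (1 << 64)) >> 58] = _b
del _b


@njit(cache=True)
def _getbit(H, i, j):
    return (H[i, j >> 6] >> np.uint64(j & 63)) & _ONE


@njit(cache=True)
def _setbit(H, i, j):
    H[i, j >> 6] |= _ONE << np.uint64(j & 63)


@njit(cache=True)
def _col_count(H, M, j):
    c = 0
    w = j >> 6
    sh = np.uint64(j & 63)
    for i in range(M):
        c += int((H[i, w] >> sh) & _ONE)
    return c


@njit(cache=True)
def _count_all_cols(H, M, S, counts):
    """Per-column derived-allele counts by iterating set bits per word."""
    for j in range(S):
        counts[j] = 0
    W = (S + 63) >> 6
    for i in range(M):
        for w in range(W):
            word = H[i, w]
            base = w << 6
            while word:
                lsb = word & (~word + _ONE)
                counts[base + _DB_TABLE[(lsb * _DEBRUIJN) >> _DB_SHIFT]] += 1
                word ^= lsb


@njit(cache=True)
def _cleanup(H, pos, S, M, sel_col, tmp, counts, colmap):
    """Compact away monomorphic columns (keep sel_col regardless); zero
    every bit at column index >= new S.  Returns (new_S, new_sel_col)."""
    _count_all_cols(H, M, S, counts)
    nkeep = 0
    new_sel = -1
    for j in range(S):
        c = counts[j]
        if (0 < c < M) or (j == sel_col):
            if j == sel_col:
                new_sel = nkeep
            colmap[j] = nkeep
            nkeep += 1
        else:
            colmap[j] = -1
    if nkeep == S:
        return S, new_sel
    W_old = (S + 63) >> 6
    W_new = (nkeep + 63) >> 6
    for i in range(M):
        for w in range(W_new):
            tmp[w] = 0
        for w in range(W_old):
            word = H[i, w]
            base = w << 6
            while word:
                lsb = word & (~word + _ONE)
                k = colmap[base + _DB_TABLE[(lsb * _DEBRUIJN) >> _DB_SHIFT]]
                if k >= 0:
                    tmp[k >> 6] |= _ONE << np.uint64(k & 63)
                word ^= lsb
        for w in range(W_new):
            H[i, w] = tmp[w]
        for w in range(W_new, W_old):
            H[i, w] = 0
    for j in range(S):
        if colmap[j] >= 0:
            pos[colmap[j]] = pos[j]
    return nkeep, new_sel


@njit(cache=True)
def _position_taken(pos, S, bp):
    for j in range(S):
        if pos[j] == bp:
            return True
    return False


@njit(cache=True)
def _ensure_word(Ha, Hb, Mall, j):
    """Zero the word containing column j in BOTH buffers when the column
    occupies a fresh word.  Generations only copy words < ceil(S/64), so
    words beyond that carry stale bits from earlier, wider states; they
    must be cleared before new columns move into them."""
    if (j & 63) == 0:
        w = j >> 6
        for i in range(Mall):
            Ha[i, w] = 0
            Hb[i, w] = 0


@njit(cache=True)
def _mutate(H, other, pos, S, M, Mall, u, L, cap):
    """Add Poisson(M*u) new infinite-sites mutations.  Returns new S or -1
    if column capacity is exhausted."""
    nm = np.random.poisson(M * u)
    for _ in range(nm):
        if S >= cap:
            return -1
        bp = np.random.randint(L)
        if _position_taken(pos, S, bp):
            continue  # infinite sites at bp resolution: drop the collision
        _ensure_word(H, other, Mall, S)
        _setbit(H, np.random.randint(M), S)
        pos[S] = bp
        S += 1
    return S


@njit(cache=True)
def _next_generation(cur, nxt, pos, S, M_cur, M_new, rL, L,
                     sel_col, s, sel_mode, maskbuf, carriers, others):
    """Write the next generation (M_new rows) into nxt from cur."""
    W = (S + 63) >> 6
    if sel_mode == NEUTRAL or sel_col < 0:
        # fast path: vectorized parent draws, Binomial(M, rL) crossovers
        pars = np.random.randint(0, M_cur, M_new)
        for o in range(M_new):
            p1 = pars[o]
            for w in range(W):
                nxt[o, w] = cur[p1, w]
        k = np.random.binomial(M_new, rL)
        for _ in range(k):
            o = np.random.randint(M_new)
            p1 = pars[o]
            p2 = np.random.randint(M_cur)
            if p1 == p2:
                continue
            cp = np.random.randint(L)
            for w in range(W):
                maskbuf[w] = 0
            for c in range(S):
                if pos[c] < cp:
                    maskbuf[c >> 6] |= _ONE << np.uint64(c & 63)
            for w in range(W):
                nxt[o, w] = (cur[p1, w] & maskbuf[w]) | (cur[p2, w] & ~maskbuf[w])
        return
    ncar = 0
    noth = 0
    pcar = 0.0
    if sel_mode == DIRECTIONAL and sel_col >= 0:
        for i in range(M_cur):
            if _getbit(cur, i, sel_col):
                carriers[ncar] = i
                ncar += 1
            else:
                others[noth] = i
                noth += 1
        wtot = noth + ncar * (1.0 + s)
        if wtot > 0.0:
            pcar = ncar * (1.0 + s) / wtot

    for o in range(M_new):
        recomb = np.random.random() < rL
        if sel_mode == BALANCING and sel_col >= 0:
            i = np.random.randint(M_cur)
            j = np.random.randint(M_cur)
            while True:
                if _getbit(cur, i, sel_col) != _getbit(cur, j, sel_col):
                    break
                if np.random.random() < 1.0 / (1.0 + s):
                    break
                i = np.random.randint(M_cur)
                j = np.random.randint(M_cur)
            if np.random.random() < 0.5:
                p1, p2 = i, j
            else:
                p1, p2 = j, i
        elif sel_mode == DIRECTIONAL and sel_col >= 0 and ncar > 0:
            if np.random.random() < pcar:
                p1 = carriers[np.random.randint(ncar)]
            else:
                p1 = others[np.random.randint(noth)]
            if recomb:
                if np.random.random() < pcar:
                    p2 = carriers[np.random.randint(ncar)]
                else:
                    p2 = others[np.random.randint(noth)]
            else:
                p2 = p1
        else:
            p1 = np.random.randint(M_cur)
            p2 = np.random.randint(M_cur) if recomb else p1
        if recomb and p1 != p2:
            cp = np.random.randint(L)
            for w in range(W):
                maskbuf[w] = 0
            for c in range(S):
                if pos[c] < cp:
                    maskbuf[c >> 6] |= _ONE << np.uint64(c & 63)
            for w in range(W):
                nxt[o, w] = (cur[p1, w] & maskbuf[w]) | (cur[p2, w] & ~maskbuf[w])
        else:
            for w in range(W):
                nxt[o, w] = cur[p1, w]


@njit(cache=True)
def _sample_rows(M, n):
    """n distinct row indices via partial Fisher-Yates."""
    idx = np.arange(M)
    for i in range(n):
        j = i + np.random.randint(M - i)
        t = idx[i]
        idx[i] = idx[j]
        idx[j] = t
    return idx[:n]


@njit(cache=True)
def _simulate_kernel(seed, M3, M2, M1, g_burn, g2, g1, onset_gens,
                     u, rL, L, sel_mode, s, init_copies, sel_pos,
                     n, cap, max_retries, clean_every):
    np.random.seed(seed)
    Mmax = max(M3, max(M2, M1))
    cap_w = (cap + 63) >> 6
    A = np.zeros((Mmax, cap_w), np.uint64)
    B = np.zeros((Mmax, cap_w), np.uint64)
    pos = np.zeros(cap, np.int64)
    maskbuf = np.zeros(cap_w, np.uint64)
    tmp = np.zeros(cap_w, np.uint64)
    counts = np.zeros(cap, np.int64)
    colmap = np.zeros(cap, np.int64)
    carriers = np.empty(Mmax, np.int64)
    others = np.empty(Mmax, np.int64)
    S = 0
    flip = 0  # 0: current is A, 1: current is B

    # --- neutral epochs: ancient burn-in, bottleneck, recent (pre-onset) ---
    g1_neutral = g1 - onset_gens if sel_mode != NEUTRAL else g1
    sizes = (M3, M2, M1)
    lengths = (g_burn, g2, g1_neutral)
    M_cur = M3
    gcount = 0
    for e in range(3):
        M_new = sizes[e]
        for _ in range(lengths[e]):
            if flip == 0:
                _next_generation(A, B, pos, S, M_cur, M_new, rL, L, -1, 0.0,
                                 NEUTRAL, maskbuf, carriers, others)
            else:
                _next_generation(B, A, pos, S, M_cur, M_new, rL, L, -1, 0.0,
                                 NEUTRAL, maskbuf, carriers, others)
            flip = 1 - flip
            M_cur = M_new
            cur = A if flip == 0 else B
            oth = B if flip == 0 else A
            S = _mutate(cur, oth, pos, S, M_cur, Mmax, u, L, cap)
            if S < 0:
                return (np.zeros((0, 0), np.uint8), np.zeros(0, np.int64),
                        -1.0, STATUS_CAPACITY, 0)
            gcount += 1
            if gcount % clean_every == 0 or S > cap - 64:
                S, _ = _cleanup(cur, pos, S, M_cur, -1, tmp, counts, colmap)

    cur = A if flip == 0 else B
    S, _ = _cleanup(cur, pos, S, M_cur, -1, tmp, counts, colmap)

    # --- selection phase with retries from a snapshot ---
    end_freq = np.nan
    n_retries = 0
    if sel_mode != NEUTRAL:
        W_snap = (S + 63) >> 6
        snap = cur[:M_cur, :W_snap].copy()
        snap_pos = pos[:S].copy()
        ok = False
        for attempt in range(max_retries):
            n_retries = attempt
            cur = A if flip == 0 else B
            for i in range(M_cur):
                for w in range(W_snap):
                    cur[i, w] = snap[i, w]
                for w in range(W_snap, cap_w):
                    cur[i, w] = 0
            for c in range(S):
                pos[c] = snap_pos[c]
            Ssel = S
            if Ssel >= cap:
                return (np.zeros((0, 0), np.uint8), np.zeros(0, np.int64),
                        -1.0, STATUS_CAPACITY, n_retries)
            # introduce the selected allele on init_copies random backgrounds
            bp = sel_pos
            while _position_taken(pos, Ssel, bp):
                bp = (bp + 1) % L
            _ensure_word(A, B, Mmax, Ssel)
            rows = _sample_rows(M_cur, init_copies)
            for t in range(init_copies):
                _setbit(cur, rows[t], Ssel)
            pos[Ssel] = bp
            sel_col = Ssel
            Ssel += 1

            lost = False
            for _ in range(onset_gens):
                if flip == 0:
                    _next_generation(A, B, pos, Ssel, M_cur, M_cur, rL, L,
                                     sel_col, s, sel_mode, maskbuf,
                                     carriers, others)
                else:
                    _next_generation(B, A, pos, Ssel, M_cur, M_cur, rL, L,
                                     sel_col, s, sel_mode, maskbuf,
                                     carriers, others)
                flip = 1 - flip
                cur = A if flip == 0 else B
                oth = B if flip == 0 else A
                Ssel = _mutate(cur, oth, pos, Ssel, M_cur, Mmax, u, L, cap)
                if Ssel < 0:
                    return (np.zeros((0, 0), np.uint8), np.zeros(0, np.int64),
                            -1.0, STATUS_CAPACITY, n_retries)
                if Ssel > cap - 64:
                    Ssel, sel_col = _cleanup(cur, pos, Ssel, M_cur, sel_col,
                                             tmp, counts, colmap)
                if _col_count(cur, M_cur, sel_col) == 0:
                    lost = True
                    break
            if lost:
                continue
            cnt = _col_count(cur, M_cur, sel_col)
            if cnt > 0:
                end_freq = cnt / M_cur
                S = Ssel
                ok = True
                break
        if not ok:
            return (np.zeros((0, 0), np.uint8), np.zeros(0, np.int64),
                    -1.0, STATUS_RETRIES_EXHAUSTED, n_retries)

    cur = A if flip == 0 else B

    # --- sample n haplotypes, keep columns segregating in the sample ---
    rows = _sample_rows(M_cur, n)
    keep = np.empty(S, np.int64)
    nkeep = 0
    for j in range(S):
        c = 0
        for t in range(n):
            c += int(_getbit(cur, rows[t], j))
        if 0 < c < n:
            keep[nkeep] = j
            nkeep += 1
    kept_pos = np.empty(nkeep, np.int64)
    for t in range(nkeep):
        kept_pos[t] = pos[keep[t]]
    order = np.argsort(kept_pos)
    out = np.empty((n, nkeep), np.uint8)
    out_pos = np.empty(nkeep, np.int64)
    for t in range(nkeep):
        j = keep[order[t]]
        out_pos[t] = pos[j]
        for i in range(n):
            out[i, t] = np.uint8(_getbit(cur, rows[i], j))
    return out, out_pos, end_freq, STATUS_OK, n_retries


def _capacity_guess(M_max: int, u: float) -> int:
    theta_pop = 2.0 * M_max * u
    return max(512, int(6.0 * theta_pop * (np.log(M_max + 1) + 2.0)) + 256)


def run_wright_fisher(*, seed: int, M3: int, M2: int, M1: int,
                      g_burn: int, g2: int, g1: int, onset_gens: int,
                      u: float, rL: float, L: int, sel_mode: int, s: float,
                      init_copies: int, sel_pos: int, n: int,
                      max_retries: int = 1000, clean_every: int = 32):
    """Run the jit kernel, growing column capacity on overflow.

    Returns (alleles, positions, end_freq, n_retries).
    Raises RuntimeError when the selection retry budget is exhausted.
    """
    cap = _capacity_guess(max(M3, M2, M1), u)
    for _ in range(8):
        out, pos, end_freq, status, n_retries = _simulate_kernel(
            seed, M3, M2, M1, g_burn, g2, g1, onset_gens, u, rL, L,
            sel_mode, s, init_copies, sel_pos, n, cap, max_retries,
            clean_every)
        if status == STATUS_CAPACITY:
            cap *= 2
            continue
        if status == STATUS_RETRIES_EXHAUSTED:
            raise RuntimeError(
                f"selection retry budget ({max_retries}) exhausted "
                f"(mode={sel_mode}, s={s}, M1={M1})")
        return out, pos, end_freq, n_retries
    raise RuntimeError("segregating-site capacity kept overflowing")
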