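"""Simulation of training/testing corpora of haplotype regions.

A corpus is a set of demographic histories (three-epoch piecewise-constant
effective population size) sampled from uniform priors; under each history,
equal numbers of regions are simulated for four selection classes:
neutral, hard sweep (positive selection on a de novo mutation), soft sweep
(positive selection on standing variation) and balancing selection
(heterozygote advantage).

Default parameter values describe the reference study conditions: 100-kb
regions of n = 100 haplotypes, N_ref = 100,000, mu = r = 8.4e-9 per bp per
generation, epoch change points t1 = 0.5 and t2 = 5 coalescent units
(units of 4*N_ref generations), selection onset 0.005, selection
coefficients s in {0.01, 0.02, 0.05, 0.1} cycled evenly within each
selected class, soft-sweep/balancing start frequency 0.001, and the
selected site placed uniformly in the middle 20% of the region.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import wrightfisher as wf
from .msformat import read_ms_format, write_ms_format

NEUTRAL, HARD, SOFT, BALANCING = 0, 1, 2, 3
CLASS_NAMES = ("Neutral", "Hard Sweep", "Soft Sweep", "Balancing")

DEFAULT_PRIOR_BOUNDS = ((3.0, 14.0), (0.5, 6.0), (2.0, 10.0))
DEFAULT_S_CHOICES = (0.01, 0.02, 0.05, 0.1)


class ConfigurationError(ValueError):
    pass


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class DemographyParams:
    """Three-epoch history: N_i = lambda_i * N_ref, recent to ancient."""

    lambda1: float
    lambda2: float
    lambda3: float
    N_ref: float = 100_000.0
    t1: float = 0.5   # coalescent units of 4*N_ref generations
    t2: float = 5.0
    mu: float = 8.4e-9
    r: float = 8.4e-9

    def __post_init__(self):
        if not (0 < self.t1 < self.t2):
            raise ConfigurationError("need 0 < t1 < t2")
        if min(self.lambda1, self.lambda2, self.lambda3) <= 0:
            raise ConfigurationError("size scaling factors must be positive")
        if self.mu < 0 or self.r < 0 or self.N_ref <= 0:
            raise ConfigurationError("rates must be non-negative, N_ref positive")

    @property
    def sizes(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2, self.lambda3]) * self.N_ref


@dataclass(frozen=True)
class SelectionParams:
    sel_class: int = NEUTRAL
    s: float = 0.0
    onset: float = 0.005          # coalescent units before present
    init_freq: float | None = None  # None: 1/M for hard, 0.001 for soft/balancing
    sel_pos: int | None = None      # bp; None: drawn in the middle 20%
    end_freq: float = float("nan")  # realized present-day frequency (output)

    def __post_init__(self):
        if self.sel_class not in (NEUTRAL, HARD, SOFT, BALANCING):
            raise ConfigurationError(f"unknown selection class {self.sel_class}")
        if self.sel_class != NEUTRAL and self.s <= 0:
            raise ConfigurationError("selected classes need s > 0")


@dataclass
class HaplotypeRegion:
    """n x S binary haplotype matrix with bp positions (0-based, strictly
    increasing) and optionally the selected-site coordinate and a missing
    mask (True where a call is unknown, used for real data)."""

    alleles: np.ndarray
    positions: np.ndarray
    region_len: int
    sel_pos: int | None = None
    missing: np.ndarray | None = None

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError("positions length must match column count")
        if self.positions.size and (np.any(np.diff(self.positions) <= 0)
                                    or self.positions[0] < 0
                                    or self.positions[-1] >= self.region_len):
            raise ValueError("positions must be strictly increasing in [0, region_len)")

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def num_sites(self) -> int:
        return self.alleles.shape[1]


@dataclass
class RegionRecord:
    region: HaplotypeRegion
    demography: DemographyParams
    selection: SelectionParams
    demography_id: int
    seed: int


@dataclass
class Corpus:
    records: list[RegionRecord]
    master_seed: int
    split: str = "all"

    def __len__(self) -> int:
        return len(self.records)

    @property
    def demography_ids(self) -> np.ndarray:
        return np.array([r.demography_id for r in self.records])

    def groups(self) -> dict[int, list[RegionRecord]]:
        out: dict[int, list[RegionRecord]] = {}
        for r in self.records:
            out.setdefault(r.demography_id, []).append(r)
        return out

    def manifest(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "demography_id": r.demography_id,
                "lambda1": r.demography.lambda1,
                "lambda2": r.demography.lambda2,
                "lambda3": r.demography.lambda3,
                "sel_class": r.selection.sel_class,
                "s": r.selection.s,
                "end_freq": r.selection.end_freq,
                "sel_pos": -1 if r.region.sel_pos is None else r.region.sel_pos,
                "seed": r.seed,
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimOptions:
    """Numerical knobs of the rescaled forward simulator (not biology).

    rescaled_N_ref: the baseline diploid-equivalent size after rescaling
    (the simulated baseline haplotype count is twice this); burn_in_mult:
    ancient-epoch burn-in in multiples of the ancient haplotype count.
    """

    rescaled_N_ref: float = 1000.0
    burn_in_mult: float = 8.0
    max_retries: int = 1000

    def __post_init__(self):
        if self.rescaled_N_ref < 50:
            raise ConfigurationError("rescaled population size must be >= 50")


@dataclass(frozen=True)
class CorpusConfig:
    prior_bounds: tuple = DEFAULT_PRIOR_BOUNDS
    region_len: int = 100_000
    n: int = 100
    demography_defaults: DemographyParams = field(
        default_factory=lambda: DemographyParams(1.0, 1.0, 1.0))
    s_choices: tuple = DEFAULT_S_CHOICES
    onset: float = 0.005
    standing_init_freq: float = 0.001
    options: SimOptions = field(default_factory=SimOptions)


def sample_demography(prior_bounds, rng, defaults: DemographyParams | None = None
                      ) -> DemographyParams:
    """Draw the three size scaling factors independently and uniformly."""
    defaults = defaults or DemographyParams(1.0, 1.0, 1.0)
    lams = []
    for lo, hi in prior_bounds:
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
            raise ConfigurationError(f"invalid prior bounds ({lo}, {hi})")
        lams.append(rng.uniform(lo, hi) if hi > lo else float(lo))
    return dataclasses.replace(defaults, lambda1=lams[0], lambda2=lams[1],
                               lambda3=lams[2])


def simulate_region(demography: DemographyParams, selection: SelectionParams,
                    region_len: int = 100_000, n: int = 100,
                    rng: np.random.Generator | None = None,
                    options: SimOptions = SimOptions(),
                    ) -> tuple[HaplotypeRegion, SelectionParams]:
    """Simulate one region; returns the region and the selection record with
    the realized present-day frequency (end_freq) filled in."""
    if n < 2:
        raise ConfigurationError("need at least 2 haplotypes")
    rng = rng if rng is not None else np.random.default_rng()

    Q = demography.N_ref / options.rescaled_N_ref
    M_ref = int(round(2 * options.rescaled_N_ref))
    M3 = max(2, int(round(demography.lambda3 * M_ref)))
    M2 = max(2, int(round(demography.lambda2 * M_ref)))
    M1 = max(2, int(round(demography.lambda1 * M_ref)))
    if M1 < n:
        raise SimulationError(
            f"sample size n={n} exceeds rescaled present-day population {M1}")

    u = demography.mu * Q * region_len
    rL = min(1.0, demography.r * Q * region_len)
    g_burn = int(round(options.burn_in_mult * M3))
    g2 = max(1, int(round((demography.t2 - demography.t1) * 2 * M_ref)))
    g1 = max(1, int(round(demography.t1 * 2 * M_ref)))

    sel_mode = wf.NEUTRAL
    s_resc = 0.0
    onset_gens = 0
    init_copies = 0
    sel_pos = -1
    if selection.sel_class != NEUTRAL:
        sel_mode = (wf.BALANCING if selection.sel_class == BALANCING
                    else wf.DIRECTIONAL)
        s_resc = selection.s * Q
        onset_gens = max(1, int(round(selection.onset * 2 * M_ref)))
        if onset_gens >= g1:
            raise ConfigurationError("selection onset must fall in the most "
                                     "recent epoch (onset < t1)")
        if selection.init_freq is not None:
            f0 = selection.init_freq
        elif selection.sel_class == HARD:
            f0 = 1.0 / M1
        else:
            f0 = 0.001
        init_copies = max(1, int(round(f0 * M1)))
        if selection.sel_pos is not None:
            sel_pos = int(selection.sel_pos)
        else:
            lo = int(round(0.4 * region_len))
            hi = int(round(0.6 * region_len))
            sel_pos = int(rng.integers(lo, hi))

    seed = int(rng.integers(0, 2**31 - 1))
    try:
        alleles, positions, end_freq, _ = wf.run_wright_fisher(
            seed=seed, M3=M3, M2=M2, M1=M1, g_burn=g_burn, g2=g2, g1=g1,
            onset_gens=onset_gens, u=u, rL=rL, L=int(region_len),
            sel_mode=sel_mode, s=s_resc, init_copies=init_copies,
            sel_pos=sel_pos, n=n, max_retries=options.max_retries)
    except RuntimeError as exc:
        raise SimulationError(str(exc)) from exc

    region = HaplotypeRegion(alleles, positions, int(region_len),
                             sel_pos=None if sel_pos < 0 else sel_pos)
    realized = dataclasses.replace(
        selection, sel_pos=None if sel_pos < 0 else sel_pos,
        end_freq=float(end_freq))
    return region, realized


def generate_corpus(n_demographies: int, regions_per_class: int,
                    config: CorpusConfig = CorpusConfig(),
                    seed: int = 0) -> Corpus:
    """Simulate a corpus of n_demographies x 4 x regions_per_class regions.

    Selection coefficients cycle through config.s_choices within each
    selected class, reproducible given the seed.
    """
    if n_demographies < 1 or regions_per_class < 1:
        raise ConfigurationError("corpus dimensions must be >= 1")
    records: list[RegionRecord] = []
    master = np.random.SeedSequence(seed)
    for d in range(n_demographies):
        dem_ss = np.random.SeedSequence(seed, spawn_key=(d,))
        dem_rng = np.random.default_rng(dem_ss)
        demography = sample_demography(config.prior_bounds, dem_rng,
                                       config.demography_defaults)
        for sel_class in (NEUTRAL, HARD, SOFT, BALANCING):
            for rep in range(regions_per_class):
                reg_ss = np.random.SeedSequence(
                    seed, spawn_key=(d, sel_class, rep))
                reg_rng = np.random.default_rng(reg_ss)
                if sel_class == NEUTRAL:
                    selection = SelectionParams()
                else:
                    s = config.s_choices[rep % len(config.s_choices)]
                    selection = SelectionParams(
                        sel_class=sel_class, s=s, onset=config.onset,
                        init_freq=(None if sel_class == HARD
                                   else config.standing_init_freq))
                try:
                    region, realized = simulate_region(
                        demography, selection, config.region_len, config.n,
                        reg_rng, config.options)
                except SimulationError as exc:
                    raise SimulationError(
                        f"demography {d}, class {sel_class}, rep {rep}: {exc}"
                    ) from exc
                records.append(RegionRecord(
                    region, demography, realized, d,
                    seed=int(reg_ss.generate_state(1)[0] & 0x7FFFFFFF)))
    return Corpus(records, master_seed=seed)


def save_corpus(corpus: Corpus, out_dir: str | Path) -> None:
    """Directory of ms-format files (one per demography) plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for dem_id, records in corpus.groups().items():
        with open(out_dir / f"demography_{dem_id:05d}.ms", "w") as fh:
            write_ms_format([r.region for r in records], fh)
    corpus.manifest().to_csv(out_dir / "manifest.tsv", sep="\t", index=False)


def load_corpus(in_dir: str | Path, region_len: int = 100_000) -> Corpus:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.tsv", sep="\t")
    records: list[RegionRecord] = []
    for dem_id, sub in manifest.groupby("demography_id", sort=True):
        with open(in_dir / f"demography_{dem_id:05d}.ms") as fh:
            regions = read_ms_format(fh, region_len)
        if len(regions) != len(sub):
            raise ValueError(f"demography {dem_id}: manifest/ms file mismatch")
        for region, (_, row) in zip(regions, sub.iterrows()):
            demography = DemographyParams(row["lambda1"], row["lambda2"],
                                          row["lambda3"])
            sel_pos = None if row["sel_pos"] < 0 else int(row["sel_pos"])
            region.sel_pos = sel_pos
            selection = SelectionParams(
                sel_class=int(row["sel_class"]),
                s=float(row["s"]) if row["sel_class"] != NEUTRAL else 0.0,
                sel_pos=sel_pos, end_freq=float(row["end_freq"]))
            records.append(RegionRecord(region, demography, selection,
                                        int(dem_id), int(row["seed"])))
    return Corpus(records, master_seed=-1)
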