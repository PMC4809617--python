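"""Windowed scanning of real phased haplotype alignments.

Real data enter as a plain haplotype matrix (one row per haplotype,
values 0/1/N over segregating sites) with a bp positions sidecar.  Each
chromosome is partitioned into 20-kb windows; the model is run on groups
of five consecutive windows (one 100-kb model region), sliding by one
window, and the selection classification is attributed to the middle
window of each group.  Within each group, samples are sorted by missing
data and the 100 most complete are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simdata import HaplotypeRegion

logger = logging.getLogger(__name__)

MISSING = 2  # matrix code for an unknown call ("N")


@dataclass(frozen=True)
class WindowPlan:
    window_len: int = 20_000
    group_windows: int = 5
    chromosome: str = ""

    @property
    def step(self) -> int:
        return self.window_len

    @property
    def group_span(self) -> int:
        return self.window_len * self.group_windows


@dataclass
class WindowGroup:
    start: int
    end: int
    middle_start: int
    middle_end: int
    region: HaplotypeRegion
    chromosome: str = ""


def parse_haplotype_matrix(lines) -> np.ndarray:
    """Rows of 0/1/N characters -> uint8 matrix with MISSING for N."""
    table = {"0": 0, "1": 1, "N": MISSING, "n": MISSING, "?": MISSING}
    rows = []
    for i, line in enumerate(lines):
        line = line.strip()
        if not line:
            continue
        try:
            rows.append([table[c] for c in line])
        except KeyError as exc:
            raise ValueError(f"row {i + 1}: unexpected character {exc}") from None
    mat = np.asarray(rows, dtype=np.uint8)
    if mat.ndim != 2:
        raise ValueError("haplotype rows have unequal lengths")
    return mat


def plan_groups(total_len: int, plan: WindowPlan) -> list[tuple[int, int, int, int]]:
    """(start, end, middle_start, middle_end) of each complete group."""
    out = []
    start = 0
    while start + plan.group_span <= total_len:
        mid_off = (plan.group_windows // 2) * plan.window_len
        out.append((start, start + plan.group_span,
                    start + mid_off, start + mid_off + plan.window_len))
        start += plan.step
    return out


def select_samples(matrix: np.ndarray, n_keep: int = 100) -> np.ndarray:
    """Indices of the n_keep most complete rows (stable sort by missing
    count, so fully missing samples are never retained ahead of any
    sample with data)."""
    miss = (matrix == MISSING).sum(axis=1)
    return np.argsort(miss, kind="stable")[:n_keep]


def window_real_data(matrix: np.ndarray, positions: np.ndarray,
                     total_len: int, plan: WindowPlan = WindowPlan(),
                     n_keep: int = 100) -> list[WindowGroup]:
    """Cut an alignment into 100-kb groups ready for the featurizer.

    Groups that would extend past the end of the contig are skipped (with
    a log entry).  Each group's region uses coordinates relative to the
    group start, so the featurizer's "close" subregion is exactly the
    middle window.
    """
    matrix = np.asarray(matrix, dtype=np.uint8)
    positions = np.asarray(positions, dtype=np.int64)
    if matrix.shape[1] != positions.size:
        raise ValueError("positions length must match matrix columns")
    groups = plan_groups(total_len, plan)
    if total_len % plan.step != 0 or not groups:
        logger.info("contig end beyond %d complete groups skipped "
                    "(total_len=%d)", len(groups), total_len)
    out: list[WindowGroup] = []
    for (a, b, ma, mb) in groups:
        cols = np.flatnonzero((positions >= a) & (positions < b))
        sub = matrix[:, cols]
        keep = select_samples(sub, n_keep)
        sub = sub[keep]
        miss = sub == MISSING
        alleles = np.where(miss, 0, sub).astype(np.uint8)
        # drop sites monomorphic among non-missing calls
        called = ~miss
        derived = (alleles * called).sum(axis=0)
        ncalled = called.sum(axis=0)
        seg = (derived > 0) & (derived < ncalled)
        region = HaplotypeRegion(
            alleles[:, seg], positions[cols[seg]] - a, plan.group_span,
            missing=miss[:, seg])
        out.append(WindowGroup(a, b, ma, mb, region, plan.chromosome))
    return out
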