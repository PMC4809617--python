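"""Reading and writing ms/msms-dialect text output.

Replicates are delimited by ``//``, followed by ``segsites: k``, a
``positions:`` line with k fractional coordinates in [0, 1), and one 0/1
row per haplotype.  Fractional positions are mapped to bp as
floor(p * region_len); bp positions are written back as (bp + 0.5) /
region_len so that the floor mapping round-trips exactly.  Duplicate bp
positions after mapping are nudged forward deterministically (+1 bp) to
preserve strict ordering.
"""

from __future__ import annotations

import math
from typing import IO, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .simdata import HaplotypeRegion


class MsParseError(ValueError):
    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def _dedupe_positions(bp: list[int], region_len: int, line_no: int) -> np.ndarray:
    out = []
    prev = -1
    for p in bp:
        p = max(p, prev + 1)
        if p >= region_len:
            raise MsParseError("too many coincident positions near the "
                               "region end to keep strict ordering", line_no)
        out.append(p)
        prev = p
    return np.asarray(out, dtype=np.int64)


def read_ms_format(stream: IO[str], region_len: int) -> list["HaplotypeRegion"]:
    """Parse every replicate in an ms-format stream."""
    from .simdata import HaplotypeRegion

    regions: list[HaplotypeRegion] = []
    lines = stream.read().splitlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        if i >= n_lines or not lines[i].startswith("segsites:"):
            raise MsParseError("expected 'segsites: k' after '//'", i + 1)
        try:
            segsites = int(lines[i].split(":", 1)[1])
        except ValueError:
            raise MsParseError("malformed segsites header", i + 1) from None
        i += 1
        if segsites == 0:
            # empty replicate: no positions line, haplotype rows are empty
            rows = []
            while i < n_lines and lines[i].strip() not in ("", "//"):
                rows.append(lines[i])
                i += 1
            regions.append(HaplotypeRegion(
                np.zeros((max(len(rows), 0), 0), dtype=np.uint8),
                np.zeros(0, dtype=np.int64), region_len))
            continue
        if i >= n_lines or not lines[i].startswith("positions:"):
            raise MsParseError("expected 'positions:' line", i + 1)
        try:
            fracs = [float(tok) for tok in lines[i].split()[1:]]
        except ValueError:
            raise MsParseError("malformed positions line", i + 1) from None
        if len(fracs) != segsites:
            raise MsParseError(
                f"positions count {len(fracs)} != segsites {segsites}", i + 1)
        if any(p < 0 or p >= 1 for p in fracs):
            raise MsParseError("positions must lie in [0, 1)", i + 1)
        bp = _dedupe_positions([math.floor(p * region_len) for p in fracs],
                               region_len, i + 1)
        i += 1
        rows = []
        while i < n_lines and lines[i].strip() not in ("", "//"):
            row = lines[i].strip()
            if len(row) != segsites:
                raise MsParseError(
                    f"haplotype row length {len(row)} != segsites {segsites}",
                    i + 1)
            if set(row) - {"0", "1"}:
                raise MsParseError("haplotype rows must contain only 0/1",
                                   i + 1)
            rows.append([int(c) for c in row])
            i += 1
        if not rows:
            raise MsParseError("replicate has no haplotype rows", i + 1)
        regions.append(HaplotypeRegion(
            np.asarray(rows, dtype=np.uint8), bp, region_len))
    return regions


def write_ms_format(regions, stream: IO[str]) -> None:
    """Emit ms-dialect text for a list of regions."""
    regions = list(regions)
    n = regions[0].n if regions else 0
    stream.write(f"ms {n} {len(regions)}\n0 0 0\n")
    for region in regions:
        stream.write("\n//\n")
        stream.write(f"segsites: {region.num_sites}\n")
        if region.num_sites == 0:
            continue  # like ms: no positions line, no haplotype rows
        fracs = (region.positions + 0.5) / region.region_len
        stream.write("positions: "
                     + " ".join(f"{p:.10f}" for p in fracs) + "\n")
        for row in region.alleles:
            stream.write("".join("1" if v else "0" for v in row) + "\n")
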