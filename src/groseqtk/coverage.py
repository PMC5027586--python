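"""Binned, strand-specific tag coverage.

Coordinates are 0-based half-open base pairs.  Tag counts live on a fixed
bin grid per chromosome; both strands of a chromosome share the grid.
Unstranded data (e.g. ChIP-seq) is represented with both strand slots
pointing at the same array and ``stranded=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StrandedCoverage", "combine_libraries"]


def _as_int_bins(arr) -> np.ndarray:
    out = np.asarray(arr, dtype=np.int64)
    if out.ndim != 1:
        raise ValueError("bin arrays must be one-dimensional")
    if (out < 0).any():
        raise ValueError("tag counts must be non-negative")
    return out


@dataclass
class StrandedCoverage:
    """Per-chromosome (plus, minus) tag counts on a fixed bin grid.

    Parameters
    ----------
    chroms
        Mapping ``chrom -> (plus, minus)`` of int64 bin-count arrays.
    bin_width
        Width of every bin in bp.
    library_id
        Free-form label of the originating library.
    stranded
        False for unstranded assays; then both arrays are identical and
        ``total_tags`` counts the signal once.
    total_tags
        Total mapped tags.  Computed from the bins when omitted.
    """

    chroms: dict[str, tuple[np.ndarray, np.ndarray]]
    bin_width: int
    library_id: str = ""
    stranded: bool = True
    total_tags: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (plus, minus) in self.chroms.items():
            plus = _as_int_bins(plus)
            minus = plus if (not self.stranded and minus is plus) else _as_int_bins(minus)
            if plus.shape != minus.shape:
                raise ValueError(f"strand bin grids differ on {chrom}")
            clean[chrom] = (plus, minus)
        self.chroms = clean
        if self.total_tags < 0:
            self.total_tags = self._sum_tags()
        if self.total_tags < 0:
            raise ValueError("total_tags must be non-negative")

    def _sum_tags(self) -> int:
        total = 0
        for plus, minus in self.chroms.values():
            total += int(plus.sum())
            if self.stranded:
                total += int(minus.sum())
        return total

    # -- grid helpers -------------------------------------------------

    def n_bins(self, chrom: str) -> int:
        return len(self.chroms[chrom][0])

    def chrom_length(self, chrom: str) -> int:
        return self.n_bins(chrom) * self.bin_width

    def strand_array(self, chrom: str, strand: str) -> np.ndarray:
        plus, minus = self.chroms[chrom]
        if strand == "+":
            return plus
        if strand == "-":
            return minus
        raise ValueError(f"unknown strand {strand!r}")

    def same_grid(self, other: "StrandedCoverage") -> bool:
        if self.bin_width != other.bin_width:
            return False
        if set(self.chroms) != set(other.chroms):
            return False
        return all(self.n_bins(c) == other.n_bins(c) for c in self.chroms)

    # -- counting -----------------------------------------------------

    def region_tags(self, chrom: str, start: int, end: int, strand: str) -> float:
        """Tags on one strand over ``[start, end)``, pro-rating partial bins."""
        if end <= start:
            raise ValueError(f"inverted region {chrom}:{start}-{end}")
        if chrom not in self.chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.chrom_length(chrom):
            raise ValueError(
                f"region {chrom}:{start}-{end} outside coverage "
                f"(length {self.chrom_length(chrom)})"
            )
        arr = self.strand_array(chrom, strand)
        b = self.bin_width
        lo, hi = start // b, (end - 1) // b  # first and last overlapped bin
        if lo == hi:
            return float(arr[lo]) * (end - start) / b
        total = 0.0
        # partial leading bin
        total += float(arr[lo]) * ((lo + 1) * b - start) / b
        # full interior bins
        if hi > lo + 1:
            total += float(arr[lo + 1 : hi].sum())
        # partial trailing bin
        total += float(arr[hi]) * (end - hi * b) / b
        return total

    def copy_scaled(self, factor: float) -> dict[str, np.ndarray]:
        """Plus-strand (signal) arrays scaled by ``factor`` as float64."""
        return {c: self.chroms[c][0].astype(np.float64) * factor for c in self.chroms}


def combine_libraries(coverages: list[StrandedCoverage]) -> StrandedCoverage:
    """Bin-wise sum of libraries sharing one grid; total tags are summed."""
    if not coverages:
        raise ValueError("no coverages to combine")
    first = coverages[0]
    for cov in coverages[1:]:
        if not first.same_grid(cov):
            raise ValueError(
                f"bin grids of {first.library_id!r} and {cov.library_id!r} differ"
            )
        if cov.stranded != first.stranded:
            raise ValueError("cannot mix stranded and unstranded coverage")
    chroms = {}
    for chrom in first.chroms:
        plus = sum(c.chroms[chrom][0] for c in coverages)
        minus = sum(c.chroms[chrom][1] for c in coverages)
        chroms[chrom] = (plus, minus)
    return StrandedCoverage(
        chroms=chroms,
        bin_width=first.bin_width,
        library_id="+".join(c.library_id for c in coverages),
        stranded=first.stranded,
        total_tags=sum(c.total_tags for c in coverages),
    )
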