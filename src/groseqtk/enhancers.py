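"""eRNA enhancer calling from de novo transcripts.

Intergenic enhancers: a pair of opposite-strand transcripts, neither
overlapping any gene and both more than ``min_tts_distance`` from every
gene TTS, whose interval hulls are within ``max_pair_gap`` of each other.
Intragenic enhancers: a single short transcript fully inside a gene,
antisense to it, overlapping an H3K4me2 interval by at least 1 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import StrandedCoverage
from .differential import FeatureCounts

logger = logging.getLogger(__name__)

__all__ = [
    "EnhancerCall",
    "call_intergenic",
    "call_intragenic",
    "enhancers_to_frame",
    "quantify_enhancers",
    "enhancer_timepoint_overlap",
]


@dataclass
class EnhancerCall:
    id: str
    kind: str  # "intergenic" | "intragenic"
    chrom: str
    start: int
    end: int
    members: list[dict] = field(default_factory=list)
    host_gene: str | None = None
    classes: dict[str, str] = field(default_factory=dict)  # condition -> class

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_sorted(transcripts: pd.DataFrame) -> None:
    key = transcripts[["chrom", "start"]]
    if not key.equals(key.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)):
        raise ValueError("transcripts must be sorted by (chrom, start)")


def _point_distance(start: int, end: int, point: int) -> int:
    """Distance from half-open interval [start, end) to a point (0 inside)."""
    if point < start:
        return start - point
    if point >= end:
        return point - (end - 1)
    return 0


def _gene_tts(gene) -> int:
    return int(gene.end) - 1 if gene.strand == "+" else int(gene.start)


def _overlaps_any(chrom: str, start: int, end: int, intervals: pd.DataFrame) -> bool:
    sub = intervals[intervals["chrom"] == chrom]
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())


def call_intergenic(
    transcripts: pd.DataFrame,
    genes: pd.DataFrame,
    max_pair_gap: int = 1000,
    min_tts_distance: int = 3000,
) -> list[EnhancerCall]:
    """Pair opposite-strand gene-distal transcripts into bidirectional enhancers.

    Greedy nearest-pair matching on the hull gap (overlap counts as 0);
    ties resolved toward the leftmost partner; each transcript joins at
    most one enhancer.
    """
    _check_sorted(transcripts)
    candidates = []
    for row in transcripts.itertuples(index=False):
        if _overlaps_any(row.chrom, row.start, row.end, genes):
            continue
        sub = genes[genes["chrom"] == row.chrom]
        ok = True
        for gene in sub.itertuples(index=False):
            tts = _gene_tts(gene)
            if _point_distance(row.start, row.end, tts) <= min_tts_distance:
                ok = False
                break
        if ok:
            candidates.append(row)

    pairs = []
    for i, a in enumerate(candidates):
        for j in range(i + 1, len(candidates)):
            b = candidates[j]
            if a.chrom != b.chrom or a.strand == b.strand:
                continue
            gap = max(b.start - a.end, a.start - b.end, 0)
            if gap <= max_pair_gap:
                left = min(a.start, b.start)
                pairs.append((gap, left, i, j))
    pairs.sort()
    used: set[int] = set()
    calls: list[EnhancerCall] = []
    for gap, _left, i, j in pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        a, b = candidates[i], candidates[j]
        span = (min(a.start, b.start), max(a.end, b.end))
        calls.append(
            EnhancerCall(
                id="",
                kind="intergenic",
                chrom=a.chrom,
                start=span[0],
                end=span[1],
                members=[a._asdict(), b._asdict()],
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    for k, call in enumerate(calls):
        call.id = f"inter_{k}"
    return calls


def call_intragenic(
    transcripts: pd.DataFrame,
    genes: pd.DataFrame,
    h3k4me2: pd.DataFrame,
    length_range: tuple[int, int] = (150, 500),
) -> list[EnhancerCall]:
    """Short antisense intragenic transcripts overlapping H3K4me2 intervals.

    A transcript contained in two opposite-strand genes at once is
    ambiguous: it is rejected and logged.
    """
    _check_sorted(transcripts)
    lo, hi = length_range
    calls: list[EnhancerCall] = []
    for row in transcripts.itertuples(index=False):
        length = row.end - row.start
        if not lo <= length <= hi:
            continue
        sub = genes[genes["chrom"] == row.chrom]
        hosts = [
            g
            for g in sub.itertuples(index=False)
            if g.start <= row.start and row.end <= g.end and g.strand != row.strand
        ]
        if not hosts:
            continue
        if len(hosts) > 1:
            logger.warning(
                "transcript %s:%d-%d inside %d opposite-strand genes; rejected as ambiguous",
                row.chrom,
                row.start,
                row.end,
                len(hosts),
            )
            continue
        if not _overlaps_any(row.chrom, row.start, row.end, h3k4me2):
            continue
        calls.append(
            EnhancerCall(
                id="",
                kind="intragenic",
                chrom=row.chrom,
                start=row.start,
                end=row.end,
                members=[row._asdict()],
                host_gene=str(hosts[0].gene_id),
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    for k, call in enumerate(calls):
        call.id = f"intra_{k}"
    return calls


def enhancers_to_frame(calls: list[EnhancerCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "id": c.id,
            "kind": c.kind,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "host_gene": c.host_gene or ".",
        }
        row.update({f"class_{cond}": cls for cond, cls in c.classes.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def quantify_enhancers(
    calls: list[EnhancerCall],
    coverages: list[StrandedCoverage],
    genes: pd.DataFrame,
    conditions: list[str],
) -> FeatureCounts:
    """Tag counts per enhancer per library.

    Intergenic enhancers count both strands over the span; intragenic ones
    count only the strand antisense to the host gene, keeping gene
    transcription out of the signal.
    """
    if len(coverages) != len(conditions):
        raise ValueError("one condition label per library required")
    strand_of_gene = dict(zip(genes["gene_id"].astype(str), genes["strand"]))
    flip = {"+": "-", "-": "+"}
    counts = np.zeros((len(calls), len(coverages)), dtype=np.int64)
    for i, call in enumerate(calls):
        for j, cov in enumerate(coverages):
            if call.kind == "intergenic":
                tags = cov.region_tags(call.chrom, call.start, call.end, "+") + cov.region_tags(
                    call.chrom, call.start, call.end, "-"
                )
            else:
                strand = flip[strand_of_gene[call.host_gene]]
                tags = cov.region_tags(call.chrom, call.start, call.end, strand)
            counts[i, j] = int(round(tags))
    return FeatureCounts(
        feature_ids=[c.id for c in calls],
        counts=counts,
        library_sizes=np.array([c.total_tags for c in coverages], dtype=float),
        feature_lengths=np.array([c.length for c in calls], dtype=float),
        conditions=list(conditions),
    )


def enhancer_timepoint_overlap(classes: pd.DataFrame, cond_a: str, cond_b: str) -> dict:
    """Shared/unique regulation sets between two timepoints of one catalog.

    ``classes`` holds one row per enhancer with columns ``id``,
    ``class_<cond_a>`` and ``class_<cond_b>``.
    """
    for col in (f"class_{cond_a}", f"class_{cond_b}", "id"):
        if col not in classes.columns:
            raise ValueError(f"missing column {col!r}; catalogs mismatched?")
    if classes["id"].duplicated().any():
        raise ValueError("duplicated enhancer ids; catalogs mismatched?")
    out: dict[str, dict] = {}
    for direction in ("up", "down"):
        set_a = set(classes.loc[classes[f"class_{cond_a}"] == direction, "id"])
        set_b = set(classes.loc[classes[f"class_{cond_b}"] == direction, "id"])
        shared = set_a & set_b
        out[direction] = {
            f"n_{cond_a}": len(set_a),
            f"n_{cond_b}": len(set_b),
            "n_shared": len(shared),
            f"frac_{cond_b}_shared_with_{cond_a}": (
                len(shared) / len(set_b) if set_b else float("nan")
            ),
            f"frac_{cond_a}_shared_with_{cond_b}": (
                len(shared) / len(set_a) if set_a else float("nan")
            ),
        }
    return out
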