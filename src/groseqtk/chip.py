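"""ChIP-seq integration: fold-enrichment peak calling, replicate consensus,
genomic categories, time-course Venn categories, peak-gene association and
the pairwise co-occurrence matrix.

Signals are normalized to 1e7 mapped tags before peak calling; the overlap
predicate everywhere is >= 1 bp on half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .coverage import StrandedCoverage
from .stats import kruskal_dunn

__all__ = [
    "Peak",
    "PeakSet",
    "call_peaks",
    "replicate_consensus",
    "categorize_genomic",
    "timepoint_venn",
    "VENN_CATEGORIES",
    "associate_to_genes",
    "cooccurrence",
    "cluster_matrix",
    "linkage_to_newick",
    "enhancer_gene_change",
]


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    norm_tags: float
    fold_over_control: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("peak end must exceed start")
        if self.norm_tags < 0:
            raise ValueError("norm_tags must be non-negative")


@dataclass
class PeakSet:
    factor: str
    condition: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
        seen = set()
        for p in self.peaks:
            key = (p.chrom, p.start, p.end)
            if key in seen:
                raise ValueError(f"duplicated peak {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.chrom, p.start, p.end, p.summit, p.norm_tags) for p in self.peaks],
            columns=["chrom", "start", "end", "summit", "norm_tags"],
        )


def call_peaks(
    treatment: StrandedCoverage,
    control: StrandedCoverage,
    factor: str = "",
    condition: str = "",
    window: int = 200,
    fold: float = 4.0,
    min_norm_tags: float = 10.0,
) -> PeakSet:
    """Sliding-window fold-enrichment peak calling.

    Both signals are scaled to 1e7 total tags.  A window (stepping one bin)
    is marked when scaled treatment >= ``fold`` x (scaled control + 0.5);
    marked windows are merged, the summit is the maximum-signal bin center,
    and peaks with normalized tags below ``min_norm_tags`` are dropped.
    Gates are inclusive.  ``fold`` <= 1 saturates the genome and is refused.
    """
    if fold <= 1:
        raise ValueError("fold must exceed 1 (fold <= 1 marks the whole genome)")
    if not treatment.same_grid(control):
        raise ValueError("treatment and control bin grids differ")
    if window <= 0 or window % treatment.bin_width:
        raise ValueError("window must be a positive multiple of the bin width")
    w = window // treatment.bin_width
    t_scale = 1e7 / treatment.total_tags
    c_scale = 1e7 / control.total_tags
    peaks: list[Peak] = []
    for chrom in sorted(treatment.chroms):
        t = treatment.chroms[chrom][0].astype(np.float64) * t_scale
        c = control.chroms[chrom][0].astype(np.float64) * c_scale
        if len(t) < w:
            continue
        kernel = np.ones(w)
        t_win = np.convolve(t, kernel, mode="valid")
        c_win = np.convolve(c, kernel, mode="valid")
        marked = t_win >= fold * (c_win + 0.5)
        if not marked.any():
            continue
        idx = np.flatnonzero(marked)
        # merge windows [i, i+w) whose marked starts are within w of each other
        breaks = np.flatnonzero(np.diff(idx) > w)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        bw = treatment.bin_width
        for s_i, e_i in zip(starts, ends):
            lo_bin = int(idx[s_i])
            hi_bin = int(idx[e_i]) + w  # exclusive
            span_tags = float(t[lo_bin:hi_bin].sum())
            if span_tags < min_norm_tags:
                continue
            ctrl_tags = float(c[lo_bin:hi_bin].sum())
            n_win = hi_bin - lo_bin - w + 1
            summit_bin = lo_bin + int(np.argmax(t[lo_bin:hi_bin]))
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=lo_bin * bw,
                    end=hi_bin * bw,
                    summit=summit_bin * bw + bw // 2,
                    norm_tags=span_tags,
                    fold_over_control=span_tags / (ctrl_tags + 0.5 * n_win),
                )
            )
    return PeakSet(factor=factor, condition=condition, peaks=peaks)


def _overlap_matrix(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Boolean vector: which intervals of ``a`` overlap any interval of ``b``."""
    out = np.zeros(len(a), dtype=bool)
    by_chrom = {chrom: sub for chrom, sub in b.groupby("chrom")}
    for i, row in enumerate(a.itertuples(index=False)):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        out[i] = bool(((sub["start"] < row.end) & (sub["end"] > row.start)).any())
    return out


def replicate_consensus(rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """Rep1 peaks overlapping any rep2 peak, with merged span and mean tags."""
    if (rep1.factor, rep1.condition) != (rep2.factor, rep2.condition):
        raise ValueError("replicates must share factor and condition")
    b = rep2.intervals()
    by_chrom = {chrom: sub for chrom, sub in b.groupby("chrom")}
    kept: list[Peak] = []
    for p in rep1.peaks:
        sub = by_chrom.get(p.chrom)
        if sub is None:
            continue
        hits = sub[(sub["start"] < p.end) & (sub["end"] > p.start)]
        if hits.empty:
            continue
        start = min(p.start, int(hits["start"].min()))
        end = max(p.end, int(hits["end"].max()))
        kept.append(
            Peak(
                chrom=p.chrom,
                start=start,
                end=end,
                summit=p.summit,
                norm_tags=(p.norm_tags + float(hits["norm_tags"].mean())) / 2.0,
                fold_over_control=p.fold_over_control,
            )
        )
    return PeakSet(factor=rep1.factor, condition=rep1.condition, peaks=kept)


def categorize_genomic(
    peaks: PeakSet, genes: pd.DataFrame, promoter_window: int = 1000
) -> pd.DataFrame:
    """Mutually exclusive summit categories with promoter precedence."""
    tss = genes.apply(lambda g: g["start"] if g["strand"] == "+" else g["end"] - 1, axis=1)
    gene_tbl = genes.assign(tss=tss)
    by_chrom = {chrom: sub for chrom, sub in gene_tbl.groupby("chrom")}
    rows = []
    for p in peaks.peaks:
        sub = by_chrom.get(p.chrom)
        category = "intergenic"
        if sub is not None:
            if (abs(sub["tss"] - p.summit) <= promoter_window).any():
                category = "promoter"
            elif ((sub["start"] <= p.summit) & (p.summit < sub["end"])).any():
                category = "intragenic"
        rows.append((p.chrom, p.start, p.end, p.summit, category))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "summit", "category"])


# Fixed numbering of the three-set overlap categories for timepoints
# (A, B, C) = (0.5 h, 2 h, 4 h):
VENN_CATEGORIES = {
    frozenset("ABC"): 1,
    frozenset("AB"): 2,
    frozenset("BC"): 3,
    frozenset("A"): 4,
    frozenset("AC"): 5,
    frozenset("B"): 6,
    frozenset("C"): 7,
}


def _merge_intervals(df: pd.DataFrame) -> list[tuple[str, int, int]]:
    merged: list[tuple[str, int, int]] = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom"):
        cur_s = cur_e = None
        for row in sub.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = row.start, row.end
            elif row.start <= cur_e:
                cur_e = max(cur_e, row.end)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = row.start, row.end
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    return merged


def timepoint_venn(set_a: PeakSet, set_b: PeakSet, set_c: PeakSet) -> pd.DataFrame:
    """Category 1-7 per merged region of the three sets' site universe."""
    frames = [s.intervals()[["chrom", "start", "end"]] for s in (set_a, set_b, set_c)]
    universe = pd.DataFrame(_merge_intervals(pd.concat(frames)), columns=["chrom", "start", "end"])
    member = {}
    for label, s in zip("ABC", (set_a, set_b, set_c)):
        member[label] = _overlap_matrix(universe, s.intervals())
    cats = []
    for i in range(len(universe)):
        present = frozenset(l for l in "ABC" if member[l][i])
        cats.append(VENN_CATEGORIES[present])
    universe["category"] = cats
    return universe


def associate_to_genes(
    peaks: PeakSet,
    genes: pd.DataFrame,
    diff_table: pd.DataFrame,
    window: int = 50000,
) -> dict:
    """Map each peak summit to the closest gene TSS within ``window`` bp.

    Ties go to the smaller absolute distance, then the lexicographically
    smaller gene id.  Returns the per-peak table, the fraction of peaks
    associated with up/non/down genes, and per-gene peak counts.
    """
    missing = set(genes["gene_id"].astype(str)) - set(diff_table["feature_id"].astype(str))
    if missing:
        raise ValueError(f"differential table misses {len(missing)} genes, e.g. {sorted(missing)[:3]}")
    cls = dict(zip(diff_table["feature_id"].astype(str), diff_table["class"]))
    tss = genes["start"].where(genes["strand"] == "+", genes["end"] - 1)
    gene_tbl = genes.assign(tss=tss)
    by_chrom = {chrom: sub for chrom, sub in gene_tbl.groupby("chrom")}
    rows = []
    for p in peaks.peaks:
        sub = by_chrom.get(p.chrom)
        gene_id, dist = None, None
        if sub is not None:
            d = (sub["tss"] - p.summit).abs()
            near = sub.assign(dist=d)[d <= window]
            if not near.empty:
                near = near.sort_values(["dist", "gene_id"], kind="mergesort")
                gene_id = str(near.iloc[0]["gene_id"])
                dist = int(near.iloc[0]["dist"])
        rows.append(
            {
                "chrom": p.chrom,
                "summit": p.summit,
                "gene_id": gene_id,
                "distance": dist,
                "gene_class": cls.get(gene_id) if gene_id else None,
            }
        )
    table = pd.DataFrame(rows)
    n = len(table)
    fractions = {
        c: float((table["gene_class"] == c).sum()) / n if n else float("nan")
        for c in ("up", "non", "down")
    }
    fractions["unassociated"] = float(table["gene_id"].isna().sum()) / n if n else float("nan")
    per_gene = table.dropna(subset=["gene_id"]).groupby("gene_id").size().to_dict()
    return {"table": table, "fractions": fractions, "peaks_per_gene": per_gene}


def cooccurrence(sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Min-set overlap percentage matrix.

    Entry (A, B) counts, in the smaller of the two interval sets, the sites
    overlapping the other set by >= 1 bp, as a percentage of the smaller
    set (the larger of the two directional percentages when sizes tie, so
    the matrix is symmetric by construction).  Empty sets yield NaN rows.
    """
    labels = list(sets)
    mat = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    frac_cache: dict[tuple[str, str], float] = {}

    def directional(a: str, b: str) -> float:
        if (a, b) not in frac_cache:
            frac_cache[(a, b)] = 100.0 * _overlap_matrix(sets[a], sets[b]).mean()
        return frac_cache[(a, b)]

    for i, a in enumerate(labels):
        for b in labels[i:]:
            if len(sets[a]) == 0 or len(sets[b]) == 0:
                continue
            if a == b:
                value = 100.0
            elif len(sets[a]) < len(sets[b]):
                value = directional(a, b)
            elif len(sets[b]) < len(sets[a]):
                value = directional(b, a)
            else:
                value = max(directional(a, b), directional(b, a))
            mat.loc[a, b] = value
            mat.loc[b, a] = value
    return mat


def cluster_matrix(matrix: pd.DataFrame) -> dict:
    """Average-linkage hierarchical clustering on Euclidean row distances."""
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix contains undefined (NaN) entries; drop empty sets first")
    if len(matrix) < 2:
        return {"order": list(matrix.index), "linkage": None, "newick": f"({matrix.index[0]});"}
    Z = hierarchy.linkage(pdist(values, metric="euclidean"), method="average")
    order = [matrix.index[i] for i in hierarchy.leaves_list(Z)]
    return {"order": order, "linkage": Z, "newick": linkage_to_newick(Z, list(matrix.index))}


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)

    def node(i: int) -> tuple[str, float]:
        if i < n:
            return labels[i], 0.0
        row = Z[i - n]
        l_str, l_h = node(int(row[0]))
        r_str, r_h = node(int(row[1]))
        h = float(row[2]) / 2.0
        return f"({l_str}:{h - l_h:.6g},{r_str}:{h - r_h:.6g})", h

    tree, _ = node(2 * n - 2)
    return tree + ";"


def enhancer_gene_change(
    groups: dict[str, pd.DataFrame],
    genes: pd.DataFrame,
    diff_table: pd.DataFrame,
    window: int = 50000,
) -> dict:
    """Per enhancer group: log2FC distribution of nearby transcribed genes.

    Each enhancer (interval frame with chrom/start/end) is associated with
    the closest transcribed-gene TSS within ``window`` of its midpoint;
    untranscribed genes never participate.  Groups are compared with
    Kruskal-Wallis and Dunn's post-test when at least two are non-empty.
    """
    transcribed = diff_table[diff_table["class"] != "untranscribed"]
    fc = dict(zip(transcribed["feature_id"].astype(str), transcribed["log2fc"]))
    sub_genes = genes[genes["gene_id"].astype(str).isin(fc)].copy()
    sub_genes["tss"] = sub_genes["start"].where(sub_genes["strand"] == "+", sub_genes["end"] - 1)
    by_chrom = {chrom: s for chrom, s in sub_genes.groupby("chrom")}
    result: dict[str, dict] = {}
    samples: dict[str, np.ndarray] = {}
    for label, intervals in groups.items():
        values = []
        for row in intervals.itertuples(index=False):
            mid = (row.start + row.end) // 2
            sub = by_chrom.get(row.chrom)
            if sub is None:
                continue
            d = (sub["tss"] - mid).abs()
            near = sub[d <= window]
            if near.empty:
                continue
            best = near.loc[d[d <= window].idxmin()]
            values.append(fc[str(best["gene_id"])])
        arr = np.asarray(values, dtype=float)
        if len(arr) == 0:
            result[label] = {"n": 0, "empty": True}
            continue
        result[label] = {
            "n": int(len(arr)),
            "empty": False,
            "median": float(np.median(arr)),
            "p10": float(np.percentile(arr, 10)),
            "p90": float(np.percentile(arr, 90)),
        }
        samples[label] = arr
    out = {"groups": result}
    comparable = {k: v for k, v in samples.items() if len(v) >= 2}
    if len(comparable) >= 2:
        out["test"] = kruskal_dunn(comparable)
    return out
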