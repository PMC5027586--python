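"""End-to-end orchestration: simulate -> detect -> quantify -> classify ->
integrate, with a checksummed manifest and a truth-evaluation report.

Every stage is a pure function of (inputs, parameters, seed); rerunning
with the same configuration reproduces byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .chip import (
    PeakSet,
    associate_to_genes,
    call_peaks,
    categorize_genomic,
    cluster_matrix,
    cooccurrence,
    enhancer_gene_change,
    replicate_consensus,
    timepoint_venn,
)
from .coverage import StrandedCoverage, combine_libraries
from .differential import ENHANCER_GATES, GENE_GATES, Thresholds, count_features, FeatureCounts, run_differential
from .enhancers import (
    call_intergenic,
    call_intragenic,
    enhancers_to_frame,
    enhancer_timepoint_overlap,
    quantify_enhancers,
)
from .simulate import (
    GRO_CONDITIONS,
    SimConfig,
    TruthSet,
    generate_truth,
    simulate_chip_coverage,
    simulate_groseq,
    write_fixtures,
)
from .transcripts import (
    DetectionParams,
    compare_ppi_groups,
    detect_transcripts,
    pausing_index,
    transcripts_to_frame,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "evaluate_against_truth"]


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    gene_gates: Thresholds = field(default_factory=lambda: dataclasses.replace(GENE_GATES))
    enhancer_gates: Thresholds = field(default_factory=lambda: dataclasses.replace(ENHANCER_GATES))
    peak_window: int = 200
    peak_fold: float = 4.0
    peak_min_norm_tags: float = 10.0
    promoter_window: int = 1000
    association_window: int = 50000
    max_pair_gap: int = 1000
    min_tts_distance: int = 3000
    intragenic_length_range: tuple[int, int] = (150, 500)
    seed: int = 0

    def __post_init__(self) -> None:
        self.sim.seed = self.seed
        self.validate()

    def validate(self) -> None:
        self.sim.validate()
        self.detection.validate(self.sim.bin_width)
        if self.peak_fold <= 1:
            raise ValueError("peak_fold must exceed 1")
        if self.association_window <= 0 or self.max_pair_gap <= 0:
            raise ValueError("windows must be positive")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        kwargs = {}
        for key, sub_cls in (("sim", SimConfig), ("detection", DetectionParams)):
            if key in raw:
                block = raw.pop(key)
                known = {f.name for f in dataclasses.fields(sub_cls)}
                bad = set(block) - known
                if bad:
                    raise ValueError(f"unknown {key} options: {sorted(bad)}")
                for name, f in ((f.name, f) for f in dataclasses.fields(sub_cls)):
                    if name in block and isinstance(block[name], list):
                        block[name] = tuple(block[name])
                kwargs[key] = sub_cls(**block)
        for key, gates in (("gene_gates", GENE_GATES), ("enhancer_gates", ENHANCER_GATES)):
            if key in raw:
                kwargs[key] = dataclasses.replace(gates, **raw.pop(key))
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config options: {sorted(bad)}")
        for name in list(raw):
            if isinstance(raw[name], list):
                raw[name] = tuple(raw[name])
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def _write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _fmt_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _peaks_bed(peaks: PeakSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "name": f"{peaks.factor}_{peaks.condition}_{i}",
                "score": int(min(p.norm_tags, 10000)),
                "strand": ".",
                "summit": p.summit,
                "norm_tags": round(p.norm_tags, 4),
                "fold": round(p.fold_over_control, 4),
            }
            for i, p in enumerate(peaks.peaks)
        ],
        columns=["chrom", "start", "end", "name", "score", "strand",
                 "summit", "norm_tags", "fold"],
    )


def _consensus_peaks(truth: TruthSet, config: RunConfig, factor: str, condition: str) -> PeakSet:
    reps = []
    for rep in range(1, config.sim.n_replicates + 1):
        treat = simulate_chip_coverage(truth, factor, condition, rep)
        ctrl = simulate_chip_coverage(truth, factor, condition, rep, control=True)
        reps.append(
            call_peaks(
                treat,
                ctrl,
                factor=factor,
                condition=condition,
                window=config.peak_window,
                fold=config.peak_fold,
                min_norm_tags=config.peak_min_norm_tags,
            )
        )
    if len(reps) == 1:
        return reps[0]
    consensus = reps[0]
    for other in reps[1:]:
        consensus = replicate_consensus(consensus, other)
    return consensus


def run_all(config: RunConfig, out_dir) -> dict:
    """Execute every stage in dependency order; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    try:
        manifest = _run_stages(config, out_dir, files)
    except Exception:
        (out_dir / "failed").write_text("run aborted; partial outputs retained\n")
        raise
    return manifest


def _run_stages(config: RunConfig, out_dir: Path, files: dict[str, str]) -> dict:
    sim = config.sim

    logger.info("stage 1/8: ground truth + GRO-seq simulation")
    truth = generate_truth(sim)
    gro_libs: list[StrandedCoverage] = []
    conditions: list[str] = []
    for cond in GRO_CONDITIONS:
        for rep in range(1, sim.n_replicates + 1):
            gro_libs.append(simulate_groseq(truth, cond, rep))
            conditions.append(cond)
    fixtures_dir = out_dir / "fixtures"
    write_fixtures(truth, {c.library_id: c for c in gro_libs}, fixtures_dir)
    files["fixtures/manifest.json"] = "fixture manifest"

    logger.info("stage 2/8: transcript detection on combined libraries")
    combined = combine_libraries(gro_libs)
    transcripts = detect_transcripts(combined, config.detection)
    tx_frame = transcripts_to_frame(transcripts)
    gio.write_bed6(tx_frame[["chrom", "start", "end", "name", "score", "strand"]],
                   out_dir / "transcripts.bed")
    files["transcripts.bed"] = "de novo transcripts"

    logger.info("stage 3/8: gene differential transcription")
    genes = truth.genes_frame()
    gene_counts = FeatureCounts(
        feature_ids=list(genes["gene_id"]),
        counts=np.column_stack([count_features(genes, cov, "sense") for cov in gro_libs]),
        library_sizes=np.array([c.total_tags for c in gro_libs], dtype=float),
        feature_lengths=(genes["end"] - genes["start"]).to_numpy(dtype=float),
        conditions=conditions,
    )
    gene_diff = run_differential(gene_counts, config.gene_gates, "vehicle")
    _fmt_tsv(gene_diff, out_dir / "genes_diff.tsv")
    files["genes_diff.tsv"] = "gene differential table"

    logger.info("stage 4/8: pausing indexes")
    ppi_rows = []
    for _, gene in genes.iterrows():
        res = pausing_index(gene, combined)
        ppi_rows.append(
            {
                "gene_id": res.gene_id,
                "promoter_density": res.promoter_density,
                "body_density": res.body_density,
                "ppi": res.ppi if res.defined else float("nan"),
                "defined": res.defined,
            }
        )
    ppi_table = pd.DataFrame(ppi_rows)
    _fmt_tsv(ppi_table, out_dir / "ppi.tsv")
    files["ppi.tsv"] = "promoter-proximal pausing indexes"

    logger.info("stage 5/8: ChIP peak calling")
    peaks_dir = out_dir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    k4_peaks = _consensus_peaks(truth, config, "H3K4me2", "t2")
    peak_sets: dict[str, PeakSet] = {"H3K4me2_t2": k4_peaks}
    ar_sets: dict[str, PeakSet] = {}
    for cond in ("t0.5", "t2", "t4"):
        ar_sets[cond] = _consensus_peaks(truth, config, "AR", cond)
        peak_sets[f"AR_{cond}"] = ar_sets[cond]
    for factor in sim.tf_factors:
        if factor == "AR":
            continue
        peak_sets[f"{factor}_t2"] = _consensus_peaks(truth, config, factor, "t2")
    for label, ps in sorted(peak_sets.items()):
        bed = _peaks_bed(ps)
        gio.write_bed6(bed, peaks_dir / f"{label}.bed")
        files[f"peaks/{label}.bed"] = f"consensus peaks ({label})"

    logger.info("stage 6/8: enhancer calling + differential")
    k4_frame = k4_peaks.intervals()[["chrom", "start", "end"]]
    inter = call_intergenic(tx_frame, genes, config.max_pair_gap, config.min_tts_distance)
    intra = call_intragenic(tx_frame, genes, k4_frame, config.intragenic_length_range)
    calls = inter + intra
    enh_diff = pd.DataFrame()
    if calls:
        enh_counts = quantify_enhancers(calls, gro_libs, genes, conditions)
        enh_diff = run_differential(enh_counts, config.enhancer_gates, "vehicle")
        by_key = {
            (row["feature_id"], row["condition"]): row["class"]
            for _, row in enh_diff.iterrows()
        }
        for call in calls:
            for cond in ("t0.5", "t2"):
                call.classes[cond] = by_key.get((call.id, cond), "non")
    enh_frame = enhancers_to_frame(calls)
    _fmt_tsv(enh_frame, out_dir / "enhancers.tsv")
    _fmt_tsv(enh_diff, out_dir / "enhancers_diff.tsv")
    files["enhancers.tsv"] = "enhancer catalog"
    files["enhancers_diff.tsv"] = "enhancer differential table"
    overlap = (
        enhancer_timepoint_overlap(enh_frame, "t0.5", "t2")
        if len(enh_frame) and "class_t0.5" in enh_frame.columns
        else {}
    )
    _write_json(overlap, out_dir / "enhancer_timepoint_overlap.json")
    files["enhancer_timepoint_overlap.json"] = "timepoint persistence of enhancer classes"

    logger.info("stage 7/8: peak-gene integration")
    gene_diff_t2 = gene_diff[gene_diff["condition"] == "t2"].reset_index(drop=True)
    categories = categorize_genomic(ar_sets["t2"], genes, config.promoter_window)
    cat_counts = categories["category"].value_counts().to_dict()
    venn = timepoint_venn(ar_sets["t0.5"], ar_sets["t2"], ar_sets["t4"])
    venn_counts = venn["category"].value_counts().sort_index().to_dict()
    assoc = associate_to_genes(ar_sets["t2"], genes, gene_diff_t2, config.association_window)
    _fmt_tsv(categories, out_dir / "ar_genomic_categories.tsv")
    _fmt_tsv(venn, out_dir / "ar_timepoint_venn.tsv")
    _fmt_tsv(assoc["table"], out_dir / "ar_gene_associations.tsv")
    _write_json(
        {
            "genomic_categories": {k: int(v) for k, v in sorted(cat_counts.items())},
            "venn_categories": {str(k): int(v) for k, v in venn_counts.items()},
            "association_fractions": assoc["fractions"],
        },
        out_dir / "ar_integration_summary.json",
    )
    files["ar_genomic_categories.tsv"] = "AR peak genomic categories"
    files["ar_timepoint_venn.tsv"] = "AR peak time-course categories"
    files["ar_gene_associations.tsv"] = "AR peak to gene associations"
    files["ar_integration_summary.json"] = "AR integration summary"

    # PPI comparison: genes with vs without an AR peak within the window
    ppi_with, ppi_without = [], []
    assoc_genes = set(assoc["peaks_per_gene"])
    for row in ppi_table.itertuples(index=False):
        if not row.defined:
            continue
        (ppi_with if row.gene_id in assoc_genes else ppi_without).append(row.ppi)
    ppi_cmp: dict = {"n_with_arb": len(ppi_with), "n_without_arb": len(ppi_without)}
    if len(ppi_with) >= 2 and len(ppi_without) >= 2:
        ppi_cmp["comparison"] = _jsonable(
            compare_ppi_groups({"with_arb": ppi_with, "without_arb": ppi_without})
        )
    _write_json(ppi_cmp, out_dir / "ppi_comparison.json")
    files["ppi_comparison.json"] = "PPI comparison of ARB-associated genes"

    logger.info("stage 8/8: co-occurrence matrix + enhancer-gene coupling")
    sets: dict[str, pd.DataFrame] = {}
    for label, ps in peak_sets.items():
        if label.startswith("H3K4me2"):
            continue
        if len(ps):
            sets[label] = ps.intervals()[["chrom", "start", "end"]]
    for cls in ("up", "down", "non"):
        sub = enh_frame[enh_frame.get("class_t2", pd.Series(dtype=object)) == cls]
        if len(sub):
            sets[f"enhancers_{cls}"] = sub[["chrom", "start", "end"]].reset_index(drop=True)
    matrix = cooccurrence(sets)
    matrix.to_csv(out_dir / "cooccurrence.tsv", sep="\t", float_format="%.4f")
    files["cooccurrence.tsv"] = "pairwise co-occurrence matrix"
    if len(matrix) >= 2 and not matrix.isna().any().any():
        clustering = cluster_matrix(matrix)
        (out_dir / "cooccurrence.nwk").write_text(clustering["newick"] + "\n")
        files["cooccurrence.nwk"] = "co-occurrence dendrogram (newick)"

    groups = {
        cls: enh_frame[enh_frame.get("class_t2", pd.Series(dtype=object)) == cls][
            ["chrom", "start", "end"]
        ].reset_index(drop=True)
        for cls in ("up", "down", "non")
    }
    egc = enhancer_gene_change(groups, genes, gene_diff_t2, config.association_window)
    _write_json(_jsonable(egc), out_dir / "enhancer_gene_change.json")
    files["enhancer_gene_change.json"] = "gene log2FC distributions per enhancer group"

    report = evaluate_against_truth(
        truth, transcripts, calls, enh_diff, gene_diff, ar_sets, config
    )
    _write_json(report, out_dir / "eval_report.json")
    files["eval_report.json"] = "recovery vs planted truth"

    manifest = gio.write_manifest(files, out_dir / "manifest.json")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {
            (k if isinstance(k, str) else "|".join(map(str, k))): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def _overlaps(start: int, end: int, spans: list[tuple[int, int]]) -> bool:
    return any(s < end and e > start for s, e in spans)


def evaluate_against_truth(
    truth: TruthSet,
    transcripts,
    enhancer_calls,
    enh_diff: pd.DataFrame,
    gene_diff: pd.DataFrame,
    ar_sets: dict[str, PeakSet],
    config: RunConfig,
) -> dict:
    """Recovery and false-call rates of every stage against the planted truth."""
    tol = config.detection.init_window
    by_cs = {}
    for t in transcripts:
        by_cs.setdefault((t.chrom, t.strand), []).append(t)
    gene_hits = 0
    for g in truth.genes:
        cands = by_cs.get((g.chrom, g.strand), [])
        if any(abs(t.start - g.start) <= tol and abs(t.end - g.end) <= tol for t in cands):
            gene_hits += 1
    report: dict = {
        "n_genes": len(truth.genes),
        "gene_recovery": gene_hits / len(truth.genes) if truth.genes else float("nan"),
    }

    inter_calls = [c for c in enhancer_calls if c.kind == "intergenic"]
    intra_calls = [c for c in enhancer_calls if c.kind == "intragenic"]
    inter_spans = {}
    for c in inter_calls:
        inter_spans.setdefault(c.chrom, []).append((c.start, c.end))
    intra_spans = {}
    for c in intra_calls:
        intra_spans.setdefault(c.chrom, []).append((c.start, c.end))
    n_inter = len(truth.intergenic_enhancers)
    n_intra = len(truth.intragenic_enhancers)
    inter_hits = sum(
        _overlaps(e.hull[0], e.hull[1], inter_spans.get(e.chrom, []))
        for e in truth.intergenic_enhancers
    )
    intra_hits = sum(
        _overlaps(e.start, e.end, intra_spans.get(e.chrom, []))
        for e in truth.intragenic_enhancers
    )
    truth_spans = {}
    for e in truth.intergenic_enhancers:
        truth_spans.setdefault(e.chrom, []).append(e.hull)
    for e in truth.intragenic_enhancers:
        truth_spans.setdefault(e.chrom, []).append((e.start, e.end))
    false_calls = sum(
        not _overlaps(c.start, c.end, truth_spans.get(c.chrom, [])) for c in enhancer_calls
    )
    report.update(
        {
            "n_intergenic_truth": n_inter,
            "intergenic_recovery": inter_hits / n_inter if n_inter else float("nan"),
            "n_intragenic_truth": n_intra,
            "intragenic_recovery": intra_hits / n_intra if n_intra else float("nan"),
            "n_enhancer_calls": len(enhancer_calls),
            "enhancer_false_rate": (
                false_calls / len(enhancer_calls) if enhancer_calls else float("nan")
            ),
        }
    )

    # differential recovery at 2 h
    sub = gene_diff[gene_diff["condition"] == "t2"]
    cls = dict(zip(sub["feature_id"], sub["class"]))
    fc_est = dict(zip(sub["feature_id"], sub["log2fc"]))
    planted_up = [g.gene_id for g in truth.genes if g.log2fc["t2"] > 0]
    planted_down = [g.gene_id for g in truth.genes if g.log2fc["t2"] < 0]
    planted_null = [g.gene_id for g in truth.genes if g.log2fc["t2"] == 0]
    if planted_up:
        report["gene_up_class_recovery"] = float(
            np.mean([cls.get(g) == "up" for g in planted_up])
        )
        report["gene_up_median_log2fc_est"] = float(
            np.median([fc_est[g] for g in planted_up if g in fc_est])
        )
    if planted_down:
        report["gene_down_class_recovery"] = float(
            np.mean([cls.get(g) == "down" for g in planted_down])
        )
    if planted_null:
        report["gene_null_false_call_rate"] = float(
            np.mean([cls.get(g) in ("up", "down") for g in planted_null])
        )

    # AR peak recovery per condition
    peak_eval = {}
    for cond, ps in ar_sets.items():
        active = [s for s in truth.tf_sites.get("AR", []) if cond in s.conditions]
        spans = {}
        for p in ps.peaks:
            spans.setdefault(p.chrom, []).append((p.start, p.end))
        hits = sum(_overlaps(s.start, s.end, spans.get(s.chrom, [])) for s in active)
        truth_sp = {}
        for s in active:
            truth_sp.setdefault(s.chrom, []).append((s.start, s.end))
        false_peaks = sum(
            not _overlaps(p.start, p.end, truth_sp.get(p.chrom, [])) for p in ps.peaks
        )
        peak_eval[cond] = {
            "n_truth_sites": len(active),
            "recovery": hits / len(active) if active else float("nan"),
            "n_peaks": len(ps),
            "false_rate": false_peaks / len(ps) if len(ps) else float("nan"),
        }
    report["ar_peaks"] = peak_eval
    return report
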