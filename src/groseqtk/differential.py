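"""Count-based differential transcription with RPKM / fold-change / FDR gates.

The test is a negative-binomial exact test conditional on the pooled sum,
with one common dispersion estimated by method of moments across features
(Poisson fallback when the estimate is non-positive).  Normalization is
per-million total tags; fold changes use library-size-normalized mean
pseudocounts with a 0.5 offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coverage import StrandedCoverage

__all__ = [
    "FeatureCounts",
    "Thresholds",
    "GENE_GATES",
    "ENHANCER_GATES",
    "count_features",
    "rpkm",
    "estimate_dispersion",
    "nb_exact_test",
    "benjamini_hochberg",
    "classify_features",
    "run_differential",
]


@dataclass
class FeatureCounts:
    """Feature x library count matrix with library metadata."""

    feature_ids: list[str]
    counts: np.ndarray  # (n_features, n_libraries) int64
    library_sizes: np.ndarray  # total mapped tags per library
    feature_lengths: np.ndarray  # bp
    conditions: list[str]  # condition label per library

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.float64)
        self.feature_lengths = np.asarray(self.feature_lengths, dtype=np.float64)
        nf, nl = self.counts.shape
        if len(self.feature_ids) != nf or len(self.feature_lengths) != nf:
            raise ValueError("feature metadata does not match count matrix")
        if len(self.library_sizes) != nl or len(self.conditions) != nl:
            raise ValueError("library metadata does not match count matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.feature_lengths <= 0).any():
            raise ValueError("feature lengths must be positive")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    def columns_for(self, condition: str) -> np.ndarray:
        cols = np.flatnonzero(np.asarray(self.conditions) == condition)
        if len(cols) == 0:
            raise ValueError(f"condition {condition!r} has no libraries")
        return cols


@dataclass
class Thresholds:
    min_rpkm: float = 0.5
    max_fdr: float = 0.01
    min_abs_log2fc: float = 0.585
    require_rpkm: bool = True

    def __post_init__(self) -> None:
        if self.min_rpkm < 0 or not 0 < self.max_fdr <= 1 or self.min_abs_log2fc <= 0:
            raise ValueError("invalid thresholds")


# Gene gates: RPKM >= 0.5, FDR <= 0.01, |log2FC| >= 0.585.  The printed
# 0.585 is log2(1.5) rounded; the exact value keeps a fold change of
# exactly 1.5 inside the inclusive gate.
GENE_GATES = Thresholds(
    min_rpkm=0.5, max_fdr=0.01, min_abs_log2fc=float(np.log2(1.5)), require_rpkm=True
)
# Enhancer gates: FDR <= 0.05, |log2FC| >= 1; no RPKM floor.
ENHANCER_GATES = Thresholds(min_rpkm=0.0, max_fdr=0.05, min_abs_log2fc=1.0, require_rpkm=False)


def count_features(
    regions: pd.DataFrame, cov: StrandedCoverage, mode: str = "sense"
) -> np.ndarray:
    """Integer tag counts per region for one library.

    ``regions`` needs columns chrom/start/end/strand.  ``mode`` selects tags
    on the region's own strand (*sense*), the opposite strand (*antisense*)
    or *both*; partial bins are pro-rated before rounding.
    """
    if mode not in {"sense", "antisense", "both"}:
        raise ValueError(f"unknown mode {mode!r}")
    flip = {"+": "-", "-": "+"}
    out = np.zeros(len(regions), dtype=np.int64)
    for i, row in enumerate(regions.itertuples(index=False)):
        if mode == "both":
            tags = cov.region_tags(row.chrom, row.start, row.end, "+") + cov.region_tags(
                row.chrom, row.start, row.end, "-"
            )
        else:
            strand = row.strand if mode == "sense" else flip[row.strand]
            tags = cov.region_tags(row.chrom, row.start, row.end, strand)
        out[i] = int(round(tags))
    return out


def rpkm(count: float, length_bp: float, library_size: float) -> float:
    if length_bp <= 0:
        raise ValueError("length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / ((length_bp / 1000.0) * (library_size / 1e6))


def estimate_dispersion(norm_counts: np.ndarray, conditions: np.ndarray) -> float:
    """Common NB dispersion by method of moments on normalized counts.

    Pools ``var - mean`` over ``mean^2`` across features and conditions with
    at least two libraries; clipped at zero (Poisson).
    """
    num = 0.0
    den = 0.0
    for cond in np.unique(conditions):
        cols = np.flatnonzero(conditions == cond)
        if len(cols) < 2:
            continue
        sub = norm_counts[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m**2))
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def _exact_p(a: int, b: int, n_a: int, n_b: int, dispersion: float) -> float:
    """Two-sided exact p conditional on the pooled sum ``a + b``.

    Doubles the smaller tail (point mass included in both), capped at 1.
    ``dispersion == 0`` reduces to the conditional binomial (Poisson) test.
    """
    s = a + b
    if s == 0:
        return 1.0
    frac_a = n_a / (n_a + n_b)
    if dispersion <= 0:
        lower = sps.binom.cdf(a, s, frac_a)
        upper = sps.binom.sf(a - 1, s, frac_a)
        return float(min(1.0, 2.0 * min(lower, upper)))
    k = np.arange(s + 1)
    size_a, size_b = n_a / dispersion, n_b / dispersion
    mu_a, mu_b = s * frac_a, s * (1 - frac_a)
    p_a = size_a / (size_a + mu_a)
    p_b = size_b / (size_b + mu_b)
    logw = sps.nbinom.logpmf(k, size_a, p_a) + sps.nbinom.logpmf(s - k, size_b, p_b)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    lower = w[: a + 1].sum()
    upper = w[a:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def nb_exact_test(
    counts: FeatureCounts,
    condition_a: str,
    condition_b: str,
    dispersion: float | None = None,
) -> np.ndarray:
    """Per-feature two-sided exact NB p-values for condition_a vs condition_b."""
    cols_a = counts.columns_for(condition_a)
    cols_b = counts.columns_for(condition_b)
    cols = np.concatenate([cols_a, cols_b])
    sizes = counts.library_sizes[cols]
    norm = counts.counts[:, cols] * (sizes.mean() / sizes)
    if dispersion is None:
        conds = np.asarray([counts.conditions[c] for c in cols])
        dispersion = estimate_dispersion(norm, conds)
    n_a, n_b = len(cols_a), len(cols_b)
    a = np.rint(norm[:, :n_a].sum(axis=1)).astype(np.int64)
    b = np.rint(norm[:, n_a:].sum(axis=1)).astype(np.int64)
    pvals = np.ones(len(a))
    for i in range(len(a)):
        pvals[i] = _exact_p(int(a[i]), int(b[i]), n_a, n_b, dispersion)
    return pvals


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up BH adjusted p-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-d sequence")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(m)
    out[order] = ranked
    return out


def classify_features(records: pd.DataFrame, thresholds: Thresholds) -> pd.DataFrame:
    """Attach a regulation class (up/down/non/untranscribed) to each record.

    Expects columns ``log2fc``, ``fdr`` and ``max_rpkm``.  Features whose
    max RPKM over all libraries falls below ``min_rpkm`` are *untranscribed*
    when the gates require an RPKM floor.
    """
    records = records.copy()
    cls = np.full(len(records), "non", dtype=object)
    sig = records["fdr"].to_numpy() <= thresholds.max_fdr
    fc = records["log2fc"].to_numpy()
    cls[sig & (fc >= thresholds.min_abs_log2fc)] = "up"
    cls[sig & (fc <= -thresholds.min_abs_log2fc)] = "down"
    if thresholds.require_rpkm:
        cls[records["max_rpkm"].to_numpy() < thresholds.min_rpkm] = "untranscribed"
    records["class"] = cls
    return records


def run_differential(
    counts: FeatureCounts,
    thresholds: Thresholds,
    control_condition: str,
    treated_conditions: list[str] | None = None,
) -> pd.DataFrame:
    """One DifferentialRecord per feature per treated condition vs control."""
    all_conditions = list(dict.fromkeys(counts.conditions))
    if control_condition not in all_conditions:
        raise ValueError(f"control condition {control_condition!r} absent")
    if treated_conditions is None:
        treated_conditions = [c for c in all_conditions if c != control_condition]
    for cond in treated_conditions:
        if cond not in all_conditions:
            raise ValueError(f"condition {cond!r} absent")

    sizes = counts.library_sizes
    norm_all = counts.counts * (sizes.mean() / sizes)
    per_lib_rpkm = counts.counts / (
        (counts.feature_lengths[:, None] / 1000.0) * (sizes[None, :] / 1e6)
    )
    max_rpkm = per_lib_rpkm.max(axis=1)

    frames = []
    for cond in treated_conditions:
        cols_t = counts.columns_for(cond)
        cols_c = counts.columns_for(control_condition)
        mean_t = norm_all[:, cols_t].mean(axis=1)
        mean_c = norm_all[:, cols_c].mean(axis=1)
        log2fc = np.log2((mean_t + 0.5) / (mean_c + 0.5))
        pvals = nb_exact_test(counts, cond, control_condition)
        all_zero = counts.counts[:, np.concatenate([cols_t, cols_c])].sum(axis=1) == 0
        pvals[all_zero] = 1.0
        fdr = benjamini_hochberg(pvals)
        frame = pd.DataFrame(
            {
                "feature_id": counts.feature_ids,
                "condition": cond,
                "rpkm_control": per_lib_rpkm[:, cols_c].mean(axis=1),
                "rpkm_treated": per_lib_rpkm[:, cols_t].mean(axis=1),
                "max_rpkm": max_rpkm,
                "log2fc": log2fc,
                "pvalue": pvals,
                "fdr": fdr,
                "all_zero": all_zero,
            }
        )
        frames.append(classify_features(frame, thresholds))
    return pd.concat(frames, ignore_index=True)
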