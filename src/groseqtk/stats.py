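"""Rank-based group comparisons: Kruskal-Wallis with Dunn's post-test."""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps

__all__ = ["kruskal_dunn", "dunn_posthoc"]


def dunn_posthoc(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], dict]:
    """Dunn's z and two-sided p for every group pair, Bonferroni-adjusted.

    Uses pooled mid-ranks with the standard tie correction
    ``sum(t^3 - t) / (12 (N - 1))`` on the rank variance.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n = {g: len(groups[g]) for g in labels}
    ranks = sps.rankdata(pooled)
    mean_rank = {}
    offset = 0
    for g in labels:
        mean_rank[g] = float(np.mean(ranks[offset : offset + n[g]]))
        offset += n[g]
    N = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    out = {}
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / n[a] + 1.0 / n[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        out[(a, b)] = {"z": float(z), "p": float(p), "p_adjusted": float(min(1.0, p * m))}
    return out


def kruskal_dunn(groups: dict[str, np.ndarray]) -> dict:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in groups]
    H, p = sps.kruskal(*arrays)
    return {
        "kruskal_H": float(H),
        "kruskal_p": float(p),
        "dunn": dunn_posthoc({g: np.asarray(v, dtype=float) for g, v in groups.items()}),
    }
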