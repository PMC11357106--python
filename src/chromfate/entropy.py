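"""Per-cell transcriptional entropy and the two-tier expression model.

Transcriptional entropy — the Shannon entropy of a cell's transcript
proportions — is a proxy for differentiation potential: progenitor cells
spread their transcripts over many genes (high entropy), while specialised
cells concentrate transcription on few genes (low entropy). The two-tier
model makes this quantitative with two dials: the number of expressed genes
and the share of all transcripts held by the top tier of genes.

Entropy is computed on raw counts (p_i = c_i / total per cell), in nats by
default; a base-2 option is exposed. No depth correction is applied, so the
depth-dependence of the expressed-gene count is a documented caveat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import ExpressionMatrix

__all__ = [
    "cell_entropy",
    "expressed_genes",
    "entropy_by_cluster",
    "TwoTierModel",
    "two_tier_entropy",
    "sample_two_tier_cells",
]


def cell_entropy(counts, base: float | None = None) -> float:
    """Shannon entropy of one cell's transcript proportions.

    S = -sum_i p_i log p_i with p_i = c_i / sum(c); zero-count genes
    contribute exactly 0. ``base=None`` gives nats, ``base=2`` bits.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero count vector has no entropy")
    p = c[c > 0] / total
    s = float(-(p * np.log(p)).sum())
    if base is not None:
        s /= math.log(base)
    return s


def expressed_genes(counts, min_count: int = 1) -> int:
    """Number of genes with count >= ``min_count``."""
    return int((np.asarray(counts) >= min_count).sum())


def entropy_by_cluster(
    matrix: ExpressionMatrix, base: float | None = None, min_count: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell entropy records plus a per-cluster summary.

    Returns ``(records, summary)``: one row per cell (cell_id, cluster,
    entropy, n_expressed) and one row per declared cluster (median and
    quartiles of both quantities, cell count), in declared cluster order.
    """
    dense = matrix.counts
    records = []
    for i, cell_id in enumerate(matrix.cell_ids):
        row = dense.getrow(i)
        counts = row.data
        records.append(
            {
                "cell_id": cell_id,
                "cluster": matrix.cluster_labels[i],
                "entropy": cell_entropy(counts, base=base),
                "n_expressed": int((counts >= min_count).sum()),
            }
        )
    records = pd.DataFrame(records)
    rows = []
    for cluster in matrix.clusters:
        sub = records[records["cluster"] == cluster]
        rows.append(
            {
                "cluster": cluster,
                "n_cells": len(sub),
                "entropy_median": sub["entropy"].median(),
                "entropy_q1": sub["entropy"].quantile(0.25),
                "entropy_q3": sub["entropy"].quantile(0.75),
                "n_expressed_median": sub["n_expressed"].median(),
                "n_expressed_q1": sub["n_expressed"].quantile(0.25),
                "n_expressed_q3": sub["n_expressed"].quantile(0.75),
            }
        )
    return records, pd.DataFrame(rows)


@dataclass(frozen=True)
class TwoTierModel:
    """Piecewise-uniform expression: a high tier of genes holding a fixed
    share of all transcripts, the remaining genes sharing the rest.

    ``top_fraction`` is the proportion of expressed genes in the high tier
    (e.g. 0.10); ``top_share`` the proportion of all transcripts they hold
    (e.g. 0.40). ``top_share == top_fraction`` recovers the uniform model.
    """

    n_genes: int
    top_fraction: float = 0.1
    top_share: float = 0.4

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError("two-tier model needs at least 2 genes")
        if not (0 < self.top_fraction < 1):
            raise ValueError("top_fraction must be in (0, 1)")
        if not (0 <= self.top_share <= 1):
            raise ValueError("top_share must be in [0, 1]")

    @property
    def k_high(self) -> int:
        return max(1, round(self.top_fraction * self.n_genes))

    @property
    def k_low(self) -> int:
        return self.n_genes - self.k_high

    def probabilities(self) -> np.ndarray:
        """Per-gene expression probabilities (high tier first)."""
        p = np.empty(self.n_genes)
        p[: self.k_high] = self.top_share / self.k_high
        p[self.k_high :] = (1.0 - self.top_share) / self.k_low
        return p


def two_tier_entropy(model: TwoTierModel, base: float | None = None) -> float:
    """Analytic entropy of the two-tier distribution.

    S = -[s ln(s/k1) + (1-s) ln((1-s)/k2)] with s the top share, k1/k2 the
    tier sizes. Increasing n_genes raises S; concentrating transcripts
    (raising s past the uniform point) lowers it.
    """
    s, k1, k2 = model.top_share, model.k_high, model.k_low
    out = 0.0
    if s > 0:
        out -= s * math.log(s / k1)
    if s < 1:
        out -= (1 - s) * math.log((1 - s) / k2)
    if base is not None:
        out /= math.log(base)
    return out


def sample_two_tier_cells(
    model: TwoTierModel,
    n_cells: int,
    depth: int,
    seed,
    cluster_label: str = "simulated",
) -> ExpressionMatrix:
    """Draw cells as multinomial samples of ``depth`` transcripts."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, model.probabilities(), size=n_cells)
    return ExpressionMatrix(
        counts,
        gene_ids=[f"g{i:05d}" for i in range(model.n_genes)],
        cell_ids=[f"c{i:05d}" for i in range(n_cells)],
        cluster_labels=[cluster_label] * n_cells,
        clusters=[cluster_label],
    )
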