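"""Consensus scores and ranking for panel-targeting miRNAs.

Three per-miRNA scores are computed over a gene panel of size ``G``
with a prediction-tool registry of size ``D``:

* **V-Score** — number of distinct panel genes with experimentally
  validated evidence (union across validated databases); bounded by G.
* **P-Score** — sum over panel genes of the number of prediction tools
  confirming each miRNA-gene pair; bounded by D*G.
* **C-Score** — the combined score

  .. math:: C = \\frac{P}{D \\cdot G} + \\frac{V}{G}

  bounded by 2, attained when all D tools confirm every panel gene and
  validated evidence covers the whole panel.

The multi-target filter keeps miRNAs able to target more than one
panel gene (any evidence kind), and ranking is descending by C-Score at
full precision with deterministic tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .evidence import EvidenceMatrix, canonicalize_mirna


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring knobs: registry size D, the multi-target threshold, and
    the number of decimals used when *reporting* C-Scores (ranking
    always uses full precision)."""

    D: int = 30
    min_target_genes: int = 2
    report_decimals: int = 2

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ConfigurationError("registry size D must be >= 1")
        if self.min_target_genes < 1:
            raise ConfigurationError("min_target_genes must be >= 1")


def v_score(matrix: EvidenceMatrix, mirna_id: str) -> int:
    """Count of distinct panel genes validated for this miRNA.

    A gene counts once even when several validated databases confirm
    it; a miRNA absent from the matrix scores 0.
    """
    mirna_id = canonicalize_mirna(mirna_id)
    sub = matrix.table[matrix.table["mirna"] == mirna_id]
    return int(sub["validated"].sum())


def p_score(matrix: EvidenceMatrix, mirna_id: str) -> int:
    """Sum of predicted tool counts over the panel genes."""
    mirna_id = canonicalize_mirna(mirna_id)
    sub = matrix.table[matrix.table["mirna"] == mirna_id]
    return int(sub["predicted_count"].sum())


def c_score(p: int, v: int, D: int, G: int) -> float:
    """Combined score ``p/(D*G) + v/G``, in [0, 2].

    ``D`` is the registry size and ``G`` the panel size; the
    denominator uses the panel size, not the per-miRNA number of
    targeted genes, so that the theoretical maximum of 2 is reached
    only by full evidence over the whole panel.
    """
    if G < 1:
        raise ConfigurationError("panel size G must be >= 1")
    if D < 1:
        raise ConfigurationError("registry size D must be >= 1")
    if not (0 <= v <= G):
        raise DomainError(f"v={v} outside [0, {G}]")
    if not (0 <= p <= D * G):
        raise DomainError(f"p={p} outside [0, {D * G}]")
    return p / (D * G) + v / G


def score_mirnas(matrix: EvidenceMatrix, config: ScoreConfig | None = None) -> pd.DataFrame:
    """Score every miRNA in the matrix.

    Returns a DataFrame with one row per miRNA and columns
    ``mirna, v_score, p_score, c_score, n_target_genes`` plus one
    per-gene predicted-count column per panel gene.  ``n_target_genes``
    is the number of distinct panel genes with *any* evidence
    (validated or predicted), used by the multi-target filter.
    """
    config = config or ScoreConfig()
    G = matrix.panel.size
    D = matrix.registry.size
    t = matrix.table
    grouped = t.groupby("mirna", sort=True)
    v = grouped["validated"].sum().astype(int)
    p = grouped["predicted_count"].sum().astype(int)
    any_ev = (
        t.assign(has=t["validated"] | (t["predicted_count"] > 0))
        .groupby("mirna", sort=True)["has"]
        .sum()
        .astype(int)
    )
    counts_wide = t.pivot(index="mirna", columns="gene", values="predicted_count")
    counts_wide = counts_wide[list(matrix.panel.genes)]  # panel order

    out = pd.DataFrame(
        {
            "mirna": v.index,
            "v_score": v.to_numpy(),
            "p_score": p.to_numpy(),
            "n_target_genes": any_ev.reindex(v.index).to_numpy(),
        }
    )
    out["c_score"] = [c_score(pi, vi, D, G) for pi, vi in zip(out["p_score"], out["v_score"])]
    for gene in matrix.panel.genes:
        out[gene] = counts_wide[gene].reindex(v.index).to_numpy()
    return out.reset_index(drop=True)


def filter_multi_target(scores: pd.DataFrame, config: ScoreConfig | None = None) -> pd.DataFrame:
    """Keep miRNAs evidencing at least ``min_target_genes`` panel genes.

    The default threshold of 2 realizes "targets more than one gene";
    evidence of either kind (validated flag or positive predicted
    count) qualifies a gene.
    """
    config = config or ScoreConfig()
    keep = scores["n_target_genes"] >= config.min_target_genes
    return scores[keep].reset_index(drop=True)


def rank_mirnas(scores: pd.DataFrame) -> pd.DataFrame:
    """Assign 1-based ranks: descending C-Score at full precision, ties
    broken by higher V-Score, then higher P-Score, then miRNA id
    alphabetically.  The output is a permutation of the input rows."""
    key = scores.assign(_id=scores["mirna"]).sort_values(
        by=["c_score", "v_score", "p_score", "_id"],
        ascending=[False, False, False, True],
        kind="mergesort",
    )
    key = key.drop(columns="_id").reset_index(drop=True)
    key.insert(0, "rank", np.arange(1, len(key) + 1))
    return key


def format_report(scores: pd.DataFrame, config: ScoreConfig | None = None) -> pd.DataFrame:
    """Reporting view: C-Scores rounded to ``report_decimals``.

    Rounding happens only here; ranking and all internal arithmetic use
    full precision.
    """
    config = config or ScoreConfig()
    out = scores.copy()
    out["c_score"] = out["c_score"].round(config.report_decimals)
    return out
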