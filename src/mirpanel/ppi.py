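"""Local filtering and summary of STRING-style protein-protein edge lists.

STRING exports score each interaction with a combined confidence in
[0, 1] (some export dialects use a 0-1000 integer scale).  The standard
confidence tiers are: lowest >= 0.15, medium >= 0.4, high >= 0.7,
highest >= 0.9.  This module works purely on an exported edge list —
no web service is queried — and summarizes the surviving simple
undirected graph (nodes, edges, degrees).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ConfigurationError, MalformedScoreError
from .evidence import canonicalize_gene

#: Inclusive lower cutoffs for the STRING-style confidence tiers.
CONFIDENCE_CUTOFFS: dict[str, float] = {
    "lowest": 0.15,
    "medium": 0.4,
    "high": 0.7,
    "highest": 0.9,
}

DEFAULT_PPI_COLUMNS = {"a": "protein1", "b": "protein2", "score": "combined_score"}


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    degree: dict[str, int]


def normalize_scores(edges: pd.DataFrame) -> pd.DataFrame:
    """Map raw export scores onto [0, 1].

    If any score exceeds 1 the whole column is on the 0-1000 integer
    dialect and is divided by 1000.  Idempotent: normalizing an already
    normalized table changes nothing.
    """
    scores = edges["combined_score"].astype(float)
    if (scores < 0).any() or (scores > 1000).any():
        raise MalformedScoreError("combined scores must lie in [0, 1000]")
    if (scores > 1).any():
        edges = edges.assign(combined_score=scores / 1000.0)
    return edges


def read_edge_list(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a STRING-style edge list into an undirected simple edge table.

    Columns of the result: ``protein_a, protein_b, combined_score``.
    A-B and B-A duplicates collapse to one edge keeping the maximum
    score; self-loops are dropped; scores are normalized to [0, 1].
    """
    cmap = {**DEFAULT_PPI_COLUMNS, **(column_map or {})}
    text = Path(path).read_text()
    if not text.strip():
        return pd.DataFrame(columns=["protein_a", "protein_b", "combined_score"])
    sep = delimiter
    if sep is None:
        header = text.splitlines()[0]
        sep = "\t" if "\t" in header else ("," if "," in header else r"\s+")
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in (cmap["a"], cmap["b"], cmap["score"]) if c not in df.columns]
    if missing:
        raise MalformedScoreError(f"{path}: missing column(s) {missing}")
    a = df[cmap["a"]].map(canonicalize_gene)
    b = df[cmap["b"]].map(canonicalize_gene)
    out = pd.DataFrame(
        {
            "protein_a": a.where(a <= b, b),
            "protein_b": b.where(a <= b, a),
            "combined_score": df[cmap["score"]].astype(float),
        }
    )
    out = normalize_scores(out)
    out = out[out["protein_a"] != out["protein_b"]]
    out = (
        out.groupby(["protein_a", "protein_b"], as_index=False)["combined_score"]
        .max()
        .sort_values(["protein_a", "protein_b"], ignore_index=True)
    )
    return out


def filter_by_confidence(edges: pd.DataFrame, level: str) -> pd.DataFrame:
    """Keep edges at or above the tier cutoff (lowest|medium|high|highest)."""
    if level not in CONFIDENCE_CUTOFFS:
        raise ConfigurationError(
            f"unknown confidence level {level!r}; "
            f"expected one of {sorted(CONFIDENCE_CUTOFFS)}"
        )
    cutoff = CONFIDENCE_CUTOFFS[level]
    return edges[edges["combined_score"] >= cutoff].reset_index(drop=True)


def summarize(
    edges: pd.DataFrame, panel: Iterable[str] | None = None
) -> NetworkSummary:
    """Node/edge/degree summary of the surviving simple undirected graph.

    ``panel`` adds isolated nodes (degree 0) for genes with no
    surviving edge, matching how a fixed query panel is displayed.
    """
    g = nx.Graph()
    if panel is not None:
        g.add_nodes_from(canonicalize_gene(x) for x in panel)
    for _, row in edges.iterrows():
        g.add_edge(row["protein_a"], row["protein_b"])
    degree = {node: int(d) for node, d in g.degree()}
    return NetworkSummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        degree=degree,
    )


def tier_profile(
    edges: pd.DataFrame, levels: Sequence[str] = ("lowest", "medium", "high", "highest")
) -> dict[str, int]:
    """Edge count per confidence tier; monotone non-increasing as the
    tier rises because the cutoffs are nested."""
    return {level: len(filter_by_confidence(edges, level)) for level in levels}
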