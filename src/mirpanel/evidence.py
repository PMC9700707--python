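"""Reading, canonicalization and assembly of miRNA-target evidence.

Two kinds of evidence feed the consensus scores: interactions curated in
experimentally *validated* databases (TarBase-class, miRTarBase-class
exports) and interactions called by computational *prediction* tools
(TargetScan-class exports, one table per tool).  This module
canonicalizes identifiers, deduplicates records, and assembles the
per-(miRNA, gene) evidence matrix over a fixed gene panel:

* ``validated`` — true iff at least one validated database lists the pair;
* ``predicted_count`` — number of *distinct* tools listing the pair,
  bounded by the registry size ``D``.

Exports are delimited text with a header; the delimiter is sniffed
(tab/comma) and can be forced.  Gene symbols are upper-cased and passed
through an alias map (``APOCIII`` -> ``APOC3`` by default) so that the
common alternative spellings of apolipoprotein C-III reconcile.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    ConfigurationError,
    MalformedIdentifierError,
    RegistryError,
    SchemaError,
)

#: Default gene-symbol alias map (identity otherwise).
DEFAULT_ALIASES: dict[str, str] = {"APOCIII": "APOC3"}

#: Default column mapping for evidence exports.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "mirna": "mirna",
    "gene": "gene",
    "source": "source",
}

_MIR_RE = re.compile(r"^([a-z]{3,4})-(mir|let)-(.+)$")


def canonicalize_mirna(raw_id: str) -> str:
    """Return the canonical display form of a mature miRNA identifier.

    Identifiers differing only in letter case map to the same canonical
    string; arm suffixes (``-3p``/``-5p``) and the species prefix are
    preserved, so ``hsa-miR-16-5p`` and ``hsa-miR-16-3p`` stay distinct.

    >>> canonicalize_mirna("HSA-MIR-124-3P")
    'hsa-miR-124-3p'
    """
    if raw_id is None or not str(raw_id).strip():
        raise MalformedIdentifierError("empty or whitespace-only miRNA identifier")
    low = str(raw_id).strip().lower()
    m = _MIR_RE.match(low)
    if m is None:
        # Unrecognized shape: lowercase is still a stable case-insensitive key.
        return low
    species, stem, rest = m.groups()
    stem = "miR" if stem == "mir" else "let"
    return f"{species}-{stem}-{rest}"


def canonicalize_gene(symbol: str, aliases: Mapping[str, str] | None = None) -> str:
    """Upper-case, strip, and alias-resolve a gene symbol."""
    if symbol is None or not str(symbol).strip():
        raise MalformedIdentifierError("empty or whitespace-only gene symbol")
    sym = str(symbol).strip().upper()
    table = DEFAULT_ALIASES if aliases is None else aliases
    return table.get(sym, sym)


@dataclass(frozen=True)
class GenePanel:
    """The fixed target-gene universe against which miRNAs are scored."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        canon = tuple(canonicalize_gene(g) for g in self.genes)
        if len(set(canon)) != len(canon):
            raise ConfigurationError(f"duplicate genes in panel: {canon}")
        if not canon:
            raise ConfigurationError("gene panel must contain at least one gene")
        object.__setattr__(self, "genes", canon)

    @property
    def size(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return canonicalize_gene(gene) in self.genes

    def __iter__(self):
        return iter(self.genes)

    @classmethod
    def from_file(cls, path: str | Path) -> "GenePanel":
        """Read a panel file: one gene symbol per line, ``#`` comments allowed."""
        lines = Path(path).read_text().splitlines()
        genes = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
        return cls(tuple(genes))


@dataclass(frozen=True)
class ToolRegistry:
    """Registry of computational prediction tools; its size is the
    denominator constant D of the combined score."""

    tools: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(str(t).strip() for t in self.tools)
        if len(set(names)) != len(names) or not names:
            raise ConfigurationError("tool registry must be non-empty and unique")
        object.__setattr__(self, "tools", names)

    @property
    def size(self) -> int:
        return len(self.tools)

    def __contains__(self, tool: str) -> bool:
        return tool in self.tools

    def __iter__(self):
        return iter(self.tools)

    @classmethod
    def default(cls, n: int = 30) -> "ToolRegistry":
        """A generic registry of ``n`` numbered prediction tools (default 30)."""
        return cls(tuple(f"tool{i:02d}" for i in range(1, n + 1)))


def _sniff_delimiter(path: str | Path) -> str:
    sample = Path(path).read_text()[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def _read_delimited(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    sep = delimiter or _sniff_delimiter(path)
    try:
        return pd.read_csv(path, sep=sep, dtype=str, comment="#")
    except FileNotFoundError:
        raise
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mapped column(s) {missing}; "
                          f"found {list(df.columns)}")


def read_validated_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    panel: GenePanel | None = None,
    aliases: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a validated-database export into canonical interaction records.

    Returns a DataFrame with columns ``mirna, gene, source_db`` (plus
    ``on_panel`` when a panel is supplied), deduplicated on the full
    triple.  Off-panel genes are retained but flagged, so the same
    export can later be re-scored against a different panel.
    """
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    df = _read_delimited(path, delimiter)
    _require_columns(df, [cmap["mirna"], cmap["gene"], cmap["source"]], path)
    out = pd.DataFrame(
        {
            "mirna": df[cmap["mirna"]].map(canonicalize_mirna),
            "gene": df[cmap["gene"]].map(lambda g: canonicalize_gene(g, aliases)),
            "source_db": df[cmap["source"]].astype(str).str.strip(),
        }
    ).drop_duplicates(ignore_index=True)
    if panel is not None:
        out["on_panel"] = out["gene"].isin(panel.genes)
    return out


def read_predicted_tables(
    paths: Mapping[str, str | Path],
    registry: ToolRegistry,
    column_map: Mapping[str, str] | None = None,
    panel: GenePanel | None = None,
    aliases: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read one export per prediction tool (``{tool: path}``).

    Each tool contributes at most one vote per (miRNA, gene) pair:
    records are deduplicated on (mirna, gene, tool).  A path attributed
    to a tool absent from the registry raises :class:`RegistryError`.
    """
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    frames = []
    for tool, path in paths.items():
        if tool not in registry:
            raise RegistryError(f"tool {tool!r} is not in the registry "
                                f"({registry.size} tools)")
        df = _read_delimited(path, delimiter)
        _require_columns(df, [cmap["mirna"], cmap["gene"]], path)
        if len(df) == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "mirna": df[cmap["mirna"]].map(canonicalize_mirna),
                    "gene": df[cmap["gene"]].map(
                        lambda g: canonicalize_gene(g, aliases)
                    ),
                    "tool": tool,
                }
            )
        )
    if not frames:
        out = pd.DataFrame(columns=["mirna", "gene", "tool"])
    else:
        out = pd.concat(frames, ignore_index=True).drop_duplicates(ignore_index=True)
    if panel is not None:
        out["on_panel"] = out["gene"].isin(panel.genes)
    return out


@dataclass
class EvidenceMatrix:
    """Per-(miRNA, panel gene) evidence: validated flag and predicted count.

    ``table`` is long-format with columns
    ``mirna, gene, validated, predicted_count`` and one row per
    (miRNA, panel gene) cell for every miRNA carrying any evidence.
    """

    panel: GenePanel
    registry: ToolRegistry
    table: pd.DataFrame = field(repr=False)

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.table["mirna"].unique())

    def cell(self, mirna: str, gene: str) -> tuple[bool, int]:
        """(validated, predicted_count) for one pair; absent pairs are (False, 0)."""
        mirna = canonicalize_mirna(mirna)
        gene = canonicalize_gene(gene)
        sub = self.table[(self.table["mirna"] == mirna) & (self.table["gene"] == gene)]
        if len(sub) == 0:
            return (False, 0)
        row = sub.iloc[0]
        return (bool(row["validated"]), int(row["predicted_count"]))

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as long-format TSV (round-trip safe)."""
        df = self.table.sort_values(["mirna", "gene"], kind="mergesort")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, panel: GenePanel, registry: ToolRegistry
    ) -> "EvidenceMatrix":
        df = pd.read_csv(path, sep="\t")
        df["validated"] = df["validated"].astype(bool)
        df["predicted_count"] = df["predicted_count"].astype(int)
        return cls(panel=panel, registry=registry, table=df)


def build_evidence_matrix(
    validated: pd.DataFrame | None,
    predicted: pd.DataFrame | None,
    panel: GenePanel,
    registry: ToolRegistry,
) -> EvidenceMatrix:
    """Assemble the evidence matrix restricted to panel genes.

    The validated flag is the union over validated databases; the
    predicted count is the number of distinct tools confirming the pair
    (each gene searched separately, contributions summed downstream).
    """
    if panel.size == 0:  # defensive; GenePanel already forbids this
        raise ConfigurationError("empty gene panel")

    cols = ["mirna", "gene"]
    val = validated if validated is not None else pd.DataFrame(columns=cols)
    pred = predicted if predicted is not None else pd.DataFrame(columns=cols)

    val = val[val["gene"].isin(panel.genes)] if len(val) else val
    pred = pred[pred["gene"].isin(panel.genes)] if len(pred) else pred

    mirnas = sorted(set(val["mirna"]) | set(pred["mirna"]))
    index = pd.MultiIndex.from_product(
        [mirnas, list(panel.genes)], names=["mirna", "gene"]
    )
    validated_pairs = (
        val.drop_duplicates(subset=cols).set_index(cols).index if len(val) else []
    )
    counts = (
        pred.drop_duplicates(subset=["mirna", "gene", "tool"])
        .groupby(cols)
        .size()
        if len(pred)
        else pd.Series(dtype=int)
    )
    bad = counts[counts > registry.size]
    if len(bad):
        raise RegistryError(
            f"predicted count exceeds registry size D={registry.size}: "
            f"{bad.index.tolist()[:3]}"
        )
    table = pd.DataFrame(index=index).reset_index()
    table["validated"] = [
        (m, g) in set(validated_pairs) for m, g in zip(table["mirna"], table["gene"])
    ]
    key = pd.MultiIndex.from_frame(table[cols])
    table["predicted_count"] = (
        counts.reindex(key).fillna(0).astype(int).to_numpy() if len(counts)
        else 0
    )
    return EvidenceMatrix(panel=panel, registry=registry, table=table)
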