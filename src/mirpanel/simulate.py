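"""Synthetic pipeline inputs with planted ground truth.

Every stage of the pipeline can be exercised without any database
download or wet-lab data: this module writes evidence exports, qPCR Ct
tables and MTT absorbance plates whose true scores, fold changes and
viability fractions are planted and returned alongside, so recovery can
be checked exactly (evidence) or within noise (expression stages).

All generation is driven by a ``numpy`` Generator seeded explicitly;
the same seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .evidence import GenePanel, ToolRegistry
from .scoring import c_score

#: Validated source databases emulated by the generator.
VALIDATED_SOURCES = ("TarBase", "miRTarBase")


@dataclass(frozen=True)
class PlantedEvidenceTruth:
    """Ground truth for one synthetic evidence-export set.

    ``validated`` maps miRNA -> set of validated panel genes;
    ``predicted`` maps miRNA -> {gene: number of tools listing the pair}.
    """

    validated: Mapping[str, frozenset[str]] = field(default_factory=dict)
    predicted: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    def expected_scores(self, panel: GenePanel, registry: ToolRegistry) -> pd.DataFrame:
        """The V/P/C scores the pipeline must recover, straight from the plant."""
        mirnas = sorted(set(self.validated) | set(self.predicted))
        rows = []
        for m in mirnas:
            vgenes = {g for g in self.validated.get(m, ()) if g in panel}
            counts = {
                g: int(c)
                for g, c in self.predicted.get(m, {}).items()
                if g in panel and c > 0
            }
            v = len(vgenes)
            p = sum(counts.values())
            rows.append(
                {
                    "mirna": m,
                    "v_score": v,
                    "p_score": p,
                    "c_score": c_score(p, v, registry.size, panel.size),
                    "n_target_genes": len(vgenes | set(counts)),
                }
            )
        return pd.DataFrame(rows, columns=["mirna", "v_score", "p_score", "c_score", "n_target_genes"])


def generate_evidence_exports(
    panel: GenePanel,
    registry: ToolRegistry,
    truth: PlantedEvidenceTruth,
    out_dir: str | Path,
    seed: int = 0,
) -> tuple[Path, dict[str, Path]]:
    """Write a validated export plus one export per prediction tool.

    For each (miRNA, gene) pair, exactly ``count`` distinct tools —
    sampled without replacement, which tools is immaterial to every
    score — list the pair; each validated pair is listed under one or
    two source databases.  Returns (validated path, {tool: path}).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    tools = list(registry.tools)

    val_rows = []
    for mirna in sorted(truth.validated):
        for gene in sorted(truth.validated[mirna]):
            n_src = int(rng.integers(1, len(VALIDATED_SOURCES) + 1))
            picked = rng.choice(len(VALIDATED_SOURCES), size=n_src, replace=False)
            for i in sorted(picked):
                val_rows.append((mirna, gene, VALIDATED_SOURCES[i]))
    validated_path = out_dir / "validated.tsv"
    pd.DataFrame(val_rows, columns=["mirna", "gene", "source"]).to_csv(
        validated_path, sep="\t", index=False
    )

    per_tool: dict[str, list[tuple[str, str]]] = {t: [] for t in tools}
    for mirna in sorted(truth.predicted):
        for gene in sorted(truth.predicted[mirna]):
            count = int(truth.predicted[mirna][gene])
            if not (0 <= count <= registry.size):
                raise DomainError(
                    f"planted count {count} for ({mirna}, {gene}) outside "
                    f"[0, {registry.size}]"
                )
            picked = rng.choice(len(tools), size=count, replace=False)
            for i in sorted(picked):
                per_tool[tools[i]].append((mirna, gene))
    tool_paths: dict[str, Path] = {}
    for tool in tools:
        path = out_dir / f"{tool}.tsv"
        pd.DataFrame(per_tool[tool], columns=["mirna", "gene"]).to_csv(
            path, sep="\t", index=False
        )
        tool_paths[tool] = path
    return validated_path, tool_paths


def random_truth(
    panel: GenePanel,
    mirna_pool: Sequence[str],
    registry: ToolRegistry,
    rng: np.random.Generator,
    p_validated: float = 0.3,
    p_predicted: float = 0.6,
) -> PlantedEvidenceTruth:
    """Draw a random planted truth over the pool (for property tests)."""
    validated = {}
    predicted = {}
    for m in mirna_pool:
        vset = frozenset(g for g in panel if rng.random() < p_validated)
        counts = {
            g: int(rng.integers(1, registry.size + 1))
            for g in panel
            if rng.random() < p_predicted
        }
        if vset:
            validated[m] = vset
        if counts:
            predicted[m] = counts
    return PlantedEvidenceTruth(validated=validated, predicted=predicted)


def generate_ct_table(
    planted_folds: Mapping[str, Mapping[str, float]],
    control_group: str = "control",
    reference_assay: str = "GAPDH",
    n_bio: int = 3,
    n_tech: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
    base_reference_ct: float = 16.0,
    base_delta_ct: float = 8.0,
) -> pd.DataFrame:
    """Simulate a long-format qPCR Ct table with planted fold changes.

    ``planted_folds`` maps treated group -> {assay: true fold versus
    control}; the control group is generated implicitly at fold 1 for
    every assay.  Per technical replicate,
    Ct(reference) ~ base + N(0, noise_sd) and
    Ct(target) = base + dCt(control) - log2(fold) + N(0, noise_sd),
    so the noiseless table recovers each planted fold exactly.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    assays = sorted({a for folds in planted_folds.values() for a in folds})
    for group, folds in planted_folds.items():
        for assay, fold in folds.items():
            if not fold > 0:
                raise DomainError(f"planted fold for ({group}, {assay}) must be > 0")
    rng = np.random.default_rng(seed)
    groups = [control_group] + sorted(planted_folds)
    rows = []
    for group in groups:
        for bio in range(1, n_bio + 1):
            sample = f"{group}_b{bio}"
            for assay in assays + [reference_assay]:
                if assay == reference_assay:
                    base = base_reference_ct
                else:
                    fold = 1.0 if group == control_group else planted_folds[group].get(assay, 1.0)
                    base = base_reference_ct + base_delta_ct - np.log2(fold)
                for tech in range(1, n_tech + 1):
                    ct = base + rng.normal(0.0, noise_sd)
                    rows.append((sample, group, bio, tech, assay, ct))
    return pd.DataFrame(rows, columns=["sample", "group", "bio_rep", "tech_rep", "assay", "ct"])


def generate_viability_plate(
    planted_fractions: Mapping[str, Mapping[float, float]],
    n_wells: int = 6,
    well_noise: float = 0.02,
    seed: int = 0,
    background: float = 0.05,
    full_signal: float = 0.6,
) -> pd.DataFrame:
    """Simulate an MTT plate: a630 background plus a570 signal
    proportional to the planted viability fraction.

    ``planted_fractions`` maps group -> {timepoint_h: fraction}; the
    control group must be included (typically at fraction 1.0).
    ``well_noise`` is the absolute SD of the well signal relative to
    full signal.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in sorted(planted_fractions):
        for tp in sorted(planted_fractions[group]):
            frac = planted_fractions[group][tp]
            if frac < 0:
                raise DomainError("planted viability fraction must be >= 0")
            for well in range(1, n_wells + 1):
                a630 = background * (1 + rng.normal(0.0, 0.05))
                signal = full_signal * frac + full_signal * rng.normal(0.0, well_noise)
                rows.append((group, float(tp), well, a630 + signal, a630))
    return pd.DataFrame(rows, columns=["group", "timepoint_h", "well", "a570", "a630"])


def write_truth_json(truth: PlantedEvidenceTruth, path: str | Path) -> None:
    payload = {
        "validated": {m: sorted(v) for m, v in truth.validated.items()},
        "predicted": {m: dict(sorted(c.items())) for m, c in truth.predicted.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
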