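"""Bundled reference data for the seven-gene atherosclerosis panel.

The package ships the curated evidence summaries for the fixed panel of
clinically validated atherosclerosis drug-target genes (PCSK9, HMGCR,
MTTP, APOC3, LPA, CETP, APOB): which panel genes the leading candidate
miRNAs hit in validated databases, the per-gene prediction-tool counts
of the top predicted miRNAs, published fold-change panels usable as
emulation scenarios for the synthetic qPCR generator, and a synthetic
STRING-style edge list (see ``data/ppi_athero_synthetic.tsv``) built to
reproduce the panel's confidence-tier edge profile for demonstration.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .evidence import GenePanel
from .simulate import PlantedEvidenceTruth

#: The fixed atherosclerosis drug-target panel (G = 7).
ATHERO_PANEL_GENES = ("PCSK9", "HMGCR", "MTTP", "APOC3", "LPA", "CETP", "APOB")


def athero_panel() -> GenePanel:
    return GenePanel(ATHERO_PANEL_GENES)


#: Validated targeting of panel genes by the leading candidate miRNAs
#: (union over TarBase-class and miRTarBase-class databases).
VALIDATED_TARGETS: dict[str, frozenset[str]] = {
    "hsa-miR-124-3p": frozenset({"CETP", "APOB", "MTTP", "PCSK9"}),
    "hsa-miR-16-5p": frozenset({"APOB", "PCSK9", "HMGCR"}),
    "hsa-miR-191-5p": frozenset({"APOB", "PCSK9", "APOC3"}),
    "hsa-miR-335-5p": frozenset({"PCSK9", "HMGCR"}),
    "hsa-miR-29c-3p": frozenset({"PCSK9", "HMGCR"}),
    "hsa-miR-27a-3p": frozenset({"MTTP", "PCSK9"}),
    "hsa-miR-147a": frozenset({"PCSK9", "LPA"}),
    "hsa-let-7b-5p": frozenset({"APOB", "PCSK9"}),
    "hsa-miR-15b-5p": frozenset({"PCSK9", "HMGCR"}),
    "hsa-miR-1915-3p": frozenset({"PCSK9", "HMGCR"}),
}

#: Per-gene prediction-tool counts for the top predicted miRNAs
#: (number of tools, out of 30, confirming each miRNA-gene pair).
PREDICTED_COUNTS: dict[str, dict[str, int]] = {
    "hsa-miR-338-3p": {"CETP": 5, "APOB": 6, "MTTP": 5, "PCSK9": 8, "HMGCR": 16, "LPA": 9, "APOC3": 8},
    "hsa-miR-211-5p": {"CETP": 3, "APOB": 6, "MTTP": 10, "PCSK9": 7, "HMGCR": 16, "LPA": 3, "APOC3": 10},
    "hsa-miR-365a-3p": {"CETP": 9, "APOB": 6, "MTTP": 6, "PCSK9": 12, "HMGCR": 15, "LPA": 2, "APOC3": 2},
    "hsa-miR-149-5p": {"CETP": 4, "APOB": 1, "MTTP": 15, "PCSK9": 13, "HMGCR": 13, "LPA": 2, "APOC3": 3},
    "hsa-miR-204-5p": {"CETP": 2, "APOB": 5, "MTTP": 8, "PCSK9": 7, "HMGCR": 16, "LPA": 2, "APOC3": 10},
    "hsa-miR-335-5p": {"CETP": 2, "APOB": 2, "MTTP": 12, "PCSK9": 12, "HMGCR": 16, "LPA": 2, "APOC3": 2},
    "hsa-miR-139-5p": {"CETP": 3, "APOB": 4, "MTTP": 6, "PCSK9": 8, "HMGCR": 20, "LPA": 2, "APOC3": 4},
    "hsa-miR-143-3p": {"CETP": 5, "APOB": 4, "MTTP": 10, "PCSK9": 12, "HMGCR": 9, "LPA": 2, "APOC3": 5},
    "hsa-miR-1237-3p": {"CETP": 9, "APOB": 9, "MTTP": 4, "PCSK9": 7, "HMGCR": 10, "LPA": 3, "APOC3": 3},
}

#: Default miRNA pool for fixtures and simulations.
MIRNA_POOL: tuple[str, ...] = tuple(
    sorted(set(VALIDATED_TARGETS) | set(PREDICTED_COUNTS))
)


def reference_truth() -> PlantedEvidenceTruth:
    """Planted truth replicating the bundled evidence summaries, so the
    synthetic generator emits exports whose pipeline scores match the
    curated tables exactly."""
    return PlantedEvidenceTruth(
        validated=dict(VALIDATED_TARGETS), predicted=dict(PREDICTED_COUNTS)
    )


#: Published fold-change panels (mean, SD) relative to the empty-vector
#: control, keyed by (miRNA, cell line); usable as qPCR emulation
#: scenarios for the synthetic Ct generator.
QPCR_FOLD_PANELS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("miR-124", "HepG2"): {
        "CETP": (0.68, 0.04),
        "PCSK9": (0.53, 0.05),
        "MTTP": (0.34, 0.02),
        "APOB": (0.29, 0.03),
        "LPA": (0.66, 0.05),
    },
    ("miR-124", "Huh7"): {
        "CETP": (0.80, 0.04),
        "PCSK9": (0.68, 0.02),
        "MTTP": (0.55, 0.03),
        "APOB": (0.27, 0.01),
        "APOC3": (0.69, 0.03),
    },
    ("miR-16", "HepG2"): {
        "APOC3": (0.32, 0.01),
        "CETP": (0.84, 0.03),
        "HMGCR": (0.62, 0.04),
        "PCSK9": (0.80, 0.03),
        "MTTP": (0.50, 0.03),
        "APOB": (0.84, 0.05),
    },
    ("miR-16", "Huh7"): {
        "APOC3": (0.69, 0.03),
        "CETP": (0.76, 0.04),
        "HMGCR": (0.84, 0.03),
        "PCSK9": (0.85, 0.02),
        "MTTP": (0.27, 0.01),
        "APOB": (0.68, 0.02),
    },
}


def ppi_fixture_path() -> Path:
    """Synthetic STRING-style edge list for the panel, constructed to
    show 20 / 14 / 8 edges at the medium / high / highest tiers."""
    return Path(resources.files("mirpanel").joinpath("data/ppi_athero_synthetic.tsv"))


def panel_file_path() -> Path:
    """Bundled panel file: one gene per line."""
    return Path(resources.files("mirpanel").joinpath("data/athero_panel.txt"))
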