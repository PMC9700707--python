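"""Canonicalization, readers, and evidence-matrix assembly."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirpanel import (
    GenePanel,
    ToolRegistry,
    build_evidence_matrix,
    canonicalize_gene,
    canonicalize_mirna,
    read_predicted_tables,
    read_validated_table,
)
from mirpanel.errors import (
    ConfigurationError,
    MalformedIdentifierError,
    RegistryError,
    SchemaError,
)
from mirpanel.evidence import EvidenceMatrix

from conftest import write_tsv


class TestCanonicalizeMirna:
    @pytest.mark.parametrize(
        "raw,canonical",
        [
            ("HSA-MIR-124-3P", "hsa-miR-124-3p"),
            ("hsa-miR-124-3p", "hsa-miR-124-3p"),
            ("  hsa-let-7b-5p ", "hsa-let-7b-5p"),
            ("Hsa-Mir-16-5P", "hsa-miR-16-5p"),
        ],
    )
    def test_case_insensitive_canonical_form(self, raw, canonical):
        assert canonicalize_mirna(raw) == canonical

    def test_arm_suffix_distinguishes_mature_mirnas(self):
        assert canonicalize_mirna("hsa-miR-16-5p") != canonicalize_mirna("hsa-miR-16-3p")

    @pytest.mark.parametrize("bad", ["", "   ", None])
    def test_empty_identifier_rejected(self, bad):
        with pytest.raises(MalformedIdentifierError):
            canonicalize_mirna(bad)

    @given(st.text(alphabet="abcdefgHSAMIR0123456789-p", min_size=1).filter(str.strip))
    @settings(max_examples=100, deadline=None)
    def test_idempotent_and_case_invariant(self, raw):
        c = canonicalize_mirna(raw)
        assert canonicalize_mirna(c) == c
        assert canonicalize_mirna(raw.upper()) == canonicalize_mirna(raw.lower())


class TestGeneSymbols:
    def test_uppercasing_and_default_alias(self):
        assert canonicalize_gene("apoc3") == "APOC3"
        assert canonicalize_gene("APOCIII") == "APOC3"

    def test_custom_alias_map(self):
        assert canonicalize_gene("foo", {"FOO": "BAR"}) == "BAR"

    def test_panel_rejects_duplicates_after_aliasing(self):
        with pytest.raises(ConfigurationError):
            GenePanel(("APOC3", "APOCIII"))

    def test_panel_from_file(self, tmp_path, panel):
        p = tmp_path / "panel.txt"
        p.write_text("# panel\n" + "\n".join(g.lower() for g in panel.genes) + "\n")
        assert GenePanel.from_file(p).genes == panel.genes


class TestReadValidatedTable:
    def test_duplicates_collapse_and_case_folds(self, tmp_path, panel):
        path = write_tsv(
            tmp_path / "val.tsv",
            ["mirna", "gene", "source"],
            [
                ("hsa-miR-124-3p", "CETP", "TarBase"),
                ("HSA-MIR-124-3P", "cetp", "TarBase"),
                ("hsa-miR-124-3p", "apoc3", "miRTarBase"),
                ("hsa-miR-124-3p", "NOTPANEL", "TarBase"),
            ],
        )
        df = read_validated_table(path, panel=panel)
        assert len(df) == 3
        assert set(df["gene"]) == {"CETP", "APOC3", "NOTPANEL"}
        assert df.set_index("gene")["on_panel"].to_dict() == {
            "CETP": True, "APOC3": True, "NOTPANEL": False,
        }

    def test_comma_delimiter_sniffed(self, tmp_path):
        path = tmp_path / "val.csv"
        path.write_text("mirna,gene,source\nhsa-miR-16-5p,APOB,TarBase\n")
        df = read_validated_table(path)
        assert df.iloc[0]["gene"] == "APOB"

    def test_missing_column_is_schema_error(self, tmp_path):
        path = write_tsv(tmp_path / "bad.tsv", ["mirna", "gene"], [("m", "G")])
        with pytest.raises(SchemaError):
            read_validated_table(path)


class TestReadPredictedTables:
    def test_within_tool_duplicates_count_once(self, tmp_path, small_registry):
        t = small_registry.tools[0]
        path = write_tsv(
            tmp_path / f"{t}.tsv",
            ["mirna", "gene"],
            [("hsa-miR-1-3p", "CETP"), ("HSA-MIR-1-3P", "CETP")],
        )
        df = read_predicted_tables({t: path}, small_registry)
        assert len(df) == 1

    def test_distinct_tools_accumulate(self, tmp_path, small_registry, panel):
        paths = {}
        for t in small_registry.tools[:5]:
            paths[t] = write_tsv(
                tmp_path / f"{t}.tsv", ["mirna", "gene"], [("hsa-miR-1-3p", "CETP")]
            )
        df = read_predicted_tables(paths, small_registry)
        matrix = build_evidence_matrix(None, df, panel, small_registry)
        assert matrix.cell("hsa-miR-1-3p", "CETP") == (False, 5)

    def test_unregistered_tool_rejected(self, tmp_path, small_registry):
        path = write_tsv(tmp_path / "x.tsv", ["mirna", "gene"], [("m-1", "G")])
        with pytest.raises(RegistryError):
            read_predicted_tables({"not-a-tool": path}, small_registry)


class TestEvidenceMatrix:
    def test_no_interactions_gives_empty_matrix(self, panel, registry):
        m = build_evidence_matrix(None, None, panel, registry)
        assert len(m.table) == 0 and m.mirnas == []

    def test_single_validated_record(self, panel, registry):
        val = pd.DataFrame(
            [("hsa-miR-124-3p", "CETP", "TarBase")],
            columns=["mirna", "gene", "source_db"],
        )
        m = build_evidence_matrix(val, None, panel, registry)
        assert m.cell("hsa-miR-124-3p", "CETP") == (True, 0)
        assert m.cell("hsa-miR-124-3p", "APOB") == (False, 0)
        # one row per panel gene for the one evidenced miRNA
        assert len(m.table) == panel.size

    def test_count_above_registry_size_rejected(self, panel):
        tiny = ToolRegistry(("t1",))
        pred = pd.DataFrame(
            [("m-1", "CETP", "t1"), ("m-1", "CETP", "t2")],
            columns=["mirna", "gene", "tool"],
        )
        with pytest.raises(RegistryError):
            build_evidence_matrix(None, pred, panel, tiny)

    def test_round_trip_is_bit_identical(self, tmp_path, panel, registry):
        val = pd.DataFrame(
            [("hsa-miR-124-3p", "CETP", "TarBase")],
            columns=["mirna", "gene", "source_db"],
        )
        pred = pd.DataFrame(
            [("hsa-miR-124-3p", "APOB", registry.tools[0])],
            columns=["mirna", "gene", "tool"],
        )
        m = build_evidence_matrix(val, pred, panel, registry)
        p1, p2 = tmp_path / "m1.tsv", tmp_path / "m2.tsv"
        m.to_tsv(p1)
        EvidenceMatrix.from_tsv(p1, panel, registry).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_predicted_count_invariant_under_row_duplication(self, seed):
        """Duplicating any input row never changes a predicted count."""
        import numpy as np

        rng = np.random.default_rng(seed)
        panel = GenePanel(("G1", "G2", "G3"))
        registry = ToolRegistry.default(4)
        rows = [
            (f"m-{rng.integers(3)}", f"G{rng.integers(1, 4)}",
             registry.tools[rng.integers(4)])
            for _ in range(rng.integers(1, 12))
        ]
        pred = pd.DataFrame(rows, columns=["mirna", "gene", "tool"])
        dup_idx = int(rng.integers(len(rows)))
        pred_dup = pd.concat([pred, pred.iloc[[dup_idx]]], ignore_index=True)
        m1 = build_evidence_matrix(None, pred, panel, registry)
        m2 = build_evidence_matrix(None, pred_dup, panel, registry)
        pd.testing.assert_frame_equal(m1.table, m2.table)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_counts_match_brute_force_recount(self, seed):
        """predicted_count equals a set-based recount of distinct
        (tool, miRNA, gene) triples."""
        import numpy as np

        rng = np.random.default_rng(seed)
        panel = GenePanel(("G1", "G2", "G3", "G4"))
        registry = ToolRegistry.default(6)
        rows = [
            (f"m-{rng.integers(4)}", f"G{rng.integers(1, 5)}",
             registry.tools[rng.integers(6)])
            for _ in range(rng.integers(0, 30))
        ]
        pred = pd.DataFrame(rows, columns=["mirna", "gene", "tool"])
        matrix = build_evidence_matrix(None, pred, panel, registry)
        triples = set(map(tuple, rows))
        for _, row in matrix.table.iterrows():
            expected = sum(
                1 for (m, g, t) in triples if m == row["mirna"] and g == row["gene"]
            )
            assert row["predicted_count"] == expected
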