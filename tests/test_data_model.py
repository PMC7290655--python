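"""Peptide windowing, benchmark assembly and redundancy clearance."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gpspbs.data_model import (
    BenchmarkDataset,
    HierarchyNode,
    PBPItem,
    PSPT_GROUP,
    PY_GROUP,
    SiteError,
    admissible_for_training,
    build_benchmark,
    extract_pbp,
)


class TestExtractPBP:
    @pytest.mark.parametrize("sequence,position,m,n,expected", [
        ("MSK", 2, 2, 2, "*MSK*"),       # both termini padded
        ("STY", 1, 2, 2, "**STY"),       # N-terminal center
        ("STY", 3, 2, 2, "STY**"),       # C-terminal center
        ("ACDEFGHIKSLMNPQRVWYT", 10, 3, 3, "HIKSLMN"),  # interior, no padding
    ])
    def test_windows_and_padding(self, sequence, position, m, n, expected):
        item = extract_pbp(sequence, position, m, n)
        assert item.peptide == expected
        assert item.center_residue == sequence[position - 1]

    def test_default_window_has_length_21(self):
        item = extract_pbp("MS" + "A" * 30, 2)
        assert item.m == item.n == 10
        assert len(item.peptide) == 21

    def test_position_out_of_range(self):
        with pytest.raises(SiteError):
            extract_pbp("MSK", 4, 2, 2)
        with pytest.raises(SiteError):
            extract_pbp("MSK", 0, 2, 2)

    def test_center_class_filtering(self):
        with pytest.raises(SiteError):
            extract_pbp("MAK", 2, 2, 2, allowed_centers="STY")

    def test_nonstandard_residues_map_to_pad(self):
        item = extract_pbp("AUSXB", 3, 2, 2)
        assert item.peptide == "A*S**"

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60),
           st.data())
    @settings(max_examples=100, deadline=None)
    def test_window_length_and_strip_recovery(self, sequence, data):
        position = data.draw(st.integers(1, len(sequence)))
        m = data.draw(st.integers(0, 12))
        n = data.draw(st.integers(0, 12))
        item = extract_pbp(sequence, position, m, n)
        assert len(item.peptide) == m + 1 + n
        assert item.peptide[m] == sequence[position - 1]
        assert item.peptide.strip("*") in sequence


class TestHierarchy:
    def test_three_level_chain(self):
        fam = HierarchyNode("family", "14-3-3", PSPT_GROUP)
        clu = HierarchyNode("cluster", "YWHAZ", fam)
        assert clu.group is PSPT_GROUP
        assert clu.center_classes == frozenset("ST")
        assert PY_GROUP.center_classes == frozenset("Y")

    def test_invalid_parents_rejected(self):
        with pytest.raises(ValueError):
            HierarchyNode("cluster", "X", PSPT_GROUP)  # cluster under a group
        with pytest.raises(ValueError):
            HierarchyNode("family", "X", None)

    def test_cluster_admissibility_floor(self):
        fam = HierarchyNode("family", "SH2", PY_GROUP)
        clu = HierarchyNode("cluster", "GRB2", fam)
        assert not admissible_for_training(clu, 2)
        assert admissible_for_training(clu, 3)


class TestBuildBenchmark:
    def site_table(self, rows):
        return pd.DataFrame(rows, columns=["protein_id", "position", "residue"])

    def test_counts_for_pspt_group(self):
        # 5 S, 3 T, 2 Y; one annotated pS site -> 5 + 3 - 1 negatives
        seq = "ASATSYTSASYTSAA"
        assert seq.count("S") == 5 and seq.count("T") == 3
        sites = self.site_table([("P", 2, "S")])
        bench = build_benchmark({"P": seq}, sites, PSPT_GROUP, m=4, n=4)
        assert len(bench.positives) == 1
        assert len(bench.negatives) == 7  # 5 S + 3 T minus the annotated site

    def test_duplicate_positives_collapse(self):
        # identical flanking context at two annotated sites -> one positive
        seq = "AAASAAA" + "AAASAAA"
        sites = self.site_table([("P", 4, "S"), ("P", 11, "S")])
        bench = build_benchmark({"P": seq}, sites, PSPT_GROUP, m=3, n=3)
        assert len(bench.positives) == 1

    def test_negatives_deduplicated_against_positives_and_themselves(self):
        proteins = {"A": "CCCSCCC", "B": "CCCSCCC", "C": "DDDSDDDSDDD"}
        sites = self.site_table([("A", 4, "S"), ("C", 4, "S")])
        bench = build_benchmark(proteins, sites, PSPT_GROUP, m=3, n=3)
        # brute-force enumeration: every S window, de-duplicated as strings
        all_windows = {(pid, i + 1): extract_pbp(seq, i + 1, 3, 3).peptide
                       for pid, seq in proteins.items()
                       for i, r in enumerate(seq) if r == "S"}
        pos_peps = {all_windows[("A", 4)], all_windows[("C", 4)]}
        neg_peps = {p for k, p in all_windows.items()
                    if k not in (("A", 4), ("C", 4))} - pos_peps
        assert {p.peptide for p in bench.positives} == pos_peps
        assert {p.peptide for p in bench.negatives} == neg_peps

    def test_site_sequence_mismatch_is_named(self):
        with pytest.raises(SiteError, match="P1:2"):
            build_benchmark({"P1": "AAAA"}, self.site_table([("P1", 2, "S")]),
                            PSPT_GROUP)

    def test_empty_positives_rejected(self):
        with pytest.raises(ValueError):
            build_benchmark({"P": "AS"}, self.site_table([]), PSPT_GROUP)

    def test_idempotence(self):
        seq = "ASATSYTSASYTSAA"
        sites = self.site_table([("P", 2, "S"), ("P", 5, "S")])
        first = build_benchmark({"P": seq}, sites, PSPT_GROUP, m=4, n=4)
        again = build_benchmark(
            {"P": seq},
            self.site_table([(p.protein_id, p.position, p.center_residue)
                             for p in first.positives]),
            PSPT_GROUP, m=4, n=4)
        assert {p.peptide for p in again.positives} == \
            {p.peptide for p in first.positives}
        assert {p.peptide for p in again.negatives} == \
            {p.peptide for p in first.negatives}

    def test_class_overlap_rejected_by_dataset_invariant(self):
        item = extract_pbp("AASAA", 3, 2, 2, protein_id="P")
        with pytest.raises(ValueError):
            BenchmarkDataset(PSPT_GROUP, [item], [item])

    def test_tsv_roundtrip(self, tmp_path, motif_benchmark):
        path = tmp_path / "bench.tsv"
        motif_benchmark.to_tsv(path)
        back = BenchmarkDataset.from_tsv(path, motif_benchmark.node)
        assert [p.peptide for p in back.positives] == \
            [p.peptide for p in motif_benchmark.positives]
        assert len(back.negatives) == len(motif_benchmark.negatives)
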