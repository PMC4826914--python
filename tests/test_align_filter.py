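"""Block filtering, singleton-window masking, and back-translation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netsel.align_filter import (
    MaskAnnotation,
    backtranslate,
    filter_blocks,
    read_mask_tsv,
    singleton_window_mask,
    write_mask_tsv,
)
from netsel.msa import Alignment


def aln(rows, ids=None):
    ids = ids or [f"t{i}" for i in range(len(rows))]
    return Alignment(ids=ids, seqs=rows)


class TestFilterBlocks:
    def test_fully_conserved_alignment_unmasked(self):
        a = aln(["A" * 30] * 4)
        assert filter_blocks(a).union() == set()

    def test_gap_column_is_nonconserved(self):
        # one gap column inside conserved flanks: run of 1 <= 8, flanks long
        rows = ["A" * 12 + "-" + "A" * 12, "A" * 25, "A" * 25, "A" * 25]
        mask = filter_blocks(aln(rows))
        assert 13 not in mask.union()  # short nonconserved run survives
        rows2 = ["A" * 12 + "-" * 9 + "A" * 12] + ["A" * 33] * 3
        mask2 = filter_blocks(aln(rows2))
        assert mask2.union() == set(range(13, 22))  # run of 9 > 8 masked

    def test_three_rules_hand_case(self, rng):
        residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        mid = ["".join(rng.choice(residues, 9)) for _ in range(4)]
        # force nonconserved: make all four rows differ at every middle column
        mid = ["ACDEFGHIK", "CDEFGHIKL", "DEFGHIKLM", "EFGHIKLMN"]
        rows = ["W" * 12 + m + "Y" * 12 for m in mid]
        mask = filter_blocks(aln(rows))
        assert mask.union() == set(range(13, 22))

    def test_short_surviving_block_masked(self):
        # conserved 5 | nonconserved 9 | conserved 20: leading block < 10 goes
        mid = ["ACDEFGHIK", "CDEFGHIKL", "DEFGHIKLM", "EFGHIKLMN"]
        rows = ["W" * 5 + m + "Y" * 20 for m in mid]
        mask = filter_blocks(aln(rows))
        assert mask.union() == set(range(1, 15))


class TestSingletonWindows:
    def test_identical_rows_unmasked(self):
        a = aln(["MKTAYIAKQRQISFVKSHFS"] * 5)
        assert singleton_window_mask(a).union() == set()

    def test_ten_singletons_mask_window_union(self):
        # 5 taxa x 20 cols; taxon 0 singleton at columns 3..12 (1-based)
        base = "A" * 20
        t0 = "AA" + "CDEFGHIKLM" + "A" * 8
        a = aln([t0] + [base] * 4)
        mask = singleton_window_mask(a)
        assert mask.union() == set(range(1, 18))

    def test_five_run_rule(self):
        base = "A" * 20
        t1 = "A" * 4 + "CDEFG" + "A" * 11  # singleton at columns 5..9 only
        a = aln([base, t1, base, base, base])
        mask = MaskAnnotation()
        mask = singleton_window_mask(a)
        assert mask.columns["window5"] == set(range(5, 10))

    def test_nine_scattered_singletons_do_not_trigger(self):
        base = "A" * 15
        t0 = "CDEFGHIKL" + "A" * 6  # 9 singletons < 10 in any 15-window
        a = aln([t0, base, base, base, base])
        mask = singleton_window_mask(a)
        assert mask.columns["window15"] == set()

    def test_short_alignment_yields_empty_mask(self):
        a = aln(["MKT", "MKT", "MKA"])
        assert singleton_window_mask(a).union() == set()

    def test_gaps_never_count_as_singletons(self):
        base = "A" * 20
        gappy = "A" * 4 + "-" * 10 + "A" * 6
        a = aln([gappy, base, base, base, base])
        assert singleton_window_mask(a).union() == set()

    def test_needs_three_sequences(self):
        with pytest.raises(ValueError):
            singleton_window_mask(aln(["AAA", "AAB"]))

    def test_masking_idempotent_on_filtered_alignment(self, rng):
        """Re-masking after removing masked columns adds nothing new."""
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(residues, 40))
        rows = [base] * 4
        corrupt = list(base)
        for c in range(10, 25):
            corrupt[c] = "W" if base[c] != "W" else "Y"
        rows.append("".join(corrupt))
        a = aln(rows)
        mask = singleton_window_mask(a)
        keep = [c for c in range(40) if c + 1 not in mask.union()]
        filtered = aln(["".join(r[c] for c in keep) for r in rows])
        again = singleton_window_mask(filtered)
        assert again.union() == set()


class TestBacktranslate:
    def test_mask_arithmetic(self):
        prot = aln(["MKMKMKMKMK"] * 2)
        cds = {"t0": "ATGAAA" * 5, "t1": "ATGAAA" * 5}
        mask = MaskAnnotation()
        mask.add("window15", [4, 5, 6])
        out = backtranslate(prot, cds, mask)
        assert out.length == 21

    def test_empty_mask_identity(self):
        prot = aln(["MK", "MK"])
        cds = {"t0": "ATGAAA", "t1": "ATGAAG"}
        out = backtranslate(prot, cds, None)
        assert out.seqs == ["ATGAAA", "ATGAAG"]

    def test_gap_maps_to_gap_codon(self):
        prot = aln(["M-K", "MQK"])
        cds = {"t0": "ATGAAA", "t1": "ATGCAGAAG"}
        out = backtranslate(prot, cds, None)
        assert out.seqs[0] == "ATG---AAA"

    def test_translation_mismatch_reports_taxon_and_position(self):
        prot = aln(["MK", "MK"])
        cds = {"t0": "ATGAAA", "t1": "ATGCCC"}  # CCC = P, not K
        with pytest.raises(ValueError, match="t1.*position 2"):
            backtranslate(prot, cds, None)

    def test_bad_cds_length_rejected(self):
        prot = aln(["MK", "MK"])
        with pytest.raises(ValueError, match="divisible"):
            backtranslate(prot, {"t0": "ATGAA", "t1": "ATGAAA"}, None)

    def test_trailing_stop_tolerated(self):
        prot = aln(["MK", "MK"])
        cds = {"t0": "ATGAAATAA", "t1": "ATGAAA"}
        out = backtranslate(prot, cds, None)
        assert out.seqs[0] == "ATGAAA"


class TestMaskIO:
    def test_roundtrip(self, tmp_path):
        mask = MaskAnnotation()
        mask.add("block", [1, 2, 3])
        mask.add("window15", [2, 7])
        write_mask_tsv({"geneA": mask}, tmp_path / "m.tsv")
        back = read_mask_tsv(tmp_path / "m.tsv")
        assert back["geneA"].columns["block"] == {1, 2, 3}
        assert back["geneA"].union() == {1, 2, 3, 7}

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            MaskAnnotation().add("bogus", [1])

    def test_out_of_range_validation(self):
        mask = MaskAnnotation()
        mask.add("block", [99])
        with pytest.raises(ValueError):
            mask.validate(10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=55))
def test_union_mask_always_contains_each_rule(start):
    """Window-rule masks are unions: each rule's columns lie inside union()."""
    base = "A" * 60
    t0 = base[:start] + "CDEFG" + base[start + 5 :]
    a = Alignment(ids=["x", "y", "z"], seqs=[t0, base, base])
    mask = singleton_window_mask(a)
    for cols in mask.columns.values():
        assert cols <= mask.union()
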