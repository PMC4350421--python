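"""Consensus compilation, scanning, variant impact, coverage, enrichment."""

import math
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sadhtools import fixtures
from sadhtools.motifs import (
    DuplicateProteinIdError,
    EmptyInputError,
    IntervalError,
    InvalidSequenceError,
    ProteinRecord,
    RefMismatchError,
    UnknownMotifVariantError,
    VariantSpec,
    apply_variant,
    compile_consensus,
    conservation_table,
    merge_intervals,
    motif_coverage,
    mutation_enrichment,
    scan_protein,
    scan_proteome,
)


def regex_for(motif) -> re.Pattern:
    """Independent oracle: the consensus as a lookahead regex (finds
    overlapping matches), built directly from the class sets."""
    parts = []
    for cls in motif.positions:
        if len(cls) > 20:  # unconstrained
            parts.append(".")
        else:
            parts.append("[" + "".join(sorted(cls)) + "]")
    return re.compile("(?=" + "".join(parts) + ")")


class TestCompileConsensus:
    def test_simplified_classes(self):
        m = compile_consensus("simplified")
        assert len(m) == 8
        assert m.positions[0] == frozenset("Y")
        assert m.positions[1] == frozenset("KR")
        assert m.positions[3] == frozenset("FL")
        assert m.positions[6] == frozenset("ILV")
        assert m.positions[7] == frozenset("P")

    def test_full_classes(self):
        m = compile_consensus("full")
        assert len(m) == 11
        assert m.positions[0] == frozenset("KR")  # [+] excludes H
        assert m.positions[10] == frozenset("P")

    def test_unknown_variant_rejected(self):
        with pytest.raises(UnknownMotifVariantError):
            compile_consensus("extended")


class TestScanProtein:
    simplified = compile_consensus("simplified")

    def test_minimal_match(self):
        rec = ProteinRecord(id="p", sequence="YKSLAAIP")
        hits = scan_protein(rec, self.simplified)
        assert [(m.start, m.end) for m in hits] == [(1, 8)]
        assert hits[0].peptide == "YKSLAAIP"

    def test_class_violation_no_match(self):
        rec = ProteinRecord(id="p", sequence="YWSLAAIP")  # W not in [KR]
        assert scan_protein(rec, self.simplified) == []

    def test_sequence_shorter_than_motif_is_empty(self):
        rec = ProteinRecord(id="p", sequence="YKS")
        assert scan_protein(rec, self.simplified) == []

    def test_x_never_matches_constrained_class(self):
        rec = ProteinRecord(id="p", sequence="XKSLAAIP")
        assert scan_protein(rec, self.simplified) == []
        # but X at the unconstrained position is fine
        rec2 = ProteinRecord(id="p", sequence="YKXLAAIP")
        assert len(scan_protein(rec2, self.simplified)) == 1

    def test_case_insensitive(self):
        rec = ProteinRecord(id="p", sequence="ykslaaip")
        assert len(scan_protein(rec, self.simplified)) == 1

    def test_non_standard_character_rejected(self):
        with pytest.raises(InvalidSequenceError):
            ProteinRecord(id="p", sequence="YKSLAA1P")

    def test_scrib_cter_has_three_motifs(self):
        hits = scan_protein(fixtures.scrib_cter_record(), self.simplified)
        assert len(hits) == 3

    def test_repeat_labels(self):
        hits = scan_protein(fixtures.scrib_record(), self.simplified)
        labelled = fixtures.label_repeats(hits)
        assert [m.repeat_label for m in labelled] == [
            "repeat 1",
            "repeat 2",
            "repeat 3",
        ]


class TestScanProteome:
    simplified = compile_consensus("simplified")

    def test_peptide_panel_specificity(self):
        """Exactly the four canonical peptides carry the consensus."""
        panel = fixtures.sadh_peptide_panel()
        result = scan_proteome([rec for rec, _ in panel.values()], self.simplified)
        assert result.n_proteins_with_match == 4
        for name, (rec, canonical) in panel.items():
            assert bool(result.matches[name]) == canonical

    def test_empty_proteome(self):
        result = scan_proteome([], self.simplified)
        assert result.matches == {} and result.n_proteins_with_match == 0

    def test_duplicate_ids_rejected(self):
        rec = ProteinRecord(id="p", sequence="YKSLAAIP")
        with pytest.raises(DuplicateProteinIdError):
            scan_proteome([rec, rec], self.simplified)


class TestOracleEquivalence:
    """Scanner output equals a position-by-position regex window checker."""

    @given(
        st.text(alphabet="YKLAPX", min_size=0, max_size=30),
        st.sampled_from(["simplified", "full"]),
    )
    @settings(max_examples=300, derandomize=True)
    def test_random_sequences(self, seq, variant):
        motif = compile_consensus(variant)
        if not seq:
            return
        rec = ProteinRecord(id="p", sequence=seq)
        mine = [m.start for m in scan_protein(rec, motif)]
        # X must not be matched by the constrained classes, so the oracle
        # strips X from every constrained class too (it never contains X).
        oracle = [m.start() + 1 for m in regex_for(motif).finditer(seq)]
        assert mine == oracle


class TestSubstitutionClosure:
    @given(st.data())
    @settings(max_examples=200, derandomize=True)
    def test_mutation_inside_class_preserves_outside_destroys(self, data):
        motif = compile_consensus("simplified")
        seq = "".join(
            data.draw(st.sampled_from(sorted(cls - {"X"})))
            for cls in motif.positions
        )
        rec = ProteinRecord(id="p", sequence=seq)
        assert len(scan_protein(rec, motif)) == 1
        i = data.draw(st.integers(0, len(motif) - 1))
        cls = motif.positions[i]
        inside = sorted(cls - {"X", seq[i]})
        outside = sorted(set("ACDEFGHIKLMNPQRSTVWY") - cls)
        if inside:
            alt = data.draw(st.sampled_from(inside))
            mutated = ProteinRecord(id="p", sequence=seq[:i] + alt + seq[i + 1:])
            assert len(scan_protein(mutated, motif)) == 1
        if outside:
            alt = data.draw(st.sampled_from(outside))
            mutated = ProteinRecord(id="p", sequence=seq[:i] + alt + seq[i + 1:])
            assert scan_protein(mutated, motif) == []


class TestApplyVariant:
    full = compile_consensus("full")
    simplified = compile_consensus("simplified")

    def test_r1322w_destroys_full_consensus(self):
        rec = fixtures.scrib_record()
        spec = VariantSpec(rec.id, 1322, "R", "W", "R1322W")
        impact = apply_variant(rec, spec, self.full)
        assert impact.category == "motif_lost"
        assert impact.affected_match.start == 1322

    def test_p1332l_destroys_both_consensus_flavours(self):
        rec = fixtures.scrib_record()
        spec = VariantSpec(rec.id, 1332, "P", "L", "P1332L")
        for motif in (self.full, self.simplified):
            assert apply_variant(rec, spec, motif).category == "motif_lost"

    def test_a1315t_outside_core(self):
        rec = fixtures.scrib_record()
        spec = VariantSpec(rec.id, 1315, "A", "T", "A1315T")
        # outside the 8-residue core under either consensus; the full
        # 11-mer of repeat 2 starts at 1322 so 1315 is outside it too
        assert apply_variant(rec, spec, self.simplified).category == "outside_motif"
        assert apply_variant(rec, spec, self.full).category == "outside_motif"

    def test_retained_when_substitution_stays_in_class(self):
        rec = ProteinRecord(id="p", sequence="GGYKSLAAIPGG")
        spec = VariantSpec("p", 4, "K", "R")  # K -> R stays in [KR]
        impact = apply_variant(rec, spec, self.simplified)
        assert impact.category == "motif_retained"

    def test_ref_mismatch_rejected(self):
        rec = ProteinRecord(id="p", sequence="YKSLAAIP")
        with pytest.raises(RefMismatchError):
            apply_variant(rec, VariantSpec("p", 1, "K", "R"), self.simplified)


class TestCoverage:
    def test_scrib_repeats_under_five_percent(self):
        cov = motif_coverage(fixtures.SCRIB_REPEAT_WINDOWS, 1657)
        assert cov == pytest.approx(75 / 1657)
        assert cov < 0.05

    def test_no_windows_is_zero(self):
        assert motif_coverage([], 100) == 0

    def test_overlapping_windows_merged(self):
        assert motif_coverage([(1, 25), (20, 44)], 100) == pytest.approx(0.44)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(IntervalError):
            motif_coverage([(0, 10)], 100)
        with pytest.raises(IntervalError):
            motif_coverage([(90, 101)], 100)

    @given(
        st.lists(
            st.tuples(st.integers(1, 200), st.integers(1, 200)).map(
                lambda t: (min(t), max(t))
            ),
            min_size=1,
            max_size=8,
        ),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounds_and_permutation_invariance(self, windows):
        cov = motif_coverage(windows, 200)
        assert 0 <= cov <= 1
        # window order does not change coverage
        assert motif_coverage(windows[::-1], 200) == pytest.approx(cov)
        # merging never increases coverage beyond the unmerged residue total
        unmerged = sum(hi - lo + 1 for lo, hi in windows)
        assert cov * 200 <= unmerged + 1e-9


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """Direct-summation oracle for P(X >= k), X ~ Binomial(n, p)."""
    return sum(
        math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
    )


class TestEnrichment:
    windows = fixtures.SCRIB_REPEAT_WINDOWS

    def test_scrib_fractions(self):
        # 6 of 61 mutation positions inside the repeats
        inside = [1245, 1250, 1315, 1322, 1332, 1560]
        outside = list(range(1, 56))
        res = mutation_enrichment(inside + outside, self.windows, 1657)
        assert res.n_mutations_total == 61
        assert res.n_mutations_in_motif == 6
        assert res.observed_fraction == pytest.approx(6 / 61)
        assert res.expected_fraction == pytest.approx(75 / 1657)

    def test_p_value_matches_direct_summation(self):
        inside = [1245, 1250, 1315, 1322, 1332, 1560]
        outside = list(range(1, 56))
        res = mutation_enrichment(inside + outside, self.windows, 1657)
        assert res.p_value == pytest.approx(
            binom_upper_tail(6, 61, 75 / 1657), rel=1e-9
        )

    def test_all_outside_gives_p_one(self):
        res = mutation_enrichment([1, 2, 3], self.windows, 1657)
        assert res.observed_fraction == 0
        assert res.p_value == 1

    def test_empty_mutation_list_rejected(self):
        with pytest.raises(EmptyInputError):
            mutation_enrichment([], self.windows, 1657)

    @pytest.mark.parametrize("n,p", [(61, 75 / 1657), (20, 0.1)])
    def test_p_value_monotone_in_hits(self, n, p):
        tails = [binom_upper_tail(k, n, p) for k in range(n + 1)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))
        # and the implementation reproduces the same monotone tail
        window = [(1, max(1, round(p * 1000)))]
        for k in range(0, 6):
            positions = [1] * k + [999] * (n - k)
            res = mutation_enrichment(positions, window, 1000)
            assert res.n_mutations_in_motif == k


class TestConservation:
    simplified = compile_consensus("simplified")

    def test_vertebrates_present_invertebrates_absent(self):
        records, clades = fixtures.ortholog_panel()
        table = conservation_table(records, self.simplified, clades)
        by_clade = table.groupby("clade")["present"].all()
        assert bool(by_clade["vertebrate"]) is True
        assert not table[table.clade == "invertebrate"]["present"].any()

    def test_all_glycine_absent(self):
        rec = ProteinRecord(id="g", sequence="G" * 50, species="test")
        table = conservation_table([rec], self.simplified)
        assert not table["present"].iloc[0]

    def test_single_planted_species_flagged(self):
        clean = ProteinRecord(id="a", sequence="G" * 40, species="sp_a")
        planted = ProteinRecord(
            id="b", sequence="G" * 16 + "YKSLAAIP" + "G" * 16, species="sp_b"
        )
        table = conservation_table([clean, planted], self.simplified)
        assert list(table[table.present]["species"]) == ["sp_b"]

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            conservation_table([], self.simplified)


def test_merge_intervals_basic():
    assert merge_intervals([(5, 9), (1, 3), (2, 4)]) == [(1, 4), (5, 9)]
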