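"""Motif pattern family, scanner-vs-oracle equivalence, pI and filters."""

import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_protein
from oracles import pi_grid, scan_spans
from rbskit.motifscan import (
    CLASS_IDS,
    EMBOSS_PKA,
    MotifMatch,
    apply_filters,
    classify_protein,
    compile_pattern,
    compute_pI,
    count_table,
    scan,
)
from rbskit.seqcore import Sequence

# Alphabet enriched in motif-relevant residues so random scans produce hits.
ENRICHED = "DDEEYFLAASTGNIVM"


class TestCompilePattern:
    def test_consensus_has_eight_elements_ending_in_leucine(self):
        pat = compile_pattern("RBS")
        assert len(pat.elements) == 8
        assert pat.elements[-1].residues == frozenset("L")
        assert (pat.min_span, pat.max_span) == (8, 12)

    def test_v2_terminal_element(self):
        pat = compile_pattern("RBS-V2")
        assert pat.elements[-1].residues == frozenset("FIMV")

    def test_v1_lacks_leading_acidic(self):
        pat = compile_pattern("RBS-V1")
        assert pat.min_span == 7  # one position shorter than the consensus

    def test_expanded_is_a_union(self):
        pat = compile_pattern("EXPANDED")
        assert len(pat.alternatives) == 2
        assert (pat.min_span, pat.max_span) == (8, 13)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            compile_pattern("RBS-X")


class TestScan:
    def test_forward_consensus_example(self):
        ms = scan(Sequence("s", "EAAYAAADL"), compile_pattern("RBS"))
        assert [(m.span, m.class_id) for m in ms] == [((1, 9), "RBS")]

    def test_all_basic_sequence_has_no_hits(self):
        assert scan(Sequence("s", "KKKKKKKKKK"), compile_pattern("RBS")) == []

    def test_reverse_orientation_covers_same_residues(self):
        rev = Sequence("s", "EAAYAAADL"[::-1])
        ms = scan(rev, compile_pattern("RBS"), orientations=("reverse",))
        assert len(ms) == 1
        assert ms[0].span == (1, 9)
        assert ms[0].orientation == "reverse"
        assert ms[0].matched_peptide == "EAAYAAADL"

    def test_bidirectional_locus_yields_two_matches(self):
        # Palindromic arrangement: reads as a motif in both directions.
        s = Sequence("s", "LEDAYAYADEL")
        ms = scan(s, compile_pattern("RBS"), orientations=("forward", "reverse"))
        orientations = {m.orientation for m in ms}
        assert orientations == {"forward", "reverse"}

    def test_x_never_matches(self):
        # X at the mandatory aromatic position kills the match.
        assert scan(Sequence("s", "EAAXAAADL"), compile_pattern("RBS")) == []

    @pytest.mark.parametrize("class_id", CLASS_IDS)
    def test_oracle_equivalence_randomised(self, class_id, rng):
        pat = compile_pattern(class_id)
        for _ in range(300):
            seq = random_protein(rng, int(rng.integers(8, 61)), ENRICHED)
            got = {m.span for m in scan(seq, pat)}
            assert got == scan_spans(seq.residues, class_id)

    def test_rbs_spans_subset_of_expanded(self, rng):
        rbs, exp = compile_pattern("RBS"), compile_pattern("EXPANDED")
        for _ in range(200):
            seq = random_protein(rng, int(rng.integers(10, 50)), ENRICHED)
            assert {m.span for m in scan(seq, rbs)} <= {m.span for m in scan(seq, exp)}


class TestClassify:
    def _match(self, cls, seq_id="p"):
        return MotifMatch(seq_id, (1, 8), "forward", cls, "EAAYAADL")

    def test_consensus_takes_precedence_over_variants(self):
        assert classify_protein([self._match("RBS"), self._match("RBS-V2")]) == "RBS"

    def test_single_variant(self):
        assert classify_protein([self._match("RBS-V1")]) == "RBS-V1"

    def test_variant_precedence_order(self):
        assert classify_protein([self._match("RBS-V3"), self._match("RBS-V2")]) == "RBS-V2"

    def test_no_matches(self):
        assert classify_protein([]) == "none"

    def test_mixed_proteins_rejected(self):
        with pytest.raises(ValueError):
            classify_protein([self._match("RBS", "a"), self._match("RBS", "b")])


class TestIsoelectricPoint:
    def test_two_termini_only(self):
        assert compute_pI("GG") == pytest.approx(pi_grid("GG", EMBOSS_PKA), abs=2e-4)

    def test_motif_peptide_passes_acidic_filter(self):
        assert compute_pI("EAAYAAADL") < 4.5

    def test_grid_oracle_agreement_randomised(self, rng):
        for _ in range(1000):
            pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(2, 25))))
            assert compute_pI(pep) == pytest.approx(pi_grid(pep, EMBOSS_PKA), abs=2e-4)

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20))
    def test_appending_aspartate_never_raises_pi(self, pep):
        assert compute_pI(pep + "D") <= compute_pI(pep) + 2e-4


class TestFilters:
    def test_acidic_match_passes(self):
        m = apply_filters(MotifMatch("p", (1, 9), "forward", "RBS", "EAAYAAADL"))
        assert m.pI_ok and m.aromatic_ok
        assert m.pI_value < 4.5

    def test_threshold_is_strict(self):
        m = MotifMatch("p", (1, 9), "forward", "RBS", "EAAYAAADL")
        out = apply_filters(m, pi_threshold=compute_pI("EAAYAAADL"))
        assert out.pI_ok is False

    def test_basic_flanked_peptide_fails(self):
        # Extra K/H inside the wildcard positions drags the pI up.
        pep = "EKHYKHADL"
        assert compute_pI(pep) >= 4.5
        m = apply_filters(MotifMatch("p", (1, 9), "forward", "RBS", pep))
        assert m.pI_ok is False


class TestCountTable:
    def test_counts_and_format(self):
        labels = {f"p{i}": "RBS" for i in range(7)}
        labels |= {"q1": "RBS-V2", "q2": "RBS-V2", "q3": "none"}
        (row,) = count_table({"NAC": labels})
        assert row.formatted == "7/10"
        assert row.variants["RBS-V2"] == 2
        assert row.variants["RBS-V1"] == 0

    def test_empty_group(self):
        (row,) = count_table({"NAC": {}})
        assert row.formatted == "0/0"

    def test_variant_partition_bound(self):
        labels = {"a": "RBS", "b": "RBS-V1", "c": "RBS-V3", "d": "none"}
        (row,) = count_table({"G": labels})
        assert sum(row.variants.values()) <= row.total - row.consensus
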