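"""ORF discovery semantics, filters, taxonomy — checked against an
exhaustive pair-enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitorf import (
    Contig,
    HitRecord,
    assign_taxonomy,
    filter_contigs,
    find_orfs,
    get_code,
    resolve_table,
    single_orf_filter,
    translate,
)
from conftest import random_contig
from _oracles import call_tuple, orf_scan_oracle


class TestFilterContigs:
    def test_length_boundary(self):
        contigs = [Contig("a", "A" * 899), Contig("b", "A" * 900)]
        assert [c.contig_id for c in filter_contigs(contigs)] == ["b"]

    def test_empty_input(self):
        assert filter_contigs([]) == []

    def test_random_lengths_match_direct_check(self):
        rng = np.random.default_rng(3)
        contigs = [
            Contig(f"c{i}", "A" * int(rng.integers(500, 1501))) for i in range(50)
        ]
        kept = filter_contigs(contigs)
        assert kept == [c for c in contigs if len(c.seq) >= 900]


def _mk_orf(n_sense: int) -> str:
    return "ATG" + "AAA" * n_sense + "TAA"


class TestFindOrfs:
    def test_min_aa_boundary(self):
        # initiator + 299 sense codons = 300 residues: exactly at threshold
        contig = Contig("c", _mk_orf(299))
        calls = find_orfs(contig, get_code(1), min_aa=300)
        assert len(calls) == 1
        assert calls[0].aa_len == 300
        assert not find_orfs(Contig("c", _mk_orf(298)), get_code(1), min_aa=300)

    def test_internal_tga_splits_standard_but_not_table4(self):
        # one long frame with an internal TGA: full-length only under
        # mitochondrial decoding
        seq = "ATG" + "AAA" * 150 + "TGA" + "AAA" * 160 + "TAA"
        contig = Contig("c", seq)
        assert not find_orfs(contig, get_code(1), min_aa=300)
        calls = find_orfs(contig, get_code(4), min_aa=300)
        assert len(calls) == 1
        assert calls[0].peptide.count("W") == 1

    def test_minus_strand_coordinates_project_forward(self):
        from mitorf import reverse_complement

        orf = _mk_orf(120)
        utr5, utr3 = "CCTAAC", "GGGG"
        fwd = utr5 + orf + utr3
        contig = Contig("c", reverse_complement(fwd))
        calls = find_orfs(contig, get_code(1), min_aa=100)
        assert len(calls) == 1
        c = calls[0]
        assert c.strand == "-"
        assert (c.start, c.end) == (len(utr3), len(utr3) + len(orf))
        assert c.peptide == "M" + "K" * 120

    def test_first_start_per_segment_wins(self):
        # two in-frame ATGs in one stop-bounded segment: one ORF, from the first
        seq = "ATG" + "AAA" * 10 + "ATG" + "AAA" * 10 + "TAA"
        calls = find_orfs(Contig("c", seq), get_code(1), min_aa=5)
        starts = [c for c in calls if c.strand == "+" and c.frame == 0]
        assert len(starts) == 1
        assert starts[0].start == 0

    def test_edge_truncated_orf_flagged(self):
        seq = "ATG" + "AAA" * 50  # no terminal stop
        calls = find_orfs(Contig("c", seq), get_code(1), min_aa=40)
        c = next(c for c in calls if c.strand == "+" and c.frame == 0)
        assert not c.has_terminal_stop
        assert c.end == len(seq)

    def test_alt_start_reported_as_met(self):
        seq = "CCTAA" + "GTG" + "AAA" * 30 + "TAA"  # GTG initiator, frame 2
        calls = find_orfs(Contig("c", seq), get_code(2), min_aa=20)
        c = next(c for c in calls if c.used_alt_start)
        assert c.peptide[0] == "M"
        calls_no_alt = find_orfs(
            Contig("c", seq), get_code(2), min_aa=20, allow_alt_starts=False
        )
        assert not any(x.used_alt_start for x in calls_no_alt)

    @pytest.mark.parametrize("tid", [1, 2, 4, 5])
    @pytest.mark.parametrize("require_start", [True, False])
    def test_matches_oracle_on_random_contigs(self, tid, require_start):
        """Implementation ≡ exhaustive start/stop enumeration, mixed GC."""
        rng = np.random.default_rng(100 + tid)
        code = get_code(tid)
        for i in range(120):
            at = (0.3, 0.5, 0.72)[i % 3]
            seq = random_contig(rng, int(rng.integers(30, 600)), at)
            contig = Contig("r", seq)
            for alt in (True, False):
                got = [
                    call_tuple(c)
                    for c in find_orfs(
                        contig, code, min_aa=25,
                        require_start=require_start, allow_alt_starts=alt,
                    )
                ]
                expected = orf_scan_oracle(
                    seq, code, min_aa=25,
                    require_start=require_start, allow_alt_starts=alt,
                )
                assert got == expected

    @given(
        seq=st.text(alphabet="ACGTN", min_size=10, max_size=300),
        tid=st.sampled_from([1, 2, 4, 5]),
    )
    @settings(max_examples=80)
    def test_oracle_equivalence_property(self, seq, tid):
        code = get_code(tid)
        got = [call_tuple(c) for c in find_orfs(Contig("h", seq), code, min_aa=8)]
        assert got == orf_scan_oracle(seq, code, min_aa=8)

    @given(seq=st.text(alphabet="ACGT", min_size=60, max_size=400))
    @settings(max_examples=60)
    def test_no_internal_stop_on_retranslation(self, seq):
        """Re-translating any reported ORF shows no internal stop."""
        for tid in (1, 4):
            code = get_code(tid)
            for c in find_orfs(Contig("h", seq), code, min_aa=10):
                nt = c.coding_nt(Contig("h", seq))
                assert "*" not in translate(nt, code)


class TestSingleOrfFilter:
    def test_multi_orf_contig_dropped(self):
        orf = _mk_orf(40)
        seq = orf + "CC" + orf
        calls = find_orfs(Contig("c", seq), get_code(1), min_aa=30)
        plus = [c for c in calls if c.strand == "+"]
        assert len(plus) >= 2
        assert single_orf_filter(plus) == []

    def test_single_orf_passes(self):
        calls = find_orfs(Contig("c", _mk_orf(40)), get_code(1), min_aa=30)
        kept = single_orf_filter(calls)
        assert kept == calls

    def test_groups_are_per_contig_and_table(self):
        a = find_orfs(Contig("a", _mk_orf(40)), get_code(1), min_aa=30)
        b = find_orfs(Contig("b", _mk_orf(50)), get_code(4), min_aa=30)
        assert single_orf_filter(a + b) == a + b


class TestResolveTable:
    def _call(self, tid):
        return find_orfs(Contig("c", _mk_orf(40)), get_code(tid), min_aa=30)[0]

    def test_table4_wins(self):
        calls = {tid: self._call(tid) for tid in (2, 4, 5)}
        assert resolve_table(calls).table_id == 4

    def test_single_table_passthrough(self):
        assert resolve_table({5: self._call(5)}).table_id == 5

    def test_preference_order_5_over_2(self):
        calls = {tid: self._call(tid) for tid in (2, 5)}
        assert resolve_table(calls).table_id == 5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            resolve_table({})


class TestAssignTaxonomy:
    def _hit(self, sid, evalue, bitscore=100.0):
        return HitRecord("orf1", sid, 0.9, evalue, bitscore)

    def test_top_hit_by_evalue(self):
        hits = [self._hit("a", 1e-50), self._hit("b", 1e-80), self._hit("c", 1e-10)]
        assert assign_taxonomy("orf1", hits).subject_id == "b"

    def test_empty_returns_none(self):
        assert assign_taxonomy("orf1", []) is None

    def test_tie_breaks_by_bitscore_then_subject(self):
        hits = [self._hit("a", 1e-40, 200.0), self._hit("b", 1e-40, 250.0)]
        assert assign_taxonomy("orf1", hits).subject_id == "b"
        hits = [self._hit("b", 1e-40, 250.0), self._hit("a", 1e-40, 250.0)]
        assert assign_taxonomy("orf1", hits).subject_id == "a"

    def test_other_queries_ignored(self):
        hits = [self._hit("a", 1e-40), HitRecord("other", "z", 0.9, 1e-99, 500.0)]
        assert assign_taxonomy("orf1", hits).subject_id == "a"
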