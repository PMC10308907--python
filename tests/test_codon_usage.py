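"""Codon-usage vectors, Pearson R², correlation matrices."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitorf import (
    CodonUsageTable,
    build_reference_table,
    codon_frequencies,
    correlate_all,
    get_code,
    pearson_r2,
    sample_orf,
)
from mitorf.codon_usage import read_usage_table, write_usage_table
from mitorf.genetic_codes import CODONS
from mitorf.synthetic import builtin_usage_table, sample_reference_cds
from _oracles import pearson_r2_textbook


class TestCodonFrequencies:
    def test_single_codon(self):
        t = codon_frequencies(["ATG"])
        assert t.freq("ATG") == 1.0
        assert t.n_codons == 1

    def test_pooled_counts(self):
        t = codon_frequencies(["ATGATG", "TTT"])
        assert t.freq("ATG") == pytest.approx(2 / 3)
        assert t.freq("TTT") == pytest.approx(1 / 3)

    def test_additivity_over_records(self):
        """Pooled counts equal the sum of per-record counts."""
        rng = np.random.default_rng(2)
        seqs = [
            "".join(rng.choice(CODONS, size=int(rng.integers(5, 40))))
            for _ in range(50)
        ]
        pooled = codon_frequencies(seqs)
        summed = np.sum([codon_frequencies([s]).counts for s in seqs], axis=0)
        assert (pooled.counts == summed).all()

    def test_terminal_stop_trimming(self):
        t = codon_frequencies(["ATGTAA"], stop_codons=frozenset({"TAA"}))
        assert t.n_codons == 1
        assert t.freq("TAA") == 0.0

    def test_remainder_raises_or_trims(self):
        with pytest.raises(ValueError, match="record 0"):
            codon_frequencies(["ATGA"])
        t = codon_frequencies(["ATGA"], on_remainder="trim")
        assert t.n_codons == 1

    def test_n_codons_skipped(self):
        t = codon_frequencies(["ATGNNNAAA"])
        assert t.n_codons == 2

    def test_freqs_sum_to_one(self):
        t = codon_frequencies(["ATGATGTTTAAA"])
        assert t.freqs.sum() == pytest.approx(1.0, abs=1e-9)


class TestReferenceTables:
    def test_build_equals_direct_frequencies(self, tmp_path):
        from mitorf.io import write_fasta
        from mitorf.orfs import Contig

        seq = "ATGAAATTTCCC"
        p = tmp_path / "one.fasta"
        write_fasta([Contig("cds1", seq)], p)
        t = build_reference_table(p, "one")
        direct = codon_frequencies([seq])
        assert (t.counts == direct.counts).all()

    def test_empty_fasta_raises(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="no CDS"):
            build_reference_table(p, "x")

    def test_sampled_cds_recover_source_frequencies(self):
        """Law of large numbers: empirical usage approaches the source table."""
        usage = builtin_usage_table("synthetic_fungal_mito_like")
        cds = sample_reference_cds(usage, n_records=100, len_range=(900, 1100), seed=9)
        emp = codon_frequencies(cds, stop_codons=frozenset({"TAA"}))
        sense = [c for c in CODONS if c not in ("TAA", "TAG", "TGA")]
        src = np.array([usage.freq(c) for c in sense])
        src = src / src.sum()
        got = np.array([emp.freq(c) for c in sense])
        tv = 0.5 * np.abs(src - got).sum()
        assert emp.n_codons > 90_000
        assert tv < 0.02

    def test_tsv_round_trip(self, tmp_path):
        t = codon_frequencies(["ATGATGTTTAAACCC"], label="rt")
        p = tmp_path / "t.tsv"
        write_usage_table(t, p)
        back = read_usage_table(p)
        assert back.label == "rt"
        assert (back.counts == t.counts).all()

    def test_hive_per_1000_normalised(self, tmp_path):
        p = tmp_path / "hive.tsv"
        rows = ["codon\tper1000"]
        rows += [f"{c}\t{1000/64:.4f}" for c in CODONS]
        p.write_text("\n".join(rows))
        t = read_usage_table(p, label="hive")
        assert t.freqs.max() == pytest.approx(1 / 64, rel=1e-3)


class TestPearsonR2:
    def test_self_correlation_is_one(self):
        t = builtin_usage_table("synthetic_fungal_mito_like")
        assert pearson_r2(t, t) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_small_vectors(self):
        # support on 4 codons; value checked against the closed-form sum formula
        a = np.zeros(64, dtype=np.int64)
        b = np.zeros(64, dtype=np.int64)
        a[:4] = [10, 20, 30, 40]
        b[:4] = [40, 10, 20, 30]
        ta, tb = CodonUsageTable("a", a), CodonUsageTable("b", b)
        expected = pearson_r2_textbook(ta.freqs.tolist(), tb.freqs.tolist())
        assert pearson_r2(ta, tb) == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance(self):
        a = codon_frequencies(["ATGAAATTT"]).counts
        t1 = CodonUsageTable("x", a)
        t5 = CodonUsageTable("y", a * 5)
        ref = builtin_usage_table("synthetic_fungal_nuclear_like")
        assert pearson_r2(t1, ref) == pytest.approx(pearson_r2(t5, ref), abs=1e-12)

    def test_zero_variance_raises(self):
        flat = CodonUsageTable("flat", np.ones(64, dtype=np.int64))
        ref = builtin_usage_table("synthetic_fungal_mito_like")
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_r2(flat, ref)

    @given(seed=st.integers(0, 10_000))
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = CodonUsageTable("a", rng.integers(0, 1000, size=64))
        b = CodonUsageTable("b", rng.integers(0, 1000, size=64))
        expected = pearson_r2_textbook(a.freqs.tolist(), b.freqs.tolist())
        assert pearson_r2(a, b) == pytest.approx(expected, abs=1e-12)


class TestCorrelateAll:
    def _refs(self):
        return [
            builtin_usage_table("synthetic_fungal_mito_like"),
            builtin_usage_table("synthetic_fungal_nuclear_like"),
        ]

    def test_best_match_recovers_source_table(self):
        """ORFs drawn from the mito-like table are assigned to it."""
        usage, nuclear = self._refs()
        rng = np.random.default_rng(77)
        orfs = [
            (f"orf{i}", sample_orf(301, usage, int(rng.integers(0, 3)),
                                   get_code(4), rng)[: 301 * 3])
            for i in range(40)
        ]
        m = correlate_all(orfs, self._refs())
        frac = (m.best_match == "synthetic_fungal_mito_like").mean()
        assert frac >= 0.95

    def test_single_cell_matrix(self):
        m = correlate_all([("o1", "ATGAAATTTCCCGGG")], [self._refs()[0]])
        assert m.values.shape == (1, 1)

    def test_symmetry_against_self_reference(self):
        seq = "ATGAAATTTCCCGGGATTAGA"
        self_ref = codon_frequencies([seq], label="self")
        m = correlate_all([("o1", seq)], [self_ref])
        assert m.values.iloc[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_duplicate_labels_raise(self):
        r = self._refs()[0]
        with pytest.raises(ValueError, match="duplicate"):
            correlate_all([("o1", "ATGAAA")], [r, r])

    def test_export_includes_best_match_and_row_order(self, tmp_path):
        usage = self._refs()[0]
        rng = np.random.default_rng(3)
        orfs = [
            (f"orf{i}", sample_orf(300, usage, 0, get_code(4), rng)[:900])
            for i in range(5)
        ]
        m = correlate_all(orfs, self._refs())
        out = tmp_path / "mat.tsv"
        m.write_tsv(out)
        header = out.read_text().splitlines()[0].split("\t")
        assert header[0] == "orf_id"
        assert "best_match" in header
        assert sorted(m.row_order) == sorted(m.values.index)
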