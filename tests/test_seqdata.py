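import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from popgenscan.seqdata import (
    CODING, EXCLUDED_AMBIGUOUS, EXCLUDED_INDEL, NONCODING,
    count_site_classes, exclude_indels, polarize, read_locus, write_locus,
)
from conftest import make_alignment, seq_matrix


class TestValidation:
    def test_direct_construction(self):
        aln = make_alignment(["ACGT" * 30] * 4, "ACGT" * 30)
        assert aln.n == 4 and aln.L == 120

    def test_unequal_length_rejected(self, tmp_path):
        fa = tmp_path / "x.fasta"
        fa.write_text(">a\n" + "A" * 120 + "\n>b\n" + "A" * 119 + "\n>out\n" + "A" * 120 + "\n")
        meta = pd.DataFrame({"haplotype_id": ["a", "b", "out"],
                             "species": ["sp1", "sp1", "outgroup"],
                             "population": ["p", "p", "o"],
                             "is_outgroup": [0, 0, 1]})
        with pytest.raises(ValueError, match="unequal alignment length"):
            read_locus(fa, meta, [])

    def test_unknown_species_rejected(self, tmp_path):
        fa = tmp_path / "x.fasta"
        fa.write_text(">a\nACGT\n>out\nACGT\n")
        meta = pd.DataFrame({"haplotype_id": ["a", "out"],
                             "species": ["spX", "outgroup"],
                             "population": ["p", "o"],
                             "is_outgroup": [0, 1]})
        with pytest.raises(ValueError, match="spX"):
            read_locus(fa, meta, [], expected_species=("sp1", "sp2"))

    def test_missing_metadata_names_the_id(self, tmp_path):
        fa = tmp_path / "x.fasta"
        fa.write_text(">mystery\nACGT\n>out\nACGT\n")
        meta = pd.DataFrame({"haplotype_id": ["out"], "species": ["o"],
                             "population": ["o"], "is_outgroup": [1]})
        with pytest.raises(ValueError, match="mystery"):
            read_locus(fa, meta, [])

    def test_zero_ingroup_rows_rejected(self, tmp_path):
        fa = tmp_path / "x.fasta"
        fa.write_text(">out\nACGT\n")
        meta = pd.DataFrame({"haplotype_id": ["out"], "species": ["o"],
                             "population": ["o"], "is_outgroup": [1]})
        with pytest.raises(ValueError, match="zero ingroup"):
            read_locus(fa, meta, [])

    def test_exon_frame_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            make_alignment(["ACGTACGT"] * 2, "ACGTACGT", exons=[(0, 4)])

    def test_roundtrip_write_read(self, tmp_path):
        aln = make_alignment(["ACGTACGTAC"] * 3, "ACGTACGTAC", exons=[(0, 6)],
                             species=["sp1", "sp1", "sp2"],
                             populations=["p1", "p2", "q1"])
        write_locus(aln, tmp_path / "l.fasta", tmp_path / "l.meta.tsv",
                    tmp_path / "l.exons.tsv")
        back = read_locus(tmp_path / "l.fasta", tmp_path / "l.meta.tsv",
                          tmp_path / "l.exons.tsv", locus_id="toy")
        assert back.ids == aln.ids
        assert back.species == aln.species
        assert back.populations == aln.populations
        assert back.exons == aln.exons
        assert np.array_equal(back.seqs, aln.seqs)
        assert np.array_equal(back.outgroup_seq, aln.outgroup_seq)


class TestSiteClassification:
    def test_gap_and_ambiguous_columns_excluded(self):
        ingroup = ["AC-TA", "ACGTA", "ACGTN"]
        aln = make_alignment(ingroup, "ACGTA")
        cls = exclude_indels(aln)
        assert cls.col_class[2] == EXCLUDED_INDEL
        assert cls.col_class[4] == EXCLUDED_AMBIGUOUS
        assert cls.analyzable.sum() == 3
        # excluded_indel count equals count of columns containing '-'
        assert (cls.col_class == EXCLUDED_INDEL).sum() == 1

    def test_class_partition_covers_alignment(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            L = 60
            rows = ["".join(rng.choice(list("ACGT-N"), size=L, p=[.23, .23, .23, .23, .05, .03]))
                    for _ in range(4)]
            aln = make_alignment(rows, rows[0], exons=[(0, 30)])
            cls = exclude_indels(aln)
            counts = {c: int((cls.col_class == c).sum())
                      for c in (EXCLUDED_INDEL, EXCLUDED_AMBIGUOUS, NONCODING, CODING)}
            assert sum(counts.values()) == L

    def test_all_gap_column_excluded(self):
        aln = make_alignment(["A-G", "A-G"], "A-G")
        assert exclude_indels(aln).col_class[1] == EXCLUDED_INDEL

    def test_exon_columns_coding(self):
        aln = make_alignment(["ACGTACGTAC"] * 2, "ACGTACGTAC", exons=[(0, 6)])
        cls = exclude_indels(aln)
        assert (cls.col_class[:6] == CODING).all()
        assert (cls.col_class[6:] == NONCODING).all()


class TestNeiGojobori:
    def test_phe_codon_fractional_sites(self):
        # TTT: only third-position changes can be synonymous (TTC), 1 of 3
        aln = make_alignment(["TTTAAA"] * 2, "TTTAAA", exons=[(0, 6)])
        cls = exclude_indels(aln)
        assert cls.syn_weight[0] == 0.0
        assert cls.syn_weight[1] == 0.0
        assert cls.syn_weight[2] == pytest.approx(1 / 3)

    def test_met_codon_no_synonymous_sites(self):
        aln = make_alignment(["ATG"] * 2, "ATG", exons=[(0, 3)])
        cls = exclude_indels(aln)
        assert cls.syn_weight.sum() == 0.0
        assert cls.nonsyn_weight.sum() == 3.0

    def test_pure_intron_locus(self):
        aln = make_alignment(["ACGT" * 75] * 2, "ACGT" * 75)
        nonsyn, syn, noncod = count_site_classes(aln, exclude_indels(aln))
        assert (nonsyn, syn, noncod) == (0.0, 0.0, 300.0)

    def test_weights_sum_to_three_per_intact_codon(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            n_codons = 10
            cds = "".join(rng.choice(list("ACGT"), size=3 * n_codons))
            aln = make_alignment([cds] * 2, cds, exons=[(0, 3 * n_codons)])
            cls = exclude_indels(aln)
            # skipped (stop) codons contribute nothing; others exactly 3 sites
            from popgenscan.seqdata import _CODON_TO_AA
            intact = sum(1 for i in range(n_codons)
                         if _CODON_TO_AA.get(cds[3 * i:3 * i + 3]) not in (None, "*"))
            total = cls.syn_weight.sum() + cls.nonsyn_weight.sum()
            assert total == pytest.approx(3 * intact)

    def test_premature_stop_warns_and_skips(self):
        aln = make_alignment(["TAAAAA"] * 2, "TAAAAA", exons=[(0, 6)])
        with pytest.warns(UserWarning, match="premature stop"):
            cls = exclude_indels(aln)
        assert cls.syn_weight[:3].sum() == 0.0
        assert cls.n_skipped_codons == 1


class TestPolarize:
    def test_toy_statuses(self, toy_locus):
        aln, cls = toy_locus
        pol = polarize(aln, cls)
        by_col = {r.column: r for r in pol.records}
        assert by_col[3].effect == "nonsynonymous"
        assert by_col[3].status.startswith("polymorphic")
        assert by_col[5].effect == "synonymous"
        assert by_col[9].effect == "noncoding"
        assert by_col[11].status == "fixed_difference_vs_outgroup"

    def test_fixed_difference_vs_polymorphism(self):
        aln = make_alignment(["AAAA", "AAAA", "AGAA", "AAAA"], "GAAA",
                             species=["sp1"] * 2 + ["sp2"] * 2)
        pol = polarize(aln, exclude_indels(aln))
        by_col = {r.column: r for r in pol.records}
        assert by_col[0].status == "fixed_difference_vs_outgroup"
        assert by_col[0].species_state == {"sp1": "fixed_difference",
                                           "sp2": "fixed_difference"}
        assert by_col[1].status == "polymorphic_sp2"
        assert by_col[1].species_state["sp1"] == "monomorphic"

    def test_triallelic_retained_once_and_logged(self):
        aln = make_alignment(["AAAA", "ACAA", "AGAA", "ACAA"], "AAAA")
        cls = exclude_indels(aln)
        pol = polarize(aln, cls)
        assert 1 in cls.triallelic_columns
        recs = [r for r in pol.records if r.column == 1]
        assert len(recs) == 1 and recs[0].triallelic

    def test_effect_matches_translation_oracle(self):
        """Random 30-codon single-variant alignments: effect classification
        agrees with brute-force translation of whole haplotypes."""
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(40):
            L = 90
            ref = rng.choice(list("ACGT"), size=L)
            pos = int(rng.integers(L))
            alt = rng.choice([b for b in "ACGT" if b != ref[pos]])
            var = ref.copy()
            var[pos] = alt
            ref_s, var_s = "".join(ref), "".join(var)
            aln = make_alignment([ref_s, var_s], ref_s, exons=[(0, L)])
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # random CDS may contain stops
                cls = exclude_indels(aln)
            pol = polarize(aln, cls)
            assert len(pol.records) == 1
            eff = pol.records[0].effect
            # oracle: translate both haplotypes in full
            p_ref = str(Seq(ref_s).translate())
            p_var = str(Seq(var_s).translate())
            codon = ref_s[3 * (pos // 3): 3 * (pos // 3) + 3]
            from popgenscan.seqdata import _CODON_TO_AA
            if _CODON_TO_AA.get(codon) in (None, "*"):
                continue  # variant inside a stop codon is classed conservatively
            checked += 1
            assert eff == ("synonymous" if p_ref == p_var else "nonsynonymous")
        assert checked > 20
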