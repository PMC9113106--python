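"""SNV effect classification and mutational-load summaries."""

import numpy as np
import pytest

from whalepop.mutational_load import (
    CodingAnnotation,
    ReferenceMismatchError,
    Transcript,
    UnsupportedVariantError,
    category_proportions,
    classify_effect,
    classify_variants,
    load_summary,
)
from whalepop.synthetic_fixtures import (
    make_cds_fixture,
    true_effect_full_translation,
)

from conftest import make_matrix


@pytest.fixture
def simple_gene():
    # contig: 10 bp pad + ATG TGG GCT TAA + 10 bp pad, plus strand
    seq = "ACGTACGTAC" + "ATGTGGGCTTAA" + "GTACGTACGT"
    t = Transcript("t1", "c", "+", [(10, 22)], phase=0)
    return CodingAnnotation([t], {"c": seq})


class TestClassifyEffect:
    def test_stop_gained(self, simple_gene):
        # TGG -> TAG (Trp -> stop): position 15 (1-based), G>A
        call = classify_effect("c", 15, "G", "A", simple_gene)
        assert call.category == "lof"
        assert call.lof_subtype == "stop_gained"
        assert (call.aa_before, call.aa_after) == ("W", "*")

    def test_synonymous(self, simple_gene):
        # GCT -> GCC (Ala -> Ala): position 19, T>C
        call = classify_effect("c", 19, "T", "C", simple_gene)
        assert call.category == "synonymous"
        assert call.codon_after == "GCC"

    def test_missense(self, simple_gene):
        # GCT -> GTT (Ala -> Val)
        call = classify_effect("c", 18, "C", "T", simple_gene)
        assert call.category == "missense"

    def test_start_lost(self, simple_gene):
        call = classify_effect("c", 11, "A", "G", simple_gene)
        assert call.lof_subtype == "start_lost"

    def test_stop_lost_default_missense(self, simple_gene):
        # TAA -> CAA at position 20
        call = classify_effect("c", 20, "T", "C", simple_gene)
        assert call.category == "missense"
        assert classify_effect("c", 20, "T", "C", simple_gene, stop_lost_is_lof=True).category == "lof"

    def test_noncoding(self, simple_gene):
        assert classify_effect("c", 2, "C", "T", simple_gene).category == "noncoding"

    def test_reference_mismatch(self, simple_gene):
        with pytest.raises(ReferenceMismatchError):
            classify_effect("c", 11, "T", "G", simple_gene)

    def test_indel_rejected(self, simple_gene):
        with pytest.raises(UnsupportedVariantError):
            classify_effect("c", 11, "AT", "A", simple_gene)


class TestSpliceAndStrand:
    def test_splice_donor_is_lof(self):
        fx = make_cds_fixture(seed=1)
        ann = fx.annotation()
        t = ann.transcripts[0]
        donor_pos0 = t.cds_intervals[0][1]  # first intron base
        ref = fx.sequence[donor_pos0]
        alt = next(b for b in "ACGT" if b != ref)
        call = classify_effect(fx.contig, donor_pos0 + 1, ref, alt, ann)
        assert call.lof_subtype == "splice_site"

    def test_minus_strand_classification(self):
        """A minus-strand gene classifies through the reverse complement."""
        fx = make_cds_fixture(n_genes=2, seed=2)
        ann = fx.annotation()
        minus = [t for t in ann.transcripts if t.strand == "-"][0]
        cds = ann.coding_sequence(minus)
        assert cds.startswith("ATG") and cds.endswith("TAA")
        # mutate the genomic base corresponding to the start codon's A
        a, b = minus.cds_intervals[-1]  # first CDS in transcription order
        pos0 = b - 1  # transcription-first base on the minus strand
        ref = fx.sequence[pos0]
        call = classify_effect(fx.contig, pos0 + 1, ref, "G" if ref != "G" else "C", ann)
        assert call.lof_subtype == "start_lost"

    def test_strand_symmetry_of_category_multiset(self):
        """Classification agrees with the full-translation oracle on both
        strands and all reading frames of a random fixture."""
        fx = make_cds_fixture(n_genes=4, n_variants=200, seed=3)
        ann = fx.annotation()
        cats = [
            classify_effect(fx.contig, pos, ref, alt, ann).category
            for pos, ref, alt in fx.variants
        ]
        assert cats == fx.truth.payload["categories"]
        assert {"synonymous", "missense", "lof", "noncoding"} <= set(cats)


class TestAnnotationIO:
    def test_gff3_fasta_roundtrip(self, tmp_path):
        fx = make_cds_fixture(n_genes=3, seed=4)
        fasta, gff = tmp_path / "ref.fa", tmp_path / "ann.gff3"
        fx.write_files(str(fasta), str(gff))
        ann = CodingAnnotation.from_files(str(gff), str(fasta))
        mem = fx.annotation()
        assert len(ann.transcripts) == 3
        for t_file in ann.transcripts:
            t_mem = next(t for t in mem.transcripts if t.transcript_id == t_file.transcript_id)
            assert t_file.cds_intervals == t_mem.cds_intervals
            assert t_file.strand == t_mem.strand
            assert ann.coding_sequence(t_file) == mem.coding_sequence(t_mem)

    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            Transcript("bad", "c", "+", [(0, 10)], phase=0)


class TestLoadSummary:
    def _setup(self):
        fx = make_cds_fixture(n_genes=2, n_variants=40, seed=5)
        ann = fx.annotation()
        rng = np.random.default_rng(5)
        positions = sorted(p for p, _, _ in fx.variants)
        by_pos = {p: (r, a) for p, r, a in fx.variants}
        g = rng.choice([0, 1, 2], size=(len(positions), 6), p=[0.5, 0.3, 0.2]).astype(np.int8)
        gm = make_matrix(g, positions=positions, chrom=fx.contig)
        gm.ref_allele = np.array([by_pos[p][0] for p in positions], dtype=object)
        gm.alt_alleles = [[by_pos[p][1]] for p in positions]
        gm.chrom_ids = np.array([fx.contig] * len(positions), dtype=object)
        return fx, ann, gm

    def test_counts_match_brute_force(self):
        fx, ann, gm = self._setup()
        effects = classify_variants(gm, ann)
        table = load_summary(effects, gm)
        cats = np.array([e.category for e in effects])
        for j, row in table.iterrows():
            g = gm.genotypes[:, j]
            carried = (g == 1) | (g == 2)
            assert row["n_total_variants"] == carried.sum()
            assert row["n_lof"] == ((cats == "lof") & carried).sum()
            assert row["n_lof"] == row["n_lof_het"] + row["n_lof_hom"]
            if row["n_total_variants"]:
                assert row["load"] == pytest.approx(row["n_lof"] / row["n_total_variants"])

    def test_load_order_of_magnitude(self):
        """2 LoF among 10,000 carried variants -> load 2e-4."""
        cats = ["lof"] * 2 + ["synonymous"] * 9998
        from whalepop.mutational_load import EffectCall

        effects = [
            EffectCall(f"v{i}", c, "stop_gained" if c == "lof" else "none")
            for i, c in enumerate(cats)
        ]
        g = np.ones((10_000, 1), dtype=np.int8)
        gm = make_matrix(g)
        table = load_summary(effects, gm)
        assert table.loc[0, "load"] == pytest.approx(2e-4)

    def test_no_variants_individual(self):
        from whalepop.mutational_load import EffectCall

        effects = [EffectCall("v0", "synonymous")]
        g = np.zeros((1, 2), dtype=np.int8)
        table = load_summary(effects, make_matrix(g))
        assert table["no_variants"].all()
        assert (table["load"] == 0).all()


class TestCategoryProportions:
    def test_identical_cohorts_p_near_one(self):
        import pandas as pd

        rows = []
        for cohort in ("a", "b"):
            for i in range(4):
                rows.append(
                    {"sample": f"{cohort}{i}", "cohort": cohort,
                     "prop_syn": 0.5, "prop_mis": 0.3, "load": 0.1 + 0.01 * i}
                )
        table, anova = category_proportions(pd.DataFrame(rows))
        assert anova.loc[0, "p"] > 0.9

    def test_single_individual_cohort_errors(self):
        import pandas as pd

        rows = [
            {"sample": "a0", "cohort": "a", "prop_syn": 0.5, "prop_mis": 0.3, "load": 0.1},
            {"sample": "b0", "cohort": "b", "prop_syn": 0.5, "prop_mis": 0.3, "load": 0.1},
            {"sample": "b1", "cohort": "b", "prop_syn": 0.5, "prop_mis": 0.3, "load": 0.2},
        ]
        with pytest.raises(ValueError):
            category_proportions(pd.DataFrame(rows))
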