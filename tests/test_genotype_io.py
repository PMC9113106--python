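"""VCF round-trips, site filters, LD pruning, relatedness and thinning."""

import numpy as np
import pytest

from whalepop.genotype_io import (
    MISSING,
    GenotypeMatrix,
    SiteFilterConfig,
    apply_site_filters,
    estimate_pihat,
    ld_prune,
    read_vcf,
    remove_related,
    thin_sites,
    write_vcf,
)
from whalepop.synthetic_fixtures import make_pedigree_genotypes

from conftest import make_matrix


MINIMAL_VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA
chr1\t5\t.\tA\tT\t.\tPASS\t.\tGT\t0/1
chr1\t9\t.\tG\tC\t.\tPASS\t.\tGT\t./.
chr1\t20\t.\tC\t.\t.\tPASS\t.\tGT\t0/0
"""


class TestReadWrite:
    def test_single_het_record(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(MINIMAL_VCF)
        gm = read_vcf(str(path))
        assert gm.n_sites == 2  # monomorphic record dropped by default
        assert gm.genotypes[0, 0] == 1
        assert gm.genotypes[1, 0] == MISSING

    def test_keep_monomorphic(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(MINIMAL_VCF)
        gm = read_vcf(str(path), keep_monomorphic=True)
        assert gm.n_sites == 3
        assert gm.alt_alleles[2] == []

    def test_roundtrip_random_matrix(self, tmp_path):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, size=(100, 6)).astype(np.int8)
        g[rng.random(g.shape) < 0.05] = MISSING
        gm = make_matrix(g, positions=np.sort(rng.choice(10_000, 100, replace=False)) + 1)
        path = tmp_path / "rt.vcf"
        write_vcf(gm, str(path))
        back = read_vcf(str(path))
        assert back.equals(gm)

    def test_empty_matrix_roundtrip(self, tmp_path):
        gm = make_matrix(np.zeros((0, 2), dtype=np.int8))
        path = tmp_path / "empty.vcf"
        write_vcf(gm, str(path))
        assert read_vcf(str(path), keep_monomorphic=True).n_sites == 0

    def test_depth_roundtrip(self, tmp_path):
        g = np.array([[0, 1], [2, 0]], dtype=np.int8)
        depths = np.array([[10.0, 12.0], [8.0, 9.0]])
        gm = make_matrix(g, depths=depths)
        path = tmp_path / "dp.vcf"
        write_vcf(gm, str(path))
        back = read_vcf(str(path))
        np.testing.assert_array_equal(back.depths, depths)


class TestInvariants:
    def test_positions_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            make_matrix(np.zeros((2, 2), dtype=np.int8), positions=[5, 5])

    def test_bad_code_rejected(self):
        with pytest.raises(ValueError, match="invalid genotype codes"):
            make_matrix(np.full((1, 2), 7, dtype=np.int8))


class TestSiteFilters:
    def test_missingness_rule(self):
        # 1 of 16 missing = 6.25% > 5% -> removed
        g = np.zeros((1, 16), dtype=np.int8)
        g[0, 0] = MISSING
        g2 = np.array([[0, 1] * 8], dtype=np.int8)
        gm = make_matrix(np.vstack([g, g2]))
        cfg = SiteFilterConfig(use_depth_filter=False, min_minor_allele_count=0)
        out, report = apply_site_filters(gm, cfg)
        assert report.removed["missingness"] == 1
        assert out.n_sites == 1

    def test_identity_when_all_pass(self, random_matrix):
        cfg = SiteFilterConfig(
            use_depth_filter=False, max_missing_frac=1.0, het_excess_max=1.0,
            min_minor_allele_count=0,
        )
        out, report = apply_site_filters(random_matrix, cfg)
        assert out.n_sites == random_matrix.n_sites
        assert all(v == 0 for v in report.removed.values())

    def test_counts_match_brute_force(self):
        """Survivor count equals an independent per-site predicate re-check."""
        rng = np.random.default_rng(3)
        n_sites, n_ind = 1000, 10
        g = rng.integers(0, 3, size=(n_sites, n_ind)).astype(np.int8)
        g[rng.random(g.shape) < 0.08] = MISSING
        depths = rng.gamma(5.0, 4.0, size=(n_sites, n_ind))
        gm = make_matrix(g, depths=depths)
        cfg = SiteFilterConfig(min_minor_allele_count=2)
        out, report = apply_site_filters(gm, cfg, expected_mean_depth=20.0)
        survivors = 0
        for i in range(n_sites):
            row = g[i]
            called = row != MISSING
            mean_dp = depths[i].mean()
            if not (0.3 * 20 <= mean_dp <= 3 * 20):
                continue
            if (row == MISSING).mean() > 0.05:
                continue
            n2 = 2 * called.sum()
            ac = row[called].sum()
            if called.sum() and (row[called] == 1).mean() > 0.6:
                continue
            if 0 < ac < n2 and min(ac, n2 - ac) < 2:
                continue
            survivors += 1
        assert out.n_sites == survivors
        assert sum(report.removed.values()) == report.n_input - report.n_output

    def test_depth_filter_requires_depths(self, random_matrix):
        with pytest.raises(ValueError, match="depth"):
            apply_site_filters(random_matrix, SiteFilterConfig(), expected_mean_depth=20)


class TestLdPrune:
    def test_duplicate_column_removed(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=np.int8)
        gm = make_matrix(np.stack([col, col], axis=0), positions=[100, 1100])
        out = ld_prune(gm, window_kb=10, r2_max=0.9)
        assert out.n_sites == 1
        assert out.positions[0] == 100  # earlier site retained

    def test_distant_sites_kept(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=np.int8)
        gm = make_matrix(np.stack([col, col]), positions=[100, 2_000_000])
        assert ld_prune(gm, window_kb=1000, r2_max=0.9).n_sites == 2

    def test_retained_set_satisfies_constraint_and_idempotence(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.1, 0.9, 200)
        g = (rng.random((200, 20, 2)) < p[:, None, None]).sum(axis=2).astype(np.int8)
        # create LD blocks by copying columns
        for i in range(0, 200, 10):
            for k in range(1, 4):
                g[i + k] = g[i]
        gm = make_matrix(g, positions=np.arange(200) * 500 + 1)
        out = ld_prune(gm, window_kb=5, r2_max=0.5)
        # exhaustive pair scan within the window
        for i in range(out.n_sites):
            for j in range(i + 1, out.n_sites):
                if out.positions[j] - out.positions[i] <= 5000:
                    x = out.genotypes[i].astype(float)
                    y = out.genotypes[j].astype(float)
                    r2 = np.corrcoef(x, y)[0, 1] ** 2
                    assert r2 <= 0.5 + 1e-12
        again = ld_prune(out, window_kb=5, r2_max=0.5)
        assert again.equals(out)

    def test_invalid_r2(self, random_matrix):
        with pytest.raises(ValueError):
            ld_prune(random_matrix, r2_max=1.5)


class TestPihat:
    def test_duplicate_individual(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.2, 0.8, 2000)
        g = (rng.random((2000, 5, 2)) < p[:, None, None]).sum(axis=2).astype(np.int8)
        g[:, 4] = g[:, 0]  # duplicate
        gm = make_matrix(g)
        pihat = estimate_pihat(gm)
        assert pihat.iloc[0, 4] > 0.95
        assert np.allclose(pihat.values, pihat.values.T)

    def test_matches_independent_moment_computation(self):
        """pi_hat equals a from-scratch IBS-moment computation (1e-8)."""
        rng = np.random.default_rng(17)
        p = rng.uniform(0.1, 0.9, 400)
        g = (rng.random((400, 4, 2)) < p[:, None, None]).sum(axis=2).astype(np.int8)
        gm = make_matrix(g)
        pihat = estimate_pihat(gm).to_numpy()
        freq = g.sum(axis=1) / 8.0
        seg = (freq > 0) & (freq < 1)
        gs, ps = g[seg], freq[seg]
        qs = 1 - ps
        for i in range(4):
            for j in range(i + 1, 4):
                d = np.abs(gs[:, i] - gs[:, j])
                ibs0, ibs1, ibs2 = float((d == 2).sum()), float((d == 1).sum()), float((d == 0).sum())
                z0 = ibs0 / np.sum(2 * ps**2 * qs**2)
                z1 = (ibs1 - z0 * np.sum(4 * ps**3 * qs + 4 * ps * qs**3)) / np.sum(2 * ps * qs)
                z2 = (ibs2 - z0 * np.sum(ps**4 + qs**4 + 4 * ps**2 * qs**2)
                      - z1 * np.sum(ps**2 + qs**2)) / len(ps)
                z = np.clip([z0, z1, z2], 0, None)
                z = z / z.sum()
                expected = min(max(z[1] / 2 + z[2], 0.0), 1.0)
                assert pihat[i, j] == pytest.approx(expected, abs=1e-8)

    def test_monomorphic_only_errors(self):
        gm = make_matrix(np.zeros((10, 3), dtype=np.int8))
        with pytest.raises(ValueError, match="polymorphic"):
            estimate_pihat(gm)

    def test_pedigree_ordering(self):
        """duplicate >= parent-offspring >= unrelated in expectation."""
        gm, truth = make_pedigree_genotypes(
            n_founders=6,
            relationships={"child": ("F0", "F1")},
            n_sites=5000,
            seed=2,
        )
        pihat = estimate_pihat(gm)
        po = pihat.loc["child", "F0"]
        unrel = pihat.loc["F2", "F3"]
        assert po > unrel
        assert abs(po - 0.5) < 0.1
        assert abs(unrel) < 0.1


class TestRemoveRelated:
    def test_no_pairs_above_cutoff(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.2, 0.8, 3000)
        g = (rng.random((3000, 6, 2)) < p[:, None, None]).sum(axis=2).astype(np.int8)
        gm = make_matrix(g)
        out = remove_related(gm, 0.2)
        assert out.sample_ids == gm.sample_ids

    def test_duplicate_pair_loses_one(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0.2, 0.8, 3000)
        g = (rng.random((3000, 5, 2)) < p[:, None, None]).sum(axis=2).astype(np.int8)
        g[:, 4] = g[:, 1]
        gm = make_matrix(g)
        out = remove_related(gm, 0.2)
        assert out.n_individuals == 4
        assert "s4" not in out.sample_ids  # tie on missingness -> later sample dropped

    def test_trio_postcondition(self):
        gm, _ = make_pedigree_genotypes(
            n_founders=4,
            relationships={"kid": ("F0", "F1")},
            n_sites=6000,
            seed=4,
        )
        out = remove_related(gm, 0.2)
        if out.n_individuals >= 2:
            pihat = estimate_pihat(out).to_numpy()
            off_diag = pihat[~np.eye(out.n_individuals, dtype=bool)]
            assert (off_diag <= 0.2).all()

    def test_invalid_cutoff(self, random_matrix):
        with pytest.raises(ValueError):
            remove_related(random_matrix, 1.5)


class TestThin:
    def test_sparse_sites_unchanged(self):
        gm = make_matrix(np.zeros((3, 2), dtype=np.int8), positions=[100, 1500, 4000])
        out = thin_sites(gm, 1000, seed=1)
        assert out.n_sites == 3

    def test_close_pair_reduced(self):
        gm = make_matrix(np.zeros((2, 2), dtype=np.int8), positions=[100, 110])
        assert thin_sites(gm, 1000, seed=1).n_sites == 1

    def test_deterministic(self, random_matrix):
        a = thin_sites(random_matrix, 50, seed=123)
        b = thin_sites(random_matrix, 50, seed=123)
        assert a.equals(b)
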