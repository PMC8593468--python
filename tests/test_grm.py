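"""VanRaden GRM construction: codings, oracle equivalence, invariances,
the combined-matrix identity, and GRM PCA."""

import numpy as np
import pandas as pd
import pytest

from _oracles import naive_grm
from cnvherit.cnv import CnvLocus
from cnvherit.grm import (
    Grm,
    MarkerMatrix,
    code_cnvs_proc1,
    code_cnvs_proc2,
    code_snps,
    combine_markers,
    compute_grm,
    grm_pca,
    impute_missing,
)
from cnvherit.qc import SnpPanel


def _markers(m, coding="snp"):
    m = np.asarray(m, float)
    p = (m.mean(axis=0) + 1) / 2
    ids = np.array([f"a{i}" for i in range(m.shape[0])], object)
    return MarkerMatrix(ids, [f"m{j}" for j in range(m.shape[1])], m, p, coding)


def _mixed_locus():
    return CnvLocus(
        "mx", 1, 10, 20, 10000, 20000,
        classes={"A": 1, "B": 3},  # C normal
    )


ANIMALS = ["A", "B", "C"]


class TestCoding:
    def test_snp_recode(self, tiny_panel):
        m = code_snps(tiny_panel)
        np.testing.assert_array_equal(m.m[0], [-1, 0, 1, -1, 0])

    def test_snp_coding_requires_complete_genotypes(self, tiny_panel):
        geno = tiny_panel.geno.copy()
        geno[0, 0] = np.nan
        panel = SnpPanel(tiny_panel.animal_ids, geno, tiny_panel.snp_map)
        with pytest.raises(ValueError):
            code_snps(panel)

    def test_proc1_splits_mixed_locus(self):
        m = code_cnvs_proc1([_mixed_locus()], ANIMALS)
        assert m.marker_ids == ["mx:del", "mx:dup"]
        np.testing.assert_array_equal(m.m[:, 0], [0, 1, 1])   # deletion locus
        np.testing.assert_array_equal(m.m[:, 1], [1, 0, 1])   # duplication locus

    def test_proc2_single_locus(self):
        m = code_cnvs_proc2([_mixed_locus()], ANIMALS)
        assert m.marker_ids == ["mx"]
        np.testing.assert_array_equal(m.m[:, 0], [-1, 1, 0])

    def test_proc1_double_deletion(self):
        locus = CnvLocus("d", 1, 0, 5, 1, 6, classes={"A": 0, "B": 1})
        m = code_cnvs_proc1([locus], ANIMALS)
        np.testing.assert_array_equal(m.m[:, 0], [-1, 0, 1])


class TestImpute:
    def test_mean_substitution_within_breed(self):
        snp_map = pd.DataFrame(
            {"snp_id": ["s0"], "chrom": [1], "pos_bp": [100], "index": [0]}
        )
        geno = np.array([[0.0], [2.0], [np.nan], [0.0], [0.0], [0.0]])
        breed = np.array(["x", "x", "x", "y", "y", "y"], object)
        panel = SnpPanel(np.array(list("abcdef"), object), geno, snp_map, breed)
        out = impute_missing(panel)
        assert out.geno[2, 0] == 1.0  # mean of {0,2} within breed x

    def test_no_missing_identity(self, tiny_panel):
        out = impute_missing(tiny_panel)
        np.testing.assert_array_equal(out.geno, tiny_panel.geno)

    def test_all_missing_snp_errors(self, tiny_panel):
        geno = tiny_panel.geno.copy()
        geno[:, 2] = np.nan
        with pytest.raises(ValueError):
            impute_missing(SnpPanel(tiny_panel.animal_ids, geno, tiny_panel.snp_map))


class TestComputeGrm:
    def test_single_marker_worked_example(self):
        g = compute_grm(_markers([[1], [0], [-1]]))
        np.testing.assert_allclose(
            g.g, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]], atol=1e-12
        )

    def test_identical_animals_identical_rows(self):
        rng = np.random.default_rng(0)
        m = rng.choice([-1.0, 0.0, 1.0], size=(4, 30))
        m[1] = m[0]
        g = compute_grm(_markers(m)).g
        np.testing.assert_allclose(g[0], g[1], atol=1e-12)
        assert abs(g[0, 0] - g[0, 1]) < 1e-12

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(1)
        m = rng.choice([-1.0, 0.0, 1.0], size=(20, 50))
        mm = _markers(m)
        g = compute_grm(mm)
        expected = naive_grm(mm.m, mm.p)
        assert np.abs(g.g - expected).max() < 1e-10

    def test_monomorphic_only_errors(self):
        with pytest.raises(ValueError):
            compute_grm(_markers([[1], [1], [1]]))

    def test_marker_permutation_invariance(self):
        rng = np.random.default_rng(2)
        m = rng.choice([-1.0, 0.0, 1.0], size=(10, 20))
        perm = rng.permutation(20)
        g1 = compute_grm(_markers(m)).g
        g2 = compute_grm(_markers(m[:, perm])).g
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_animal_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        m = rng.choice([-1.0, 0.0, 1.0], size=(10, 20))
        perm = rng.permutation(10)
        g1 = compute_grm(_markers(m)).g
        g2 = compute_grm(_markers(m[perm])).g
        np.testing.assert_allclose(g1[np.ix_(perm, perm)], g2, atol=1e-12)


class TestCombine:
    def test_empty_cnv_part_is_identity(self):
        rng = np.random.default_rng(4)
        snp = _markers(rng.choice([-1.0, 0.0, 1.0], size=(8, 15)))
        cnv = MarkerMatrix(snp.animal_ids, [], np.empty((8, 0)), np.empty(0), "cnv_proc1")
        combined = combine_markers(snp, cnv)
        np.testing.assert_allclose(
            compute_grm(combined).g, compute_grm(snp).g, atol=1e-12
        )

    def test_column_count_bookkeeping(self):
        rng = np.random.default_rng(5)
        snp = _markers(rng.choice([-1.0, 0.0, 1.0], size=(3, 7)))
        cnv = code_cnvs_proc1([_mixed_locus()], ANIMALS)
        cnv.animal_ids = snp.animal_ids
        combined = combine_markers(snp, cnv)
        assert len(combined.marker_ids) == 7 + 2

    def test_combined_matches_oracle_and_weighted_average(self):
        rng = np.random.default_rng(6)
        snp = _markers(rng.choice([-1.0, 0.0, 1.0], size=(12, 25)))
        cnv = _markers(rng.choice([-1.0, 0.0, 1.0], size=(12, 5)), "cnv_proc2")
        combined = combine_markers(snp, cnv)
        g_comb = compute_grm(combined)
        expected = naive_grm(combined.m, combined.p)
        assert np.abs(g_comb.g - expected).max() < 1e-10
        # algebraic identity: combined GRM is the denominator-weighted average
        g_snp, g_cnv = compute_grm(snp), compute_grm(cnv)
        avg = (
            g_snp.g * g_snp.denominator + g_cnv.g * g_cnv.denominator
        ) / (g_snp.denominator + g_cnv.denominator)
        np.testing.assert_allclose(g_comb.g, avg, atol=1e-10)

    def test_mismatched_animals_error(self):
        rng = np.random.default_rng(7)
        snp = _markers(rng.choice([-1.0, 0.0, 1.0], size=(3, 7)))
        cnv = _markers(rng.choice([-1.0, 0.0, 1.0], size=(4, 2)))
        with pytest.raises(ValueError):
            combine_markers(snp, cnv)


class TestPca:
    def _grm(self, g):
        ids = np.array([f"a{i}" for i in range(g.shape[0])], object)
        return Grm(ids, np.asarray(g, float), 1.0, "snp")

    def test_percent_variance_sums_to_100(self):
        rng = np.random.default_rng(8)
        m = rng.choice([-1.0, 0.0, 1.0], size=(15, 40))
        g = compute_grm(_markers(m))
        _, pct, _ = grm_pca(g, k=15)
        assert abs(pct.sum() - 100.0) < 1e-8

    def test_identity_grm_equal_shares(self):
        _, pct, _ = grm_pca(self._grm(np.eye(6)), k=6)
        np.testing.assert_allclose(pct, 100.0 / 6, atol=1e-10)

    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(9)
        # disjoint allele-frequency profiles per cluster
        p1, p2 = rng.uniform(0.05, 0.25, 60), rng.uniform(0.75, 0.95, 60)
        g1 = rng.binomial(2, p1, size=(20, 60)) - 1.0
        g2 = rng.binomial(2, p2, size=(20, 60)) - 1.0
        g = compute_grm(_markers(np.vstack([g1, g2])))
        scores, _, _ = grm_pca(g, k=2)
        pc1 = scores["PC1"].to_numpy()
        labels = pc1 > 0
        assert labels[:20].all() != labels[20:].all()
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1

    def test_nonfinite_rejected(self):
        g = np.eye(3)
        g[0, 0] = np.nan
        with pytest.raises(ValueError):
            grm_pca(self._grm(g), 2)


def test_proc1_proc2_offdiagonal_rank_agreement():
    """Without mixed loci or double classes the two CNV codings are
    monotone recodings of each other: off-diagonal rank order agrees."""
    rng = np.random.default_rng(10)
    n, k = 25, 12
    loci = []
    for j in range(k):
        carriers = rng.choice(n, size=4, replace=False)
        direction = 1 if rng.random() < 0.5 else 3
        loci.append(
            CnvLocus(
                f"l{j}", 1, 10 * j, 10 * j + 6, 1000 * j, 1000 * j + 600,
                classes={f"a{i}": direction for i in carriers},
            )
        )
    animals = [f"a{i}" for i in range(n)]
    g1 = compute_grm(code_cnvs_proc1(loci, animals)).g
    g2 = compute_grm(code_cnvs_proc2(loci, animals)).g
    iu = np.triu_indices(n, 1)
    from scipy.stats import spearmanr

    rho, _ = spearmanr(g1[iu], g2[iu])
    assert rho > 0.9
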