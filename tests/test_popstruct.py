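"""Relatedness estimation, PCA, and ancestry-outlier flagging."""

import numpy as np
import pandas as pd
import pytest

from regiongwas.io import StudyGenotypes, variant_frame
from regiongwas.popstruct import (ancestry_outliers, compute_pcs, pihat,
                                  pihat_matrix, relatedness_filter, PcaResult)
from regiongwas.simulate import build_haplotype_pool, simulate_study


def _study_from_dosage(dosage, sids=None, seed=0):
    n, m = dosage.shape
    rng = np.random.default_rng(seed)
    samples = pd.DataFrame({
        "sid": sids or [f"s{i:03d}" for i in range(n)],
        "phenotype": np.where(np.arange(n) % 2 == 0, "case", "control"),
        "sex": rng.choice(["male", "female"], n),
        "age": 50.0, "study": "t"})
    variants = variant_frame(["1"] * m, (np.arange(m) + 1) * 100,
                             [f"v{j}" for j in range(m)], ["A"] * m, ["G"] * m)
    return StudyGenotypes(samples, variants, dosage.astype(np.int8))


def _diploid(pool, h1, h2):
    return (pool.haplotypes[h1].astype(np.int8)
            + pool.haplotypes[h2].astype(np.int8))


class TestPihat:
    @pytest.fixture(scope="class")
    def big_pool(self):
        return build_haplotype_pool(n_hap=600, n_snp=1200, block_len=25,
                                    recomb_between_blocks=0.5, mutation=0.5,
                                    recomb_within=0.5, maf_range=(0.2, 0.5),
                                    seed=31)

    def test_self_pair_near_one(self, big_pool):
        g = _diploid(big_pool, np.arange(10), np.arange(10, 20))
        study = _study_from_dosage(np.vstack([g, g[0]]))
        p = pihat(study, ("s000", "s010"))
        assert p.pi_hat >= 0.98

    def test_unrelated_near_zero(self, big_pool):
        rng = np.random.default_rng(1)
        idx = rng.integers(0, 600, size=(40, 2))
        g = _diploid(big_pool, idx[:, 0], idx[:, 1])
        study = _study_from_dosage(g)
        p = pihat(study, ("s001", "s002"))
        assert abs(p.pi_hat) < 0.07

    def test_parent_offspring_near_half(self, big_pool):
        rng = np.random.default_rng(2)
        idx = rng.integers(0, 600, size=(30, 2))
        g = _diploid(big_pool, idx[:, 0], idx[:, 1])
        # child shares exactly one haplotype (idx[0,0]) with sample 0
        child = _diploid(big_pool, idx[0, 0], 599)
        study = _study_from_dosage(np.vstack([g, child]))
        p = pihat(study, ("s000", "s030"))
        assert p.pi_hat == pytest.approx(0.5, abs=0.08)

    def test_insufficient_overlap_raises(self):
        d = np.full((3, 120), -1, dtype=np.int8)
        d[:, :50] = 1
        study = _study_from_dosage(d)
        with pytest.raises(RuntimeError):
            pihat(study, ("s000", "s001"))


class TestRelatednessFilter:
    def _pool_study(self, extra_rows, seed=3):
        pool = build_haplotype_pool(n_hap=600, n_snp=800, block_len=25,
                                    recomb_between_blocks=0.5, mutation=0.5,
                                    recomb_within=0.5, maf_range=(0.2, 0.5),
                                    seed=33)
        rng = np.random.default_rng(seed)
        # disjoint haplotypes so no pair is related by construction
        idx = rng.permutation(600)[:50].reshape(25, 2)
        g = _diploid(pool, idx[:, 0], idx[:, 1])
        return pool, idx, g

    def test_duplicate_sample_one_removed(self):
        pool, idx, g = self._pool_study(1)
        g2 = np.vstack([g, g[3]])
        study = _study_from_dosage(g2)
        filtered, flagged = relatedness_filter(study)
        assert filtered.n_samples == g2.shape[0] - 1
        assert {p.sid_a for p in flagged} | {p.sid_b for p in flagged} == {
            "s003", f"s{g2.shape[0] - 1:03d}"}

    def test_exact_threshold_retained(self):
        # pi_hat == threshold must not trigger removal (strict >)
        pool, idx, g = self._pool_study(2)
        study = _study_from_dosage(g)
        pm = pihat_matrix(study)
        assert (np.triu(pm, 1) <= 0.1875).all()
        filtered, flagged = relatedness_filter(study, threshold=0.1875)
        assert filtered.n_samples == study.n_samples and not flagged

    def test_trio_removes_shared_sample_only(self):
        pool, idx, g = self._pool_study(4)
        # parent (row 25) has two children sharing one haplotype each
        parent = _diploid(pool, np.array([100]), np.array([101]))[0]
        child1 = _diploid(pool, np.array([100]), np.array([250]))[0]
        child2 = _diploid(pool, np.array([101]), np.array([251]))[0]
        study = _study_from_dosage(np.vstack([g, parent, child1, child2]))
        filtered, flagged = relatedness_filter(study)
        kept = set(filtered.samples["sid"])
        # minimal vertex cover on the parent-child1/parent-child2 pair graph
        assert "s025" not in kept and {"s026", "s027"} <= kept

    def test_no_pair_above_threshold_after_filter(self):
        pool, idx, g = self._pool_study(5)
        g2 = np.vstack([g, g[0], g[1]])
        study = _study_from_dosage(g2)
        filtered, _ = relatedness_filter(study)
        pm = pihat_matrix(filtered)
        assert (np.triu(pm, 1) <= 0.1875).all()


class TestPca:
    def _two_cluster_study(self, n=120, m=300, shift=0.35, seed=5):
        rng = np.random.default_rng(seed)
        f1 = rng.uniform(0.2, 0.6, m)
        f2 = np.clip(f1 + rng.choice([-shift, shift], m), 0.05, 0.95)
        g1 = rng.binomial(2, f1, size=(n // 2, m))
        g2 = rng.binomial(2, f2, size=(n - n // 2, m))
        return _study_from_dosage(np.vstack([g1, g2])), np.r_[
            np.zeros(n // 2), np.ones(n - n // 2)]

    def test_pc1_separates_clusters(self):
        study, labels = self._two_cluster_study()
        pcs = compute_pcs(study, k=4)
        r = np.corrcoef(pcs.scores[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_sample_permutation_equivariance(self):
        study, _ = self._two_cluster_study(n=60, m=100)
        pcs = compute_pcs(study, k=3)
        perm = np.random.default_rng(0).permutation(60)
        shuffled = StudyGenotypes(study.samples.iloc[perm],
                                  study.variants, study.dosage[perm])
        pcs2 = compute_pcs(shuffled, k=3)
        assert np.allclose(pcs.eigenvalues, pcs2.eigenvalues, rtol=1e-8)
        assert np.allclose(pcs.scores[perm], pcs2.scores, atol=1e-6)

    def test_rank_one_structure(self):
        # a single dominant direction: top eigenvalue carries ~all variance
        rng = np.random.default_rng(7)
        u = rng.choice([0, 2], size=60)
        dosage = np.tile(u[:, None], (1, 40))
        study = _study_from_dosage(dosage)
        pcs = compute_pcs(study, k=3)
        assert pcs.eigenvalues[0] / pcs.eigenvalues.sum() > 0.99

    def test_k_reduced_with_warning(self):
        study, _ = self._two_cluster_study(n=12, m=8)
        with pytest.warns(UserWarning, match="reduced"):
            pcs = compute_pcs(study, k=50)
        assert pcs.scores.shape[1] < 50

    def test_eigenvalues_non_increasing_invariant(self):
        with pytest.raises(ValueError):
            PcaResult(loadings=np.eye(2), scores=np.eye(2),
                      eigenvalues=np.array([1.0, 2.0]))


class TestAncestryOutliers:
    def _pcs(self, scores):
        k = scores.shape[1]
        return PcaResult(loadings=np.zeros((1, k)), scores=scores,
                         eigenvalues=np.arange(k, 0, -1).astype(float))

    def test_single_cluster_no_flags(self):
        rng = np.random.default_rng(1)
        scores = rng.standard_normal((200, 2))
        flags = ancestry_outliers(self._pcs(scores), np.ones(200, bool))
        assert not flags.any()

    def test_planted_outliers_flagged(self):
        rng = np.random.default_rng(2)
        scores = rng.standard_normal((200, 2))
        planted = rng.choice(200, 10, replace=False)
        scores[planted] += 10.0  # 10-sd offset
        ref = np.ones(200, bool)
        ref[planted] = False
        flags = ancestry_outliers(self._pcs(scores), ref, n_sd=6)
        assert flags[planted].all()
        assert flags[~np.isin(np.arange(200), planted)].sum() <= 2

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal((100, 2))
        scores[0] += 12
        f1 = ancestry_outliers(self._pcs(scores), np.ones(100, bool))
        f2 = ancestry_outliers(self._pcs(-scores), np.ones(100, bool))
        assert np.array_equal(f1, f2)

    def test_degenerate_mad_falls_back(self):
        scores = np.zeros((50, 2))
        scores[:, 1] = np.random.default_rng(4).standard_normal(50)
        with pytest.warns(UserWarning, match="MAD"):
            ancestry_outliers(self._pcs(scores), np.ones(50, bool))

    def test_small_reference_rejected(self):
        with pytest.raises(ValueError):
            ancestry_outliers(self._pcs(np.zeros((30, 2))),
                              np.arange(30) < 5)
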