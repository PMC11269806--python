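"""Consensus partitioning: ATC, spherical k-means, consensus machinery,
stability metrics and the three best-k rules."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from serostrat import (
    ConsensusRun,
    KMetrics,
    PartitionConfig,
    atc_scores,
    consensus_classes,
    consensus_for_k,
    jaccard_index,
    pac_score,
    select_best_k,
    select_top_features,
    spherical_kmeans,
)
from conftest import make_matrix


class TestAtc:
    def test_collinear_rows_score_one(self):
        m = make_matrix([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]])
        np.testing.assert_allclose(atc_scores(m), [1.0, 1.0, 1.0])

    def test_hand_computed_scores(self):
        # |r| pairs: (A,B)=0.5, (A,C)=0.5, (B,C)=1
        m = make_matrix([[1, 2, 3], [1, 3, 2], [3, 1, 2]])
        np.testing.assert_allclose(atc_scores(m), [0.5, 0.75, 0.75])

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6, 20))
        base = atc_scores(make_matrix(vals))
        vals2 = vals.copy()
        vals2[2] = 3.0 * vals2[2] + 11.0
        np.testing.assert_allclose(atc_scores(make_matrix(vals2)), base, atol=1e-12)

    def test_zero_variance_row_rejected(self):
        m = make_matrix([[1, 1, 1], [1, 2, 3], [3, 2, 1]])
        with pytest.raises(ValueError):
            atc_scores(m)


class TestTopFeatures:
    def test_top_frac_one_is_identity(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(10, 12)))
        out = select_top_features(m, 1.0)
        assert out.protein_ids == m.protein_ids

    def test_counting_and_selection(self):
        rng = np.random.default_rng(2)
        noise = rng.normal(size=(7, 30))
        strong = np.vstack([noise[0] * s for s in (1.0, 2.0, 0.5)])  # collinear trio
        m = make_matrix(np.vstack([strong, noise[1:]]))
        out = select_top_features(m, 0.3)     # ceil(0.3*9) = 3
        assert out.shape[0] == 3
        assert out.protein_ids == ["P0", "P1", "P2"]

    def test_tie_keeps_earlier_row(self):
        # duplicated rows give identical ATC; stable sort keeps first rows
        base = np.array([[1.0, 2.0, 3.0, 4.0]])
        m = make_matrix(np.vstack([base, base, base, base]))
        out = select_top_features(m, 0.5)     # keep 2 of 4, all tied
        assert out.protein_ids == ["P0", "P1"]


class TestSphericalKmeans:
    def test_orthogonal_directions_perfectly_separated(self):
        rng = np.random.default_rng(4)
        a = np.array([1.0, 0.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, 0.0])
        x = np.vstack([a * s for s in (1, 2, 3)] + [b * s for s in (1, 2, 3)])
        x = x + rng.normal(0, 0.01, x.shape)
        labels = spherical_kmeans(x, 2, seed=0)
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1], labels) == 1.0

    def test_scale_invariance_single_cluster(self):
        x = np.outer([1.0, 2.0, 5.0, 0.1], [3.0, 4.0])
        labels = spherical_kmeans(x, 1, seed=0)
        assert set(labels) == {0}

    def test_duplicates_colabeled(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(8, 10))
        x = np.vstack([x, x[3]])            # duplicate of sample 3
        labels = spherical_kmeans(x, 3, seed=1)
        assert labels[3] == labels[-1]

    def test_positive_per_sample_scaling_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(12, 8))
        scales = rng.uniform(0.2, 5.0, size=12)
        l1 = spherical_kmeans(x, 3, seed=7)
        l2 = spherical_kmeans(x * scales[:, None], 3, seed=7)
        assert adjusted_rand_score(l1, l2) == 1.0

    def test_zero_norm_vector_rejected(self):
        x = np.array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            spherical_kmeans(x, 2)


class TestConsensusForK:
    def _separated_matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        base = np.zeros((40, 24))
        base[:20, :12] += 5.0
        base[20:, 12:] += 5.0
        return make_matrix(base + rng.normal(0, 0.3, base.shape))

    def test_separated_groups_binary_consensus(self):
        m = self._separated_matrix()
        run = consensus_for_k(m, 2, PartitionConfig(n_repeats=10, seed=0))
        assert set(np.round(run.consensus, 6).ravel()) <= {0.0, 1.0}
        truth = np.repeat([0, 1], 12)
        within = run.consensus[np.ix_(truth == 0, truth == 0)]
        assert (within == 1.0).all()

    def test_single_repeat_is_comembership_indicator(self):
        m = self._separated_matrix(1)
        run = consensus_for_k(m, 2, PartitionConfig(n_repeats=1, seed=3))
        labels = run.partitions[0]
        expected = (labels[:, None] == labels[None, :]).astype(float)
        np.testing.assert_allclose(run.consensus, expected)

    def test_consensus_matrix_invariants(self, planted_qc):
        _, qc_matrix, _, _ = planted_qc
        run = consensus_for_k(qc_matrix, 3, PartitionConfig(n_repeats=8, seed=2))
        c = run.consensus
        np.testing.assert_allclose(c, c.T)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert (c >= 0).all() and (c <= 1).all()

    def test_pure_noise_is_ambiguous(self):
        # PAC stays away from 0 on structureless data
        pacs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m = make_matrix(rng.normal(size=(40, 30)))
            run = consensus_for_k(m, 2, PartitionConfig(n_repeats=15, seed=seed))
            pacs.append(1.0 - pac_score(run))
        assert np.mean(pacs) > 0.3


class TestPacScore:
    def _run(self, consensus):
        c = np.asarray(consensus, dtype=float)
        return ConsensusRun(k=2, partitions=np.zeros((1, len(c)), dtype=int),
                            consensus=c)

    def test_binary_entries_give_one(self):
        c = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        assert pac_score(self._run(c)) == 1.0

    def test_all_half_gives_zero(self):
        c = np.full((4, 4), 0.5)
        np.fill_diagonal(c, 1.0)
        assert pac_score(self._run(c)) == 0.0

    def test_one_third_ambiguous(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.95
        c[0, 2] = c[2, 0] = 0.5
        c[1, 2] = c[2, 1] = 0.05
        assert pac_score(self._run(c)) == pytest.approx(2.0 / 3.0)


class TestConsensusClasses:
    def test_identical_repeats_full_concordance(self):
        parts = np.tile([0, 0, 1, 1], (5, 1))
        co = np.array([[1, 1, 0, 0], [1, 1, 0, 0],
                       [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float)
        run = ConsensusRun(k=2, partitions=parts, consensus=co)
        classes, sil, concord = consensus_classes(run)
        assert concord == 1.0
        assert adjusted_rand_score(classes, [0, 0, 1, 1]) == 1.0
        assert (sil > 0.99).all()

    def test_hand_vote_and_concordance(self):
        # three repeats {AB|CD}, one {AC|BD}: vote -> {AB|CD}, concordance 0.875
        parts = np.array([[0, 0, 1, 1]] * 3 + [[0, 1, 0, 1]])
        co = np.zeros((4, 4))
        for p in parts:
            co += p[:, None] == p[None, :]
        co /= len(parts)
        run = ConsensusRun(k=2, partitions=parts, consensus=co)
        classes, _, concord = consensus_classes(run)
        assert list(classes) == [0, 0, 1, 1]
        assert concord == pytest.approx(0.875)

    def test_equidistant_sample_not_confident(self):
        # sample 4 has consensus 0.5 to both groups -> silhouette ~ 0
        co = np.eye(5)
        co[:2, :2] = 1.0
        co[2:4, 2:4] = 1.0
        co[4, :4] = co[:4, 4] = 0.5
        parts = np.array([[0, 0, 1, 1, 0], [0, 0, 1, 1, 1]])
        run = ConsensusRun(k=2, partitions=parts, consensus=co)
        _, sil, _ = consensus_classes(run)
        assert abs(sil[4]) < 0.2
        assert sil[4] < 0.5            # below the confidence threshold


class TestJaccard:
    def test_identical_partitions(self):
        p = np.array([0, 1, 1, 2, 0])
        assert jaccard_index(p, p) == 1.0

    def test_pairs_example_one_third(self):
        assert jaccard_index([0, 0, 1, 1], [0, 0, 0, 0]) == pytest.approx(1 / 3)

    def test_singletons_convention(self):
        assert jaccard_index([0, 1, 2], [2, 1, 0]) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            p1 = rng.integers(0, 3, 12)
            p2 = rng.integers(0, 4, 12)
            assert jaccard_index(p1, p2) == jaccard_index(p2, p1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            jaccard_index([0, 1], [0, 1, 2])


class TestSelectBestK:
    def _metrics(self, pac, sil=None, con=None, jac=None):
        ks = sorted(pac)
        return [
            KMetrics(k=k, one_minus_pac=pac[k],
                     mean_silhouette=(sil or {}).get(k, 0.5),
                     concordance=(con or {}).get(k, 0.5),
                     jaccard_prev=(jac or {}).get(k))
            for k in ks
        ]

    def test_rule2_takes_max_passing_k(self):
        metrics = self._metrics({2: 0.95, 3: 0.92, 4: 0.95},
                                jac={3: 0.6, 4: 0.6})
        best, optional = select_best_k(metrics, PartitionConfig())
        assert best == 4 and optional == [2, 3]

    def test_rule1_removes_redundant_k(self):
        metrics = self._metrics({2: 0.95, 3: 0.99, 4: 0.5},
                                jac={3: 0.97, 4: 0.6})
        best, optional = select_best_k(metrics, PartitionConfig())
        assert best == 2 and optional == []

    def test_rule3_majority_vote(self):
        metrics = self._metrics({2: 0.7, 3: 0.8, 4: 0.6},
                                sil={2: 0.4, 3: 0.9, 4: 0.2},
                                con={2: 0.99, 3: 0.5, 4: 0.5},
                                jac={3: 0.5, 4: 0.5})
        best, optional = select_best_k(metrics, PartitionConfig())
        assert best == 3 and optional == []

    def test_rule3_three_way_disagreement_falls_to_pac(self):
        metrics = self._metrics({2: 0.8, 3: 0.7, 4: 0.6},
                                sil={2: 0.2, 3: 0.9, 4: 0.2},
                                con={2: 0.5, 3: 0.5, 4: 0.99},
                                jac={3: 0.5, 4: 0.5})
        best, _ = select_best_k(metrics, PartitionConfig())
        assert best == 2


class TestPipeline:
    def test_planted_recovery(self, planted_consensus):
        _, truth, result = planted_consensus
        assert result.best_k == 4
        assert adjusted_rand_score(truth.sample_group, result.classes) >= 0.9
        assert not result.weak_structure

    def test_totality_and_confidence(self, planted_consensus):
        qc_matrix, _, result = planted_consensus
        n = qc_matrix.shape[1]
        assert len(result.classes) == n
        assert set(result.classes) == set(range(1, result.best_k + 1))
        assert result.n_confident <= n
        assert (result.confident == (result.sample_silhouette >= 0.5)).all()

    def test_null_data_flags_weak_structure(self):
        rng = np.random.default_rng(21)
        m = make_matrix(rng.normal(size=(60, 36)))
        from serostrat import run_consensus_pipeline

        result = run_consensus_pipeline(
            m, PartitionConfig(n_repeats=15, seed=21)
        )
        assert result.weak_structure
        assert result.n_confident < m.shape[1]

    def test_summary_mentions_best_k(self, planted_consensus):
        _, _, result = planted_consensus
        text = result.summary()
        assert "best k = 4" in text
        assert "1-PAC" in text
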