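"""Mention-vector aggregation, similarity benchmarks, clustering validation."""

from itertools import product

import numpy as np
import pytest

import entdec as e


def pair_counting_ari(a, b):
    """Independent oracle: chance-corrected pair-counting agreement."""
    from math import comb
    n = len(a)
    labels_a, labels_b = sorted(set(a)), sorted(set(b))
    nij = np.array([[sum(1 for x, y in zip(a, b) if x == i and y == j)
                     for j in labels_b] for i in labels_a])
    sum_ij = sum(comb(int(v), 2) for v in nij.ravel())
    sum_a = sum(comb(int(v), 2) for v in nij.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in nij.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    maximum = (sum_a + sum_b) / 2
    if maximum == expected:
        return 1.0
    return (sum_ij - expected) / (maximum - expected)


class TestAggregation:
    def test_single_mention_single_layer_identity(self):
        v = np.array([[1.0, 2.0, 3.0]])
        mv = e.MentionVectors(entity_id="x", mentions=[v])
        np.testing.assert_array_equal(
            e.aggregate_contextual_vectors(mv, [0]), [1.0, 2.0, 3.0])

    def test_two_mentions_mean(self):
        mv = e.MentionVectors(entity_id="x",
                              mentions=[np.array([[1.0, 0.0]]),
                                        np.array([[0.0, 1.0]])])
        np.testing.assert_allclose(
            e.aggregate_contextual_vectors(mv, [0]), [0.5, 0.5])

    def test_layer_and_mention_means_commute(self):
        rng = np.random.default_rng(0)
        blocks = [rng.standard_normal((4, 6)) for _ in range(5)]
        mv = e.MentionVectors(entity_id="x", mentions=blocks)
        layers = [1, 3]
        by_layer_first = e.aggregate_contextual_vectors(mv, layers)
        by_mention_first = np.mean(
            [np.mean([b[l] for b in blocks], axis=0) for l in layers], axis=0)
        np.testing.assert_allclose(by_layer_first, by_mention_first)

    def test_mentions_truncated_to_cap(self):
        rng = np.random.default_rng(1)
        blocks = [rng.standard_normal((1, 3)) for _ in range(40)]
        mv = e.MentionVectors(entity_id="x", mentions=blocks)
        assert len(mv.mentions) == 32
        capped = e.aggregate_contextual_vectors(mv, [0])
        np.testing.assert_allclose(
            capped, np.mean([b[0] for b in blocks[:32]], axis=0))

    def test_empty_layer_set_raises(self):
        mv = e.MentionVectors(entity_id="x", mentions=[np.ones((2, 3))])
        with pytest.raises(ValueError):
            e.aggregate_contextual_vectors(mv, [])

    def test_aggregate_generated_mentions_recovers_vectors(self, vectors):
        mentions = e.generate_mention_vectors(vectors, n_mentions=30,
                                              n_layers=2,
                                              mention_noise_sd=0.05, seed=2)
        agg = e.aggregate_vector_set(mentions, layers=[0, 1])
        for name in vectors.names:
            np.testing.assert_allclose(agg.get(name), vectors.get(name),
                                       atol=0.1)


class TestSimilarityBenchmark:
    def _bench_from(self, vectors, scores):
        names = vectors.names
        pairs = []
        k = 0
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if k >= len(scores):
                    break
                pairs.append((names[i], names[j], scores[k]))
                k += 1
        return e.SimilarityBenchmark(pairs=tuple(pairs))

    def test_cosines_equal_scores_give_one(self, vectors):
        names = vectors.names[:10]
        U = vectors.subset(names).vectors
        U = U / np.linalg.norm(U, axis=1, keepdims=True)
        pairs = [(names[i], names[j], float(U[i] @ U[j]))
                 for i in range(10) for j in range(i + 1, 10)]
        bench = e.SimilarityBenchmark(pairs=tuple(pairs))
        assert e.similarity_benchmark_correlation(
            vectors, bench) == pytest.approx(1.0)
        negated = e.SimilarityBenchmark(
            pairs=tuple((a, b, -s) for a, b, s in pairs))
        assert e.similarity_benchmark_correlation(
            vectors, negated) == pytest.approx(-1.0)

    def test_three_pair_rank_example(self):
        # cosine ranking (1,2,3) vs human ranking (1,3,2): rho = 0.5
        v = e.VectorSet(
            names=("a", "b", "c", "d"),
            vectors=np.array([[1.0, 0.0], [1.0, 0.2], [1.0, 0.5],
                              [0.0, 1.0]]))
        bench = e.SimilarityBenchmark(pairs=(("a", "b", 3.0),
                                             ("a", "c", 1.0),
                                             ("a", "d", 2.0)))
        # cosines: ab > ac > ad -> ranks (3,2,1); human (3,1,2)
        assert e.similarity_benchmark_correlation(
            v, bench) == pytest.approx(0.5)

    def test_unresolvable_pairs_dropped_and_floor_enforced(self, vectors):
        bench = e.SimilarityBenchmark(pairs=(
            (vectors.names[0], "nonexistent", 1.0),
            (vectors.names[0], vectors.names[1], 1.0)))
        with pytest.raises(e.InsufficientDataError):
            e.similarity_benchmark_correlation(vectors, bench)

    def test_tsv_loading(self, tmp_path):
        path = tmp_path / "bench.tsv"
        path.write_text("id1\tid2\tscore\na\tb\t3.5\nb\tc\t1.0\n")
        bench = e.SimilarityBenchmark.from_tsv(path)
        assert bench.pairs == (("a", "b", 3.5), ("b", "c", 1.0))


class TestClustering:
    def test_separated_clouds_perfect_ari(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [50, 0], [0, 50], [50, 50]], float)
        X = np.concatenate(
            [c + rng.standard_normal((10, 2)) for c in centers])
        names = tuple(f"v{i}" for i in range(40))
        labels = {f"v{i}": f"c{i // 10}" for i in range(40)}
        out = e.cluster_and_score(
            e.VectorSet(names=names, vectors=X), labels, seed=0)
        assert out.ari == 1.0 and out.k == 4

    def test_ari_matches_pair_counting_oracle(self):
        from sklearn.metrics import adjusted_rand_score
        # exhaustive over 4-item labelings, sampled 8-item labelings
        for a in product(range(3), repeat=4):
            for b in product(range(2), repeat=4):
                assert adjusted_rand_score(a, b) == pytest.approx(
                    pair_counting_ari(a, b))
        rng = np.random.default_rng(5)
        for _ in range(200):
            a = rng.integers(0, 3, 8)
            b = rng.integers(0, 4, 8)
            assert adjusted_rand_score(a, b) == pytest.approx(
                pair_counting_ari(list(a), list(b)))

    def test_shuffled_labels_ari_near_zero(self):
        rng = np.random.default_rng(6)
        clusters = list(rng.integers(0, 4, 40))
        means = [pair_counting_ari(clusters,
                                   list(rng.permutation(clusters)))
                 for _ in range(500)]
        assert abs(np.mean(means)) < 0.02

    def test_coarse_easier_than_fine_on_hierarchical_vectors(self, design):
        # entity scatter comparable to the fine-category separation makes
        # fine clustering imperfect while the coarse split stays trivial
        v = e.generate_entity_vectors(design, dim=10, sigma_coarse=3.0,
                                      sigma_fine=0.2, sigma_entity=0.3,
                                      seed=8)
        ids = [s.id for s in design.entities]
        ent = v.subset(ids)
        coarse = e.cluster_and_score(
            ent, {s.id: s.coarse for s in design.entities}, seed=0,
            scheme="coarse/entities")
        fine = e.cluster_and_score(
            ent, {s.id: s.fine for s in design.entities}, seed=0,
            scheme="fine/entities")
        assert coarse.ari > fine.ari

    def test_k_mismatch_raises(self, design, vectors):
        labels = {s.id: s.coarse for s in e.build_design(seed=0).stimuli}
        with pytest.raises(ValueError):
            e.cluster_and_score(vectors, labels, k=5)
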