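"""Zero-shot ridge decoding and the leave-two-out pairwise evaluation."""

from dataclasses import replace
from itertools import combinations

import numpy as np
import pytest

import entdec as e


class TestFeatures:
    def test_feature_length_small_case(self, evoked):
        spec = e.DecoderSpec(feature_window=(100.0, 1200.0))
        X = e.features_from_evoked(evoked, spec)
        i0, i1 = e.window_indices(evoked.times, evoked.rate, (100.0, 1200.0))
        assert X.shape == (40, evoked.evoked.shape[1] * (i1 - i0 + 1))

    def test_full_scale_feature_length(self):
        # 128 channels x 282 in-window samples at 256 Hz -> 36,096 features
        times = e.sample_times((-100.0, 1200.0), 256.0)
        ev = e.EvokedSet(subject_id="x",
                         evoked=np.zeros((2, 128, len(times))),
                         stimulus_ids=("a", "b"), times=times, rate=256.0)
        X = e.features_from_evoked(ev, e.DecoderSpec())
        assert X.shape == (2, 36096)

    def test_flatten_is_channel_major_bijection(self, evoked):
        spec = e.DecoderSpec(feature_window=(100.0, 1200.0))
        X = e.features_from_evoked(evoked, spec)
        i0, i1 = e.window_indices(evoked.times, evoked.rate, (100.0, 1200.0))
        block = X[0].reshape(evoked.evoked.shape[1], i1 - i0 + 1)
        np.testing.assert_array_equal(block, evoked.evoked[0, :, i0:i1 + 1])


class TestPairwiseScore:
    def test_exact_predictions_win(self):
        rng = np.random.default_rng(0)
        e1, e2 = rng.standard_normal(10), rng.standard_normal(10)
        out = e.pairwise_score(e1, e2, e1, e2)
        assert out.accuracy == 1.0
        assert out.rho_matched == pytest.approx((1.0, 1.0))

    def test_swapped_predictions_lose(self):
        rng = np.random.default_rng(1)
        e1, e2 = rng.standard_normal(10), rng.standard_normal(10)
        assert e.pairwise_score(e1, e2, e2, e1).accuracy == 0.0

    def test_hand_computed_rank_example(self):
        out = e.pairwise_score([1, 2, 3], [3, 2, 1], [1, 2, 3], [3, 1, 2])
        assert out.rho_matched == pytest.approx((1.0, 0.5))
        assert out.rho_mismatched == pytest.approx((-0.5, -1.0))
        assert out.accuracy == 1.0

    def test_tie_scores_half(self):
        out = e.pairwise_score([1, 2, 3], [1, 2, 3], [3, 2, 1], [3, 2, 1])
        assert out.accuracy == 0.5

    def test_constant_vector_raises(self):
        with pytest.raises(e.DegenerateVectorError):
            e.pairwise_score([1, 1, 1], [1, 2, 3], [1, 2, 3], [1, 2, 3])


class TestLeaveTwoOut:
    def test_pair_counts(self, design, evoked, vectors):
        res = e.leave_two_out_decoding(evoked, vectors, design, "entities_only")
        assert len(res.outcomes) == 496  # C(32, 2)

    def test_noiseless_linear_recovery(self, design, vectors, small_config):
        cfg = replace(small_config, noise_sd=0.0, n_repetitions=1)
        ev = e.preprocess(
            e.generate_epoch_dataset(design, vectors, cfg, "s00"), design)
        res = e.leave_two_out_decoding(
            ev, vectors, design, "entities_only", e.DecoderSpec(alpha=1e-6))
        assert res.accuracy >= 0.99

    def test_independent_predictions_score_chance(self, design, vectors):
        # predictions statistically independent of the targets -> ~0.5
        rng = np.random.default_rng(7)
        ids = [s.id for s in design.entities]
        Y = vectors.subset(ids).vectors
        accs = []
        for i, j in combinations(range(len(ids)), 2):
            out = e.pairwise_score(Y[i], Y[j], rng.standard_normal(Y.shape[1]),
                                   rng.standard_normal(Y.shape[1]))
            accs.append(out.accuracy)
        assert abs(np.mean(accs) - 0.5) < 3 * 0.5 / np.sqrt(len(accs))

    def test_dimension_permutation_invariance(self, design, vectors,
                                              small_config):
        cfg = replace(small_config, noise_sd=0.0, n_repetitions=1)
        ev = e.preprocess(
            e.generate_epoch_dataset(design, vectors, cfg, "s00"), design)
        perm = np.random.default_rng(3).permutation(vectors.dim)
        permuted = e.VectorSet(names=vectors.names,
                               vectors=vectors.vectors[:, perm])
        a = e.leave_two_out_decoding(ev, vectors, design, "entities_only")
        b = e.leave_two_out_decoding(ev, permuted, design, "entities_only")
        assert a.accuracy == pytest.approx(b.accuracy)

    def test_noise_monotonicity(self, design, vectors):
        # accuracy non-increasing over a noise ladder, one small violation
        # tolerated
        accs = []
        for noise in (0.0, 1.0, 5.0, 20.0):
            cfg = e.GeneratorConfig(n_channels=16, rate=64.0, n_repetitions=4,
                                    noise_sd=noise, seed=9)
            ev = e.preprocess(
                e.generate_epoch_dataset(design, vectors, cfg, "s00"), design)
            accs.append(e.leave_two_out_decoding(
                ev, vectors, design, "entities_only").accuracy)
        violations = [max(0.0, b - a) for a, b in zip(accs, accs[1:])]
        assert sum(v > 0.02 for v in violations) <= 1

    def test_too_few_stimuli_raise(self, design, evoked, vectors):
        small = evoked.subset(evoked.stimulus_ids[:3])
        with pytest.raises(ValueError):
            e.leave_two_out_decoding(small, vectors, design, "entities_only")


class TestBreakdown:
    def test_bin_counts_sum_to_all_pairs(self, design, evoked, vectors):
        res = e.leave_two_out_decoding(evoked, vectors, design, "all")
        table = e.breakdown_by_pair_type(res)
        assert table["n_pairs"].sum() == 780  # C(40, 2)
        ee_people = table[(table.ontology_bin == "entity-entity")
                          & (table.coarse_bin == "people")]
        assert ee_people["n_pairs"].iloc[0] == 120  # C(16, 2)

    def test_tags_symmetric(self, design):
        assert e.pair_tags(design, "musician_0", "city_noun") == \
            e.pair_tags(design, "city_noun", "musician_0")
        assert e.pair_tags(design, "musician_0", "city_0")[1] == "mixed"
        assert e.pair_tags(design, "musician_0", "actor_noun") == \
            ("mixed", "people")


class TestLengthSimilarity:
    def test_constructed_monotone_association(self, design):
        # vectors built so cosine falls exactly with the length gap
        ids = design.stimulus_ids
        lengths = np.array([design.by_id(i).word_length for i in ids], float)
        # 2-d unit vectors at angle proportional to length: cosine of a pair
        # decreases monotonically with |length difference|
        theta = (lengths - lengths.min()) / np.ptp(lengths) * (np.pi / 2)
        V = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        rho = e.length_similarity_correlation(
            e.VectorSet(names=tuple(ids), vectors=V), design)
        # floating-point jitter breaks exact rank ties between equal length
        # gaps, so the association is near-perfect rather than exactly -1
        assert rho <= -0.99

    def test_independent_vectors_near_zero(self, design):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            V = e.VectorSet(names=tuple(design.stimulus_ids),
                            vectors=rng.standard_normal((40, 50)))
            if abs(e.length_similarity_correlation(V, design)) < 0.3:
                hits += 1
        assert hits >= 38  # ~95% of null replicates

    def test_bounded(self, design, vectors):
        rho = e.length_similarity_correlation(vectors, design)
        assert -1.0 <= rho <= 1.0
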