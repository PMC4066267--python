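import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from vmlong.core_data import CommunityState, SampleMetadata
from vmlong.divergence import (
    cst_frequencies,
    js_distance,
    js_divergence,
    kl_divergence,
    label_csts,
    pairwise_divergence,
    ward_cluster,
)


def _state(i, vec):
    v = np.asarray(vec, dtype=float)
    return CommunityState(f"s{i}", v / v.sum())


class TestKL:
    def test_identity_is_zero(self):
        assert kl_divergence([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_one_bit(self):
        # p concentrated on a component with q-mass 1/2: 1*log2(1/0.5) = 1 bit
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_support_violation_is_infinite(self):
        assert kl_divergence([0.5, 0.5], [1.0, 0.0]) == float("inf")

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kl_divergence([1.0], [0.5, 0.5])


class TestJSD:
    def test_identical_states_zero(self):
        assert js_divergence([0.5, 0.3, 0.2], [0.5, 0.3, 0.2]) == 0.0

    def test_disjoint_support_is_one(self):
        assert js_divergence([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # a = (0.75, 0.25); [KL(p,a) + KL(q,a)]/2 with base-2 logs
        assert js_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(0.311278, abs=1e-6)

    def test_symmetric_bounded_finite_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(500):
            p = rng.dirichlet(np.full(8, 0.3))
            q = rng.dirichlet(np.full(8, 0.3))
            d, d2 = js_divergence(p, q), js_divergence(q, p)
            assert d == pytest.approx(d2, abs=1e-12)
            assert 0.0 <= d <= 1.0
            assert np.isfinite(d)  # never infinite even when KL would be

    def test_finite_where_kl_is_not(self):
        p, q = [1.0, 0.0, 0.0], [0.0, 0.5, 0.5]
        assert kl_divergence(p, q) == float("inf")
        assert np.isfinite(js_divergence(p, q))


class TestJSDistance:
    def test_endpoints(self):
        assert js_distance([0.4, 0.6], [0.4, 0.6]) == 0.0
        assert js_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p, q, r = (rng.dirichlet(np.full(5, 0.5)) for _ in range(3))
            assert js_distance(p, r) <= js_distance(p, q) + js_distance(q, r) + 1e-12


class TestPairwise:
    def test_identical_states_zero_matrix(self):
        states = [_state(0, [2, 1]), _state(1, [2, 1])]
        m = pairwise_divergence(states)
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_matches_elementwise_calls(self):
        rng = np.random.default_rng(3)
        states = [_state(i, rng.dirichlet(np.ones(6))) for i in range(5)]
        m = pairwise_divergence(states)
        for i in range(5):
            for j in range(5):
                expected = js_divergence(states[i].abundances, states[j].abundances)
                assert m.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_metric_option(self):
        states = [_state(0, [1, 0]), _state(1, [0, 1])]
        assert pairwise_divergence(states, "js_distance").values[0, 1] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            pairwise_divergence(states, "euclidean")


class TestWardClustering:
    @staticmethod
    def _planted_states(rng, n_per=15):
        profiles = [
            np.array([0.90, 0.02, 0.02, 0.02, 0.02, 0.02]),
            np.array([0.02, 0.90, 0.02, 0.02, 0.02, 0.02]),
            np.array([0.05, 0.05, 0.30, 0.25, 0.20, 0.15]),
        ]
        states, labels = [], []
        for g, base in enumerate(profiles):
            for i in range(n_per):
                states.append(_state(g * n_per + i, rng.dirichlet(base * 400)))
                labels.append(g)
        return states, labels

    def test_recovers_planted_partition(self):
        rng = np.random.default_rng(11)
        states, labels = self._planted_states(rng)
        assign = ward_cluster(pairwise_divergence(states), n_clusters=3)
        assert adjusted_rand_score(labels, assign.cluster_index) == 1.0

    def test_degenerate_cluster_counts(self):
        rng = np.random.default_rng(12)
        states = [_state(i, rng.dirichlet(np.ones(4))) for i in range(6)]
        m = pairwise_divergence(states)
        assert len(np.unique(ward_cluster(m, 6).cluster_index)) == 6
        assert len(np.unique(ward_cluster(m, 1).cluster_index)) == 1
        with pytest.raises(ValueError):
            ward_cluster(m, 7)


class TestLabeling:
    def test_dominant_taxon_rules(self):
        taxa = (
            "Lactobacillus crispatus",
            "Lactobacillus iners",
            "Gardnerella vaginalis",
            "BVAB1",
        )
        comps = [
            [0.9, 0.05, 0.03, 0.02],  # -> CST I
            [0.9, 0.05, 0.03, 0.02],
            [0.05, 0.8, 0.1, 0.05],  # -> CST III
            [0.05, 0.8, 0.1, 0.05],
            [0.05, 0.05, 0.4, 0.5],  # Lactobacillus-poor -> IV-B
            [0.05, 0.05, 0.5, 0.4],
        ]
        states = [CommunityState(f"s{i}", np.array(c)) for i, c in enumerate(comps)]
        m = pairwise_divergence(states)
        assign = label_csts(ward_cluster(m, 3), states, taxa)
        assert assign.label_of("s0") == "I"
        assert assign.label_of("s2") == "III"
        assert assign.label_of("s4") == "IV-B"


class TestFrequencies:
    def test_single_type(self):
        taxa = ("Lactobacillus crispatus", "Gardnerella vaginalis")
        states = [CommunityState(f"s{i}", np.array([0.95, 0.05])) for i in range(10)]
        meta = [SampleMetadata(f"s{i}", f"p{i}", "term", 10.0, 100) for i in range(10)]
        assign = label_csts(ward_cluster(pairwise_divergence(states), 1), states, taxa)
        freqs = cst_frequencies(assign, meta)
        assert freqs.loc["overall", "I"] == pytest.approx(100.0)

    def test_mixture_recovered_within_sampling_and_clustering_error(self, default_cohort):
        """Recovered CST frequencies track the generator's planted mixture.

        Tolerance allows both binomial sampling error and the few percent of
        genuinely ambiguous samples (structural zeros can make a
        Lactobacillus-dominated sample look diverse).
        """
        table, meta, truth = default_cohort
        from vmlong.core_data import to_relative_abundance

        states = to_relative_abundance(table)
        assign = ward_cluster(pairwise_divergence(states), 3)
        assign = label_csts(assign, states, table.taxa)
        true_labels = [truth.sample_cst[s] for s in table.samples]
        assert adjusted_rand_score(true_labels, assign.cluster_index) > 0.85
        freqs = cst_frequencies(assign, meta)
        true_freq = {}
        for lab in true_labels:
            true_freq[lab] = true_freq.get(lab, 0) + 1
        n = table.n_samples
        for cst in ("I", "III", "IV-B"):
            expected = 100.0 * true_freq.get(cst, 0) / n
            assert freqs.loc["overall", cst] == pytest.approx(expected, abs=5.0)

    def test_empty_group_absent_not_crashing(self):
        taxa = ("Lactobacillus crispatus", "Gardnerella vaginalis")
        states = [CommunityState(f"s{i}", np.array([0.95, 0.05])) for i in range(4)]
        meta = [SampleMetadata(f"s{i}", f"p{i}", "term", 10.0, 50) for i in range(4)]
        assign = label_csts(ward_cluster(pairwise_divergence(states), 1), states, taxa)
        freqs = cst_frequencies(assign, meta)
        assert "preterm" not in freqs.index
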