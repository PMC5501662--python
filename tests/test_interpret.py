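import collections

import numpy as np
import pytest

from mitonet import (
    LengthDistribution,
    branchpoint_lengths,
    brute_force_enumerate,
    cluster_distribution,
    image_distribution,
    longest_path_lengths,
    make_bin_edges,
    sample_interpretations,
)
from mitonet.elements import JUNCTION, TUBULE
from mitonet.interpret import (
    Interpretation,
    InterpretationTable,
    enumerate_local_interpretations,
    interpretation_lengths,
    realize_interpretation,
)

from conftest import PX_UM, clusters_from_skeleton


@pytest.fixture(scope="module")
def table():
    return InterpretationTable.default()


class TestLocalPatterns:
    def test_end_has_single_terminate_pattern(self, table, straight_line):
        clusters, graph = clusters_from_skeleton(straight_line)
        (cl,) = clusters
        end = graph.elements[cl.ids_of_kind("end")[0]]
        pats = enumerate_local_interpretations(end, table, graph)
        assert len(pats) == 1 and pats[0].terminated == (0,)

    def test_tubule_has_single_passthrough(self, table, straight_line):
        clusters, graph = clusters_from_skeleton(straight_line)
        tub = graph.elements[clusters[0].ids_of_kind("tubule")[0]]
        pats = enumerate_local_interpretations(tub, table, graph)
        assert len(pats) == 1 and pats[0].links == ((0, 1),)

    def test_degree3_table_matches_committed_pattern_count(self, table, t_cluster):
        """The shipped degree-3 table has the documented 8 patterns: one
        all-terminate, 3 pass+terminate, 3 pass+abut, one full fusion."""
        clusters, graph = clusters_from_skeleton(t_cluster)
        jun = graph.elements[clusters[0].ids_of_kind("junction")[0]]
        pats = enumerate_local_interpretations(jun, table, graph)
        assert len(pats) == 8
        by_links = collections.Counter(len(p.links) for p in pats)
        assert by_links == {0: 1, 1: 6, 3: 1}

    def test_unsupported_degree_raises(self, table):
        with pytest.raises(KeyError):
            table.patterns(7)

    def test_every_pattern_covers_all_slots(self, table):
        for p in table.patterns(3):
            covered = {s for link in p.links for s in link} | set(p.terminated)
            assert covered == {0, 1, 2}


class TestSampling:
    def test_junction_free_cluster_has_unique_interpretation(self, straight_line, table):
        clusters, _ = clusters_from_skeleton(straight_line)
        samples = sample_interpretations(clusters[0], table, n_samples=50, seed=0)
        dist = cluster_distribution(samples, PX_UM)
        assert np.all(dist.sd == 0)
        assert dist.expected_count == 1.0

    def test_pattern_frequencies_uniform(self, t_cluster, table):
        clusters, _ = clusters_from_skeleton(t_cluster)
        (cl,) = clusters
        (jid,) = cl.ids_of_kind(JUNCTION)
        n = 2000
        samples = sample_interpretations(cl, table, n_samples=n, seed=7)
        freqs = collections.Counter(s.choices[jid] for s in samples)
        p = 1 / 8
        se = np.sqrt(p * (1 - p) / n)
        for k in range(8):
            assert abs(freqs[k] / n - p) < 3 * se + 1e-9

    def test_same_seed_reproducible(self, t_cluster, table):
        clusters, _ = clusters_from_skeleton(t_cluster)
        s1 = sample_interpretations(clusters[0], table, n_samples=100, seed=42)
        s2 = sample_interpretations(clusters[0], table, n_samples=100, seed=42)
        assert [s.choices for s in s1] == [s.choices for s in s2]

    def test_invalid_n_samples(self, straight_line, table):
        clusters, _ = clusters_from_skeleton(straight_line)
        with pytest.raises(ValueError):
            sample_interpretations(clusters[0], table, n_samples=0)


class TestLengths:
    def test_straight_tubule_recovers_known_length(self, table):
        # 46-px drawn line = 45 steps = 3.0 um at 15 px/um
        arr = np.zeros((9, 60), bool)
        arr[4, 5:51] = True
        clusters, _ = clusters_from_skeleton(arr)
        samples = sample_interpretations(clusters[0], table, n_samples=1, seed=0)
        (length,) = interpretation_lengths(samples[0], PX_UM)
        assert abs(length - 3.0) <= 0.5  # within one default bin

    def test_junction_contribution_nonnegative(self, t_cluster, table):
        clusters, graph = clusters_from_skeleton(t_cluster)
        (cl,) = clusters
        tub_len = {t: graph.tubule_length_px(t) for t in cl.ids_of_kind(TUBULE)}
        for s in sample_interpretations(cl, table, n_samples=50, seed=3):
            for path, plen in zip(s.paths, s.lengths_px):
                member_sum = sum(tub_len.get(e, 0.0) for e in path)
                assert plen >= member_sum - 1e-9

    def test_empty_paths_empty_lengths(self):
        interp = Interpretation({}, [], [])
        assert interpretation_lengths(interp, PX_UM) == []

    def test_tubule_length_conserved_across_interpretations(self, h_cluster, table):
        """Connectivity choices redistribute, never create, tubule length."""
        clusters, graph = clusters_from_skeleton(h_cluster)
        (cl,) = clusters
        total = sum(graph.tubule_length_px(t) for t in cl.ids_of_kind(TUBULE))
        for s in sample_interpretations(cl, table, n_samples=64, seed=5):
            member = sum(
                graph.tubule_length_px(e)
                for path in s.paths
                for e in path
                if graph.elements[e].kind == TUBULE
            )
            assert member == pytest.approx(total)


class TestClusterDistribution:
    def test_identical_samples_zero_sd(self):
        i = Interpretation({}, [frozenset({0})], [45.0])
        dist = cluster_distribution([i, i, i], PX_UM)
        assert np.all(dist.sd == 0)

    def test_hand_computed_average_of_two_histograms(self):
        edges = make_bin_edges(0.5, 10.0)
        a = Interpretation({0: 0}, [frozenset({0}), frozenset({1})], [45.0, 45.0])
        b = Interpretation({0: 1}, [frozenset({0, 1})], [90.0])
        dist = cluster_distribution([a, b], PX_UM)
        # sample a: all mass at 3.0 um; sample b: all mass at 6.0 um
        bin3 = np.searchsorted(edges, 3.0, side="right") - 1
        bin6 = np.searchsorted(edges, 6.0, side="right") - 1
        assert dist.mass[bin3] == pytest.approx(0.5)
        assert dist.mass[bin6] == pytest.approx(0.5)
        assert dist.expected_count == pytest.approx(1.5)

    def test_isolated_mitochondrion_expected_count_one(self, straight_line, table):
        clusters, _ = clusters_from_skeleton(straight_line)
        samples = sample_interpretations(clusters[0], table, n_samples=10, seed=0)
        assert cluster_distribution(samples, PX_UM).expected_count == 1.0


class TestBruteForce:
    def test_junction_free_matches_sampled(self, straight_line, table):
        clusters, _ = clusters_from_skeleton(straight_line)
        exact = brute_force_enumerate(clusters[0], table)
        sampled = cluster_distribution(
            sample_interpretations(clusters[0], table, 10, seed=0), PX_UM, exact.bin_edges
        )
        assert np.allclose(exact.mass, sampled.mass)

    def test_one_junction_tv_bound(self, t_cluster, table):
        clusters, _ = clusters_from_skeleton(t_cluster)
        n = 2000
        exact = brute_force_enumerate(clusters[0], table)
        sampled = cluster_distribution(
            sample_interpretations(clusters[0], table, n, seed=1), PX_UM, exact.bin_edges
        )
        tv = 0.5 * np.abs(exact.mass - sampled.mass).sum()
        assert tv < 3 / np.sqrt(n)

    def test_two_junction_expected_count_within_5pct(self, h_cluster, table):
        clusters, _ = clusters_from_skeleton(h_cluster)
        exact = brute_force_enumerate(clusters[0], table)
        sampled = cluster_distribution(
            sample_interpretations(clusters[0], table, 2000, seed=2), PX_UM, exact.bin_edges
        )
        assert abs(sampled.expected_count - exact.expected_count) / exact.expected_count < 0.05


class TestImageDistribution:
    def test_single_cluster_identity(self):
        edges = make_bin_edges()
        mass = np.zeros(len(edges) - 1)
        mass[4] = 1.0
        d = LengthDistribution(edges, mass, np.zeros_like(mass), 3.0)
        combined = image_distribution([d])
        assert np.allclose(combined.mass, d.mass)
        assert combined.expected_count == 3.0

    def test_count_weighted_combination(self):
        edges = make_bin_edges()
        m3 = np.zeros(len(edges) - 1)
        m3[np.searchsorted(edges, 3.0, side="right") - 1] = 1.0
        m6 = np.zeros(len(edges) - 1)
        m6[np.searchsorted(edges, 6.0, side="right") - 1] = 1.0
        a = LengthDistribution(edges, m3, np.zeros_like(m3), 2.0)
        b = LengthDistribution(edges, m6, np.zeros_like(m6), 1.0)
        combined = image_distribution([a, b])
        assert combined.mass[m3.argmax()] == pytest.approx(2 / 3)
        assert combined.mass[m6.argmax()] == pytest.approx(1 / 3)
        assert combined.expected_count == 3.0

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            image_distribution([])


class TestLengthVariants:
    def test_straight_line_both_variants_agree(self, straight_line):
        clusters, _ = clusters_from_skeleton(straight_line)
        bp = branchpoint_lengths(clusters[0])
        lp = longest_path_lengths(clusters[0])
        assert len(bp) == len(lp) == 1
        assert bp[0] == pytest.approx(lp[0])

    def test_t_cluster_variants(self, t_cluster):
        """Arms of 3, 3 and 4 um: branch-to-branch gives {3, 3, 4}, the
        longest-path extreme {7, 3}."""
        clusters, _ = clusters_from_skeleton(t_cluster)
        bp = sorted(branchpoint_lengths(clusters[0]))
        lp = sorted(longest_path_lengths(clusters[0]))
        assert np.allclose(bp, [3.0, 3.0, 4.0], atol=0.2)
        assert np.allclose(lp, [3.0, 7.0], atol=0.3)

    def test_h_cluster_longest_fewer_and_longer(self, h_cluster):
        clusters, _ = clusters_from_skeleton(h_cluster)
        bp = branchpoint_lengths(clusters[0])
        lp = longest_path_lengths(clusters[0])
        assert len(lp) < len(bp)
        assert max(lp) > max(bp)

    def test_mean_length_ordering(self, t_cluster, h_cluster, table):
        """Branch-to-branch mean <= probabilistic mean <= longest-path mean."""
        for arr in (t_cluster, h_cluster):
            clusters, _ = clusters_from_skeleton(arr)
            (cl,) = clusters
            bp_mean = np.mean(branchpoint_lengths(cl))
            lp_mean = np.mean(longest_path_lengths(cl))
            samples = sample_interpretations(cl, table, 500, seed=9)
            tot = np.mean([sum(s.lengths_px) for s in samples]) * PX_UM
            prob_mean = tot / np.mean([s.n_paths for s in samples])
            assert bp_mean <= prob_mean * 1.05
            assert prob_mean <= lp_mean * 1.05
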