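import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats as sps

from mitonet import (
    LengthDistribution,
    channel_metric_ratio,
    condition_emd_protocol,
    emd,
    make_bin_edges,
    pool_clusters,
)
from mitonet.elements import ConnectivityMetrics
from mitonet.stats import cell_phenotype_scatter


def dist_from_mass(mass, bin_width=0.5, sd=None):
    mass = np.asarray(mass, dtype=float)
    edges = np.arange(len(mass) + 1) * bin_width
    return LengthDistribution(edges, mass / mass.sum(), np.zeros_like(mass) if sd is None else sd)


def random_dist(rng, n_bins=10, bin_width=0.5):
    return dist_from_mass(rng.random(n_bins) + 1e-6, bin_width)


def emd_lp(d1, d2):
    """Transportation LP optimum between two histograms (oracle)."""
    c1, c2 = d1.mass, d2.mass
    centers = d1.bin_centers
    n = len(c1)
    cost = np.abs(centers[:, None] - centers[None, :]).ravel()
    a_eq = []
    for i in range(n):
        row = np.zeros((n, n))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(n):
        row = np.zeros((n, n))
        row[:, j] = 1
        a_eq.append(row.ravel())
    b_eq = np.concatenate([c1, c2])
    res = optimize.linprog(cost, A_eq=np.array(a_eq), b_eq=b_eq, method="highs")
    assert res.success
    return res.fun


class TestEMD:
    def test_self_distance_zero(self):
        rng = np.random.default_rng(0)
        d = random_dist(rng)
        assert emd(d, d) == 0.0

    def test_point_masses_closed_form(self):
        edges = make_bin_edges(1.0, 10.0)
        m1 = np.zeros(10)
        m1[2] = 1.0  # mass at 2-3 um bin
        m2 = np.zeros(10)
        m2[5] = 1.0  # mass at 5-6 um bin
        d1 = LengthDistribution(edges, m1, np.zeros(10))
        d2 = LengthDistribution(edges, m2, np.zeros(10))
        assert emd(d1, d2) == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_lp_transportation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d1, d2 = random_dist(rng), random_dist(rng)
        assert emd(d1, d2) == pytest.approx(emd_lp(d1, d2), abs=1e-9)

    def test_matches_scipy_wasserstein(self):
        rng = np.random.default_rng(4)
        d1, d2 = random_dist(rng), random_dist(rng)
        ref = sps.wasserstein_distance(d1.bin_centers, d2.bin_centers, d1.mass, d2.mass)
        assert emd(d1, d2) == pytest.approx(ref, abs=1e-9)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 10_000), st.integers(0, 10_000), st.integers(0, 10_000))
    def test_metric_axioms(self, s1, s2, s3):
        da = random_dist(np.random.default_rng(s1))
        db = random_dist(np.random.default_rng(s2))
        dc = random_dist(np.random.default_rng(s3))
        dab, dba = emd(da, db), emd(db, da)
        assert dab >= 0
        assert dab == pytest.approx(dba)  # symmetry
        if s1 != s2:
            assert (dab == 0) == np.allclose(da.mass, db.mass)  # identity
        assert emd(da, dc) <= dab + emd(db, dc) + 1e-12  # triangle

    @pytest.mark.parametrize("seed", [5, 15, 25])
    def test_stable_under_joint_bin_refinement(self, seed):
        """Splitting every bin in two changes the value by at most the
        half-bin discretization bound of the grid EMD."""
        rng = np.random.default_rng(seed)
        d1, d2 = random_dist(rng), random_dist(rng)
        split = lambda d: dist_from_mass(np.repeat(d.mass / 2, 2), d.bin_width / 2)
        assert abs(emd(split(d1), split(d2)) - emd(d1, d2)) <= d1.bin_width / 2

    def test_mismatched_bins_raise(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            emd(random_dist(rng, 10), random_dist(rng, 12))

    def test_unnormalized_warns(self):
        edges = np.arange(6) * 1.0
        raw = LengthDistribution(edges, np.ones(5), np.zeros(5))
        with pytest.warns(UserWarning, match="unnormalized"):
            emd(raw, raw)


class TestProtocol:
    def test_identical_conditions_all_zero(self):
        d = dist_from_mass([1, 2, 3, 2, 1])
        report = condition_emd_protocol({"C": [d, d, d], "T": [d, d, d]})
        assert np.allclose(report.table["value"], 0.0)

    def test_three_vs_three_emits_six_within_six_between(self):
        rng = np.random.default_rng(7)
        conds = {
            "C": [random_dist(rng) for _ in range(3)],
            "T": [random_dist(rng) for _ in range(3)],
        }
        report = condition_emd_protocol(conds)
        assert len(report.values("within")) == 6
        assert len(report.values("between")) == 6

    def test_shifted_conditions_between_exceeds_within(self):
        rng = np.random.default_rng(8)
        base = rng.random(10) + 0.1
        mk = lambda shift: dist_from_mass(np.roll(base, shift) + rng.normal(0, 0.01, 10).clip(-0.05))
        conds = {"C": [mk(0) for _ in range(3)], "T": [mk(2) for _ in range(3)]}
        report = condition_emd_protocol(conds)
        assert report.values("between").mean() > report.values("within").mean()

    def test_replicate_permutation_leaves_value_multiset(self):
        rng = np.random.default_rng(9)
        reps_c = [random_dist(rng) for _ in range(3)]
        reps_t = [random_dist(rng) for _ in range(3)]
        r1 = condition_emd_protocol({"C": reps_c, "T": reps_t})
        r2 = condition_emd_protocol({"C": reps_c[::-1], "T": reps_t[::-1]})
        assert sorted(r1.table["value"].round(12)) == sorted(r2.table["value"].round(12))

    def test_single_condition_raises(self):
        d = dist_from_mass([1, 1])
        with pytest.raises(ValueError):
            condition_emd_protocol({"C": [d, d]})


class TestPooling:
    def _clusters(self, arr):
        from conftest import clusters_from_skeleton

        return clusters_from_skeleton(arr)[0]

    def test_pool_single_image_identity(self, straight_line):
        cls = self._clusters(straight_line)
        assert pool_clusters([cls]) == cls

    def test_pool_k_copies_scales_count(self, straight_line):
        from mitonet import brute_force_enumerate, image_distribution

        cls = self._clusters(straight_line)
        pooled = pool_clusters([cls, cls, cls])
        dists = [brute_force_enumerate(c) for c in pooled]
        combined = image_distribution(dists)
        single = image_distribution([brute_force_enumerate(c) for c in cls])
        assert combined.expected_count == pytest.approx(3 * single.expected_count)
        assert np.allclose(combined.mass, single.mass)

    def test_pool_disjoint_sections_gives_bimodal_mixture(self):
        from mitonet import brute_force_enumerate, image_distribution

        short = np.zeros((9, 40), bool)
        short[4, 5:21] = True  # 1 um
        long = np.zeros((9, 120), bool)
        long[4, 5:96] = True  # 6 um
        pooled = pool_clusters([self._clusters(short), self._clusters(long)])
        combined = image_distribution([brute_force_enumerate(c) for c in pooled])
        occupied = np.flatnonzero(combined.mass > 0)
        assert len(occupied) == 2
        assert combined.bin_centers[occupied[1]] - combined.bin_centers[occupied[0]] > 3.0

    def test_pixel_size_mismatch_raises(self, straight_line):
        from conftest import clusters_from_skeleton

        a = clusters_from_skeleton(straight_line, pixel_size_um=1 / 15)[0]
        b = clusters_from_skeleton(straight_line, pixel_size_um=1 / 10)[0]
        with pytest.raises(ValueError):
            pool_clusters([a, b])


def metrics_with(e_c, j_over_e):
    return ConnectivityMetrics(
        n_ends=10, n_tubules=5, n_junctions=2, pct_ends=50, pct_tubules=30,
        pct_junctions=20, elements_per_cluster=e_c, j_over_e=j_over_e,
        t_over_e=0.5, connections_per_um=0.1, total_length_um=30.0, n_clusters=5,
    )


class TestChannelRatio:
    def test_identical_channels_ratio_one(self):
        m = metrics_with(4.0, 0.3)
        ratios = channel_metric_ratio(m, m)
        assert ratios["elements_per_cluster"] == pytest.approx(1.0)
        assert ratios["j_over_e"] == pytest.approx(1.0)

    def test_ec_6_over_3_is_2(self):
        ratios = channel_metric_ratio(metrics_with(6.0, 0.3), metrics_with(3.0, 0.3))
        assert ratios["elements_per_cluster"] == pytest.approx(2.0)

    def test_inner_zero_gives_missing(self):
        with pytest.warns(UserWarning):
            ratios = channel_metric_ratio(metrics_with(6.0, 0.3), metrics_with(3.0, 0.0))
        assert np.isnan(ratios["j_over_e"])


class TestPhenotypeScatter:
    def _frame(self):
        return pd.DataFrame(
            {
                "cell": range(6),
                "condition": ["ctrl"] * 3 + ["treated"] * 3,
                "j_over_e": [0.30, 0.32, 0.28, 0.60, 0.62, 0.58],
                "mass_1um": [0.20, 0.22, 0.18, 0.20, 0.0, 0.21],
            }
        )

    def test_control_cloud_centred_at_unity(self):
        df, bands = cell_phenotype_scatter(self._frame(), "ctrl")
        ctrl = df[df["condition"] == "ctrl"]
        assert ctrl["connectivity_norm"].mean() == pytest.approx(1.0)
        assert ctrl["length_norm"].mean() == pytest.approx(1.0)
        assert bands["control_connectivity_sd"] > 0

    def test_doubled_je_maps_to_two(self):
        df, _ = cell_phenotype_scatter(self._frame(), "ctrl")
        treated = df[df["condition"] == "treated"]
        assert treated["connectivity_norm"].iloc[0] == pytest.approx(2.0)

    def test_zero_mass_flagged_missing(self):
        df, _ = cell_phenotype_scatter(self._frame(), "ctrl")
        assert bool(df.loc[df["mass_1um"] == 0.0, "length_missing"].iloc[0])
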