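import math

import numpy as np
import pytest

from gnome import genome
from gnome.analysis import (
    LabeledPointSet,
    chord_adjacency,
    cluster_counts,
    edge_correction_vs,
    inter_intra_ratio,
    proximity_score,
    radial_positioning,
    ripley_k,
)


def brute_force_counts(ps: LabeledPointSet, radius: float, mode: str) -> np.ndarray:
    """Independent O(n^2) oracle for the clustering definitions."""
    n = ps.n
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.linalg.norm(ps.points[i] - ps.points[j]) > radius:
                continue
            same_label = ps.labels[i] == ps.labels[j]
            same_key = ps.homolog_keys[i] == ps.homolog_keys[j]
            if mode == "total":
                counts[i] += 1
            elif mode == "intra" and same_label:
                counts[i] += 1
            elif mode == "inter" and not same_key:
                counts[i] += 1
            elif mode == "homolog" and same_key and not same_label:
                counts[i] += 1
    return counts


@pytest.fixture
def csr_labelled(sphere5):
    rng = np.random.default_rng(77)
    pts = sphere5.uniform_points(600, rng)
    labels = [f"chr{rng.integers(1, 12)}_{'AB'[rng.integers(2)]}" for _ in range(600)]
    return LabeledPointSet(pts, labels, sphere5)


class TestClusterCounts:
    def test_three_chromosomes_inter_mean(self, sphere5):
        pts = np.array([[0, 0, 0], [0.01, 0, 0], [0, 0.01, 0]])
        ps = LabeledPointSet(pts, ["chr1_A", "chr2_A", "chr3_A"], sphere5)
        assert cluster_counts(ps, 0.1, "inter").mean == 2.0

    def test_homolog_pair_excluded_from_both(self, sphere5):
        pts = np.array([[0, 0, 0], [0.01, 0, 0]])
        ps = LabeledPointSet(pts, ["chr1_A", "chr1_B"], sphere5)
        assert cluster_counts(ps, 0.1, "inter").mean == 0.0
        assert cluster_counts(ps, 0.1, "intra").mean == 0.0
        assert cluster_counts(ps, 0.1, "homolog").mean == 1.0

    def test_same_chromosome_is_intra(self, sphere5):
        pts = np.array([[0, 0, 0], [0.01, 0, 0]])
        ps = LabeledPointSet(pts, ["chr1_A", "chr1_A"], sphere5)
        assert cluster_counts(ps, 0.1, "intra").mean == 1.0
        assert cluster_counts(ps, 0.1, "inter").mean == 0.0

    def test_membership_inclusive_at_radius(self, sphere5):
        pts = np.array([[0, 0, 0], [0.5, 0, 0]])
        ps = LabeledPointSet(pts, ["chr1_A", "chr2_A"], sphere5)
        assert cluster_counts(ps, 0.5, "total").mean == 1.0

    @pytest.mark.parametrize("mode", ["total", "inter", "intra", "homolog"])
    def test_matches_brute_force_oracle(self, csr_labelled, mode):
        for radius in (0.3, 0.8, 1.5):
            got = cluster_counts(csr_labelled, radius, mode)
            expected = brute_force_counts(csr_labelled, radius, mode)
            assert np.array_equal(got.counts, expected)
            assert got.mean == pytest.approx(expected.mean())

    def test_partition_total_inter_intra_homolog(self, csr_labelled):
        total = cluster_counts(csr_labelled, 0.8, "total").counts
        parts = sum(
            cluster_counts(csr_labelled, 0.8, m).counts
            for m in ("inter", "intra", "homolog")
        )
        assert np.array_equal(total, parts)

    def test_monotone_in_radius(self, csr_labelled):
        means = [cluster_counts(csr_labelled, r, "total").mean for r in (0.2, 0.5, 1.0, 2.0)]
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_empty_point_set_rejected(self, sphere5):
        ps = LabeledPointSet(np.empty((0, 3)), [], sphere5)
        with pytest.raises(ValueError):
            cluster_counts(ps, 0.5)

    def test_csr_interchromosomal_loglog_slope_three(self, sphere5):
        # no territories: expected count ~ density * (4/3) pi r^3
        rng = np.random.default_rng(5)
        pts = sphere5.uniform_points(5000, rng)
        labels = [f"c{i % 46}" for i in range(5000)]
        ps = LabeledPointSet(pts, labels, sphere5)
        radii = [0.4, 0.6, 0.8, 1.0]
        means = [cluster_counts(ps, r, "inter").mean for r in radii]
        slope = np.polyfit(np.log(radii), np.log(means), 1)[0]
        assert slope == pytest.approx(3.0, abs=0.2)


class TestInterIntraRatio:
    def test_simple_ratio(self, sphere5):
        pts = np.array([[0, 0, 0], [0.01, 0, 0], [0.02, 0, 0], [0, 0.01, 0]])
        labels = ["chr1_A", "chr1_A", "chr1_A", "chr2_A"]
        ps = LabeledPointSet(pts, labels, sphere5)
        r = inter_intra_ratio(ps, 0.1)
        assert r.defined
        assert r.value == pytest.approx((6 / 4) / (6 / 4))

    def test_all_same_chromosome_gives_zero(self, sphere5):
        pts = np.array([[0, 0, 0], [0.01, 0, 0]])
        ps = LabeledPointSet(pts, ["chr1_A", "chr1_A"], sphere5)
        r = inter_intra_ratio(ps, 0.1)
        assert r.defined and r.value == 0.0

    def test_no_intra_flags_undefined(self, sphere5):
        pts = np.array([[0, 0, 0], [0.01, 0, 0]])
        ps = LabeledPointSet(pts, ["chr1_A", "chr2_A"], sphere5)
        r = inter_intra_ratio(ps, 0.1)
        assert not r.defined and math.isnan(r.value)


class TestEdgeCorrection:
    def test_full_containment(self, sphere5):
        assert edge_correction_vs((0, 0, 0), 1.0, sphere5) == 1.0

    def test_boundary_limit_small_radius(self, sphere5):
        # V_s -> 1/2 as CR -> 0 for a centre on the boundary
        vs = edge_correction_vs((5.0, 0, 0), 5.0 / 1e4, sphere5)
        assert vs == pytest.approx(0.5, abs=1e-3)

    def test_boundary_exact_lens_value(self, sphere5):
        # at d = R the lens fraction is 1/2 - (3/16) CR/R exactly
        cr = 0.05
        vs = edge_correction_vs((5.0, 0, 0), cr, sphere5)
        assert vs == pytest.approx(0.5 - 3 * cr / (16 * 5.0), rel=1e-12)

    def test_lens_against_monte_carlo_grid(self, sphere5):
        rng = np.random.default_rng(11)
        n = 1_000_000
        g = rng.standard_normal((n, 3))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        u = rng.random(n) ** (1 / 3)
        for d, cr in ((2.5, 5.0), (4.0, 2.0), (4.9, 0.5)):
            analytic = edge_correction_vs((d, 0, 0), cr, sphere5)
            samples = np.array([d, 0, 0]) + g * (u * cr)[:, None]
            mc = float(np.mean(sphere5.contains(samples)))
            assert analytic == pytest.approx(mc, abs=1.5e-3)

    def test_ellipsoid_monte_carlo_seeded(self):
        nuc = genome.NucleusShape.ellipsoid(1.0, 11.8, 11.8)
        rng_a = np.random.default_rng(3)
        rng_b = np.random.default_rng(3)
        a = edge_correction_vs((0.9, 0, 0), 0.5, nuc, rng=rng_a)
        b = edge_correction_vs((0.9, 0, 0), 0.5, nuc, rng=rng_b)
        assert a == b
        assert 0.0 < a < 1.0

    def test_center_outside_rejected(self, sphere5):
        with pytest.raises(ValueError):
            edge_correction_vs((5.1, 0, 0), 0.5, sphere5)


class TestRipleyK:
    def test_two_close_points_closed_form(self, sphere5):
        ps = LabeledPointSet(
            np.array([[0, 0, 0], [0.1, 0, 0]]), ["a", "b"], sphere5
        )
        r = ripley_k(ps, 0.5)
        assert r.k == pytest.approx(sphere5.volume / 2)

    def test_two_far_points_zero(self, sphere5):
        ps = LabeledPointSet(
            np.array([[0, 0, 0], [3.0, 0, 0]]), ["a", "b"], sphere5
        )
        assert ripley_k(ps, 0.5).k == 0.0

    def test_requires_two_points(self, sphere5):
        ps = LabeledPointSet(np.zeros((1, 3)), ["a"], sphere5)
        with pytest.raises(ValueError):
            ripley_k(ps, 0.5)

    def test_monotone_in_radius(self, sphere5):
        rng = np.random.default_rng(2)
        ps = LabeledPointSet(sphere5.uniform_points(400, rng), ["x"] * 400, sphere5)
        ks = [ripley_k(ps, cr).k for cr in (0.2, 0.5, 1.0, 2.0)]
        assert all(a <= b for a, b in zip(ks, ks[1:]))

    def test_uncorrected_csr_matches_analytic_expectation(self, sphere5):
        # without the 1/V_s correction the CSR expectation carries the
        # boundary deficit E[V_s] (= 0.94378 at CR=0.5, R=5), computed by
        # quadrature over the lens formula
        rng = np.random.default_rng(3)
        n = 5000
        ps = LabeledPointSet(sphere5.uniform_points(n, rng), ["x"] * n, sphere5)
        r = ripley_k(ps, 0.5, edge_correction=False)
        v_cr = 4 / 3 * math.pi * 0.5**3
        expected = v_cr * 0.9437812500561293 * (n - 1) / n
        assert r.k == pytest.approx(expected, rel=0.02)
        corrected = ripley_k(ps, 0.5, edge_correction=True)
        assert abs(corrected.normalised) < abs(r.k / v_cr - 1.0)


class TestRadialPositioning:
    def test_central_bead_at_origin(self, sphere5):
        spec = genome.BeadSpec("chr1_A", 0, 10**7, "b0")
        conf = genome.GenomeConformation(
            (spec,), np.zeros((1, 3)), np.array([0.2]), sphere5, 0.01
        )
        binned, periph = radial_positioning(conf)
        assert binned["central_fraction"].iloc[0] == 1.0
        assert periph == 0.0

    def test_half_volume_threshold(self, sphere5):
        # threshold radius is 5 * 2^(-1/3) = 3.9685; 4.5 um is peripheral
        spec = genome.BeadSpec("chr1_A", 0, 10**7, "b0")
        conf = genome.GenomeConformation(
            (spec,), np.array([[4.5, 0, 0]]), np.array([0.2]), sphere5, 0.01
        )
        _, periph = radial_positioning(conf)
        assert periph == 100.0
        conf.centers[0, 0] = 3.9
        _, periph = radial_positioning(conf)
        assert periph == 0.0

    def test_uniform_random_splits_evenly(self, sphere5):
        specs = [
            genome.BeadSpec("chr1_A", i * 10**6, (i + 1) * 10**6, f"b{i}")
            for i in range(10_000)
        ]
        conf = genome.generate_pseudo_random(specs, sphere5, seed=4)
        _, periph = radial_positioning(conf)
        assert periph == pytest.approx(50.0, abs=2.0)

    def test_bins_are_bp_weighted_by_homolog_key(self, sphere5):
        specs = (
            genome.BeadSpec("chr1_A", 0, 10**7, "a0"),
            genome.BeadSpec("chr1_B", 0, 10**7, "b0"),
        )
        conf = genome.GenomeConformation(
            specs, np.array([[0.0, 0, 0], [4.5, 0, 0]]), np.array([0.2, 0.2]),
            sphere5, 0.01,
        )
        binned, periph = radial_positioning(conf)
        assert list(binned["chrom"]) == ["chr1"]
        assert binned["central_fraction"].iloc[0] == 0.5
        assert periph == 50.0


def _one_pair_conformation(sphere5, distance_um):
    specs = (
        genome.BeadSpec("chr1_A", 0, 10**6, "a"),
        genome.BeadSpec("chr2_A", 0, 10**6, "b"),
    )
    centers = np.array([[0.0, 0, 0], [distance_um, 0, 0]])
    return genome.GenomeConformation(
        specs, centers, np.array([0.1, 0.1]), sphere5, 0.01
    )


class TestChordAdjacency:
    def test_always_proximal_included(self, sphere5):
        ensemble = [_one_pair_conformation(sphere5, 0.3) for _ in range(5)]
        assert chord_adjacency(ensemble, threshold=0.9) == {("chr1", "chr2")}

    def test_600nm_everywhere_excluded(self, sphere5):
        ensemble = [_one_pair_conformation(sphere5, 0.6) for _ in range(5)]
        assert chord_adjacency(ensemble, threshold=0.1) == set()

    def test_threshold_fraction_comparison(self, sphere5):
        # proximal in 9 of 20 geometries (45 %)
        ensemble = [_one_pair_conformation(sphere5, 0.3) for _ in range(9)]
        ensemble += [_one_pair_conformation(sphere5, 2.0) for _ in range(11)]
        assert chord_adjacency(ensemble, threshold=0.40) == {("chr1", "chr2")}
        assert chord_adjacency(ensemble, threshold=0.50) == set()

    def test_homolog_pairs_never_reported(self, sphere5):
        specs = (
            genome.BeadSpec("chr1_A", 0, 10**6, "a"),
            genome.BeadSpec("chr1_B", 0, 10**6, "b"),
        )
        conf = genome.GenomeConformation(
            specs, np.array([[0.0, 0, 0], [0.1, 0, 0]]),
            np.array([0.1, 0.1]), sphere5, 0.01,
        )
        assert chord_adjacency([conf], threshold=0.5) == set()

    def test_strictly_less_than_500nm(self, sphere5):
        ensemble = [_one_pair_conformation(sphere5, 0.5)]
        assert chord_adjacency(ensemble, threshold=0.5) == set()


class TestProximityScore:
    def test_touching_pair_score_one(self, sphere5):
        specs = (
            genome.BeadSpec("chr1_A", 0, 10**6, "a", edges=frozenset({"b"})),
            genome.BeadSpec("chr2_A", 0, 10**6, "b", edges=frozenset({"a"})),
        )
        conf = genome.GenomeConformation(
            specs, np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            np.array([0.5, 0.5]), sphere5, 0.01,
        )
        score = proximity_score(conf)
        assert score.defined and score.value == pytest.approx(1.0)

    def test_coincident_pairs_zero(self, sphere5):
        specs = (
            genome.BeadSpec("chr1_A", 0, 10**6, "a", edges=frozenset({"b"})),
            genome.BeadSpec("chr2_A", 0, 10**6, "b", edges=frozenset({"a"})),
        )
        conf = genome.GenomeConformation(
            specs, np.zeros((2, 3)), np.array([0.5, 0.5]), sphere5, 0.01
        )
        assert proximity_score(conf).value == 0.0

    def test_no_constraints_flagged_undefined(self, sphere5):
        specs = (genome.BeadSpec("chr1_A", 0, 10**6, "a"),)
        conf = genome.GenomeConformation(
            specs, np.zeros((1, 3)), np.array([0.5]), sphere5, 0.01
        )
        score = proximity_score(conf)
        assert not score.defined

    def test_random_worse_than_solved(self, small_specs, sphere5):
        from gnome.solver import SolverConfig, solve

        random_conf = genome.generate_pseudo_random(small_specs, sphere5, seed=31)
        solved, _ = solve(
            random_conf, None,
            SolverConfig(n_successful_moves=3000, scheme="greedy", seed=32),
        )
        assert proximity_score(solved).value < proximity_score(random_conf).value
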