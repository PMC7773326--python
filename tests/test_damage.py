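import math

import numpy as np
import pytest

from gnome import genome
from gnome.damage import (
    DamageParams,
    Deposits,
    EnergyDeposit,
    StrandBreak,
    classify_deposits,
    cluster_breaks,
    damage_yields,
    energy_probability,
    photon_exposure,
    read_deposits_tsv,
    read_sdd,
    sites_to_records,
    write_deposits_tsv,
    write_sdd,
)


@pytest.fixture
def one_bead_conformation(sphere5):
    spec = genome.BeadSpec("chr1_A", 0, 2_000_000, "b0")
    return genome.GenomeConformation(
        (spec,), np.zeros((1, 3)), np.array([1.0]), sphere5, 0.01, seed=0
    )


def uniform_deposits_in_bead(conf, n, energy, rng, bead=0):
    g = rng.standard_normal((n, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    u = rng.random(n) ** (1 / 3)
    pts = conf.centers[bead] + g * (u * conf.radii[bead])[:, None]
    return Deposits(pts, np.full(n, float(energy)), np.zeros(n, dtype=np.int64))


def far_apart_break(chrom, strand, bp, x_nm):
    """Break whose 3D position encodes a distinct location (x in nm)."""
    return StrandBreak(chrom, strand, bp, (x_nm * 1e-3, 0.0, 0.0))


class TestEnergyProbability:
    def test_ramp_endpoints_and_midpoint(self):
        assert energy_probability(5.0) == 0.0
        assert energy_probability(37.5) == 1.0
        assert energy_probability(21.25) == pytest.approx(0.5)

    def test_clamped_outside_ramp(self):
        assert energy_probability(1.0) == 0.0
        assert energy_probability(100.0) == 1.0

    def test_vectorised(self):
        p = energy_probability(np.array([5.0, 21.25, 37.5]))
        assert np.allclose(p, [0.0, 0.5, 1.0])


class TestClassifyDeposits:
    def test_outside_bead_discarded(self, one_bead_conformation, rng):
        dep = Deposits(np.array([[3.0, 0, 0]]), np.array([100.0]), np.array([0]))
        assert classify_deposits(dep, one_bead_conformation, rng=rng) == []

    def test_below_ramp_never_breaks(self, one_bead_conformation, rng):
        dep = uniform_deposits_in_bead(one_bead_conformation, 5000, 4.0, rng)
        assert classify_deposits(dep, one_bead_conformation, rng=rng) == []

    def test_sensitive_fraction_at_high_energy(self, one_bead_conformation, rng):
        dep = uniform_deposits_in_bead(one_bead_conformation, 100_000, 100.0, rng)
        breaks = classify_deposits(dep, one_bead_conformation, rng=rng)
        assert len(breaks) / 100_000 == pytest.approx(0.141, abs=0.004)

    def test_break_fields_within_bead(self, one_bead_conformation, rng):
        dep = uniform_deposits_in_bead(one_bead_conformation, 2000, 100.0, rng)
        breaks = classify_deposits(dep, one_bead_conformation, rng=rng)
        spec = one_bead_conformation.specs[0]
        for b in breaks[:50]:
            assert spec.start <= b.bp < spec.end
            assert b.strand in (1, 2)
            assert b.chrom == "chr1_A"

    def test_strands_balanced(self, one_bead_conformation, rng):
        dep = uniform_deposits_in_bead(one_bead_conformation, 50_000, 100.0, rng)
        breaks = classify_deposits(dep, one_bead_conformation, rng=rng)
        frac1 = np.mean([b.strand == 1 for b in breaks])
        assert frac1 == pytest.approx(0.5, abs=0.02)

    def test_deterministic_given_seed(self, one_bead_conformation):
        dep = uniform_deposits_in_bead(
            one_bead_conformation, 1000, 100.0, np.random.default_rng(1)
        )
        a = classify_deposits(dep, one_bead_conformation, rng=np.random.default_rng(2))
        b = classify_deposits(dep, one_bead_conformation, rng=np.random.default_rng(2))
        assert a == b

    def test_record_input_accepted(self, one_bead_conformation, rng):
        records = [EnergyDeposit((0.0, 0.0, 0.0), 100.0)] * 100
        breaks = classify_deposits(records, one_bead_conformation, rng=rng)
        assert 0 < len(breaks) < 100

    def test_non_positive_energy_rejected(self):
        with pytest.raises(ValueError):
            Deposits(np.zeros((1, 3)), np.array([0.0]), np.array([0]))


class TestClusterBreaks:
    def test_opposite_strands_within_window_form_dsb(self):
        breaks = [far_apart_break("chr1_A", 1, 100, 0),
                  far_apart_break("chr1_A", 2, 108, 50)]
        sites = cluster_breaks(breaks)
        assert [s.kind for s in sites] == ["DSB"]
        assert sites[0].complexity == 2

    def test_just_outside_window_two_ssbs(self):
        breaks = [far_apart_break("chr1_A", 1, 100, 0),
                  far_apart_break("chr1_A", 2, 111, 50)]
        sites = cluster_breaks(breaks)
        assert sorted(s.kind for s in sites) == ["SSB", "SSB"]

    def test_chain_rule_complexity_three(self):
        breaks = [
            far_apart_break("chr1_A", 1, 100, 0),
            far_apart_break("chr1_A", 2, 105, 50),
            far_apart_break("chr1_A", 1, 109, 100),
        ]
        sites = cluster_breaks(breaks)
        assert [s.kind for s in sites] == ["DSB"]
        assert sites[0].complexity == 3

    @pytest.mark.parametrize("k,expect_dsb", [(k, k <= 10) for k in range(1, 16)])
    def test_bp_window_sweep(self, k, expect_dsb):
        breaks = [far_apart_break("chr1_A", 1, 100, 0),
                  far_apart_break("chr1_A", 2, 100 + k, 50)]
        sites = cluster_breaks(breaks)
        dsb = [s for s in sites if s.kind == "DSB"]
        assert bool(dsb) == expect_dsb

    def test_spatial_window_links_distant_bp(self):
        # 3D separation 2 nm merges opposite-strand breaks that are
        # genomically far apart within one bead
        breaks = [
            StrandBreak("chr1_A", 1, 1000, (0.0, 0.0, 0.0)),
            StrandBreak("chr1_A", 2, 900_000, (0.002, 0.0, 0.0)),
        ]
        sites = cluster_breaks(breaks)
        assert [s.kind for s in sites] == ["DSB"]

    def test_same_strand_only_all_ssb(self):
        breaks = [far_apart_break("chr1_A", 1, 100, 0),
                  far_apart_break("chr1_A", 1, 105, 50)]
        sites = cluster_breaks(breaks)
        assert sorted(s.kind for s in sites) == ["SSB", "SSB"]

    def test_different_chromosomes_never_merge(self):
        breaks = [far_apart_break("chr1_A", 1, 100, 0),
                  far_apart_break("chr1_B", 2, 105, 0)]
        sites = cluster_breaks(breaks)
        assert sorted(s.kind for s in sites) == ["SSB", "SSB"]

    def test_duplicates_merged(self):
        b = far_apart_break("chr1_A", 1, 100, 0)
        sites = cluster_breaks([b, b, b])
        assert len(sites) == 1 and sites[0].kind == "SSB"

    def test_partition_and_order_invariance(self, rng):
        breaks = []
        for i in range(300):
            breaks.append(
                StrandBreak(
                    f"chr{rng.integers(1, 4)}_A",
                    int(rng.integers(1, 3)),
                    int(rng.integers(0, 5000)),
                    tuple(rng.uniform(-1, 1, 3)),
                )
            )
        # dedupe as the clusterer will, to compare totals
        unique = {(b.chrom, b.bp, b.strand) for b in breaks}
        sites = cluster_breaks(breaks)
        assert sum(len(s.breaks) for s in sites) == len(unique)
        shuffled = list(breaks)
        rng.shuffle(shuffled)  # type: ignore[arg-type]
        sites2 = cluster_breaks(shuffled)
        assert len(sites2) == len(sites)
        assert sorted(s.centroid for s in sites2) == sorted(s.centroid for s in sites)

    def test_dsb_centroid_is_mean_position(self):
        breaks = [
            StrandBreak("chr1_A", 1, 100, (0.0, 0.0, 0.0)),
            StrandBreak("chr1_A", 2, 105, (0.002, 0.0, 0.0)),
        ]
        sites = cluster_breaks(breaks)
        assert sites[0].centroid == pytest.approx((0.001, 0.0, 0.0))


class TestPhotonExposure:
    def test_zero_dose(self, one_bead_conformation, rng):
        assert photon_exposure(one_bead_conformation, 0.0, rng=rng) == []

    def test_mean_25_per_gy(self, one_bead_conformation):
        rng = np.random.default_rng(8)
        counts = [
            len(photon_exposure(one_bead_conformation, 1.0, rng=rng))
            for _ in range(200)
        ]
        assert np.mean(counts) == pytest.approx(25.0, abs=1.0)

    def test_poisson_dispersion(self, one_bead_conformation):
        rng = np.random.default_rng(9)
        counts = np.array(
            [len(photon_exposure(one_bead_conformation, 1.0, rng=rng)) for _ in range(1000)]
        )
        assert 0.9 < counts.var(ddof=1) / counts.mean() < 1.1

    def test_chromosome_share_weighted_by_bp(self, sphere5):
        # chr1_A holds 10 % of the genome
        specs = (
            genome.BeadSpec("chr1_A", 0, 100, "a"),
            genome.BeadSpec("chr2_A", 0, 900, "b"),
        )
        conf = genome.GenomeConformation(
            specs, np.array([[0.0, 0, 0], [2.0, 0, 0]]),
            np.array([0.3, 0.62]), sphere5, 0.01,
        )
        rng = np.random.default_rng(10)
        sites = photon_exposure(conf, 400.0, rng=rng)  # ~10,000 DSBs
        share = np.mean([s.chrom == "chr1_A" for s in sites])
        assert share == pytest.approx(0.1, abs=0.01)

    def test_sites_are_complexity_two_dsbs_inside_bead(self, one_bead_conformation, rng):
        sites = photon_exposure(one_bead_conformation, 2.0, rng=rng)
        for s in sites:
            assert s.kind == "DSB" and s.complexity == 2
            assert {b.strand for b in s.breaks} == {1, 2}
            assert np.linalg.norm(np.array(s.centroid)) <= 1.0 + 1e-9

    def test_negative_dose_rejected(self, one_bead_conformation, rng):
        with pytest.raises(ValueError):
            photon_exposure(one_bead_conformation, -1.0, rng=rng)

    def test_yields_independent_of_nucleus_shape(self, tiny_specs):
        # photon placement is bead-weighted, not geometric
        sphere = genome.NucleusShape.sphere(5.0)
        ellipsoid = genome.NucleusShape.ellipsoid(1.0, 11.8, 11.8)
        counts = {}
        for nuc in (sphere, ellipsoid):
            conf = genome.build_initial_conformation(tiny_specs, nuc, seed=2)
            rng = np.random.default_rng(77)
            counts[nuc.kind] = [
                len(photon_exposure(conf, 1.0, rng=rng)) for _ in range(200)
            ]
        assert np.mean(counts["sphere"]) == np.mean(counts["ellipsoid"])


class TestYields:
    def test_arithmetic(self, one_bead_conformation):
        rng = np.random.default_rng(0)
        sites = photon_exposure(one_bead_conformation, 2.0, rng=rng)
        y = damage_yields(sites, 2.0)
        assert y.dsb_per_gy == len(sites) / 2.0
        assert y.backbones_per_dsb == 2.0

    def test_no_dsb_flagged_nan(self):
        breaks = [far_apart_break("chr1_A", 1, 100, 0)]
        y = damage_yields(cluster_breaks(breaks), 1.0)
        assert y.ssb_per_gy == 1.0 and math.isnan(y.backbones_per_dsb)

    def test_three_break_site_backbones(self):
        breaks = [
            far_apart_break("chr1_A", 1, 100, 0),
            far_apart_break("chr1_A", 2, 105, 50),
            far_apart_break("chr1_A", 1, 109, 100),
        ]
        y = damage_yields(cluster_breaks(breaks), 1.0)
        assert y.backbones_per_dsb == 3.0

    def test_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            damage_yields([], 0.0)


class TestSddIO:
    def test_round_trip(self, one_bead_conformation, tmp_path):
        rng = np.random.default_rng(4)
        sites = photon_exposure(one_bead_conformation, 4.0, rng=rng)
        path = tmp_path / "d.sdd"
        write_sdd(sites, {"Dose or fluence": "1, 4.0"}, path)
        records, header = read_sdd(path)
        assert header["SDD version"] == "1.0"
        assert header["Dose or fluence"] == "1, 4.0"
        assert records == sites_to_records(sites)

    def test_empty_site_list_header_only(self, tmp_path):
        path = tmp_path / "d.sdd"
        write_sdd([], {}, path)
        records, header = read_sdd(path)
        assert records == [] and "SDD version" in header

    def test_dsb_record_backbone_count(self, tmp_path):
        breaks = [
            far_apart_break("chr1_A", 1, 100, 0),
            far_apart_break("chr1_A", 2, 105, 50),
            far_apart_break("chr1_A", 1, 109, 100),
        ]
        sites = cluster_breaks(breaks)
        path = tmp_path / "d.sdd"
        write_sdd(sites, {}, path)
        records, _ = read_sdd(path)
        assert records[0].kind == "DSB" and records[0].backbones == 3

    def test_deposits_tsv_round_trip(self, tmp_path, rng):
        dep = Deposits(rng.uniform(-5, 5, (50, 3)), rng.exponential(60, 50),
                       rng.integers(0, 5, 50))
        path = tmp_path / "dep.tsv"
        write_deposits_tsv(dep, path)
        back = read_deposits_tsv(path)
        assert np.array_equal(back.positions, dep.positions)
        assert np.array_equal(back.energies, dep.energies)
        assert np.array_equal(back.track_ids, dep.track_ids)
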