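"""Parameterised straight-track energy-deposition generator.

This is an amorphous-track surrogate for detailed track-structure
transport: each primary is a straight chord through the nucleus whose
only physical contract is an LET-correct energy budget and spatially
concentrated deposition.  Deposit count along a chord is Poisson with
mean LET * chord / mean-deposit-energy, deposit energies are
exponential, and positions get a small Gaussian lateral jitter, so the
expected energy deposited per track is LET * chord.

Absorbed dose bookkeeping uses the nucleus as liquid water at
1.0 g/cm^3 and the Cauchy mean chord 4V/S.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .damage import (
    DamageParams,
    DamageSite,
    Deposits,
    classify_deposits,
    cluster_breaks,
)
from .genome import GenomeConformation, NucleusShape

__all__ = [
    "TrackConfig",
    "ExposurePlan",
    "J_PER_KEV",
    "nucleus_mass_kg",
    "tracks_for_dose",
    "generate_track_deposits",
    "realized_dose_gy",
    "ion_exposure",
]

J_PER_KEV = 1.602e-16
WATER_DENSITY_KG_M3 = 1000.0


@dataclass(frozen=True)
class TrackConfig:
    """Track parameters.

    ``let`` is the track-averaged LET in keV/um; ``mean_deposit_ev`` the
    mean energy of a single deposition event; ``lateral_sigma_nm`` the
    radial spread of ionization-cluster centres around the track axis.
    Deposits arrive in nm-scale ionization clusters (mean
    ``cluster_mean_size`` deposits within ``cluster_sigma_nm``), the
    mechanism that concentrates damage at high LET; ``cluster_mean_size
    = 1`` recovers independent single deposits.  The expected energy
    deposited per track is LET * chord regardless of clustering.
    """

    let: float
    mean_deposit_ev: float = 60.0
    lateral_sigma_nm: float = 5.0
    cluster_mean_size: float | None = None  # default: LET-scaled
    cluster_size_per_let: float = 0.05  # mean extra deposits per keV/um
    cluster_sigma_nm: float = 1.5
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    isotropic: bool = False

    def __post_init__(self) -> None:
        if self.let <= 0:
            raise ValueError("LET must be positive")
        if self.mean_deposit_ev <= 0:
            raise ValueError("mean deposit energy must be positive")
        if self.cluster_mean_size is not None and self.cluster_mean_size < 1:
            raise ValueError("cluster_mean_size must be >= 1")

    @property
    def effective_cluster_size(self) -> float:
        """Mean ionization-cluster multiplicity.

        Unless fixed explicitly, grows linearly with LET (denser local
        ionization at higher stopping power), the nanodosimetric driver
        of clustered DNA damage.
        """
        if self.cluster_mean_size is not None:
            return self.cluster_mean_size
        return 1.0 + self.cluster_size_per_let * self.let


@dataclass(frozen=True)
class ExposurePlan:
    dose_gy: float
    n_tracks: int
    mass_kg: float

    def __post_init__(self) -> None:
        if self.n_tracks < 0:
            raise ValueError("n_tracks must be >= 0")


def nucleus_mass_kg(nucleus: NucleusShape) -> float:
    """Nucleus mass assuming liquid water; volume um^3 -> m^3."""
    return WATER_DENSITY_KG_M3 * nucleus.volume * 1e-18


def tracks_for_dose(nucleus: NucleusShape, let: float, dose_gy: float) -> int:
    """Number of tracks delivering ``dose_gy`` at the given LET.

    n = round(dose * mass / (LET * <chord> * 1.602e-16 J/keV)) with
    <chord> = 4V/S, so the expected energy of n tracks matches the
    requested dose.
    """
    if let <= 0:
        raise ValueError("LET must be positive")
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    energy_j = dose_gy * nucleus_mass_kg(nucleus)
    per_track_j = let * nucleus.mean_chord_length * J_PER_KEV
    return int(round(energy_j / per_track_j))


def plan_exposure(nucleus: NucleusShape, let: float, dose_gy: float) -> ExposurePlan:
    return ExposurePlan(dose_gy, tracks_for_dose(nucleus, let, dose_gy), nucleus_mass_kg(nucleus))


def _orthonormal_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def generate_track_deposits(
    nucleus: NucleusShape,
    config: TrackConfig,
    n_tracks: int,
    rng: np.random.Generator | None = None,
) -> Deposits:
    """Generate straight-track deposits through the nucleus.

    Entry points are uniform over the nucleus's projected disc along the
    beam direction (isotropic mode redraws the direction per track);
    deposits are uniform along each chord with Gaussian lateral jitter
    and exponential energies.
    """
    rng = rng or np.random.default_rng(0)
    if n_tracks == 0:
        return Deposits.empty()
    axes = np.asarray(nucleus.semi_axes)
    sigma_um = config.lateral_sigma_nm * 1e-3
    parts: list[Deposits] = []
    base_dir = np.asarray(config.direction, dtype=float)
    for t in range(n_tracks):
        direction = _random_unit(rng) if config.isotropic else base_dir
        # map to the unit sphere: p' = p / axes, lines stay lines
        d_scaled = direction / axes
        d_scaled /= np.linalg.norm(d_scaled)
        e1, e2 = _orthonormal_basis(d_scaled)
        # impact point uniform over the projected unit disc
        while True:
            q1, q2 = rng.uniform(-1.0, 1.0, 2)
            if q1 * q1 + q2 * q2 <= 1.0:
                break
        q = q1 * e1 + q2 * e2
        half = math.sqrt(max(0.0, 1.0 - q1 * q1 - q2 * q2))
        p_in = (q - half * d_scaled) * axes
        p_out = (q + half * d_scaled) * axes
        chord = float(np.linalg.norm(p_out - p_in))
        mean_deposits = config.let * chord * 1000.0 / config.mean_deposit_ev
        m_cluster = config.effective_cluster_size
        n_clusters = int(rng.poisson(mean_deposits / m_cluster))
        if n_clusters == 0:
            continue
        # cluster sizes: 1 + Poisson keeps the mean at m_cluster
        sizes = 1 + rng.poisson(m_cluster - 1.0, n_clusters)
        m = int(sizes.sum())
        u = rng.random(n_clusters)
        cluster_pts = p_in[None, :] + u[:, None] * (p_out - p_in)[None, :]
        dir_real = (p_out - p_in) / chord
        f1, f2 = _orthonormal_basis(dir_real)
        lat = rng.standard_normal((n_clusters, 2)) * sigma_um
        cluster_pts = cluster_pts + lat[:, :1] * f1[None, :] + lat[:, 1:] * f2[None, :]
        pts = np.repeat(cluster_pts, sizes, axis=0)
        pts = pts + rng.standard_normal((m, 3)) * (config.cluster_sigma_nm * 1e-3)
        energies = rng.exponential(config.mean_deposit_ev, m)
        parts.append(Deposits(pts, energies, np.full(m, t, dtype=np.int64)))
    return Deposits.concatenate(parts)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def realized_dose_gy(deposits: Deposits, nucleus: NucleusShape) -> float:
    """Absorbed dose implied by the generated deposits (energy / mass)."""
    energy_j = float(np.sum(deposits.energies)) * J_PER_KEV / 1000.0
    return energy_j / nucleus_mass_kg(nucleus)


def ion_exposure(
    conformation: GenomeConformation,
    config: TrackConfig,
    dose_gy: float,
    params: DamageParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[DamageSite], Deposits]:
    """One ion exposure: tracks -> deposits -> breaks -> damage sites."""
    rng = rng or np.random.default_rng(0)
    n = tracks_for_dose(conformation.nucleus, config.let, dose_gy)
    deposits = generate_track_deposits(conformation.nucleus, config, n, rng)
    breaks = classify_deposits(deposits, conformation, params, rng)
    return cluster_breaks(breaks, params), deposits
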