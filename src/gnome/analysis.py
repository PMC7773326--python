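"""Spatial statistics over bead conformations and damage point sets.

The metrics operate on labelled 3D point sets where a point is either a
polymer bead centre or a DSB centroid.  Chromosome labels carry a
homolog suffix (``_A``/``_B``); pairs of points on homologous copies of
the same chromosome are excluded from *both* inter- and
intra-chromosomal counts and reported separately so that
total = inter + intra + homolog is auditable.

Distances are centre-to-centre.  Cluster membership uses <= radius;
chord-plot proximity uses < 500 nm.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .genome import GenomeConformation, NucleusShape, homolog_key

__all__ = [
    "LabeledPointSet",
    "ClusterSummary",
    "RipleyResult",
    "Ratio",
    "cluster_counts",
    "inter_intra_ratio",
    "edge_correction_vs",
    "ripley_k",
    "radial_positioning",
    "chord_adjacency",
    "proximity_score",
]


@dataclass
class LabeledPointSet:
    """3D points (um) with a chromosome label per point."""

    points: np.ndarray
    labels: list[str]
    nucleus: NucleusShape

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) != len(self.labels):
            raise ValueError("points and labels must have equal length")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def homolog_keys(self) -> list[str]:
        return [homolog_key(lab) for lab in self.labels]

    @classmethod
    def from_conformation(cls, conf: GenomeConformation) -> "LabeledPointSet":
        return cls(conf.centers.copy(), conf.chrom_labels, conf.nucleus)

    @classmethod
    def from_sites(cls, sites: Sequence, nucleus: NucleusShape) -> "LabeledPointSet":
        pts = np.array([s.centroid for s in sites], dtype=float).reshape(-1, 3)
        return cls(pts, [s.chrom for s in sites], nucleus)


@dataclass(frozen=True)
class ClusterSummary:
    radius_um: float
    mode: str
    counts: np.ndarray  # per-object neighbour count under the mode filter
    mean: float


_MODES = ("total", "inter", "intra", "homolog")


def cluster_counts(
    pointset: LabeledPointSet, radius: float, mode: str = "total"
) -> ClusterSummary:
    """Mean number of objects within ``radius`` (um) of each object.

    inter: different chromosome, homologs excluded; intra: same
    chromosome label; homolog: same chromosome identity, different copy;
    total: all other objects.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    if pointset.n == 0:
        raise ValueError("empty point set")
    labels = np.asarray(pointset.labels)
    hkeys = np.asarray(pointset.homolog_keys)
    counts = np.zeros(pointset.n, dtype=np.int64)
    tree = cKDTree(pointset.points)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        same_label = labels[i] == labels[j]
        same_key = hkeys[i] == hkeys[j]
        if mode == "total":
            keep = np.ones(len(pairs), dtype=bool)
        elif mode == "intra":
            keep = same_label
        elif mode == "homolog":
            keep = same_key & ~same_label
        else:  # inter
            keep = ~same_key
        np.add.at(counts, i[keep], 1)
        np.add.at(counts, j[keep], 1)
    return ClusterSummary(radius, mode, counts, float(counts.mean()))


@dataclass(frozen=True)
class Ratio:
    value: float
    defined: bool


def inter_intra_ratio(pointset: LabeledPointSet, radius: float) -> Ratio:
    """Ratio of mean inter- to mean intra-chromosomal clustering.

    Flagged undefined (not an exception) when the intra mean is zero.
    """
    inter = cluster_counts(pointset, radius, "inter").mean
    intra = cluster_counts(pointset, radius, "intra").mean
    if intra == 0.0:
        return Ratio(math.nan, False)
    return Ratio(inter / intra, True)


def _sphere_vs_fraction(d: np.ndarray, cr: float, R: float) -> np.ndarray:
    """Fraction of a radius-``cr`` sphere centred at distance ``d`` from
    the origin that lies inside the radius-``R`` nucleus (lens formula)."""
    d = np.asarray(d, dtype=float)
    frac = np.empty_like(d)
    v_cr = 4.0 / 3.0 * math.pi * cr**3
    inside = d + cr <= R
    frac[inside] = 1.0
    engulfed = (cr - d) >= R  # nucleus entirely inside the cluster sphere
    frac[engulfed] = (4.0 / 3.0 * math.pi * R**3) / v_cr
    partial = ~inside & ~engulfed
    dd = d[partial]
    lens = (
        math.pi
        * (R + cr - dd) ** 2
        * (dd**2 + 2 * dd * cr - 3 * cr**2 + 2 * dd * R + 6 * cr * R - 3 * R**2)
        / (12 * dd)
    )
    frac[partial] = lens / v_cr
    return frac


def edge_correction_vs(
    center: np.ndarray,
    cr: float,
    nucleus: NucleusShape,
    rng: np.random.Generator | None = None,
    n_samples: int = 10_000,
) -> float:
    """V_s: fraction of the cluster-radius sphere inside the nucleus.

    Sphere nuclei use the analytic sphere-sphere lens volume; ellipsoids
    use seeded Monte-Carlo sampling of the cluster sphere.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    if nucleus.scaled_radius(center[None, :])[0] > 1.0 + 1e-12:
        raise ValueError("center lies outside the nucleus")
    if cr <= 0:
        raise ValueError("cluster radius must be positive")
    if nucleus.kind == "sphere":
        R = nucleus.semi_axes[0]
        return float(_sphere_vs_fraction(np.array([np.linalg.norm(center)]), cr, R)[0])
    rng = rng or np.random.default_rng(0)
    g = rng.standard_normal((n_samples, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    u = rng.random(n_samples) ** (1.0 / 3.0)
    samples = center + g * (u * cr)[:, None]
    return float(np.mean(nucleus.contains(samples)))


@dataclass(frozen=True)
class RipleyResult:
    cr: float  # cluster radius, um
    k: float  # Ripley-K, um^3
    normalised: float  # K / ((4/3) pi CR^3) - 1; 0 under CSR
    n: int
    v_nuc: float


def ripley_k(
    pointset: LabeledPointSet,
    cr: float,
    edge_correction: bool = True,
    rng: np.random.Generator | None = None,
) -> RipleyResult:
    """Edge-corrected 3D Ripley-K.

    K(CR) = V_nuc / n^2 * sum_i sum_{j != i} I[D(i,j) <= CR] / V_s(i),
    with V_s the fraction of the CR-sphere around point i that lies
    inside the nucleus.  The normalised statistic
    K / ((4/3) pi CR^3) - 1 has expectation ~0 (exactly -1/n) under
    complete spatial randomness.
    """
    n = pointset.n
    if n < 2:
        raise ValueError("Ripley-K requires at least two points")
    if cr <= 0:
        raise ValueError("cluster radius must be positive")
    nuc = pointset.nucleus
    tree = cKDTree(pointset.points)
    pairs = tree.query_pairs(r=cr, output_type="ndarray")
    if edge_correction:
        if nuc.kind == "sphere":
            vs = _sphere_vs_fraction(
                np.linalg.norm(pointset.points, axis=1), cr, nuc.semi_axes[0]
            )
        else:
            rng = rng or np.random.default_rng(0)
            vs = np.array(
                [edge_correction_vs(p, cr, nuc, rng=rng) for p in pointset.points]
            )
    else:
        vs = np.ones(n)
    weights = 1.0 / vs
    total = 0.0
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        total = float(np.sum(weights[i]) + np.sum(weights[j]))
    k = nuc.volume * total / n**2
    v_cr = 4.0 / 3.0 * math.pi * cr**3
    return RipleyResult(cr=cr, k=k, normalised=k / v_cr - 1.0, n=n, v_nuc=nuc.volume)


HALF_VOLUME_SCALE = 2.0 ** (-1.0 / 3.0)


def radial_positioning(
    conformation: GenomeConformation, bin_bp: int = 10_000_000
):
    """Central/peripheral bead positioning per 10 Mbp genomic bin.

    A bead is central iff its centre lies within the inner region
    holding half the nuclear volume (an axis-preserving scaled copy of
    the nucleus, factor 2^(-1/3)).  Fractions are bead-bp-weighted and
    binned per chromosome identity (homolog copies pooled).  Returns
    (DataFrame, overall periphery percentage of DNA content).
    """
    import pandas as pd

    t = conformation.nucleus.scaled_radius(conformation.centers)
    central = t <= HALF_VOLUME_SCALE
    bp = conformation.bp.astype(float)
    rows = []
    for i, spec in enumerate(conformation.specs):
        mid = (spec.start + spec.end) // 2
        rows.append(
            (
                homolog_key(spec.chrom),
                int(mid // bin_bp) * bin_bp,
                bp[i],
                bp[i] if central[i] else 0.0,
            )
        )
    df = pd.DataFrame(rows, columns=["chrom", "bin_start", "bp", "central_bp"])
    binned = df.groupby(["chrom", "bin_start"], as_index=False).sum()
    binned["central_fraction"] = binned["central_bp"] / binned["bp"]
    binned["peripheral_fraction"] = 1.0 - binned["central_fraction"]
    binned = binned.drop(columns="central_bp")
    periphery_percent = 100.0 * float(np.sum(bp[~central]) / np.sum(bp))
    return binned, periphery_percent


def chord_adjacency(
    ensemble: Iterable[GenomeConformation],
    distance_um: float = 0.5,
    threshold: float = 0.4,
) -> set[tuple[str, str]]:
    """Chromosome pairs with consistently proximal interchromosomal beads.

    A pair of chromosome identities (homolog copies pooled, homolog
    pairs excluded) is included iff the fraction of geometries in which
    at least one bead of one lies strictly within ``distance_um`` of a
    bead of the other reaches ``threshold``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    counts: dict[tuple[str, str], int] = {}
    n_geom = 0
    for conf in ensemble:
        n_geom += 1
        hkeys = np.asarray([homolog_key(c) for c in conf.chrom_labels])
        tree = cKDTree(conf.centers)
        pairs = tree.query_pairs(r=distance_um * (1 - 1e-12), output_type="ndarray")
        found: set[tuple[str, str]] = set()
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            diff = hkeys[i] != hkeys[j]
            for a, b in zip(hkeys[i][diff], hkeys[j][diff]):
                found.add((a, b) if a < b else (b, a))
        for key in found:
            counts[key] = counts.get(key, 0) + 1
    if n_geom == 0:
        raise ValueError("ensemble is empty")
    return {pair for pair, c in counts.items() if c / n_geom >= threshold}


def proximity_score(
    conformation: GenomeConformation,
    constraints: np.ndarray | Sequence[tuple[str, str]] | None = None,
) -> Ratio:
    """Mean euclidean distance between contact-constrained bead pairs.

    Per bead with at least one constraint, the mean centre-to-centre
    distance to all its partners is computed; the score is the average
    over such beads.  Lower is better-optimised; nuclear and lamina
    constraints are ignored.  Flagged undefined with no constraints.
    """
    if constraints is None:
        pairs = conformation.constraint_index_pairs()
    else:
        arr = np.asarray(constraints)
        if arr.dtype.kind in "iu" and arr.ndim == 2:
            pairs = arr.astype(np.intp)
        else:
            pairs = conformation.constraint_index_pairs(list(constraints))  # type: ignore[arg-type]
    if len(pairs) == 0:
        return Ratio(math.nan, False)
    d = np.linalg.norm(
        conformation.centers[pairs[:, 0]] - conformation.centers[pairs[:, 1]], axis=1
    )
    n = conformation.n_beads
    dist_sum = np.zeros(n)
    deg = np.zeros(n)
    np.add.at(dist_sum, pairs[:, 0], d)
    np.add.at(dist_sum, pairs[:, 1], d)
    np.add.at(deg, pairs[:, 0], 1)
    np.add.at(deg, pairs[:, 1], 1)
    has = deg > 0
    return Ratio(float(np.mean(dist_sum[has] / deg[has])), True)
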