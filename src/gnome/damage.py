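"""Radiation-induced DNA damage: deposits -> strand breaks -> DSB/SSB sites.

Energy depositions landing inside beads are converted to backbone
strand breaks by two stochastic filters: a sensitive-fraction draw
(default 14.1 %, the fraction of bead volume occupied by damageable
backbone) and a linear energy ramp (probability 0 at 5 eV rising to 1
at 37.5 eV).  Accepted breaks receive a random strand (1 or 2, equal
probability) and a base-pair position uniform in the bead's genomic
interval.

Breaks on one chromosome are clustered into damage sites: breaks link
when separated by at most 10 bp genomically or 3.2 nm spatially (the
two criteria the damage model treats as equivalent), and a linked
cluster containing both strands is a double-strand break (DSB) whose
complexity is its backbone count.  Breaks that do not form a DSB are
single-strand breaks (SSBs).

Photon exposures bypass track structure: DSBs are drawn directly,
Poisson with mean 25 DSB/Gy, placed on chromosomes with probability
proportional to base-pair content.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

try:  # optional acceleration of deposit-in-bead lookup
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

from .genome import GenomeConformation

__all__ = [
    "DamageParams",
    "EnergyDeposit",
    "Deposits",
    "StrandBreak",
    "DamageSite",
    "Yields",
    "SddRecord",
    "energy_probability",
    "classify_deposits",
    "cluster_breaks",
    "photon_exposure",
    "damage_yields",
    "write_sdd",
    "read_sdd",
    "read_deposits_tsv",
    "write_deposits_tsv",
]

BP_PER_NM = 10.0 / 3.2  # 10 bp corresponds to 3.2 nm of double helix


@dataclass(frozen=True)
class DamageParams:
    """Deposit-to-damage conversion parameters.

    sensitive_fraction: probability that an in-bead deposit hits the
    damageable backbone volume.  e_zero/e_one: energies (eV) where the
    break probability ramp leaves 0 and reaches 1.  dsb_bp_window /
    dsb_nm_window: genomic and spatial break-linking criteria.
    photon_dsb_per_gy: mean DSB yield of the photon model.
    """

    sensitive_fraction: float = 0.141
    e_zero: float = 5.0
    e_one: float = 37.5
    dsb_bp_window: int = 10
    dsb_nm_window: float = 3.2
    photon_dsb_per_gy: float = 25.0

    def __post_init__(self) -> None:
        if not 0 < self.sensitive_fraction < 1:
            raise ValueError("sensitive_fraction must lie in (0, 1)")
        if self.e_one <= self.e_zero:
            raise ValueError("e_one must exceed e_zero")
        if self.dsb_bp_window <= 0 or self.dsb_nm_window <= 0:
            raise ValueError("DSB windows must be positive")


@dataclass(frozen=True)
class EnergyDeposit:
    position: tuple[float, float, float]  # um
    energy: float  # eV
    track_id: int = 0

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValueError("deposit energy must be positive")


@dataclass
class Deposits:
    """Column container for energy depositions (positions um, energies eV)."""

    positions: np.ndarray
    energies: np.ndarray
    track_ids: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.energies = np.asarray(self.energies, dtype=float).reshape(-1)
        self.track_ids = np.asarray(self.track_ids, dtype=np.int64).reshape(-1)
        if not (len(self.positions) == len(self.energies) == len(self.track_ids)):
            raise ValueError("deposit columns must have equal length")
        if np.any(self.energies <= 0):
            raise ValueError("deposit energies must be positive")

    def __len__(self) -> int:
        return len(self.energies)

    @classmethod
    def empty(cls) -> "Deposits":
        return cls(np.empty((0, 3)), np.empty(0), np.empty(0, dtype=np.int64))

    @classmethod
    def from_records(cls, records: Sequence[EnergyDeposit]) -> "Deposits":
        if not records:
            return cls.empty()
        return cls(
            np.array([r.position for r in records]),
            np.array([r.energy for r in records]),
            np.array([r.track_id for r in records]),
        )

    @classmethod
    def concatenate(cls, parts: Sequence["Deposits"]) -> "Deposits":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls.empty()
        return cls(
            np.vstack([p.positions for p in parts]),
            np.concatenate([p.energies for p in parts]),
            np.concatenate([p.track_ids for p in parts]),
        )


@dataclass(frozen=True)
class StrandBreak:
    chrom: str
    strand: int  # 1 or 2
    bp: int
    position: tuple[float, float, float]  # um
    origin: str = "particle"  # particle | photon

    def __post_init__(self) -> None:
        if self.strand not in (1, 2):
            raise ValueError("strand must be 1 or 2")


@dataclass(frozen=True)
class DamageSite:
    """A clustered lesion: DSB (>=2 breaks spanning both strands) or SSB."""

    kind: str  # DSB | SSB
    breaks: tuple[StrandBreak, ...]
    centroid: tuple[float, float, float]
    chrom: str
    complexity: int  # backbone count

    def __post_init__(self) -> None:
        if self.kind == "DSB":
            strands = {b.strand for b in self.breaks}
            if len(self.breaks) < 2 or strands != {1, 2}:
                raise ValueError("DSB must have >=2 breaks spanning both strands")
        elif self.kind == "SSB":
            if len(self.breaks) != 1:
                raise ValueError("SSB has exactly one break")
        else:
            raise ValueError(f"unknown site kind {self.kind!r}")

    @property
    def bp(self) -> int:
        return min(b.bp for b in self.breaks)


def energy_probability(energy, params: DamageParams | None = None):
    """Break probability for a deposit energy (eV): linear ramp clamped
    to 0 below ``e_zero`` and 1 above ``e_one``."""
    params = params or DamageParams()
    e = np.asarray(energy, dtype=float)
    p = np.clip((e - params.e_zero) / (params.e_one - params.e_zero), 0.0, 1.0)
    return float(p) if np.isscalar(energy) or p.ndim == 0 else p


if _HAVE_NUMBA:

    @njit(cache=True)
    def _grid_lookup(points, centers, radii, origin, cell, dims, indptr, cell_beads):
        out = np.full(len(points), -1, dtype=np.int64)
        for p in range(len(points)):
            cx = int((points[p, 0] - origin[0]) / cell)
            cy = int((points[p, 1] - origin[1]) / cell)
            cz = int((points[p, 2] - origin[2]) / cell)
            if cx < 0 or cy < 0 or cz < 0 or cx >= dims[0] or cy >= dims[1] or cz >= dims[2]:
                continue
            c = (cx * dims[1] + cy) * dims[2] + cz
            best = -1
            best_d2 = 1e30
            for q in range(indptr[c], indptr[c + 1]):
                b = cell_beads[q]
                dx = points[p, 0] - centers[b, 0]
                dy = points[p, 1] - centers[b, 1]
                dz = points[p, 2] - centers[b, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 <= radii[b] * radii[b] and d2 < best_d2:
                    best = b
                    best_d2 = d2
            out[p] = best
        return out


def _bead_grid(conf: GenomeConformation):
    """Uniform grid of bead membership (cached on the conformation)."""
    import hashlib

    stamp = hashlib.blake2b(conf.centers.tobytes() + conf.radii.tobytes(), digest_size=8).digest()
    cached = conf.__dict__.get("_bead_grid_cache")
    if cached is not None and cached[0] == stamp:
        return cached[1]
    centers, radii = conf.centers, conf.radii
    r_max = float(radii.max())
    origin = centers.min(axis=0) - r_max
    extent = centers.max(axis=0) + r_max - origin
    cell = max(r_max, 1e-9)
    dims = np.maximum(1, np.ceil(extent / cell).astype(np.int64))
    # register each bead in every cell its bounding box overlaps
    lo = np.clip(np.floor((centers - radii[:, None] - origin) / cell).astype(np.int64), 0, dims - 1)
    hi = np.clip(np.floor((centers + radii[:, None] - origin) / cell).astype(np.int64), 0, dims - 1)
    span = hi - lo + 1
    counts_per_bead = span.prod(axis=1)
    total = int(counts_per_bead.sum())
    all_cells = np.empty(total, dtype=np.int64)
    all_beads = np.repeat(np.arange(conf.n_beads, dtype=np.int64), counts_per_bead)
    pos = 0
    for b in range(conf.n_beads):
        xs = np.arange(lo[b, 0], hi[b, 0] + 1)
        ys = np.arange(lo[b, 1], hi[b, 1] + 1)
        zs = np.arange(lo[b, 2], hi[b, 2] + 1)
        cid = ((xs[:, None] * dims[1] + ys[None, :])[:, :, None] * dims[2] + zs).ravel()
        all_cells[pos : pos + len(cid)] = cid
        pos += len(cid)
    order = np.argsort(all_cells, kind="stable")
    cell_beads = all_beads[order]
    n_cells = int(np.prod(dims))
    counts = np.bincount(all_cells, minlength=n_cells)
    indptr = np.concatenate(([0], np.cumsum(counts)))
    grid = (origin.astype(float), float(cell), dims, indptr.astype(np.int64), cell_beads)
    conf.__dict__["_bead_grid_cache"] = (stamp, grid)
    return grid


def _containing_bead(positions: np.ndarray, conf: GenomeConformation) -> np.ndarray:
    """Index of a bead containing each position, or -1.

    Overlapping beads are resolved towards the nearest bead centre.
    Uses a uniform spatial grid when numba is available, otherwise a
    k-nearest-centres KD-tree query.
    """
    if len(positions) == 0:
        return np.empty(0, dtype=np.intp)
    if _HAVE_NUMBA and conf.n_beads > 1:
        grid = _bead_grid(conf)
        return _grid_lookup(np.ascontiguousarray(positions), conf.centers, conf.radii, *grid).astype(np.intp)
    tree = cKDTree(conf.centers)
    k = min(12, conf.n_beads)
    dist, idx = tree.query(positions, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    inside = dist <= conf.radii[idx]
    first = inside.argmax(axis=1)
    hit = inside[np.arange(len(positions)), first]
    out = np.where(hit, idx[np.arange(len(positions)), first], -1)
    return out.astype(np.intp)


def classify_deposits(
    deposits: Deposits | Sequence[EnergyDeposit],
    conformation: GenomeConformation,
    params: DamageParams | None = None,
    rng: np.random.Generator | None = None,
) -> list[StrandBreak]:
    """Convert energy deposits to strand breaks.

    Deposits outside all beads are discarded; the rest pass a
    Bernoulli(sensitive_fraction) draw, then the energy ramp draw.
    Survivors get strand ~ Bernoulli(0.5) + 1, a uniform bp position in
    the bead's genomic interval, and keep their 3D position.
    """
    params = params or DamageParams()
    rng = rng or np.random.default_rng(0)
    if not isinstance(deposits, Deposits):
        deposits = Deposits.from_records(list(deposits))
    if len(deposits) == 0:
        return []
    bead_idx = _containing_bead(deposits.positions, conformation)
    mask = bead_idx >= 0
    # draw the stochastic filters for every deposit so the stream is
    # independent of geometry
    u_sens = rng.random(len(deposits))
    u_ramp = rng.random(len(deposits))
    p = energy_probability(deposits.energies, params)
    accept = mask & (u_sens < params.sensitive_fraction) & (u_ramp < p)
    acc_idx = np.nonzero(accept)[0]
    strands = rng.integers(1, 3, size=len(acc_idx))
    u_bp = rng.random(len(acc_idx))
    breaks: list[StrandBreak] = []
    for row, strand, u in zip(acc_idx, strands, u_bp):
        spec = conformation.specs[bead_idx[row]]
        bp = spec.start + int(u * (spec.end - spec.start))
        breaks.append(
            StrandBreak(
                chrom=spec.chrom,
                strand=int(strand),
                bp=bp,
                position=tuple(deposits.positions[row]),
                origin="particle",
            )
        )
    return breaks


def cluster_breaks(
    breaks: Sequence[StrandBreak], params: DamageParams | None = None
) -> list[DamageSite]:
    """Cluster strand breaks into DSB/SSB damage sites.

    Per chromosome, breaks are chained transitively: two breaks link
    when |delta bp| <= dsb_bp_window or their 3D separation is
    <= dsb_nm_window.  A chain containing both strands is one DSB
    (complexity = backbone count); every other break is a singleton SSB.
    Duplicate breaks at identical (chrom, strand, bp) are merged first.
    The output partitions the deduplicated input and is independent of
    input order.
    """
    params = params or DamageParams()
    # dedupe and canonical order; among coordinate duplicates keep the
    # one with the smallest 3D position so the result is order-free
    seen: dict[tuple[str, int, int], StrandBreak] = {}
    for b in breaks:
        key = (b.chrom, b.bp, b.strand)
        prev = seen.get(key)
        if prev is None or tuple(b.position) < tuple(prev.position):
            seen[key] = b
    ordered = [seen[k] for k in sorted(seen)]

    sites: list[DamageSite] = []
    by_chrom: dict[str, list[StrandBreak]] = {}
    for b in ordered:
        by_chrom.setdefault(b.chrom, []).append(b)

    window_um = params.dsb_nm_window * 1e-3
    for chrom in sorted(by_chrom):
        blist = by_chrom[chrom]  # already sorted by (bp, strand)
        n = len(blist)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a: int, b: int) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

        # genomic chaining: sorted by bp, so transitive closure of the
        # bp criterion links consecutive breaks with gap <= window
        for i in range(n - 1):
            if blist[i + 1].bp - blist[i].bp <= params.dsb_bp_window:
                union(i, i + 1)
        # spatial chaining
        if n > 1:
            pts = np.array([b.position for b in blist])
            tree = cKDTree(pts)
            for a, b in tree.query_pairs(r=window_um):
                union(a, b)

        clusters: dict[int, list[int]] = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(i)
        for root in sorted(clusters):
            members = [blist[i] for i in clusters[root]]
            strands = {m.strand for m in members}
            if len(members) >= 2 and strands == {1, 2}:
                centroid = tuple(np.mean([m.position for m in members], axis=0))
                sites.append(
                    DamageSite(
                        kind="DSB",
                        breaks=tuple(members),
                        centroid=centroid,
                        chrom=chrom,
                        complexity=len(members),
                    )
                )
            else:
                for m in members:
                    sites.append(
                        DamageSite(
                            kind="SSB",
                            breaks=(m,),
                            centroid=m.position,
                            chrom=chrom,
                            complexity=1,
                        )
                    )
    return sites


def photon_exposure(
    conformation: GenomeConformation,
    dose_gy: float,
    params: DamageParams | None = None,
    rng: np.random.Generator | None = None,
) -> list[DamageSite]:
    """Photon damage model: direct Poisson DSB induction.

    N ~ Poisson(photon_dsb_per_gy * dose); each DSB picks a chromosome
    with probability proportional to its bp content, a bead within it
    proportional to bead bp, a uniform position inside the bead sphere
    and a uniform bp in the bead's interval.  Each DSB is emitted as one
    damage site with two opposite-strand breaks (complexity 2); photon
    sites are never re-clustered.
    """
    params = params or DamageParams()
    rng = rng or np.random.default_rng(0)
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    n_sites = int(rng.poisson(params.photon_dsb_per_gy * dose_gy))
    if n_sites == 0:
        return []

    slices = conformation.chain_slices
    labels = list(slices)
    bp = conformation.bp.astype(float)
    chrom_bp = np.array([bp[slices[lab]].sum() for lab in labels])
    p_chrom = chrom_bp / chrom_bp.sum()

    sites: list[DamageSite] = []
    chrom_draws = rng.choice(len(labels), size=n_sites, p=p_chrom)
    for ci in chrom_draws:
        sl = slices[labels[ci]]
        w = bp[sl]
        bi = sl.start + int(rng.choice(sl.stop - sl.start, p=w / w.sum()))
        spec = conformation.specs[bi]
        # uniform point inside the bead sphere
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        pos = conformation.centers[bi] + d * conformation.radii[bi] * rng.random() ** (
            1.0 / 3.0
        )
        bp_pos = spec.start + int(rng.random() * (spec.end - spec.start))
        b1 = StrandBreak(spec.chrom, 1, bp_pos, tuple(pos), origin="photon")
        b2 = StrandBreak(spec.chrom, 2, bp_pos, tuple(pos), origin="photon")
        sites.append(
            DamageSite(
                kind="DSB",
                breaks=(b1, b2),
                centroid=tuple(pos),
                chrom=spec.chrom,
                complexity=2,
            )
        )
    return sites


@dataclass(frozen=True)
class Yields:
    dsb_per_gy: float
    ssb_per_gy: float
    backbones_per_dsb: float  # nan when there are no DSBs
    n_dsb: int
    n_ssb: int


def damage_yields(sites: Sequence[DamageSite], dose_gy: float) -> Yields:
    """Damage yields per gray and mean DSB complexity."""
    if dose_gy <= 0:
        raise ValueError("dose must be positive")
    n_dsb = sum(1 for s in sites if s.kind == "DSB")
    n_ssb = sum(1 for s in sites if s.kind == "SSB")
    if n_dsb:
        backbones = sum(s.complexity for s in sites if s.kind == "DSB") / n_dsb
    else:
        backbones = math.nan
    return Yields(n_dsb / dose_gy, n_ssb / dose_gy, backbones, n_dsb, n_ssb)


@dataclass(frozen=True)
class SddRecord:
    """One damage record of the minimal SDD dialect written here."""

    kind: str
    x: float
    y: float
    z: float
    chrom: str
    bp: int
    backbones: int


_SDD_END_HEADER = "***EndOfHeader***;"


def chromosome_sizes_header(conf: GenomeConformation) -> str:
    """SDD 'Chromosome sizes' value: chain count then per-chain Mbp."""
    slices = conf.chain_slices
    bp = conf.bp
    sizes = [float(bp[sl].sum()) / 1e6 for sl in slices.values()]
    return ", ".join([str(len(sizes))] + [f"{s:g}" for s in sizes])


def write_sdd(
    sites: Sequence[DamageSite],
    header: dict[str, str] | None = None,
    path: str | Path = "damage.sdd",
) -> None:
    """Write damage sites in a minimal Standard DNA Damage (SDD) dialect.

    Header: ``key, value;`` lines terminated by ``***EndOfHeader***;``.
    Each data line has five ``;``-delimited field groups:
    classification; centroid x,y,z (um); chromosome id; bp position;
    backbone-break count.
    """
    lines = []
    hdr = {"SDD version": "1.0"}
    hdr.update(header or {})
    for key, value in hdr.items():
        lines.append(f"{key}, {value};")
    lines.append(_SDD_END_HEADER)
    for s in sites:
        x, y, z = (float(v) for v in s.centroid)
        lines.append(
            f"{s.kind}; {x!r},{y!r},{z!r}; {s.chrom}; {s.bp}; {s.complexity};"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_sdd(path: str | Path) -> tuple[list[SddRecord], dict[str, str]]:
    """Read the SDD dialect written by :func:`write_sdd`."""
    header: dict[str, str] = {}
    records: list[SddRecord] = []
    in_header = True
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if in_header:
            if line == _SDD_END_HEADER:
                in_header = False
                continue
            key, _, value = line.rstrip(";").partition(",")
            header[key.strip()] = value.strip()
            continue
        kind, xyz, chrom, bp, backbones = [g.strip() for g in line.rstrip(";").split(";")]
        x, y, z = (float(v) for v in xyz.split(","))
        records.append(SddRecord(kind, x, y, z, chrom, int(bp), int(backbones)))
    return records, header


def sites_to_records(sites: Sequence[DamageSite]) -> list[SddRecord]:
    return [
        SddRecord(s.kind, *map(float, s.centroid), s.chrom, s.bp, s.complexity)
        for s in sites
    ]


def write_deposits_tsv(deposits: Deposits, path: str | Path) -> None:
    """Write deposits as a TSV (x, y, z, energy_eV, track_id)."""
    lines = ["x\ty\tz\tenergy_eV\ttrack_id"]
    for i in range(len(deposits)):
        x, y, z = (float(v) for v in deposits.positions[i])
        lines.append(
            f"{x!r}\t{y!r}\t{z!r}\t{float(deposits.energies[i])!r}\t{deposits.track_ids[i]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_deposits_tsv(path: str | Path) -> Deposits:
    """Read a deposits TSV, e.g. exported from an external transport code."""
    positions, energies, tracks = [], [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("x\t", "#")):
            continue
        x, y, z, e, t = line.split("\t")
        positions.append((float(x), float(y), float(z)))
        energies.append(float(e))
        tracks.append(int(t))
    if not positions:
        return Deposits.empty()
    return Deposits(np.array(positions), np.array(energies), np.array(tracks))
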