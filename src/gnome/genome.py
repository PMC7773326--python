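"""Genome/bead data model, gtrack and CMM I/O, and conformation builders.

The genome is modelled as chains of spherical beads, one bead per
topologically associated domain (TAD).  Each bead carries a genomic
interval, an optional lamina-association (periphery) flag and a set of
contact partners derived from Hi-C interaction calls.  Beads of one
chromosome form an ordered chain; a diploid genome carries two copies of
each chromosome distinguished by an ``_A``/``_B`` label suffix.

All lengths are micrometres; genomic coordinates are 0-based half-open
(BED-like) base-pair intervals.
"""
from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NucleusShape",
    "BeadSpec",
    "Bead",
    "GenomeConformation",
    "GenomeConfig",
    "GtrackFormatError",
    "GtrackValidationError",
    "PlacementError",
    "read_gtrack",
    "write_gtrack",
    "contact_pairs",
    "assign_radii",
    "build_initial_conformation",
    "generate_pseudo_random",
    "synthesize_genome",
    "write_cmm",
    "write_coords",
    "read_coords",
    "homolog_key",
]


class GtrackFormatError(ValueError):
    """Raised when a gtrack file is structurally malformed."""


class GtrackValidationError(ValueError):
    """Raised when a gtrack file parses but violates bead invariants."""


class PlacementError(RuntimeError):
    """Raised when chains cannot be placed inside the nucleus."""


def homolog_key(label: str) -> str:
    """Chromosome identity with the homolog copy suffix stripped.

    ``chr1_A`` and ``chr1_B`` are copies of the same chromosome; damage
    and clustering statistics treat them as homologs, which is neither
    "same chromosome" nor "different chromosome".
    """
    if label.endswith(("_A", "_B")):
        return label[:-2]
    return label


@dataclass(frozen=True)
class NucleusShape:
    """Spherical or ellipsoidal nuclear boundary.

    ``semi_axes`` holds three semi-axis lengths in micrometres; a sphere
    stores its radius three times.  Ellipsoid membership uses the scaled
    radius t = sqrt((x/a)^2 + (y/b)^2 + (z/c)^2) <= 1.
    """

    kind: str
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown nucleus kind {self.kind!r}")
        if len(self.semi_axes) != 3 or any(a <= 0 for a in self.semi_axes):
            raise ValueError("all semi-axes must be positive")
        if self.kind == "sphere" and len(set(self.semi_axes)) != 1:
            raise ValueError("sphere must have equal semi-axes")

    @classmethod
    def sphere(cls, radius: float) -> "NucleusShape":
        return cls("sphere", (float(radius),) * 3)

    @classmethod
    def ellipsoid(cls, a: float, b: float, c: float) -> "NucleusShape":
        return cls("ellipsoid", (float(a), float(b), float(c)))

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def surface_area(self) -> float:
        a, b, c = self.semi_axes
        if self.kind == "sphere":
            return 4.0 * math.pi * a * a
        # Thomsen approximation (p = 1.6075), relative error < 1.2 %
        p = 1.6075
        s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
        return 4.0 * math.pi * s ** (1.0 / p)

    @property
    def mean_chord_length(self) -> float:
        """Cauchy mean chord 4V/S of a convex body, in micrometres."""
        return 4.0 * self.volume / self.surface_area

    @property
    def characteristic_length(self) -> float:
        a, b, c = self.semi_axes
        return (a * b * c) ** (1.0 / 3.0)

    def scaled_radius(self, points: np.ndarray) -> np.ndarray:
        """Normalised radius t; the boundary is t == 1."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.sqrt(np.sum((pts / np.asarray(self.semi_axes)) ** 2, axis=1))

    def contains(self, points: np.ndarray, tol: float = 1e-12) -> np.ndarray:
        return self.scaled_radius(points) <= 1.0 + tol

    def boundary_excess(self, points: np.ndarray) -> np.ndarray:
        """Distance outside the boundary; exactly 0 for interior points.

        Spheres use the exact euclidean distance |p| - R.  Ellipsoids use
        the scaled-radial approximation |p| (1 - 1/t), which agrees with
        the true distance on the axes and is exact for spheres.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "sphere":
            return np.maximum(0.0, np.linalg.norm(pts, axis=1) - self.semi_axes[0])
        t = self.scaled_radius(pts)
        norm = np.linalg.norm(pts, axis=1)
        out = np.zeros(len(pts))
        mask = t > 1.0
        out[mask] = norm[mask] * (1.0 - 1.0 / t[mask])
        return out

    def uniform_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n points i.i.d. uniform over the nuclear volume."""
        g = rng.standard_normal((n, 3))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        u = rng.random(n) ** (1.0 / 3.0)
        return g * u[:, None] * np.asarray(self.semi_axes)


@dataclass(frozen=True)
class BeadSpec:
    """One TAD: genomic interval, periphery flag and contact partners."""

    chrom: str
    start: int
    end: int
    bead_id: str
    periphery: bool = False
    edges: frozenset[str] = field(default_factory=frozenset)
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise GtrackValidationError(
                f"bead {self.bead_id}: end ({self.end}) must exceed start ({self.start})"
            )
        object.__setattr__(self, "edges", frozenset(self.edges))

    @property
    def bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Bead:
    """A positioned bead: spec plus centre coordinate and radius (um)."""

    spec: BeadSpec
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("bead radius must be positive")


GTRACK_COLUMNS = ("seqid", "start", "end", "id", "radius", "periphery", "edges")
_MANDATORY_COLUMNS = ("seqid", "start", "end", "id")


def _validate_and_symmetrize(specs: list[BeadSpec]) -> list[BeadSpec]:
    ids = [s.bead_id for s in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise GtrackValidationError(f"duplicate bead ids: {dupes}")
    known = set(ids)
    dangling = sorted({e for s in specs for e in s.edges} - known)
    if dangling:
        raise GtrackValidationError(f"edges reference unknown bead ids: {dangling}")
    partners: dict[str, set[str]] = {i: set() for i in ids}
    for s in specs:
        for e in s.edges:
            if e == s.bead_id:
                continue
            partners[s.bead_id].add(e)
            partners[e].add(s.bead_id)
    return [replace(s, edges=frozenset(partners[s.bead_id])) for s in specs]


def read_gtrack(path: str | Path) -> tuple[list[BeadSpec], dict[str, str]]:
    """Read a Chrom3D-dialect gtrack file.

    Lines starting ``##`` are metadata (``##key: value``); the column
    header starts ``###``.  Edges are ``;``-joined partner ids (an
    optional ``:weight`` suffix is read and ignored); ``.`` means none.
    Edges are symmetrized after load.
    """
    path = Path(path)
    metadata: dict[str, str] = {}
    columns: list[str] | None = None
    specs: list[BeadSpec] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("###"):
                columns = [c.strip() for c in line[3:].split("\t")]
                for col in _MANDATORY_COLUMNS:
                    if col not in columns:
                        raise GtrackFormatError(
                            f"{path}: missing mandatory column {col!r}"
                        )
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition(":")
                metadata[key.strip()] = value.strip()
                continue
            if columns is None:
                raise GtrackFormatError(f"{path}:{lineno}: data before column header")
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise GtrackFormatError(
                    f"{path}:{lineno}: expected {len(columns)} fields, got {len(fields)}"
                )
            row = dict(zip(columns, fields))
            edges: frozenset[str] = frozenset()
            if row.get("edges", ".") not in (".", ""):
                edges = frozenset(
                    tok.split(":")[0].strip()
                    for tok in row["edges"].split(";")
                    if tok.strip()
                )
            radius = None
            if row.get("radius", ".") not in (".", ""):
                radius = float(row["radius"])
            specs.append(
                BeadSpec(
                    chrom=row["seqid"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    bead_id=row["id"],
                    periphery=row.get("periphery", ".") == "1",
                    edges=edges,
                    radius=radius,
                )
            )
    return _validate_and_symmetrize(specs), metadata


def write_gtrack(
    specs: Sequence[BeadSpec],
    path: str | Path,
    metadata: Mapping[str, str] | None = None,
) -> None:
    """Write specs as a gtrack file; inverse of :func:`read_gtrack`."""
    path = Path(path)
    lines = []
    for key, value in (metadata or {}).items():
        lines.append(f"##{key}: {value}")
    lines.append("###" + "\t".join(GTRACK_COLUMNS))
    for s in specs:
        lines.append(
            "\t".join(
                (
                    s.chrom,
                    str(s.start),
                    str(s.end),
                    s.bead_id,
                    "." if s.radius is None else repr(float(s.radius)),
                    "1" if s.periphery else ".",
                    ";".join(sorted(s.edges)) if s.edges else ".",
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")


def contact_pairs(specs: Sequence[BeadSpec]) -> list[tuple[str, str]]:
    """Deduplicated unordered contact-constraint pairs from bead edges."""
    seen: set[tuple[str, str]] = set()
    for s in specs:
        for e in s.edges:
            if e != s.bead_id:
                seen.add(tuple(sorted((s.bead_id, e))))  # type: ignore[arg-type]
    return sorted(seen)


def assign_radii(
    specs: Sequence[BeadSpec], nucleus: NucleusShape, occupancy: float = 0.15
) -> np.ndarray:
    """Bead radii (um) such that total bead volume is occupancy * V_nucleus.

    Bead volume is proportional to base-pair content, so
    r_i = (3 occupancy V_nuc bp_i / (4 pi bp_total))^(1/3).
    """
    if not 0 < occupancy < 1:
        raise ValueError("occupancy must lie in (0, 1)")
    bp = np.array([s.bp for s in specs], dtype=float)
    total = bp.sum()
    if total <= 0:
        raise ValueError("zero-length genome")
    volumes = occupancy * nucleus.volume * bp / total
    return np.cbrt(volumes * 3.0 / (4.0 * math.pi))


def _order_indices(specs: Sequence[BeadSpec]) -> list[int]:
    """Permutation grouping specs by chromosome (first-appearance order)
    and sorting by genomic start within each chain."""
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(specs):
        if s.chrom not in groups:
            groups[s.chrom] = []
            order.append(s.chrom)
        groups[s.chrom].append(i)
    out: list[int] = []
    for label in order:
        out.extend(sorted(groups[label], key=lambda i: specs[i].start))
    return out


def _order_specs(specs: Sequence[BeadSpec]) -> tuple[BeadSpec, ...]:
    return tuple(specs[i] for i in _order_indices(specs))


@dataclass
class GenomeConformation:
    """Positioned genome: ordered bead chains inside a nucleus.

    ``specs`` are grouped by chromosome chain and ordered by genomic
    start within each chain; ``centers``/``radii`` are parallel arrays.
    """

    specs: tuple[BeadSpec, ...]
    centers: np.ndarray
    radii: np.ndarray
    nucleus: NucleusShape
    occupancy: float
    seed: int | None = None

    def __post_init__(self) -> None:
        perm = _order_indices(self.specs)
        self.specs = tuple(self.specs[i] for i in perm)
        self.centers = np.asarray(self.centers, dtype=float).reshape(len(self.specs), 3)[perm]
        self.radii = np.asarray(self.radii, dtype=float).reshape(len(self.specs))[perm]
        if np.any(self.radii <= 0):
            raise ValueError("all bead radii must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.specs)

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.specs:
            if not seen or seen[-1] != s.chrom:
                seen.append(s.chrom)
        return seen

    @property
    def chain_slices(self) -> dict[str, slice]:
        slices: dict[str, slice] = {}
        start = 0
        current = self.specs[0].chrom if self.specs else None
        for i, s in enumerate(self.specs):
            if s.chrom != current:
                slices[current] = slice(start, i)
                current, start = s.chrom, i
        if current is not None:
            slices[current] = slice(start, self.n_beads)
        return slices

    @property
    def chrom_labels(self) -> list[str]:
        return [s.chrom for s in self.specs]

    @property
    def bp(self) -> np.ndarray:
        return np.array([s.bp for s in self.specs], dtype=np.int64)

    @property
    def periphery_mask(self) -> np.ndarray:
        return np.array([s.periphery for s in self.specs], dtype=bool)

    @property
    def chains(self) -> dict[str, list[Bead]]:
        out: dict[str, list[Bead]] = {}
        for label, sl in self.chain_slices.items():
            out[label] = [
                Bead(self.specs[i], tuple(self.centers[i]), float(self.radii[i]))
                for i in range(sl.start, sl.stop)
            ]
        return out

    @property
    def total_bead_volume(self) -> float:
        return float(np.sum(4.0 / 3.0 * math.pi * self.radii**3))

    def index_of(self) -> dict[str, int]:
        return {s.bead_id: i for i, s in enumerate(self.specs)}

    def constraint_index_pairs(
        self, pairs: Sequence[tuple[str, str]] | None = None
    ) -> np.ndarray:
        """Contact constraints as an (m, 2) array of bead indices."""
        idx = self.index_of()
        if pairs is None:
            pairs = contact_pairs(self.specs)
        try:
            arr = np.array([(idx[a], idx[b]) for a, b in pairs], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"constraint references unknown bead id {exc}") from exc
        return arr.reshape(-1, 2)

    def inside_fraction(self) -> float:
        if self.n_beads == 0:
            return 1.0
        return float(np.mean(self.nucleus.contains(self.centers)))

    def copy(self) -> "GenomeConformation":
        return GenomeConformation(
            specs=self.specs,
            centers=self.centers.copy(),
            radii=self.radii.copy(),
            nucleus=self.nucleus,
            occupancy=self.occupancy,
            seed=self.seed,
        )


def _resolve_radii(
    specs: tuple[BeadSpec, ...],
    nucleus: NucleusShape,
    occupancy: float,
    radii: np.ndarray | None,
) -> tuple[np.ndarray, float]:
    if radii is not None:
        radii = np.asarray(radii, dtype=float)
    elif all(s.radius is not None for s in specs):
        radii = np.array([s.radius for s in specs], dtype=float)
    else:
        radii = assign_radii(specs, nucleus, occupancy)
    total_vol = float(np.sum(4.0 / 3.0 * math.pi * radii**3))
    return radii, total_vol / nucleus.volume


def build_initial_conformation(
    specs: Sequence[BeadSpec],
    nucleus: NucleusShape,
    seed: int,
    occupancy: float = 0.15,
    radii: np.ndarray | None = None,
    max_retries: int = 1000,
    max_chain_restarts: int = 100,
) -> GenomeConformation:
    """Random-walk starting conformation with consecutive beads touching.

    Each chain is grown bead by bead: the next centre is placed at
    distance r_i + r_{i+1} from the previous in a uniform random
    direction, retried (up to ``max_retries``) until it lies inside the
    nucleus.  Overlap with non-adjacent beads is tolerated here and
    penalised later by the solver.  Deterministic given ``seed``.
    """
    ordered = _order_specs(specs)
    radii_arr, occ = _resolve_radii(ordered, nucleus, occupancy, radii)
    rng = np.random.default_rng(seed)
    centers = np.zeros((len(ordered), 3))
    conf = GenomeConformation(ordered, centers, radii_arr, nucleus, occ, seed)
    for label, sl in conf.chain_slices.items():
        n = sl.stop - sl.start
        r = conf.radii[sl]
        for _restart in range(max_chain_restarts):
            chain = np.zeros((n, 3))
            chain[0] = nucleus.uniform_points(1, rng)[0]
            ok = True
            for i in range(1, n):
                step = r[i - 1] + r[i]
                placed = False
                for _ in range(max_retries):
                    d = rng.standard_normal(3)
                    d /= np.linalg.norm(d)
                    cand = chain[i - 1] + d * step
                    if nucleus.contains(cand[None, :])[0]:
                        chain[i] = cand
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if ok:
                conf.centers[sl] = chain
                break
        else:
            raise PlacementError(
                f"could not place chain {label!r} inside the nucleus "
                f"after {max_chain_restarts} restarts"
            )
    return conf


def generate_pseudo_random(
    specs: Sequence[BeadSpec],
    nucleus: NucleusShape,
    seed: int,
    occupancy: float = 0.15,
    radii: np.ndarray | None = None,
) -> GenomeConformation:
    """Reference geometry: bead centres i.i.d. uniform in the nucleus.

    Chain adjacency and all contact constraints are ignored, so the
    result is devoid of chromosome territories — the upper bound of
    chromosome intermingling used to normalise clustering metrics.
    """
    ordered = _order_specs(specs)
    radii_arr, occ = _resolve_radii(ordered, nucleus, occupancy, radii)
    rng = np.random.default_rng(seed)
    centers = nucleus.uniform_points(len(ordered), rng)
    return GenomeConformation(ordered, centers, radii_arr, nucleus, occ, seed)


# Approximate human chromosome lengths (Mbp), used as default size weights.
HUMAN_CHROM_MBP: dict[str, float] = {
    "chr1": 248, "chr2": 242, "chr3": 198, "chr4": 190, "chr5": 182,
    "chr6": 171, "chr7": 159, "chr8": 145, "chr9": 138, "chr10": 134,
    "chr11": 135, "chr12": 133, "chr13": 114, "chr14": 107, "chr15": 102,
    "chr16": 90, "chr17": 83, "chr18": 80, "chr19": 59, "chr20": 64,
    "chr21": 47, "chr22": 51, "chrX": 156,
}


@dataclass(frozen=True)
class GenomeConfig:
    """Synthetic-genome parameters.

    Defaults emulate a normal diploid human cell: 6 Gbp over 46
    chromosomes (23 pairs, sizes in human proportions), segmented into
    TAD beads of 1-3 Mbp, with Hi-C-like contact edges (mostly
    intra-chromosomal, genomically local) and ~30 % of beads flagged as
    lamina-associated.
    """

    total_bp: int = 6_000_000_000
    chrom_weights: Mapping[str, float] | None = None
    diploid: bool = True
    tad_bp_min: int = 1_000_000
    tad_bp_max: int = 3_000_000
    contact_density: float = 1.0
    intra_fraction: float = 0.7
    intra_offset_p: float = 0.3
    periphery_fraction: float = 0.3


def _partition_chromosome(bp: int, cfg: GenomeConfig, rng: np.random.Generator) -> list[int]:
    if bp < 1:
        raise ValueError("chromosome must contain at least 1 bp")
    sizes: list[int] = []
    remaining = bp
    while remaining > cfg.tad_bp_max:
        size = int(rng.integers(cfg.tad_bp_min, cfg.tad_bp_max + 1))
        sizes.append(size)
        remaining -= size
    if remaining >= cfg.tad_bp_min or not sizes:
        sizes.append(remaining)
    else:
        sizes[-1] += remaining
    return sizes


def synthesize_genome(config: GenomeConfig | None = None, seed: int = 0) -> list[BeadSpec]:
    """Generate gtrack-ready bead specs for a synthetic genome."""
    cfg = config or GenomeConfig()
    rng = np.random.default_rng(seed)
    weights = dict(cfg.chrom_weights) if cfg.chrom_weights else dict(HUMAN_CHROM_MBP)
    copies = 2 if cfg.diploid else 1
    haploid_bp = cfg.total_bp // copies
    if haploid_bp * copies != cfg.total_bp:
        raise ValueError("total_bp must be divisible by the number of genome copies")

    wsum = sum(weights.values())
    labels = list(weights)
    sizes = {lab: int(round(haploid_bp * weights[lab] / wsum)) for lab in labels}
    sizes[labels[-1]] += haploid_bp - sum(sizes.values())  # fix rounding on last
    if any(v < 1 for v in sizes.values()):
        raise ValueError("chromosome weights leave a chromosome with <1 bp")

    partitions = {lab: _partition_chromosome(sizes[lab], cfg, rng) for lab in labels}

    specs: list[BeadSpec] = []
    suffixes = ["_A", "_B"] if cfg.diploid else [""]
    for lab in labels:
        for suffix in suffixes:
            chrom = lab + suffix
            pos = 0
            for k, size in enumerate(partitions[lab]):
                specs.append(
                    BeadSpec(
                        chrom=chrom,
                        start=pos,
                        end=pos + size,
                        bead_id=f"{chrom}.{k}",
                        periphery=bool(rng.random() < cfg.periphery_fraction),
                    )
                )
                pos += size

    n = len(specs)
    by_chain: dict[str, list[int]] = {}
    for i, s in enumerate(specs):
        by_chain.setdefault(s.chrom, []).append(i)
    chain_list = list(by_chain.values())

    n_edges = int(round(cfg.contact_density * n / 2.0))
    edges: set[tuple[int, int]] = set()
    attempts = 0
    while len(edges) < n_edges and attempts < 50 * max(n_edges, 1):
        attempts += 1
        if rng.random() < cfg.intra_fraction:
            chain = chain_list[rng.integers(len(chain_list))]
            if len(chain) < 2:
                continue
            i = int(rng.integers(len(chain)))
            off = int(rng.geometric(cfg.intra_offset_p))
            j = i + off
            if j >= len(chain):
                continue
            a, b = chain[i], chain[j]
        else:
            a, b = (int(x) for x in rng.integers(n, size=2))
            if specs[a].chrom == specs[b].chrom:
                continue
        if a != b:
            edges.add((min(a, b), max(a, b)))

    partners: dict[int, set[str]] = {i: set() for i in range(n)}
    for a, b in edges:
        partners[a].add(specs[b].bead_id)
        partners[b].add(specs[a].bead_id)
    return [replace(s, edges=frozenset(partners[i])) for i, s in enumerate(specs)]


# 20-colour qualitative palette (tab20) cycled per chromosome chain.
_PALETTE = [
    (0.121, 0.466, 0.705), (0.682, 0.780, 0.909), (1.000, 0.498, 0.054),
    (1.000, 0.733, 0.470), (0.172, 0.627, 0.172), (0.596, 0.874, 0.541),
    (0.839, 0.152, 0.156), (1.000, 0.596, 0.588), (0.580, 0.403, 0.741),
    (0.772, 0.690, 0.835), (0.549, 0.337, 0.294), (0.768, 0.611, 0.580),
    (0.890, 0.466, 0.760), (0.968, 0.713, 0.823), (0.498, 0.498, 0.498),
    (0.780, 0.780, 0.780), (0.737, 0.741, 0.133), (0.858, 0.858, 0.553),
    (0.090, 0.745, 0.811), (0.619, 0.854, 0.898),
]


def chromosome_colors(labels: Iterable[str]) -> dict[str, tuple[float, float, float]]:
    return {lab: _PALETTE[i % len(_PALETTE)] for i, lab in enumerate(labels)}


def write_cmm(conformation: GenomeConformation, path: str | Path, name: str = "genome") -> None:
    """Export a conformation as a Chimera marker-set (CMM) XML file.

    One ``<marker>`` per bead with position (um), bead radius and a
    per-chromosome colour.
    """
    colors = chromosome_colors(conformation.labels)
    root = ET.Element("marker_set", name=name)
    for i, spec in enumerate(conformation.specs):
        r, g, b = colors[spec.chrom]
        x, y, z = conformation.centers[i]
        ET.SubElement(
            root,
            "marker",
            id=str(i + 1),
            x=f"{x:.6f}",
            y=f"{y:.6f}",
            z=f"{z:.6f}",
            radius=f"{conformation.radii[i]:.6f}",
            r=f"{r:.4f}",
            g=f"{g:.4f}",
            b=f"{b:.4f}",
            note=spec.bead_id,
        )
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def write_coords(conformation: GenomeConformation, path: str | Path) -> None:
    """Write bead coordinates as a TSV with a small metadata header."""
    nuc = conformation.nucleus
    lines = [
        f"#nucleus\t{nuc.kind}\t{nuc.semi_axes[0]!r}\t{nuc.semi_axes[1]!r}\t{nuc.semi_axes[2]!r}",
        f"#occupancy\t{conformation.occupancy!r}",
        f"#seed\t{conformation.seed if conformation.seed is not None else '.'}",
        "bead_id\tchrom\tstart\tend\tperiphery\tedges\tx\ty\tz\tradius",
    ]
    for i, s in enumerate(conformation.specs):
        x, y, z = conformation.centers[i]
        lines.append(
            "\t".join(
                (
                    s.bead_id, s.chrom, str(s.start), str(s.end),
                    "1" if s.periphery else "0",
                    ";".join(sorted(s.edges)) if s.edges else ".",
                    repr(float(x)), repr(float(y)), repr(float(z)),
                    repr(float(conformation.radii[i])),
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_coords(path: str | Path) -> GenomeConformation:
    """Read a conformation written by :func:`write_coords`."""
    specs: list[BeadSpec] = []
    centers: list[tuple[float, float, float]] = []
    radii: list[float] = []
    nucleus: NucleusShape | None = None
    occupancy = 0.15
    seed: int | None = None
    header_seen = False
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#nucleus"):
            _, kind, a, b, c = line.split("\t")
            nucleus = NucleusShape(kind, (float(a), float(b), float(c)))
            continue
        if line.startswith("#occupancy"):
            occupancy = float(line.split("\t")[1])
            continue
        if line.startswith("#seed"):
            val = line.split("\t")[1]
            seed = None if val == "." else int(val)
            continue
        if line.startswith("bead_id"):
            header_seen = True
            continue
        if not header_seen:
            raise GtrackFormatError(f"{path}: missing column header")
        (bead_id, chrom, start, end, periph, edges, x, y, z, radius) = line.split("\t")
        specs.append(
            BeadSpec(
                chrom=chrom,
                start=int(start),
                end=int(end),
                bead_id=bead_id,
                periphery=periph == "1",
                edges=frozenset(edges.split(";")) if edges != "." else frozenset(),
            )
        )
        centers.append((float(x), float(y), float(z)))
        radii.append(float(radius))
    if nucleus is None:
        raise GtrackFormatError(f"{path}: missing #nucleus header line")
    return GenomeConformation(
        tuple(specs), np.array(centers), np.array(radii), nucleus, occupancy, seed
    )
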