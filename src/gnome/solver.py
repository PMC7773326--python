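"""MCMC optimisation of a genome conformation.

The solver arranges bead chains so that Hi-C contact constraints are
satisfied while beads stay inside the nucleus, lamina-associated beads
sit near the periphery and beads do not overlap.  Five chain move types
(crankshaft, arm rotation, arm wiggle, whole-chromosome translation and
rotation) are proposed at random and accepted greedily, by
Metropolis-Hastings, or by simulated annealing.  Iterations are counted
as *accepted* ("successful") moves; an attempt cap guarantees
termination.

All cost terms are hinge losses on surface-gap distances: they are
continuous, non-negative and exactly zero when the constraint is
satisfied.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

try:  # optional acceleration of the per-move cost delta
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]

from .genome import GenomeConformation

__all__ = [
    "SolverConfig",
    "CostWeights",
    "CostBreakdown",
    "MoveProposal",
    "evaluate_cost",
    "propose_move",
    "accept_move",
    "solve",
    "SolveResult",
    "MOVE_TYPES",
]

MOVE_TYPES = ("crankshaft", "arm_rotation", "arm_wiggle", "translation", "rotation")


@dataclass(frozen=True)
class CostWeights:
    contact: float = 1.0
    boundary: float = 1.0
    lad: float = 1.0
    overlap: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.contact, self.boundary, self.lad, self.overlap)
        if any(w < 0 for w in vals):
            raise ValueError("cost weights must be non-negative")
        if not any(w > 0 for w in vals):
            raise ValueError("at least one cost weight must be positive")


@dataclass(frozen=True)
class SolverConfig:
    """Solver parameters.

    ``n_successful_moves`` is the target number of accepted moves (the
    optimisation budget); ``max_attempts`` caps total proposals (default
    50x the target).  ``scheme`` is one of greedy / metropolis / anneal;
    annealing multiplies the temperature by ``cooling`` after every
    accepted move.
    """

    n_successful_moves: int = 2_000_000
    max_attempts: int | None = None
    scheme: str = "metropolis"
    temperature: float = 1.0
    cooling: float = 0.999995
    move_weights: dict[str, float] = field(
        default_factory=lambda: {m: 1.0 for m in MOVE_TYPES}
    )
    constrain_nucleus: bool = True
    weights: CostWeights = field(default_factory=CostWeights)
    lad_shell_fraction: float = 0.8
    max_translation_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_successful_moves < 0:
            raise ValueError("n_successful_moves must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.scheme not in ("greedy", "metropolis", "anneal"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        bad = set(self.move_weights) - set(MOVE_TYPES)
        if bad:
            raise ValueError(f"unknown move types {sorted(bad)}")
        if any(w < 0 for w in self.move_weights.values()) or not any(
            w > 0 for w in self.move_weights.values()
        ):
            raise ValueError("move weights must be >= 0 with at least one > 0")

    @property
    def attempt_cap(self) -> int:
        if self.max_attempts is not None:
            return self.max_attempts
        return max(50 * self.n_successful_moves, 1)


@dataclass(frozen=True)
class CostBreakdown:
    contact: float
    boundary: float
    lad: float
    overlap: float

    @property
    def total(self) -> float:
        return self.contact + self.boundary + self.lad + self.overlap


@dataclass(frozen=True)
class MoveProposal:
    move_type: str
    chrom: str
    indices: np.ndarray  # global bead indices whose centres change
    new_centers: np.ndarray


def _contact_cost(centers: np.ndarray, radii: np.ndarray, pairs: np.ndarray) -> float:
    if len(pairs) == 0:
        return 0.0
    d = np.linalg.norm(centers[pairs[:, 0]] - centers[pairs[:, 1]], axis=1)
    gap = d - (radii[pairs[:, 0]] + radii[pairs[:, 1]])
    return float(np.sum(np.maximum(0.0, gap)))


def _overlap_cost(centers: np.ndarray, radii: np.ndarray) -> float:
    n = len(centers)
    if n < 2:
        return 0.0
    total = 0.0
    # chunked upper-triangle scan keeps memory bounded for large genomes
    chunk = max(1, int(4e6 // max(n, 1)))
    for i0 in range(0, n - 1, chunk):
        i1 = min(i0 + chunk, n - 1)
        block = centers[i0:i1, None, :] - centers[None, i0 + 1 :, :]  # noqa: E203
        d = np.linalg.norm(block, axis=2)
        pen = (radii[i0:i1, None] + radii[None, i0 + 1 :]) - d  # noqa: E203
        rows = np.arange(i0, i1)
        cols = np.arange(i0 + 1, n)
        mask = cols[None, :] > rows[:, None]
        total += float(np.sum(np.maximum(0.0, pen)[mask]))
    return total


def _lad_cost(
    conf: GenomeConformation, centers: np.ndarray, config: SolverConfig
) -> float:
    mask = conf.periphery_mask
    if not mask.any():
        return 0.0
    t = conf.nucleus.scaled_radius(centers[mask])
    scale = conf.nucleus.characteristic_length
    return float(np.sum(np.maximum(0.0, config.lad_shell_fraction - t) * scale))


def evaluate_cost(
    conformation: GenomeConformation,
    constraints: np.ndarray | Sequence[tuple[str, str]] | None = None,
    config: SolverConfig | None = None,
) -> CostBreakdown:
    """Full objective evaluation.

    contact: sum over constraints of max(0, d - (r_a + r_b));
    boundary: sum of euclidean distance outside the nucleus (0 inside),
    active only when ``constrain_nucleus``;
    lad: hinge pushing periphery-flagged beads outside the inner shell
    (``lad_shell_fraction`` of the normalised radius);
    overlap: sum over bead pairs of max(0, (r_i + r_j) - d).
    """
    config = config or SolverConfig()
    pairs = _as_index_pairs(conformation, constraints)
    w = config.weights
    contact = w.contact * _contact_cost(conformation.centers, conformation.radii, pairs)
    boundary = 0.0
    if config.constrain_nucleus:
        boundary = w.boundary * float(
            np.sum(conformation.nucleus.boundary_excess(conformation.centers))
        )
    lad = w.lad * _lad_cost(conformation, conformation.centers, config)
    overlap = w.overlap * _overlap_cost(conformation.centers, conformation.radii)
    return CostBreakdown(contact=contact, boundary=boundary, lad=lad, overlap=overlap)


def _as_index_pairs(
    conf: GenomeConformation,
    constraints: np.ndarray | Sequence[tuple[str, str]] | None,
) -> np.ndarray:
    if constraints is None:
        return conf.constraint_index_pairs()
    arr = np.asarray(constraints)
    if arr.dtype.kind in "iu" and arr.ndim == 2:
        return arr.astype(np.intp)
    return conf.constraint_index_pairs(list(constraints))  # type: ignore[arg-type]


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _inside_scalar(nucleus, x: float, y: float, z: float) -> bool:
    a, b, c = nucleus.semi_axes
    return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0


def propose_move(
    conformation: GenomeConformation,
    config: SolverConfig,
    rng: np.random.Generator,
    chains: list[tuple[str, int, int]] | None = None,
) -> MoveProposal:
    """Draw one geometrically valid move proposal.

    Move types are sampled by ``config.move_weights``; a type that is
    invalid for the drawn chain (e.g. crankshaft on a 2-bead chain) is
    resampled.  Crankshaft keeps its two pivot beads fixed; translation
    components are bounded by ``max_translation_um``; rotation and
    translation are rigid for the whole chromosome.  ``chains`` is an
    optional precomputed list of (label, start, stop) chain bounds.
    """
    if chains is None:
        chains = [
            (label, sl.start, sl.stop) for label, sl in conformation.chain_slices.items()
        ]
    if not chains:
        raise ValueError("conformation has no chromosomes")
    names = [m for m in MOVE_TYPES if config.move_weights.get(m, 0.0) > 0]
    cum = np.cumsum([config.move_weights[m] for m in names])
    cum = cum / cum[-1]

    for _ in range(1000):
        label, start, stop = chains[int(rng.integers(len(chains)))]
        sl = slice(start, stop)
        n = stop - start
        move = names[int(np.searchsorted(cum, rng.random(), side="right"))]
        chain = conformation.centers[sl]
        radii = conformation.radii[sl]

        if move == "crankshaft":
            if n < 3:
                continue
            i = int(rng.integers(0, n - 2))
            j = int(rng.integers(i + 2, n))
            axis = chain[j] - chain[i]
            if np.linalg.norm(axis) < 1e-12:
                axis = _random_unit(rng)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            R = _rotation_matrix(axis, theta)
            seg = chain[i + 1 : j]
            new = (seg - chain[i]) @ R.T + chain[i]
            idx = np.arange(sl.start + i + 1, sl.start + j)
            return MoveProposal(move, label, idx, new)

        if move == "arm_rotation":
            if n < 2:
                continue
            p = int(rng.integers(0, n))
            toward_end = bool(rng.integers(2))
            if toward_end and p >= n - 1:
                toward_end = False
            if not toward_end and p == 0:
                toward_end = True
            if toward_end and p >= n - 1:
                continue
            R = _rotation_matrix(_random_unit(rng), rng.uniform(0.0, 2.0 * math.pi))
            if toward_end:
                seg = chain[p + 1 :]
                idx = np.arange(sl.start + p + 1, sl.stop)
            else:
                seg = chain[:p]
                idx = np.arange(sl.start, sl.start + p)
            new = (seg - chain[p]) @ R.T + chain[p]
            return MoveProposal(move, label, idx, new)

        if move == "arm_wiggle":
            if n < 2:
                continue
            p = int(rng.integers(0, n))
            toward_end = bool(rng.integers(2))
            if toward_end and p >= n - 1:
                toward_end = False
            if not toward_end and p == 0:
                toward_end = True
            if toward_end and p >= n - 1:
                continue
            order = range(p + 1, n) if toward_end else range(p - 1, -1, -1)
            new_chain = chain.copy()
            nucleus = conformation.nucleus
            idx_list = []
            for k in order:
                prev = k - 1 if toward_end else k + 1
                step = radii[prev] + radii[k]
                px, py, pz = new_chain[prev]
                for _try in range(1000):
                    u = rng.standard_normal(3)
                    s = step / math.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
                    cx, cy, cz = px + u[0] * s, py + u[1] * s, pz + u[2] * s
                    if _inside_scalar(nucleus, cx, cy, cz):
                        break
                new_chain[k] = (cx, cy, cz)
                idx_list.append(start + k)
            idx = np.array(idx_list, dtype=np.intp)
            return MoveProposal(move, label, idx, new_chain[[i - start for i in idx_list]])

        if move == "translation":
            delta = rng.uniform(-config.max_translation_um, config.max_translation_um, 3)
            idx = np.arange(sl.start, sl.stop)
            return MoveProposal(move, label, idx, chain + delta)

        if move == "rotation":
            R = _rotation_matrix(_random_unit(rng), rng.uniform(0.0, 2.0 * math.pi))
            centroid = chain.mean(axis=0)
            idx = np.arange(sl.start, sl.stop)
            return MoveProposal(move, label, idx, (chain - centroid) @ R.T + centroid)

    raise RuntimeError("failed to draw a valid move after 1000 resamples")


def accept_move(
    delta_cost: float,
    scheme: str,
    temperature: float,
    rng: np.random.Generator,
) -> bool:
    """Acceptance rule.

    greedy: accept iff the objective strictly improves.  metropolis /
    anneal: always accept non-worsening moves, otherwise accept with
    probability exp(-delta/T).
    """
    if not math.isfinite(delta_cost):
        raise ValueError("delta_cost must be finite")
    if scheme == "greedy":
        return delta_cost < 0.0
    if delta_cost <= 0.0:
        return True
    return bool(rng.random() < math.exp(-delta_cost / temperature))


@dataclass
class SolveResult:
    trace: np.ndarray  # total cost after each accepted move
    initial_cost: CostBreakdown
    final_cost: CostBreakdown
    n_attempted: int
    n_accepted: int
    attempted_by_type: dict[str, int]
    accepted_by_type: dict[str, int]
    hit_attempt_cap: bool


@njit(cache=True)
def _delta_kernel(  # noqa: PLR0913 - flat argument list for numba
    centers,
    radii,
    periph,
    idx,
    newc,
    pair_a,
    pair_b,
    indptr,
    rows,
    ax,
    ay,
    az,
    is_sphere,
    constrain,
    wc,
    wb,
    wl,
    wo,
    shell,
    charlen,
    pos,
    inidx,
):
    """new-minus-old weighted cost over all terms touching beads in idx."""
    k = len(idx)
    n = len(radii)
    for t in range(k):
        pos[idx[t]] = t
        inidx[idx[t]] = True
    delta = 0.0
    for t in range(k):
        i = idx[t]
        for old in range(2):
            if old == 1:
                x, y, z = centers[i, 0], centers[i, 1], centers[i, 2]
                sign = -1.0
            else:
                x, y, z = newc[t, 0], newc[t, 1], newc[t, 2]
                sign = 1.0
            tt = math.sqrt((x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2)
            if constrain and wb > 0.0:
                if is_sphere:
                    excess = math.sqrt(x * x + y * y + z * z) - ax
                else:
                    r = math.sqrt(x * x + y * y + z * z)
                    excess = r * (1.0 - 1.0 / tt) if tt > 1.0 else 0.0
                if excess > 0.0:
                    delta += sign * wb * excess
            if wl > 0.0 and periph[i] and tt < shell:
                delta += sign * wl * (shell - tt) * charlen
    # contact rows touching idx (rows with both endpoints moved are
    # handled once, by the smaller-indexed endpoint)
    if wc > 0.0:
        for t in range(k):
            i = idx[t]
            for rp in range(indptr[i], indptr[i + 1]):
                r = rows[rp]
                a = pair_a[r]
                b = pair_b[r]
                other = b if a == i else a
                if inidx[other] and other < i:
                    continue
                touch = radii[a] + radii[b]
                # old distance
                dx = centers[a, 0] - centers[b, 0]
                dy = centers[a, 1] - centers[b, 1]
                dz = centers[a, 2] - centers[b, 2]
                d_old = math.sqrt(dx * dx + dy * dy + dz * dz)
                # new distance (take moved coordinates where applicable)
                if inidx[a]:
                    axn, ayn, azn = newc[pos[a], 0], newc[pos[a], 1], newc[pos[a], 2]
                else:
                    axn, ayn, azn = centers[a, 0], centers[a, 1], centers[a, 2]
                if inidx[b]:
                    bxn, byn, bzn = newc[pos[b], 0], newc[pos[b], 1], newc[pos[b], 2]
                else:
                    bxn, byn, bzn = centers[b, 0], centers[b, 1], centers[b, 2]
                dx, dy, dz = axn - bxn, ayn - byn, azn - bzn
                d_new = math.sqrt(dx * dx + dy * dy + dz * dz)
                if d_old > touch:
                    delta -= wc * (d_old - touch)
                if d_new > touch:
                    delta += wc * (d_new - touch)
    # overlap: idx x non-idx plus pairs within idx
    if wo > 0.0:
        for t in range(k):
            i = idx[t]
            ri = radii[i]
            oxo, oyo, ozo = centers[i, 0], centers[i, 1], centers[i, 2]
            oxn, oyn, ozn = newc[t, 0], newc[t, 1], newc[t, 2]
            for j in range(n):
                if j == i or inidx[j]:
                    continue
                touch = ri + radii[j]
                dx = oxo - centers[j, 0]
                dy = oyo - centers[j, 1]
                dz = ozo - centers[j, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < touch * touch:
                    delta -= wo * (touch - math.sqrt(d2))
                dx = oxn - centers[j, 0]
                dy = oyn - centers[j, 1]
                dz = ozn - centers[j, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < touch * touch:
                    delta += wo * (touch - math.sqrt(d2))
            for s in range(t + 1, k):
                j = idx[s]
                touch = ri + radii[j]
                dx = oxo - centers[j, 0]
                dy = oyo - centers[j, 1]
                dz = ozo - centers[j, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < touch * touch:
                    delta -= wo * (touch - math.sqrt(d2))
                dx = oxn - newc[s, 0]
                dy = oyn - newc[s, 1]
                dz = ozn - newc[s, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < touch * touch:
                    delta += wo * (touch - math.sqrt(d2))
    for t in range(k):
        pos[idx[t]] = -1
        inidx[idx[t]] = False
    return delta


class _CostState:
    """Incremental cost bookkeeping for single-move deltas.

    A move changes the centres of a subset of beads of one chromosome;
    only cost terms touching those beads change.  Contact constraints
    are indexed per bead, overlap deltas are O(k n).
    """

    def __init__(
        self,
        conf: GenomeConformation,
        pairs: np.ndarray,
        config: SolverConfig,
    ) -> None:
        self.conf = conf
        self.config = config
        self.pairs = pairs
        self.centers = conf.centers
        self.radii = conf.radii
        self.periph = conf.periphery_mask
        n = conf.n_beads
        rows_per_bead: list[list[int]] = [[] for _ in range(n)]
        for row, (a, b) in enumerate(pairs):
            rows_per_bead[a].append(row)
            rows_per_bead[b].append(row)
        self.rows_per_bead = [np.array(r, dtype=np.intp) for r in rows_per_bead]
        # CSR layout + scratch buffers for the accelerated kernel
        self.indptr = np.zeros(n + 1, dtype=np.int64)
        for i, r in enumerate(rows_per_bead):
            self.indptr[i + 1] = self.indptr[i] + len(r)
        self.rows_flat = (
            np.concatenate(self.rows_per_bead)
            if any(len(r) for r in rows_per_bead)
            else np.empty(0, dtype=np.intp)
        ).astype(np.int64)
        self.pair_a = pairs[:, 0].astype(np.int64) if len(pairs) else np.empty(0, np.int64)
        self.pair_b = pairs[:, 1].astype(np.int64) if len(pairs) else np.empty(0, np.int64)
        self.pos_buf = np.full(n, -1, dtype=np.int64)
        self.inidx_buf = np.zeros(n, dtype=np.bool_)

    def _terms_at(self, idx: np.ndarray, centers_idx: np.ndarray) -> float:
        """Weighted cost of all terms that involve beads in ``idx``,
        evaluated with those beads at ``centers_idx``."""
        cfg, w = self.config, self.config.weights
        nuc = self.conf.nucleus
        total = 0.0
        # boundary
        if cfg.constrain_nucleus and w.boundary > 0:
            total += w.boundary * float(np.sum(nuc.boundary_excess(centers_idx)))
        # lad
        pm = self.periph[idx]
        if w.lad > 0 and pm.any():
            t = nuc.scaled_radius(centers_idx[pm])
            total += w.lad * float(
                np.sum(np.maximum(0.0, cfg.lad_shell_fraction - t))
                * nuc.characteristic_length
            )
        # contact: constraint rows with >=1 endpoint in idx
        if w.contact > 0 and len(self.pairs):
            rows = np.unique(np.concatenate([self.rows_per_bead[i] for i in idx]))
            if len(rows):
                pos = np.full(len(self.centers), -1, dtype=np.intp)
                pos[idx] = np.arange(len(idx))
                a, b = self.pairs[rows, 0], self.pairs[rows, 1]
                ca = np.where(pos[a, None] >= 0, centers_idx[pos[a]], self.centers[a])
                cb = np.where(pos[b, None] >= 0, centers_idx[pos[b]], self.centers[b])
                d = np.linalg.norm(ca - cb, axis=1)
                gap = d - (self.radii[a] + self.radii[b])
                total += w.contact * float(np.sum(np.maximum(0.0, gap)))
        # overlap: pairs (idx x non-idx) + pairs within idx
        if w.overlap > 0:
            others = np.ones(len(self.centers), dtype=bool)
            others[idx] = False
            co = self.centers[others]
            if len(co):
                d = np.linalg.norm(centers_idx[:, None, :] - co[None, :, :], axis=2)
                pen = (self.radii[idx][:, None] + self.radii[others][None, :]) - d
                total += w.overlap * float(np.sum(np.maximum(0.0, pen)))
            k = len(idx)
            if k > 1:
                dd = np.linalg.norm(
                    centers_idx[:, None, :] - centers_idx[None, :, :], axis=2
                )
                pen = (self.radii[idx][:, None] + self.radii[idx][None, :]) - dd
                iu = np.triu_indices(k, 1)
                total += w.overlap * float(np.sum(np.maximum(0.0, pen[iu])))
        return total

    def delta(self, proposal: MoveProposal) -> float:
        idx = proposal.indices
        if _HAVE_NUMBA:
            nuc = self.conf.nucleus
            w = self.config.weights
            return float(
                _delta_kernel(
                    self.centers,
                    self.radii,
                    self.periph,
                    idx.astype(np.int64),
                    np.ascontiguousarray(proposal.new_centers),
                    self.pair_a,
                    self.pair_b,
                    self.indptr,
                    self.rows_flat,
                    nuc.semi_axes[0],
                    nuc.semi_axes[1],
                    nuc.semi_axes[2],
                    nuc.kind == "sphere",
                    self.config.constrain_nucleus,
                    w.contact,
                    w.boundary,
                    w.lad,
                    w.overlap,
                    self.config.lad_shell_fraction,
                    nuc.characteristic_length,
                    self.pos_buf,
                    self.inidx_buf,
                )
            )
        old = self._terms_at(idx, self.centers[idx])
        new = self._terms_at(idx, proposal.new_centers)
        return new - old

    def apply(self, proposal: MoveProposal) -> None:
        self.centers[proposal.indices] = proposal.new_centers


def solve(
    conformation: GenomeConformation,
    constraints: np.ndarray | Sequence[tuple[str, str]] | None = None,
    config: SolverConfig | None = None,
    checkpoint: Callable[[int, float], None] | None = None,
) -> tuple[GenomeConformation, SolveResult]:
    """Optimise a conformation; returns a new conformation and the trace.

    Terminates after ``n_successful_moves`` accepted moves or
    ``attempt_cap`` attempts, whichever comes first.  Bit-reproducible
    given ``config.seed``.  ``checkpoint(accepted, total_cost)`` is
    called every 10,000 accepted moves when provided.
    """
    config = config or SolverConfig()
    pairs = _as_index_pairs(conformation, constraints)
    work = conformation.copy()
    initial = evaluate_cost(work, pairs, config)
    if config.n_successful_moves == 0:
        return work, SolveResult(
            trace=np.empty(0),
            initial_cost=initial,
            final_cost=initial,
            n_attempted=0,
            n_accepted=0,
            attempted_by_type={m: 0 for m in MOVE_TYPES},
            accepted_by_type={m: 0 for m in MOVE_TYPES},
            hit_attempt_cap=False,
        )

    rng = np.random.default_rng(config.seed)
    state = _CostState(work, pairs, config)
    chains = [(label, sl.start, sl.stop) for label, sl in work.chain_slices.items()]
    total = initial.total
    temperature = config.temperature
    trace: list[float] = []
    attempted = {m: 0 for m in MOVE_TYPES}
    accepted = {m: 0 for m in MOVE_TYPES}
    n_att = 0
    n_acc = 0
    cap = config.attempt_cap

    while n_acc < config.n_successful_moves and n_att < cap:
        proposal = propose_move(work, config, rng, chains)
        n_att += 1
        attempted[proposal.move_type] += 1
        delta = state.delta(proposal)
        if accept_move(delta, config.scheme, temperature, rng):
            state.apply(proposal)
            total += delta
            n_acc += 1
            accepted[proposal.move_type] += 1
            trace.append(total)
            if config.scheme == "anneal":
                temperature *= config.cooling
            if checkpoint is not None and n_acc % 10_000 == 0:
                checkpoint(n_acc, total)

    if n_acc == 0 and config.n_successful_moves > 0:
        warnings.warn(
            "attempt cap reached before any move was accepted; "
            "returning best-so-far (input) conformation",
            RuntimeWarning,
            stacklevel=2,
        )
    final = evaluate_cost(work, pairs, config)
    return work, SolveResult(
        trace=np.asarray(trace),
        initial_cost=initial,
        final_cost=final,
        n_attempted=n_att,
        n_accepted=n_acc,
        attempted_by_type=attempted,
        accepted_by_type=accepted,
        hit_attempt_cap=n_att >= cap and n_acc < config.n_successful_moves,
    )
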