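"""End-to-end pipeline: synthesize -> solve -> analyze -> irradiate -> cluster.

A run is described by one declarative YAML config.  Every stochastic
stage derives its seed from the base seed and the geometry index, so
each geometry of an ensemble is independently reproducible and a rerun
of the same config is bit-identical (verified via output hashes in the
manifest).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, damage, genome, solver, tracks

logger = logging.getLogger("gnome")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative pipeline configuration.

    Exactly one of ``gtrack`` (input file) or ``synth`` (generator
    parameters, possibly empty for defaults) must be provided.
    """

    gtrack: str | None = None
    synth: dict | None = None
    nucleus_kind: str = "sphere"
    semi_axes: tuple[float, float, float] = (5.0, 5.0, 5.0)
    occupancy: float = 0.15
    n_geometries: int = 200
    n_exposures: int = 50
    iterations: int = 2_000_000
    scheme: str = "metropolis"
    constrain_nucleus: bool = True
    mode: str = "photon"  # photon | tracks
    dose_gy: float = 1.0
    let: float = 10.0
    radii_nm: tuple[float, ...] = (100.0, 250.0, 500.0, 1000.0)
    base_seed: int = 0

    def __post_init__(self) -> None:
        if (self.gtrack is None) == (self.synth is None):
            raise PipelineError("config", "provide exactly one of 'gtrack' or 'synth'")
        if self.mode not in ("photon", "tracks"):
            raise PipelineError("config", f"unknown exposure mode {self.mode!r}")

    @property
    def nucleus(self) -> genome.NucleusShape:
        return genome.NucleusShape(self.nucleus_kind, tuple(self.semi_axes))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "semi_axes" in data:
            data["semi_axes"] = tuple(data["semi_axes"])
        if "radii_nm" in data:
            data["radii_nm"] = tuple(data["radii_nm"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["semi_axes"] = list(self.semi_axes)
        data["radii_nm"] = list(self.radii_nm)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    Emits, per geometry, a coordinates TSV and a CMM file; per exposure
    an SDD file; a tidy metrics TSV across the ensemble; and a manifest
    recording seeds, versions and output hashes.
    """
    from . import __version__

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "base_seed": config.base_seed,
        "geometries": [],
        "status": "running",
    }
    manifest_path = out / "manifest.json"

    try:
        if config.gtrack is not None:
            specs, _meta = genome.read_gtrack(config.gtrack)
        else:
            synth_cfg = genome.GenomeConfig(**(config.synth or {}))
            specs = genome.synthesize_genome(synth_cfg, seed=config.base_seed)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        _write_manifest(manifest_path, manifest, "failed: inputs")
        raise PipelineError("inputs", str(exc)) from exc

    nucleus = config.nucleus
    constraints = genome.contact_pairs(specs)
    metric_rows = []

    for g in range(config.n_geometries):
        seed = config.base_seed + g
        entry: dict = {"index": g, "seed": seed, "files": {}}
        try:
            conf = genome.build_initial_conformation(
                specs, nucleus, seed=seed, occupancy=config.occupancy
            )
            scfg = solver.SolverConfig(
                n_successful_moves=config.iterations,
                scheme=config.scheme,
                constrain_nucleus=config.constrain_nucleus,
                seed=seed,
            )
            solved, result = solver.solve(
                conf,
                constraints,
                scfg,
                checkpoint=lambda acc, cost: logger.info(
                    "geometry=%d accepted=%d cost=%.4f", g, acc, cost
                ),
            )
        except Exception as exc:  # noqa: BLE001
            manifest["geometries"].append(entry)
            _write_manifest(manifest_path, manifest, f"failed: solve (geometry {g})")
            raise PipelineError("solve", f"geometry {g}: {exc}") from exc

        coords_path = out / f"geometry_{g:04d}.coords.tsv"
        cmm_path = out / f"geometry_{g:04d}.cmm"
        trace_path = out / f"geometry_{g:04d}.trace.tsv"
        genome.write_coords(solved, coords_path)
        genome.write_cmm(solved, cmm_path)
        pd.DataFrame({"total_cost": result.trace}).to_csv(
            trace_path, sep="\t", index_label="accepted_move"
        )
        entry["files"]["coords"] = coords_path.name
        entry["files"]["cmm"] = cmm_path.name
        entry["files"]["sdd"] = []

        ps = analysis.LabeledPointSet.from_conformation(solved)
        for radius_nm in config.radii_nm:
            r_um = radius_nm / 1000.0
            for metric in ("total", "inter", "intra"):
                metric_rows.append(
                    (g, "beads", radius_nm, metric,
                     analysis.cluster_counts(ps, r_um, metric).mean)
                )

        for e in range(config.n_exposures):
            exp_seed = (seed * 100_003 + e) % (2**31)
            rng = np.random.default_rng(exp_seed)
            try:
                if config.mode == "photon":
                    sites = damage.photon_exposure(solved, config.dose_gy, rng=rng)
                else:
                    sites, _dep = tracks.ion_exposure(
                        solved, tracks.TrackConfig(let=config.let), config.dose_gy, rng=rng
                    )
            except Exception as exc:  # noqa: BLE001
                manifest["geometries"].append(entry)
                _write_manifest(
                    manifest_path, manifest, f"failed: irradiate (geometry {g}, exposure {e})"
                )
                raise PipelineError("irradiate", f"geometry {g} exposure {e}: {exc}") from exc
            sdd_path = out / f"geometry_{g:04d}.exposure_{e:03d}.sdd"
            damage.write_sdd(
                sites,
                {
                    "Dose or fluence": f"1, {config.dose_gy}",
                    "Chromosome sizes": damage.chromosome_sizes_header(solved),
                    "Seed": str(exp_seed),
                },
                sdd_path,
            )
            entry["files"]["sdd"].append(sdd_path.name)
            logger.info("geometry=%d exposure=%d sites=%d", g, e, len(sites))
            dsbs = [s for s in sites if s.kind == "DSB"]
            if len(dsbs) >= 2:
                dsb_ps = analysis.LabeledPointSet.from_sites(dsbs, nucleus)
                for radius_nm in config.radii_nm:
                    r_um = radius_nm / 1000.0
                    for metric in ("total", "inter", "intra"):
                        metric_rows.append(
                            (g, f"dsb_exposure_{e}", radius_nm, metric,
                             analysis.cluster_counts(dsb_ps, r_um, metric).mean)
                        )
        manifest["geometries"].append(entry)

    metrics = pd.DataFrame(
        metric_rows, columns=["geometry", "objects", "radius_nm", "metric", "value"]
    )
    metrics_path = out / "metrics.tsv"
    metrics.to_csv(metrics_path, sep="\t", index=False)

    hashes = {}
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json":
            hashes[p.name] = _sha256(p)
    manifest["hashes"] = hashes
    _write_manifest(manifest_path, manifest, "complete")
    return out


def _write_manifest(path: Path, manifest: dict, status: str) -> None:
    manifest["status"] = status
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
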