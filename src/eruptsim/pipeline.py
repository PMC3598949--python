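"""End-to-end orchestration: generate -> solve -> analyze -> report.

A run is configured by a :class:`RunConfig` (loadable from YAML), writes
all artefacts into one self-describing output directory, and records a
manifest with stage timings, content hashes of every output file, the
seed and the package version, so every reported number is traceable to a
manifest-listed input.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

import eruptsim
from eruptsim.caps import (
    CapSpec,
    classify_exceptions,
    pool_caps,
    select_cap_elements,
    summarize_cap,
    tooth_axis,
)
from eruptsim.geometry import GeometryConfig, TetMesh, build_labelled_grid, voxels_to_tets
from eruptsim.materials import MaterialTable, RegionLabel, TOOTH_LABELS
from eruptsim.metrics import element_records
from eruptsim.scene import SceneSpec, build_scene_load_case
from eruptsim.solver import reaction_forces, recover_strain_stress, solve
from eruptsim.vtkio import read_vtk, write_vtk

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "read_write_mesh_and_fields"]

_VOIGT = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2)]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    material_overrides: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    modes: Tuple[str, ...] = ("incisive", "unilateral_molar")
    cap_depth: float = 3.0
    exception_margin: float = 4.0
    tooth_name: str = "first_premolar"
    tooth_side: str = "left"
    seed: int = 0
    muscle_cross_section: float = 6.0
    muscle_constant: float = 40.0
    activation: Dict[str, float] = field(
        default_factory=lambda: {"incisive": 0.4, "unilateral_molar": 0.8}
    )

    def __post_init__(self) -> None:
        if isinstance(self.geometry, dict):
            self.geometry = GeometryConfig(**self.geometry)
        self.modes = tuple(self.modes)
        for mode in self.modes:
            if mode not in ("incisive", "unilateral_molar"):
                raise ValueError(f"unknown bite mode '{mode}'")
            if mode not in self.activation:
                raise ValueError(f"no muscle activation given for mode '{mode}'")
        if not self.cap_depth > 0:
            raise ValueError("cap_depth must be positive")
        # materials validated eagerly so bad values fail before meshing
        self.materials()

    def materials(self) -> MaterialTable:
        return MaterialTable.with_overrides(self.material_overrides)

    def scene(self) -> SceneSpec:
        return SceneSpec(
            geometry=self.geometry,
            muscle_cross_section=self.muscle_cross_section,
            muscle_constant=self.muscle_constant,
            activation=dict(self.activation),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        # round-trip through JSON to turn tuples into YAML-safe lists
        data = json.loads(json.dumps(asdict(self)))
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class RunManifest:
    """Provenance record of a run."""

    seed: int
    version: str
    stages: Dict[str, float] = field(default_factory=dict)
    files: Dict[str, str] = field(default_factory=dict)
    info: Dict[str, object] = field(default_factory=dict)

    def add_file(self, outdir: Path, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[str(path.relative_to(outdir))] = digest

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def tensors_to_cell_data(tensors) -> Dict[str, np.ndarray]:
    """Flatten symmetric tensors to 6-component Voigt cell arrays."""
    out = {}
    for name, arr in [("strain", tensors.strain), ("stress", tensors.stress)]:
        out[name] = np.stack([arr[:, i, j] for i, j in _VOIGT], axis=1)
    return out


def cell_data_to_tensor(voigt: np.ndarray) -> np.ndarray:
    """Rebuild (m, 3, 3) symmetric tensors from Voigt cell arrays."""
    m = voigt.shape[0]
    t = np.zeros((m, 3, 3))
    for k, (i, j) in enumerate(_VOIGT):
        t[:, i, j] = voigt[:, k]
        t[:, j, i] = voigt[:, k]
    return t


def read_write_mesh_and_fields(path) -> Tuple[TetMesh, Dict, Dict]:
    """Read a mesh plus its point/cell data fields from legacy VTK."""
    return read_vtk(path)


def _analyze_mode(
    config: RunConfig,
    mesh: TetMesh,
    records: pd.DataFrame,
    mode: str,
) -> List[Tuple[object, pd.DataFrame]]:
    """Cap summaries (with per-cap records) for one solved mode."""
    tooth_mask = mesh.mask(TOOTH_LABELS)
    axis = tooth_axis(mesh, tooth_mask)
    follicle_mask = mesh.mask(RegionLabel.FOLLICLE_PDL)
    follicle_records = records[
        records["region"] == RegionLabel.FOLLICLE_PDL.value
    ].reset_index(drop=True)
    centroids = mesh.centroids()[follicle_mask]
    out = []
    for kind in ("coronal", "apical"):
        spec = CapSpec(
            tooth=config.tooth_name,
            side=config.tooth_side,
            kind=kind,
            axis=tuple(axis),
            depth=config.cap_depth,
        )
        member = select_cap_elements(centroids, spec)
        cap_records = follicle_records[member].reset_index(drop=True)
        out.append((summarize_cap(spec, mode, cap_records), cap_records))
    return out


def run_pipeline(config: RunConfig, outdir) -> RunManifest:
    """Execute generate, solve (per mode), analyze and report stages.

    Deterministic for a fixed seed: repeated runs produce byte-identical
    CSV outputs.  Stage failures propagate with the stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, version=eruptsim.__version__)
    config.to_yaml(outdir / "config.yaml")
    manifest.add_file(outdir, outdir / "config.yaml")
    materials = config.materials()
    scene = config.scene()

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest.info["failed_stage"] = name
            manifest.save(outdir / "manifest.json")
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        manifest.stages[name] = round(time.perf_counter() - t0, 4)
        return result

    # generate
    def _generate():
        grid = build_labelled_grid(config.geometry)
        mesh = voxels_to_tets(grid, config.geometry.pitch)
        write_vtk(outdir / "mesh.vtk", mesh)
        manifest.add_file(outdir, outdir / "mesh.vtk")
        manifest.info["n_nodes"] = mesh.n_nodes
        manifest.info["n_elements"] = mesh.n_elements
        logger.info("generated mesh: %d nodes, %d elements", mesh.n_nodes, mesh.n_elements)
        return mesh

    mesh = stage("generate", _generate)

    summaries: List[Tuple[object, pd.DataFrame]] = []
    for mode in config.modes:
        def _solve(mode=mode):
            load = build_scene_load_case(mesh, scene, mode)
            u = solve(mesh, materials, load)
            tensors = recover_strain_stress(mesh, materials, u)
            reactions = reaction_forces(mesh, materials, u, load)
            total_reaction = np.zeros(3)
            for (node, ax), val in reactions.items():
                total_reaction[ax] += val
            applied = load.forces.sum(axis=0)
            residual = np.linalg.norm(total_reaction + applied) / max(
                np.linalg.norm(applied), 1e-30
            )
            manifest.info[f"equilibrium_residual_{mode}"] = float(residual)
            manifest.info[f"vertical_reaction_N_{mode}"] = float(
                sum(v for (n, a), v in reactions.items() if a == 2)
            )
            logger.info("%s: equilibrium residual %.2e", mode, residual)
            cell_data = tensors_to_cell_data(tensors)
            records = element_records(mesh, tensors, materials)
            cell_data.update(
                {
                    "volume": records["volume"].to_numpy(),
                    "sigma_h": records["sigma_h"].to_numpy(),
                    "S_e": records["S_e"].to_numpy(),
                    "bru": records["bru"].to_numpy(),
                }
            )
            path = outdir / f"solution_{mode}.vtk"
            write_vtk(path, mesh, point_data={"displacement": u}, cell_data=cell_data)
            manifest.add_file(outdir, path)
            return records

        records = stage(f"solve_{mode}", _solve)
        summaries.extend(
            stage(f"analyze_{mode}", lambda m=mode, r=records: _analyze_mode(config, mesh, r, m))
        )

    def _report():
        rows = []
        for summary, _ in summaries:
            for basis, pct in [
                ("volume", summary.compression_volume_pct),
                ("bru", summary.compression_bru_pct),
            ]:
                rows.append(
                    {
                        "side": summary.spec.side,
                        "load": summary.load_mode,
                        "tooth": summary.spec.tooth,
                        "cap": summary.spec.kind,
                        "basis": basis,
                        "compression_pct": pct,
                        "total_volume_mm3": summary.total_volume,
                    }
                )
        cap_table = pd.DataFrame(rows)
        cap_table.to_csv(outdir / "cap_summary.csv", index=False)
        manifest.add_file(outdir, outdir / "cap_summary.csv")

        pooled_rows = []
        for mode in config.modes:
            for kind in ("coronal", "apical"):
                subset = [
                    (s, r)
                    for s, r in summaries
                    if s.load_mode == mode and s.spec.kind == kind
                ]
                pooled = pool_caps(subset)
                for basis, pct in [
                    ("volume", pooled.compression_volume_pct),
                    ("bru", pooled.compression_bru_pct),
                ]:
                    pooled_rows.append(
                        {"load": mode, "cap": kind, "basis": basis, "compression_pct": pct}
                    )
        pd.DataFrame(pooled_rows).to_csv(outdir / "pooled_summary.csv", index=False)
        manifest.add_file(outdir, outdir / "pooled_summary.csv")

        for summary, _ in summaries:
            tag = f"{summary.spec.kind}_{summary.load_mode}"
            summary.stress_histogram.table.to_csv(
                outdir / f"histogram_stress_{tag}.csv", index_label="bin"
            )
            summary.bru_histogram.table.to_csv(
                outdir / f"histogram_bru_{tag}.csv", index_label="bin"
            )
            manifest.add_file(outdir, outdir / f"histogram_stress_{tag}.csv")
            manifest.add_file(outdir, outdir / f"histogram_bru_{tag}.csv")

        exc_frames = []
        for basis in ("volume", "bru"):
            report = classify_exceptions(
                cap_table,
                basis=basis,
                margin=config.exception_margin,
                require_full_grid=False,
            )
            frame = report.table.copy()
            exc_frames.append(frame)
            manifest.info[f"n_exceptions_{basis}"] = report.n_exceptions
        pd.concat(exc_frames, ignore_index=True).to_csv(
            outdir / "exceptions.csv", index=False
        )
        manifest.add_file(outdir, outdir / "exceptions.csv")

    stage("report", _report)
    manifest.save(outdir / "manifest.json")
    return manifest
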