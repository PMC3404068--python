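"""Output writers: legacy ASCII VTK time series, CSV summaries, manifests.

One VTK unstructured-grid file is written per recorded day with the
phenotype code map and the field snapshots as cell data, viewable in any
standard VTK-based viewer.  The per-day CSV summary tabulates tissue
volume fractions within the callus and the healing status, and a JSON
manifest records the complete configuration, the phenotype code table and
the package version so that every run is self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .geometry import Mesh, REGION_CALLUS
from .materials import PHENOTYPE_CODES, Phenotype
from .orchestrator import DayRecord, SimulationConfig, healing_day

__all__ = ["write_vtk", "write_outputs", "summary_table"]

_BONE = (int(Phenotype.IMMATURE_BONE), int(Phenotype.MATURE_BONE))


def write_vtk(
    mesh: Mesh,
    path: str,
    cell_data: Optional[Dict[str, np.ndarray]] = None,
    point_data: Optional[Dict[str, np.ndarray]] = None,
    title: str = "callusim fields",
) -> None:
    """Write the mesh and fields as a legacy ASCII VTK unstructured grid."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for r, z in mesh.nodes:
            fh.write(f"{r:.10g} {z:.10g} 0\n")
        fh.write(f"CELLS {mesh.n_elems} {mesh.n_elems * 5}\n")
        for quad in mesh.elems:
            fh.write("4 " + " ".join(str(int(n)) for n in quad) + "\n")
        fh.write(f"CELL_TYPES {mesh.n_elems}\n")
        fh.write("9\n" * mesh.n_elems)
        if cell_data:
            fh.write(f"CELL_DATA {mesh.n_elems}\n")
            for name, arr in cell_data.items():
                _write_scalar(fh, name, np.asarray(arr))
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                _write_scalar(fh, name, np.asarray(arr))


def _write_scalar(fh, name: str, arr: np.ndarray) -> None:
    kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
    fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
    for v in arr:
        fh.write(f"{v:d}\n" if kind == "int" else f"{v:.10g}\n")


def summary_table(
    history: Sequence[DayRecord], mesh: Mesh, gap_mask: np.ndarray
) -> pd.DataFrame:
    """Per-day tissue volume fractions of the callus region + healing flag."""
    callus = mesh.region == REGION_CALLUS
    vol = mesh.volume
    total = vol[callus].sum()
    rows = []
    for rec in history:
        row: Dict[str, object] = {"day": rec.day}
        for p in Phenotype:
            row[f"frac_{p.name.lower()}"] = float(
                vol[callus & (rec.phenotype == int(p))].sum() / total
            )
        bone_full = np.isin(rec.phenotype, _BONE) & (rec.fill >= 1.0 - 1e-9)
        row["gap_healed"] = bool(np.all(bone_full[gap_mask]))
        row["supplied_fraction"] = float(rec.supplied[callus].mean())
        row["mean_o2_mmhg"] = float(rec.o2_elem[callus].mean())
        row["resorbed"] = rec.resorbed
        row["matured"] = rec.matured
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(
    history: Sequence[DayRecord],
    mesh: Mesh,
    config: SimulationConfig,
    out_dir: str,
    gap_mask: Optional[np.ndarray] = None,
    every: int = 1,
) -> Dict[str, object]:
    """Write the VTK series, CSV summary and JSON manifest for one run.

    Returns the manifest dictionary.  ``every`` thins the VTK series (the
    CSV summary always covers every recorded day).
    """
    if len(history) == 0:
        raise ValueError("empty history")
    os.makedirs(out_dir, exist_ok=True)
    from .config import dump_config  # local import to avoid a cycle

    for rec in history:
        if (rec.day - 1) % every and rec.day != history[-1].day:
            continue
        write_vtk(
            mesh,
            os.path.join(out_dir, f"day_{rec.day:04d}.vtk"),
            cell_data={
                "phenotype": rec.phenotype.astype(np.int64),
                "fill": rec.fill,
                "gamma_pct": rec.gamma_pct,
                "fluid_velocity_um_s": rec.fluid_velocity,
                "supplied": rec.supplied.astype(np.int64),
                "o2_mmhg": rec.o2_elem,
                "cell_density": rec.n_elem,
                "vessel_pct": rec.vessel_elem,
                "young_eff_mpa": rec.young_eff,
                "region": mesh.region,
            },
            title=f"day {rec.day}",
        )
    if gap_mask is None:
        gap_mask = np.zeros(mesh.n_elems, dtype=bool)
    df = summary_table(history, mesh, gap_mask)
    df.to_csv(os.path.join(out_dir, "summary.csv"), index=False)
    cfg_dict = dump_config(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=float)
    manifest = {
        "code_version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "phenotype_codes": PHENOTYPE_CODES,
        "days_recorded": len(history),
        "healing_day": healing_day(history, gap_mask) if gap_mask.any() else None,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest
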