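"""File formats and surface-mesh utilities.

CSV dialects (all plain text, lengths in mm, pressures in mmHg,
stresses in MPa, strains as fractions unless a percent flag is used):

* tensile curves   ``specimen_id, material, strain, stress_mpa``
* vessel geometry  ``z_mm, inner_radius_mm, thickness_mm`` (+ markers JSON)
* PV log           ``step, injected_mm3, pressure_mmHg``
* diameter series  ``site, pressure_mmHg, diameter_mm``
* thickness grid   ``model_id, branch, slice, position, thickness_mm``
* inflation result ``pressure_mmHg, volume_mm3, station, diameter_mm`` (long)

Modulus tables are JSON ``{"nodes": [[eps_m, E_mpa], ...], "schedule": ...}``.
STL surfaces (ASCII or binary) are read through :mod:`trimesh`; planar
cross-sections are cut by triangle--plane intersection and chained into
closed loops for perimeter measurement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import trimesh

from .characterization import (
    ComplianceReport,
    DiameterSeries,
    PVMeasurement,
    ThicknessGrid,
)
from .inflation import InflationResult, VesselGeometry
from .material import ModulusTable, StressStrainCurve

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceMesh",
    "read_stl",
    "slice_perimeter",
    "read_tensile_csv",
    "write_tensile_csv",
    "read_geometry_csv",
    "write_geometry_csv",
    "read_markers_json",
    "write_markers_json",
    "read_pv_csv",
    "write_pv_csv",
    "read_diameter_csv",
    "write_diameter_csv",
    "read_thickness_csv",
    "write_thickness_csv",
    "read_modulus_table",
    "write_modulus_table",
    "write_inflation_csv",
    "read_inflation_csv",
    "write_report_json",
]


# ---------------------------------------------------------------------------
# surface meshes


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangle soup in mm: array of shape (n_triangles, 3 vertices, 3 coords)."""

    triangles: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        tri = np.asarray(self.triangles, dtype=float)
        object.__setattr__(self, "triangles", tri)
        if tri.ndim != 3 or tri.shape[1:] != (3, 3):
            raise ValueError("triangles must have shape (n, 3, 3)")
        if tri.shape[0] < 4:
            raise ValueError("a surface mesh needs at least 4 triangles")
        if not np.all(np.isfinite(tri)):
            raise ValueError("mesh coordinates must be finite")

    @property
    def n_triangles(self) -> int:
        return int(self.triangles.shape[0])


def read_stl(path: str | Path) -> SurfaceMesh:
    """Read an ASCII or binary STL file.

    Degenerate (zero-area) triangles are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        mesh = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # pragma: no cover - error text from trimesh
        raise ValueError(f"malformed STL file {path}: {exc}") from exc
    tri = np.asarray(mesh.triangles, dtype=float)
    if tri.shape[0] == 0:
        raise ValueError(f"STL file {path} contains no triangles")
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    area2 = np.linalg.norm(np.cross(e1, e2), axis=1)
    keep = area2 > 0.0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d degenerate triangles from %s", dropped, path.name)
    return SurfaceMesh(triangles=tri[keep], name=path.stem)


def _chain_loops(segments: np.ndarray, tol: float = 1e-6) -> list[np.ndarray]:
    """Chain unordered intersection segments into polylines/loops.

    Greedy endpoint matching with absolute tolerance ``tol`` (mm).  Each
    returned array is the ordered vertex list of one chain; closed loops
    repeat their first vertex at the end.
    """
    remaining = list(range(segments.shape[0]))
    loops: list[np.ndarray] = []
    while remaining:
        i = remaining.pop()
        chain = [segments[i, 0], segments[i, 1]]
        extended = True
        while extended and remaining:
            extended = False
            tail = chain[-1]
            head = chain[0]
            for j in list(remaining):
                p0, p1 = segments[j]
                if np.linalg.norm(p0 - tail) < tol:
                    chain.append(p1)
                elif np.linalg.norm(p1 - tail) < tol:
                    chain.append(p0)
                elif np.linalg.norm(p1 - head) < tol:
                    chain.insert(0, p0)
                elif np.linalg.norm(p0 - head) < tol:
                    chain.insert(0, p1)
                else:
                    continue
                remaining.remove(j)
                extended = True
                break
        loops.append(np.asarray(chain))
    return loops


def slice_perimeter(
    mesh: SurfaceMesh,
    plane_point,
    plane_normal,
    tol: float = 1e-6,
) -> tuple[list[float], float]:
    """Perimeters of the cross-section loops cut by a plane.

    Triangle--plane intersection segments are chained into loops by
    endpoint matching (tolerance ``tol`` mm); the perimeter of each loop
    is the sum of its segment lengths.  Returns (per-loop perimeters,
    total).  An empty result means the plane misses the mesh.
    """
    tmesh = trimesh.Trimesh(
        vertices=mesh.triangles.reshape(-1, 3),
        faces=np.arange(mesh.n_triangles * 3).reshape(-1, 3),
        process=False,
    )
    segments = trimesh.intersections.mesh_plane(
        tmesh, np.asarray(plane_normal, dtype=float), np.asarray(plane_point, dtype=float)
    )
    if segments is None or len(segments) == 0:
        logger.warning("slicing plane does not intersect the mesh")
        return [], 0.0
    loops = _chain_loops(np.asarray(segments), tol=tol)
    perims = []
    for loop in loops:
        length = float(np.sum(np.linalg.norm(np.diff(loop, axis=0), axis=1)))
        if length <= tol:
            logger.warning("near-degenerate slice loop of length %.3g mm", length)
        perims.append(length)
    return perims, float(sum(perims))


# ---------------------------------------------------------------------------
# CSV / JSON formats


def read_tensile_csv(path: str | Path, percent: bool = False) -> list[StressStrainCurve]:
    """Read tensile curves; ``percent`` converts strain from % to fraction."""
    df = pd.read_csv(path)
    required = {"specimen_id", "material", "strain", "stress_mpa"}
    if not required.issubset(df.columns):
        raise ValueError(f"tensile CSV must have columns {sorted(required)}")
    scale = 0.01 if percent else 1.0
    curves = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        curves.append(
            StressStrainCurve(
                strain=grp["strain"].to_numpy() * scale,
                stress=grp["stress_mpa"].to_numpy(),
                specimen_id=str(sid),
                material=str(grp["material"].iloc[0]),
            )
        )
    return curves


def write_tensile_csv(curves: Iterable[StressStrainCurve], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "specimen_id": c.specimen_id,
                "material": c.material,
                "strain": c.strain,
                "stress_mpa": c.stress,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_geometry_csv(path: str | Path, markers: str | Path | None = None) -> VesselGeometry:
    df = pd.read_csv(path)
    required = {"z_mm", "inner_radius_mm", "thickness_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"geometry CSV must have columns {sorted(required)}")
    site_markers = read_markers_json(markers) if markers else {}
    return VesselGeometry(
        z=df["z_mm"].to_numpy(),
        inner_radius=df["inner_radius_mm"].to_numpy(),
        thickness=df["thickness_mm"].to_numpy(),
        site_markers=site_markers,
    )


def write_geometry_csv(
    geom: VesselGeometry, path: str | Path, markers: str | Path | None = None
) -> None:
    pd.DataFrame(
        {"z_mm": geom.z, "inner_radius_mm": geom.inner_radius, "thickness_mm": geom.thickness}
    ).to_csv(path, index=False)
    if markers:
        write_markers_json(geom.site_markers, markers)


def read_markers_json(path: str | Path) -> dict[str, int]:
    with open(path) as fh:
        data = json.load(fh)
    return {str(k): int(v) for k, v in data.items()}


def write_markers_json(markers: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: int(v) for k, v in markers.items()}, fh, indent=2)
        fh.write("\n")


def read_pv_csv(path: str | Path, baseline_volume: float | None = None) -> PVMeasurement:
    df = pd.read_csv(path)
    required = {"injected_mm3", "pressure_mmHg"}
    if not required.issubset(df.columns):
        raise ValueError(f"PV CSV must have columns {sorted(required)}")
    if baseline_volume is None:
        baseline_volume = float(df.attrs.get("baseline_volume", 0.0))
        if "baseline_volume_mm3" in df.columns:
            baseline_volume = float(df["baseline_volume_mm3"].iloc[0])
    return PVMeasurement(
        injected=df["injected_mm3"].to_numpy(),
        pressure=df["pressure_mmHg"].to_numpy(),
        baseline_volume=baseline_volume,
    )


def write_pv_csv(m: PVMeasurement, path: str | Path) -> None:
    pd.DataFrame(
        {
            "step": np.arange(1, m.injected.size + 1),
            "injected_mm3": m.injected,
            "pressure_mmHg": m.pressure,
            "baseline_volume_mm3": m.baseline_volume,
        }
    ).to_csv(path, index=False)


def read_diameter_csv(path: str | Path) -> list[DiameterSeries]:
    df = pd.read_csv(path)
    required = {"site", "pressure_mmHg", "diameter_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"diameter CSV must have columns {sorted(required)}")
    return [
        DiameterSeries(
            site=str(site),
            pressure=grp["pressure_mmHg"].to_numpy(),
            diameter=grp["diameter_mm"].to_numpy(),
        )
        for site, grp in df.groupby("site", sort=False)
    ]


def write_diameter_csv(series: Iterable[DiameterSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"site": s.site, "pressure_mmHg": s.pressure, "diameter_mm": s.diameter}
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_thickness_csv(path: str | Path) -> ThicknessGrid:
    return ThicknessGrid(table=pd.read_csv(path))


def write_thickness_csv(g: ThicknessGrid, path: str | Path) -> None:
    g.table.to_csv(path, index=False)


def read_modulus_table(path: str | Path) -> ModulusTable:
    with open(path) as fh:
        data = json.load(fh)
    nodes = np.asarray(data["nodes"], dtype=float)
    return ModulusTable(nodes[:, 0], nodes[:, 1], built_from=data.get("schedule", ""))


def write_modulus_table(table: ModulusTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "nodes": [[float(e), float(E)] for e, E in table.nodes],
                "schedule": table.built_from,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def write_inflation_csv(res: InflationResult, path: str | Path) -> None:
    """Long-format dump: one row per (pressure, station)."""
    n_p, n_s = res.station_diameters.shape
    pp, ss = np.meshgrid(np.arange(n_p), np.arange(n_s), indexing="ij")
    pd.DataFrame(
        {
            "pressure_mmHg": res.pressures[pp.ravel()],
            "volume_mm3": res.volumes[pp.ravel()],
            "station": ss.ravel(),
            "diameter_mm": res.station_diameters.ravel(),
        }
    ).to_csv(path, index=False)


def read_inflation_csv(path: str | Path, material_mode: str = "") -> InflationResult:
    df = pd.read_csv(path)
    pressures = np.sort(df["pressure_mmHg"].unique())
    stations = np.sort(df["station"].unique())
    piv = df.pivot_table(index="pressure_mmHg", columns="station", values="diameter_mm")
    vols = df.groupby("pressure_mmHg")["volume_mm3"].first()
    return InflationResult(
        pressures=pressures,
        volumes=vols.loc[pressures].to_numpy(),
        station_diameters=piv.loc[pressures, stations].to_numpy(),
        material_mode=material_mode,
    )


def write_report_json(report: ComplianceReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
        fh.write("\n")
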