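"""Data model and I/O for time-resolved 3D intracardiac velocity fields.

A "flow study" bundles everything needed to separate the left-ventricular
end-diastolic blood volume into functional flow components:

* a 4D phase-contrast velocity field (three Cartesian components, mm/s) on a
  regular grid, cyclic over one cardiac cycle;
* binary LV segmentation masks at end-diastole (ED) and end-systole (ES);
* a basal-plane definition with inlet (mitral) and outlet (aortic) regions;
* cardiac timing (RR interval, ED/ES frame indices).

Conventions
-----------
World coordinates are in millimetres; the centre of voxel ``(0, 0, 0)`` sits
at ``origin``.  Masks are voxel-centre sets.  Time is cyclic on the half-open
interval ``[0, rr_ms)``; every temporal query is reduced modulo the RR
interval.  Positions outside the grid hull sample a zero velocity and raise an
out-of-domain flag rather than extrapolating.

Volumes are exchanged as NIfTI files with an mm affine, accompanied by a
versioned JSON sidecar (schema ``"ventriflow-study/1"``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

SIDECAR_SCHEMA = "ventriflow-study/1"
SIDECAR_NAME = "study.json"

__all__ = [
    "ValidationError",
    "VelocityField4D",
    "Plane",
    "Disc",
    "CrossingSurface",
    "ChamberGeometry",
    "CardiacTiming",
    "FlowStudy",
    "sample_velocity",
    "sample_velocity_many",
    "load_flow_study",
    "save_flow_study",
    "export_pathlines",
    "read_pathlines_csv",
]


class ValidationError(ValueError):
    """An input violates a structural invariant of the data model."""


def _as_float_array(x, shape, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != shape:
        raise ValidationError(f"{name}: expected shape {shape}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: non-finite values")
    return arr


@dataclass
class VelocityField4D:
    """Cyclic 4D velocity field on a regular Cartesian grid.

    Parameters
    ----------
    velocity
        Array of shape ``(nx, ny, nz, nt, 3)`` holding the per-voxel,
        per-frame velocity vector in mm/s.
    spacing
        Voxel spacing per axis in mm (isotropic allowed).
    origin
        World coordinates (mm) of the centre of voxel ``(0, 0, 0)``.
    rr_ms
        Length of the cardiac cycle in ms.
    frame_times_ms
        Length-``nt`` strictly increasing times, first equal to 0, all
        inside ``[0, rr_ms)``.
    venc_mm_s
        Optional velocity-encoding limit (metadata only).
    """

    velocity: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    rr_ms: float
    frame_times_ms: np.ndarray
    venc_mm_s: float | None = None

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise ValidationError(
                f"velocity must have shape (nx, ny, nz, nt, 3), got {self.velocity.shape}"
            )
        if not np.all(np.isfinite(self.velocity)):
            raise ValidationError("velocity contains non-finite values")
        if min(self.velocity.shape[:3]) < 2:
            raise ValidationError("grid must be at least 2 voxels along every axis")
        self.spacing = _as_float_array(self.spacing, (3,), "spacing")
        if np.any(self.spacing <= 0):
            raise ValidationError("spacing must be positive")
        self.origin = _as_float_array(self.origin, (3,), "origin")
        self.rr_ms = float(self.rr_ms)
        if not np.isfinite(self.rr_ms) or self.rr_ms <= 0:
            raise ValidationError("rr_ms must be positive and finite")
        nt = self.velocity.shape[3]
        if nt < 2:
            raise ValidationError("at least two time frames are required")
        self.frame_times_ms = _as_float_array(self.frame_times_ms, (nt,), "frame_times_ms")
        if self.frame_times_ms[0] != 0.0:
            raise ValidationError("first frame time must be 0")
        if np.any(np.diff(self.frame_times_ms) <= 0):
            raise ValidationError("frame times must be strictly increasing")
        if self.frame_times_ms[-1] >= self.rr_ms:
            raise ValidationError("all frame times must lie in [0, rr_ms)")

    @property
    def dims(self) -> tuple[int, int, int, int]:
        nx, ny, nz, nt, _ = self.velocity.shape
        return nx, ny, nz, nt

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.velocity.shape[:3]

    @property
    def nt(self) -> int:
        return self.velocity.shape[3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates (mm) of voxel centres, optionally restricted to a mask."""
        if mask is None:
            idx = np.indices(self.grid_shape).reshape(3, -1).T
        else:
            idx = np.argwhere(np.asarray(mask, dtype=bool))
        return self.origin + idx * self.spacing


def _time_bracket(field: VelocityField4D, t_ms: float) -> tuple[int, int, float]:
    """Indices of the two frames bracketing ``t`` (cyclic) and the blend weight."""
    tau = float(t_ms) % field.rr_ms
    ft = field.frame_times_ms
    k = int(np.searchsorted(ft, tau, side="right")) - 1
    if k == field.nt - 1:  # wrap segment: last frame interpolates to frame 0
        dt = field.rr_ms - ft[-1]
        return k, 0, (tau - ft[-1]) / dt
    dt = ft[k + 1] - ft[k]
    return k, k + 1, (tau - ft[k]) / dt


_CORNERS = [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]


def sample_velocity_many(
    field: VelocityField4D, positions: np.ndarray, t_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the field at many positions and one time.

    Trilinear in space, linear in time between the two bracketing frames with
    cyclic wrap.  Positions outside the voxel-centre hull return a zero vector.

    Returns
    -------
    (velocity, in_domain)
        ``velocity`` has shape ``(n, 3)`` (mm/s); ``in_domain`` is a boolean
        array marking positions inside the grid hull.
    """
    if not np.isfinite(t_ms):
        raise ValueError("time must be finite")
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("positions must have shape (n, 3)")
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions must be finite")

    ka, kb, w = _time_bracket(field, t_ms)
    dims = np.array(field.grid_shape)
    g = (pos - field.origin) / field.spacing
    in_domain = np.all((g >= 0.0) & (g <= dims - 1), axis=1)
    gc = np.clip(g, 0.0, dims - 1)
    i0 = np.minimum(gc.astype(int), dims - 2)
    f = gc - i0

    vel = field.velocity
    out = np.zeros((pos.shape[0], 3))
    for dx, dy, dz in _CORNERS:
        wx = f[:, 0] if dx else 1.0 - f[:, 0]
        wy = f[:, 1] if dy else 1.0 - f[:, 1]
        wz = f[:, 2] if dz else 1.0 - f[:, 2]
        wgt = (wx * wy * wz)[:, None]
        ix, iy, iz = i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz
        corner = (1.0 - w) * vel[ix, iy, iz, ka] + w * vel[ix, iy, iz, kb]
        out += wgt * corner
    out[~in_domain] = 0.0
    return out, in_domain


def sample_velocity(
    field: VelocityField4D,
    position: Sequence[float],
    t_ms: float,
    return_status: bool = False,
):
    """Sample the velocity (mm/s) at one world position (mm) and time (ms).

    With ``return_status=True`` also returns ``in_domain`` (False means the
    position lies outside the grid hull and a zero vector was returned).
    """
    v, ok = sample_velocity_many(field, np.asarray(position, float)[None, :], t_ms)
    if return_status:
        return v[0], bool(ok[0])
    return v[0]


# ---------------------------------------------------------------------------
# Geometry


def _unit(v: np.ndarray, name: str) -> np.ndarray:
    v = _as_float_array(v, (3,), name)
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValidationError(f"{name}: zero-length normal")
    return v / n


@dataclass
class Plane:
    """Oriented plane: a point on the plane and a unit normal.

    By convention the normal points away from the LV (toward atrium/aorta),
    so the ventricular interior has negative signed distance.
    """

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = _as_float_array(self.point, (3,), "plane point")
        self.normal = _unit(self.normal, "plane normal")

    def signed_distance(self, positions: np.ndarray) -> np.ndarray:
        return (np.asarray(positions, float) - self.point) @ self.normal


@dataclass
class Disc:
    """Circular in-plane region (mm).

    ``normal=None`` means the disc lies on the study's basal plane; a disc may
    instead carry its own normal, in which case it defines its own crossing
    plane through ``center`` (used e.g. for straight-channel phantoms whose
    entry and exit faces are parallel planes).
    """

    center: np.ndarray
    radius: float
    normal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.center = _as_float_array(self.center, (3,), "disc center")
        self.radius = float(self.radius)
        if self.radius <= 0:
            raise ValidationError("disc radius must be positive")
        if self.normal is not None:
            self.normal = _unit(self.normal, "disc normal")


@dataclass
class CrossingSurface:
    """A detection plane with the labelled regions that lie on it."""

    plane: Plane
    regions: list[tuple[str, Disc]]

    def classify_point(self, point: np.ndarray) -> str:
        """Label a crossing point: region name if inside a disc, else 'wall'."""
        for label, disc in self.regions:
            d = point - disc.center
            d_inplane = d - (d @ self.plane.normal) * self.plane.normal
            if np.linalg.norm(d_inplane) <= disc.radius:
                return label
        return "wall"


@dataclass
class ChamberGeometry:
    """LV segmentations plus the basal plane with inlet/outlet regions."""

    mask_ed: np.ndarray
    mask_es: np.ndarray
    basal_plane: Plane
    inlet_region: Disc
    outlet_region: Disc

    def __post_init__(self) -> None:
        self.mask_ed = np.asarray(self.mask_ed).astype(bool)
        self.mask_es = np.asarray(self.mask_es).astype(bool)
        if self.mask_ed.ndim != 3 or self.mask_es.ndim != 3:
            raise ValidationError("masks must be 3D")
        if self.mask_ed.shape != self.mask_es.shape:
            raise ValidationError("ED and ES masks must share one grid")
        if self.inlet_region.normal is None and self.outlet_region.normal is None:
            gap = np.linalg.norm(self.inlet_region.center - self.outlet_region.center)
            if gap < self.inlet_region.radius + self.outlet_region.radius:
                raise ValidationError("inlet and outlet regions overlap")

    def crossing_surfaces(self) -> list[CrossingSurface]:
        """Detection planes with their regions (one plane when both discs are basal)."""
        basal_regions: list[tuple[str, Disc]] = []
        surfaces: list[CrossingSurface] = []
        for label, disc in (("inlet", self.inlet_region), ("outlet", self.outlet_region)):
            if disc.normal is None:
                basal_regions.append((label, disc))
            else:
                surfaces.append(
                    CrossingSurface(Plane(disc.center, disc.normal), [(label, disc)])
                )
        if basal_regions:
            surfaces.insert(0, CrossingSurface(self.basal_plane, basal_regions))
        return surfaces


@dataclass
class CardiacTiming:
    """ED/ES frame indices and cycle length.

    ED is the frame after mitral valve closure, ES the frame after aortic
    valve closure; cycle traversal is cyclic modulo ``rr_ms``.
    """

    i_ed: int
    i_es: int
    rr_ms: float

    def __post_init__(self) -> None:
        self.i_ed = int(self.i_ed)
        self.i_es = int(self.i_es)
        self.rr_ms = float(self.rr_ms)
        if self.i_ed == self.i_es:
            raise ValidationError("ED and ES frames must differ")
        if self.i_ed < 0 or self.i_es < 0:
            raise ValidationError("frame indices must be non-negative")


@dataclass
class FlowStudy:
    """One subject's velocity field, geometry and timing."""

    field: VelocityField4D
    geometry: ChamberGeometry
    timing: CardiacTiming
    subject_id: str = "anonymous"

    def __post_init__(self) -> None:
        if self.geometry.mask_ed.shape != self.field.grid_shape:
            raise ValidationError(
                f"mask grid {self.geometry.mask_ed.shape} does not match "
                f"velocity grid {self.field.grid_shape}"
            )
        nt = self.field.nt
        if not (0 <= self.timing.i_ed < nt and 0 <= self.timing.i_es < nt):
            raise ValidationError("ED/ES frame index out of range")
        if abs(self.timing.rr_ms - self.field.rr_ms) > 1e-6 * self.field.rr_ms:
            raise ValidationError("timing rr_ms disagrees with field rr_ms")

    @property
    def lvedv_ml(self) -> float:
        return float(self.geometry.mask_ed.sum()) * self.field.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# File round trip


def _affine(field: VelocityField4D) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(field.spacing)
    aff[:3, 3] = field.origin
    return aff


def save_flow_study(study: FlowStudy, path: str | Path) -> Path:
    """Write a study directory: NIfTI volumes plus the JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.field)
    for axis, name in enumerate(("velocity_x", "velocity_y", "velocity_z")):
        img = nib.Nifti1Image(study.field.velocity[..., axis], aff)
        nib.save(img, path / f"{name}.nii.gz")
    for mask, name in ((study.geometry.mask_ed, "mask_ed"), (study.geometry.mask_es, "mask_es")):
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff), path / f"{name}.nii.gz")

    def disc_json(disc: Disc) -> dict:
        out = {"center_mm": disc.center.tolist(), "radius_mm": disc.radius}
        if disc.normal is not None:
            out["normal"] = disc.normal.tolist()
        return out

    sidecar = {
        "schema": SIDECAR_SCHEMA,
        "subject_id": study.subject_id,
        "rr_ms": study.field.rr_ms,
        "frame_times_ms": study.field.frame_times_ms.tolist(),
        "venc_mm_s": study.field.venc_mm_s,
        "i_ed": study.timing.i_ed,
        "i_es": study.timing.i_es,
        "basal_plane": {
            "point_mm": study.geometry.basal_plane.point.tolist(),
            "normal": study.geometry.basal_plane.normal.tolist(),
        },
        "inlet_region": disc_json(study.geometry.inlet_region),
        "outlet_region": disc_json(study.geometry.outlet_region),
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    return path


def _load_volume(path: Path, name: str) -> tuple[np.ndarray, np.ndarray]:
    f = path / f"{name}.nii.gz"
    if not f.exists():
        f = path / f"{name}.nii"
    if not f.exists():
        raise FileNotFoundError(f"missing volume file: {path / (name + '.nii.gz')}")
    img = nib.load(f)
    return np.asarray(img.dataobj, dtype=float), img.affine


def load_flow_study(path: str | Path) -> FlowStudy:
    """Load and validate a study directory written by :func:`save_flow_study`."""
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("schema") != SIDECAR_SCHEMA:
        raise ValidationError(
            f"unsupported sidecar schema {sidecar.get('schema')!r}; expected {SIDECAR_SCHEMA!r}"
        )

    comps, affine = [], None
    for name in ("velocity_x", "velocity_y", "velocity_z"):
        data, aff = _load_volume(path, name)
        if data.ndim != 4:
            raise ValidationError(f"{name} must be a 4D volume, got {data.ndim}D")
        comps.append(data)
        affine = aff
    if not (comps[0].shape == comps[1].shape == comps[2].shape):
        raise ValidationError("velocity component volumes have mismatched shapes")
    velocity = np.stack(comps, axis=-1)

    spacing = np.diag(affine)[:3].copy()
    origin = affine[:3, 3].copy()
    field = VelocityField4D(
        velocity=velocity,
        spacing=spacing,
        origin=origin,
        rr_ms=sidecar["rr_ms"],
        frame_times_ms=np.asarray(sidecar["frame_times_ms"], float),
        venc_mm_s=sidecar.get("venc_mm_s"),
    )

    masks = {}
    for name in ("mask_ed", "mask_es"):
        data, _ = _load_volume(path, name)
        if data.ndim != 3:
            raise ValidationError(f"{name} must be a 3D volume")
        if data.shape != field.grid_shape:
            raise ValidationError(
                f"{name} grid {data.shape} does not match velocity grid {field.grid_shape}"
            )
        masks[name] = data > 0.5

    def disc_from(d: dict) -> Disc:
        return Disc(
            center=np.asarray(d["center_mm"], float),
            radius=d["radius_mm"],
            normal=None if d.get("normal") is None else np.asarray(d["normal"], float),
        )

    geometry = ChamberGeometry(
        mask_ed=masks["mask_ed"],
        mask_es=masks["mask_es"],
        basal_plane=Plane(
            np.asarray(sidecar["basal_plane"]["point_mm"], float),
            np.asarray(sidecar["basal_plane"]["normal"], float),
        ),
        inlet_region=disc_from(sidecar["inlet_region"]),
        outlet_region=disc_from(sidecar["outlet_region"]),
    )
    timing = CardiacTiming(i_ed=sidecar["i_ed"], i_es=sidecar["i_es"], rr_ms=sidecar["rr_ms"])
    return FlowStudy(field=field, geometry=geometry, timing=timing,
                     subject_id=sidecar.get("subject_id", "anonymous"))


# ---------------------------------------------------------------------------
# Pathline export


def export_pathlines(traced, path: str | Path, format: str = "csv",
                     labels: np.ndarray | None = None) -> Path:
    """Export traced pathlines for external viewers.

    ``format='csv'`` writes one row per (pathline, sample) with id, optional
    component label, time, position and speed.  ``format='vtk'`` writes a
    legacy ASCII VTK polydata file with one polyline per pathline.
    """
    path = Path(path)
    n = traced.n_pathlines
    if n == 0:
        raise ValueError("cannot export an empty pathline set")
    if labels is None:
        labels = np.full(n, "unlabeled", dtype=object)
    times = traced.times_ms
    speed = np.linalg.norm(traced.velocities, axis=-1)

    if format == "csv":
        with open(path, "w") as fh:
            fh.write("pathline_id,component,t_ms,x_mm,y_mm,z_mm,speed_mm_s\n")
            for k in range(n):
                for j, t in enumerate(times):
                    x, y, z = traced.positions[k, j]
                    fh.write(
                        f"{k},{labels[k]},{t:.6g},{x:.6f},{y:.6f},{z:.6f},{speed[k, j]:.6f}\n"
                    )
        return path
    if format == "vtk":
        n_samples = len(times)
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nventriflow pathlines\nASCII\n")
            fh.write("DATASET POLYDATA\n")
            fh.write(f"POINTS {n * n_samples} float\n")
            for k in range(n):
                for j in range(n_samples):
                    x, y, z = traced.positions[k, j]
                    fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
            fh.write(f"LINES {n} {n * (n_samples + 1)}\n")
            for k in range(n):
                ids = " ".join(str(k * n_samples + j) for j in range(n_samples))
                fh.write(f"{n_samples} {ids}\n")
            fh.write(f"POINT_DATA {n * n_samples}\nSCALARS speed_mm_s float 1\n")
            fh.write("LOOKUP_TABLE default\n")
            for k in range(n):
                for j in range(n_samples):
                    fh.write(f"{speed[k, j]:.6f}\n")
        return path
    raise ValueError(f"unknown export format {format!r} (expected 'csv' or 'vtk')")


def read_pathlines_csv(path: str | Path):
    """Read a CSV pathline export back into a DataFrame (round-trip checks)."""
    import pandas as pd

    return pd.read_csv(path)
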