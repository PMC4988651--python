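"""Kinetic energy of the flow components over the cardiac cycle.

Each pathline represents a fixed blood volume V (one voxel) moving with the
local velocity v(t), so its kinetic energy is

    KE(t) = 1/2 * rho_blood * V * |v(t)|^2,      rho_blood = 1060 kg/m^3.

Component KE curves sum the pathline energies per label over the common time
grid of the traced set; the total curve sums all non-aberrant pathlines.  The
end-diastolic snapshot gives the DF/LVEDV and NE/LVEDV KE ratios: the
component's KE at ED divided by the KE of the whole end-diastolic volume at
ED.  The ED speed comes from the stored seed sample, i.e. the field velocity
at the seed voxel centre — ED is the seeding time, so no interpolation
asymmetry enters.

KE is reported in millijoules.  It is not integrated over time; the analysis
uses the curves plus the ED snapshot only.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .components import (
    ABERRANT,
    COMPONENTS,
    DIRECT_FLOW,
    RESIDUAL_VOLUME,
    RETAINED_INFLOW,
)
from .tracing import TracedSet

RHO_BLOOD_KG_M3 = 1060.0

# 1/2 * rho * (mm^3 -> m^3) * (mm/s -> m/s)^2 * (J -> mJ)
_KE_MJ_FACTOR = 0.5 * RHO_BLOOD_KG_M3 * 1e-9 * 1e-6 * 1e3

__all__ = ["RHO_BLOOD_KG_M3", "KECurves", "pathline_ke", "ke_timecurves", "ke_ratios_at_ed"]


def pathline_ke(volume_mm3, velocity_mm_s) -> np.ndarray | float:
    """Kinetic energy (mJ) of a parcel of ``volume_mm3`` at the given velocity.

    ``velocity_mm_s`` may be a 3-vector (or array of them, last axis 3), in
    which case the speed is its Euclidean norm, or already a scalar speed.
    """
    volume = np.asarray(volume_mm3, dtype=float)
    if np.any(volume < 0):
        raise ValueError("pathline volume must be non-negative")
    v = np.asarray(velocity_mm_s, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity must be finite")
    speed2 = np.sum(v * v, axis=-1) if (v.ndim and v.shape[-1] == 3) else v * v
    out = _KE_MJ_FACTOR * volume * speed2
    return float(out) if np.isscalar(volume_mm3) and out.ndim == 0 else out


@dataclass
class KECurves:
    """KE over the cycle per component and for the total LVEDV (mJ)."""

    times_ms: np.ndarray
    curves_mj: dict                 # component label -> (T,) array
    total_mj: np.ndarray            # (T,) sum over non-aberrant pathlines
    i_ed_sample: int

    @property
    def ke_at_ed_mj(self) -> dict:
        out = {name: float(curve[self.i_ed_sample]) for name, curve in self.curves_mj.items()}
        out["total"] = float(self.total_mj[self.i_ed_sample])
        return out

    def to_frame(self):
        """Tidy (time, component, KE_mJ) DataFrame for export."""
        import pandas as pd

        rows = []
        for name, curve in {**self.curves_mj, "total": self.total_mj}.items():
            for t, ke in zip(self.times_ms, curve):
                rows.append({"t_ms": t, "component": name, "ke_mj": ke})
        return pd.DataFrame(rows)


def ke_timecurves(traced: TracedSet, labels: np.ndarray) -> KECurves:
    """Per-component and total KE curves on the traced set's time grid.

    Pathlines frozen after leaving the grid carry zero recorded velocity and
    therefore contribute nothing after their exit.  Aberrant pathlines are
    excluded from the total.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != traced.n_pathlines:
        raise ValueError("labels do not cover the traced set")
    speed2 = np.sum(traced.velocities ** 2, axis=-1)  # (N, T)
    per_pathline = _KE_MJ_FACTOR * traced.volume_mm3 * speed2
    curves = {
        name: per_pathline[labels == name].sum(axis=0) for name in COMPONENTS
    }
    total = per_pathline[labels != ABERRANT].sum(axis=0)
    return KECurves(
        times_ms=traced.times_ms,
        curves_mj=curves,
        total_mj=total,
        i_ed_sample=traced.i_ed_sample,
    )


def ke_ratios_at_ed(curves: KECurves) -> dict:
    """DF/LVEDV and NE/LVEDV KE ratios at end-diastole.

    Returns ``{"df_ke_ratio", "ne_ke_ratio", "reason"}``; the ratios are None
    with a reason when the total KE at ED is zero.
    """
    ed = curves.ke_at_ed_mj
    total = ed["total"]
    if total <= 0.0:
        return {
            "df_ke_ratio": None,
            "ne_ke_ratio": None,
            "reason": "total KE at ED is zero; ratios undefined",
        }
    return {
        "df_ke_ratio": ed[DIRECT_FLOW] / total,
        "ne_ke_ratio": (ed[RETAINED_INFLOW] + ed[RESIDUAL_VOLUME]) / total,
        "reason": "",
    }
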