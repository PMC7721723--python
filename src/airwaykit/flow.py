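"""Steady incompressible airflow: reduced-order model and flow summaries.

Inspiratory airflow through the upper airway is modeled as steady, Newtonian,
homogeneous and incompressible, driven by a constant volumetric flow rate
with the nostril pressure fixed at 0 Pa.  Two solvers share this contract:

* :func:`solve_flow_1d` — a quasi-one-dimensional model along the centerline,
  Bernoulli dynamic-pressure exchange plus a circular-equivalent Poiseuille
  loss::

      P(s) = P(0) - (rho/2) [ (Q/A(s))^2 - (Q/A(0))^2 ]
                  - 8 pi mu Q * integral_0^s du / A(u)^2

  For a constant-area tube the viscous term reduces to the Hagen-Poiseuille
  law, 8 mu L Q / (pi R^4).

* :mod:`airwaykit.solver3d` — a voxel-grid laminar Navier-Stokes solution
  (pseudo-transient projection) summarized through the same interface.

The summary reports the quantities used for between-genotype comparison:
maximum speed per region (nasal cavity = nostrils to the meatus merge;
pharyngeal airway = hard-palate edge to the epiglottis), the most negative
station pressure Pmax at the epiglottis, and the telescoping per-segment
pressure drops P_nasal, P_hard, P_soft.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ParameterError, StationRangeError

__all__ = [
    "FluidProperties",
    "FlowBoundaryConditions",
    "Flow1DResult",
    "FlowSummary",
    "solve_flow_1d",
    "summarize_flow_1d",
    "summarize_flow_3d",
]

MM2_TO_M2 = 1e-6
MM_TO_M = 1e-3
ML_S_TO_M3_S = 1e-6


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants; defaults are air at ~20 C."""

    density: float = 1.204            # kg/m^3
    dynamic_viscosity: float = 1.825e-5  # Pa s

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity < 0:
            raise ParameterError("density must be > 0 and viscosity >= 0")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


@dataclass(frozen=True)
class FlowBoundaryConditions:
    """Pressure-inlet / constant-flow-outlet boundary conditions."""

    inlet_pressure_pa: float = 0.0
    outlet_flow_ml_s: float = 5.28  # cohort mean of peak inspiratory flow

    def __post_init__(self):
        if self.outlet_flow_ml_s < 0:
            raise ParameterError("outlet flow rate must be non-negative")


@dataclass
class Flow1DResult:
    """Arclength profiles of mean velocity and pressure."""

    s_mm: np.ndarray
    area_mm2: np.ndarray
    velocity_m_s: np.ndarray
    pressure_pa: np.ndarray
    bc: FlowBoundaryConditions = field(default_factory=FlowBoundaryConditions)

    def pressure_at(self, s_mm):
        return np.interp(s_mm, self.s_mm, self.pressure_pa)

    def velocity_at(self, s_mm):
        return np.interp(s_mm, self.s_mm, self.velocity_m_s)


@dataclass
class FlowSummary:
    """Region maxima, epiglottis pressure and segment pressure drops.

    ``p_nasal + p_hard + p_soft`` telescopes exactly to
    ``pmax - inlet_pressure``.
    """

    vmax_nasal_m_s: float
    vmax_pharyngeal_m_s: float
    pmax_pa: float
    p_nasal_pa: float
    p_hard_pa: float
    p_soft_pa: float
    v_nasal_mm3: float | None = None
    v_pharyngeal_mm3: float | None = None
    pharyngeal_length_mm: float | None = None
    pmax_pointwise_pa: float | None = None
    solver: str = "1d"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _as_profile_arrays(area_profile):
    """Accept (N,2) arrays, [(s, a), ...] lists or CrossSection sequences."""
    if hasattr(area_profile, "__len__") and len(area_profile) and hasattr(
        area_profile[0], "area_mm2"
    ):
        pairs = [
            (cs.station_label_mm, cs.area_mm2)
            for cs in area_profile
            if not cs.missing and np.isfinite(cs.area_mm2)
        ]
        arr = np.asarray(sorted(pairs), dtype=float)
    else:
        arr = np.asarray(area_profile, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ParameterError("area profile must be an (N>=2, 2) array of (s, area)")
    s, a = arr[:, 0], arr[:, 1]
    if not np.all(np.diff(s) > 0):
        raise ParameterError("arclengths must be strictly increasing")
    if np.any(a <= 0):
        raise ParameterError("singular geometry: zero or negative cross-section area")
    return s, a


def solve_flow_1d(area_profile, bc: FlowBoundaryConditions | None = None,
                  fluid: FluidProperties | None = None) -> Flow1DResult:
    """Quasi-1-D pressure and mean-velocity profiles along arclength.

    ``area_profile`` is (arclength mm, area mm^2) pairs (or measured
    cross-sections).  The viscous integral uses trapezoidal quadrature on the
    supplied stations; refine the profile to refine the quadrature.
    """
    bc = bc or FlowBoundaryConditions()
    fluid = fluid or FluidProperties()
    s_mm, a_mm2 = _as_profile_arrays(area_profile)
    s = s_mm * MM_TO_M
    area = a_mm2 * MM2_TO_M2
    q = bc.outlet_flow_ml_s * ML_S_TO_M3_S
    v = q / area
    dynamic = 0.5 * fluid.density * (v**2 - v[0] ** 2)
    visc_integrand = 1.0 / area**2
    viscous = 8.0 * np.pi * fluid.dynamic_viscosity * q * np.concatenate(
        [[0.0], cumulative_trapezoid(visc_integrand, s)]
    )
    pressure = bc.inlet_pressure_pa - dynamic - viscous
    return Flow1DResult(s_mm=s_mm, area_mm2=a_mm2, velocity_m_s=v,
                        pressure_pa=pressure, bc=bc)


def _segment_drops(p_at, segments, inlet_pressure):
    p_meatus = p_at(segments.s_meatus_merge)
    p_hp = p_at(segments.s_hard_palate)
    p_epi = p_at(segments.s_epiglottis)
    p_nasal = p_meatus - inlet_pressure
    p_hard = p_hp - p_meatus
    p_soft = p_epi - p_hp
    return p_nasal, p_hard, p_soft, p_epi


def summarize_flow_1d(result: Flow1DResult, segments,
                      v_nasal_mm3=None, v_pharyngeal_mm3=None,
                      pharyngeal_length_mm=None) -> FlowSummary:
    """Region maxima and telescoping segment drops from a 1-D solution."""
    s = result.s_mm
    if segments.s_epiglottis > s[-1] + 1e-9 or segments.s_meatus_merge < s[0] - 1e-9:
        raise StationRangeError("segment stations outside the solved arclength range")
    nasal = (s >= s[0]) & (s <= segments.s_meatus_merge)
    phar = (s >= segments.s_hard_palate) & (s <= segments.s_epiglottis)
    p_nasal, p_hard, p_soft, p_epi = _segment_drops(
        result.pressure_at, segments, result.bc.inlet_pressure_pa
    )
    return FlowSummary(
        vmax_nasal_m_s=float(result.velocity_m_s[nasal].max()) if nasal.any() else float("nan"),
        vmax_pharyngeal_m_s=float(result.velocity_m_s[phar].max()) if phar.any() else float("nan"),
        pmax_pa=float(p_epi),
        p_nasal_pa=float(p_nasal),
        p_hard_pa=float(p_hard),
        p_soft_pa=float(p_soft),
        v_nasal_mm3=v_nasal_mm3,
        v_pharyngeal_mm3=v_pharyngeal_mm3,
        pharyngeal_length_mm=pharyngeal_length_mm,
        solver="1d",
    )


def summarize_flow_3d(field, centerline, segments,
                      v_nasal_mm3=None, v_pharyngeal_mm3=None,
                      pharyngeal_length_mm=None,
                      outlet_exclusion_diameters: float = 2.0) -> FlowSummary:
    """Region maxima and station-averaged pressures from a 3-D field.

    Each fluid cell is assigned the arclength of its nearest centerline
    point.  Station pressures are cross-section averages (cells within half
    a voxel of the station); Pmax is the station-averaged pressure at the
    epiglottis (the pointwise minimum there is also reported).  Cells within
    ``outlet_exclusion_diameters`` hydraulic diameters of the outlet are
    excluded from Vmax extraction to avoid the Dirichlet-outlet artifact.
    """
    pts, speed, pressure = field.cell_samples()
    s_cells = centerline.nearest_arclength(pts)
    h = float(np.max(field.spacing_mm))

    def station_pressure(s0):
        sel = np.abs(s_cells - s0) <= max(h, 0.5)
        if not sel.any():
            raise StationRangeError(f"no cells near station s={s0:.2f} mm")
        return float(pressure[sel].mean()), float(pressure[sel].min())

    p_at = lambda s0: station_pressure(s0)[0]
    p_nasal, p_hard, p_soft, p_epi = _segment_drops(p_at, segments, field.inlet_pressure_pa)
    _, p_epi_min = station_pressure(segments.s_epiglottis)

    s_max = s_cells.max()
    excl = s_max - outlet_exclusion_diameters * field.hydraulic_diameter_mm
    ok = s_cells <= excl
    nasal = ok & (s_cells <= segments.s_meatus_merge)
    phar = ok & (s_cells >= segments.s_hard_palate) & (s_cells <= segments.s_epiglottis)
    if not phar.any():
        warnings.warn("pharyngeal Vmax region empty after outlet exclusion")
    return FlowSummary(
        vmax_nasal_m_s=float(speed[nasal].max()) if nasal.any() else float("nan"),
        vmax_pharyngeal_m_s=float(speed[phar].max()) if phar.any() else float("nan"),
        pmax_pa=float(p_epi),
        p_nasal_pa=float(p_nasal),
        p_hard_pa=float(p_hard),
        p_soft_pa=float(p_soft),
        v_nasal_mm3=v_nasal_mm3,
        v_pharyngeal_mm3=v_pharyngeal_mm3,
        pharyngeal_length_mm=pharyngeal_length_mm,
        pmax_pointwise_pa=p_epi_min,
        solver="3d",
    )
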