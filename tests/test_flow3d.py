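"""Voxel-grid Navier-Stokes solver against the Poiseuille benchmark.

All quantitative benchmarks run in the viscous-dominated regime (Re < 1)
where the Hagen-Poiseuille closed form is exact away from the ends; the
solver itself carries the convection terms.  The pseudo-transient stepping
makes these the slowest tests in the suite, so the converged tube solution
is shared module-wide.
"""
import numpy as np
import pytest

from airwaykit.errors import SolverError, TopologyError
from airwaykit.flow import (FluidProperties, FlowBoundaryConditions,
                            summarize_flow_3d)
from airwaykit.phantoms import make_tube_phantom, make_venturi_phantom
from airwaykit.solver3d import solve_flow_3d

FLUID = FluidProperties()
Q_LOW = 0.01  # ml/s -> Re ~ 0.9 in an r = 0.5 mm tube
R_MM = 0.5
L_MM = 3.0
SPACING = 0.06  # 16.7 voxels across the diameter: a non-integer
# radius-to-spacing ratio avoids degenerate single-voxel staircase spurs


def hagen_poiseuille_pa(mu, length_m, q_m3_s, radius_m):
    return 8.0 * mu * length_m * q_m3_s / (np.pi * radius_m**4)


@pytest.fixture(scope="module")
def tube_solution():
    _, mask, truth = make_tube_phantom(R_MM, L_MM, SPACING)
    field = solve_flow_3d(mask, "z-", "z+",
                          FlowBoundaryConditions(0.0, Q_LOW), FLUID,
                          grid_tolerance=1e-4)
    return mask, truth, field


def _plane_mean_pressure(field, k):
    p = field.pressure[:, :, k]
    return float(np.nanmean(p))


def test_tube_pressure_drop_within_5pc(tube_solution):
    mask, truth, field = tube_solution
    nz = mask.shape[2]
    dp = _plane_mean_pressure(field, 1) - _plane_mean_pressure(field, nz - 2)
    span_m = (nz - 3) * SPACING * 1e-3
    dp_ref = hagen_poiseuille_pa(FLUID.dynamic_viscosity, span_m,
                                 Q_LOW * 1e-6, R_MM * 1e-3)
    assert dp == pytest.approx(dp_ref, rel=0.05)


def test_tube_parabolic_peak_speed(tube_solution):
    mask, _, field = tube_solution
    k = mask.shape[2] // 2
    speed = field.speed()[:, :, k]
    peak = float(speed[mask.voxels[:, :, k]].max())
    v_mean = Q_LOW * 1e-6 / (np.pi * (R_MM * 1e-3) ** 2)
    assert peak == pytest.approx(2.0 * v_mean, rel=0.05)


def test_flux_conserved_through_every_section(tube_solution):
    mask, _, field = tube_solution
    for k in range(0, mask.shape[2] + 1, 4):
        assert field.flux_ml_s(k) == pytest.approx(Q_LOW, rel=0.01)


def test_inlet_pressure_is_zero_and_walls_no_slip(tube_solution):
    mask, _, field = tube_solution
    # cross-section-averaged pressure in the inlet cell layer sits within a
    # cell's pressure gradient of the 0 Pa Dirichlet face
    h_m = SPACING * 1e-3
    grad = hagen_poiseuille_pa(FLUID.dynamic_viscosity, 1.0, Q_LOW * 1e-6,
                               R_MM * 1e-3)
    assert abs(_plane_mean_pressure(field, 0)) < 1.5 * grad * h_m
    # every face adjacent to a solid cell carries zero velocity
    solid = ~mask.voxels
    assert np.all(field.ux[1:-1][solid[:-1] | solid[1:]] == 0.0)
    assert np.all(field.uy[:, 1:-1][(solid[:, :-1] | solid[:, 1:])] == 0.0)


def test_divergence_free(tube_solution):
    _, _, field = tube_solution
    v_mean = Q_LOW * 1e-6 / (np.pi * (R_MM * 1e-3) ** 2)
    h_m = SPACING * 1e-3
    assert field.max_interior_divergence() < 1e-6 * v_mean / h_m


def test_drop_linear_in_flow_at_low_re(tube_solution):
    """Halving Q halves the viscous pressure drop (within 3% at Re < 1)."""
    mask, _, field = tube_solution
    half = solve_flow_3d(mask, "z-", "z+",
                         FlowBoundaryConditions(0.0, Q_LOW / 2), FLUID,
                         grid_tolerance=1e-4)
    nz = mask.shape[2]
    dp_full = _plane_mean_pressure(field, 1) - _plane_mean_pressure(field, nz - 2)
    dp_half = _plane_mean_pressure(half, 1) - _plane_mean_pressure(half, nz - 2)
    assert dp_full == pytest.approx(2.0 * dp_half, rel=0.03)


def test_1d_and_3d_agree_on_tube(tube_solution):
    from airwaykit.flow import solve_flow_1d

    mask, truth, field = tube_solution
    nz = mask.shape[2]
    sol = solve_flow_1d(truth.area_profile_true,
                        FlowBoundaryConditions(0.0, Q_LOW), FLUID)
    dp_1d = sol.pressure_pa[0] - sol.pressure_pa[-1]
    dp_3d = (_plane_mean_pressure(field, 1) - _plane_mean_pressure(field, nz - 2))
    dp_3d *= (nz * SPACING) / ((nz - 3) * SPACING)  # rescale to full length
    assert dp_3d == pytest.approx(dp_1d, rel=0.10)


def test_grid_refinement_monotone():
    """Poiseuille gradient error decreases from 8 -> 16 -> 32 voxels/diameter."""
    errs = []
    for spacing in (0.12, 0.06, 0.03):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # 8 voxels/diameter warns as coarse
            _, mask, _ = make_tube_phantom(R_MM, 1.5, spacing)
        field = solve_flow_3d(mask, "z-", "z+",
                              FlowBoundaryConditions(0.0, Q_LOW), FLUID,
                              grid_tolerance=1e-4)
        nz = mask.shape[2]
        k0, k1 = nz // 4, 3 * nz // 4
        dp = _plane_mean_pressure(field, k0) - _plane_mean_pressure(field, k1)
        grad = dp / ((k1 - k0) * spacing * 1e-3)
        grad_ref = hagen_poiseuille_pa(FLUID.dynamic_viscosity, 1.0,
                                       Q_LOW * 1e-6, R_MM * 1e-3)
        errs.append(abs(grad / grad_ref - 1.0))
    assert errs[0] > errs[1] > errs[2]


def test_venturi_peak_speed_at_throat():
    """Max speed localizes to the minimum-area station (away from the outlet)."""
    _, mask, truth = make_venturi_phantom(
        0.45, 0.28, l_inlet_mm=1.2, l_throat_mm=1.0, l_outlet_mm=1.6,
        taper_len_mm=0.8, spacing_mm=0.05,
    )
    field = solve_flow_3d(mask, "z-", "z+",
                          FlowBoundaryConditions(0.0, 0.005), FLUID,
                          grid_tolerance=1e-4)
    speed = field.speed()
    speed[~mask.voxels] = 0.0
    # exclude two hydraulic diameters near the uniform-velocity outlet
    kz_max = mask.shape[2] - int(2 * field.hydraulic_diameter_mm / 0.05)
    k_peak = np.unravel_index(np.argmax(speed[:, :, :kz_max]), speed[:, :, :kz_max].shape)[2]
    s_peak = k_peak * 0.05
    throat = truth.landmark_truth["throat_center"][2]
    prof = truth.area_profile_true
    s_min = prof[np.argmin(prof[:, 1]), 0]
    # the whole throat section is minimal; the peak must fall inside it
    assert abs(s_peak - throat) <= 0.5 + 0.1


def test_disconnected_inlet_outlet_raises():
    vox = np.zeros((10, 10, 20), dtype=bool)
    vox[3:7, 3:7, :8] = True
    vox[3:7, 3:7, 12:] = True
    from airwaykit.volume import BinaryMask

    mask = BinaryMask(vox, [0.05] * 3, [0, 0, 0])
    with pytest.raises(TopologyError):
        solve_flow_3d(mask, "z-", "z+", FlowBoundaryConditions(0.0, 0.01), FLUID)


def test_high_reynolds_warns():
    _, mask, _ = make_tube_phantom(R_MM, 1.0, 0.1)
    with pytest.warns(UserWarning, match="Reynolds"):
        with pytest.raises(SolverError):
            # huge flow: warn about the regime, then fail to converge quickly
            solve_flow_3d(mask, "z-", "z+", FlowBoundaryConditions(0.0, 50.0),
                          FLUID, grid_tolerance=1e-12, max_iterations=5)


def test_summary_telescoping_and_narrowing_direction(tube_solution):
    from airwaykit.centerline import Centerline
    from airwaykit.geometry import AirwaySegments

    mask, _, field = tube_solution
    c = mask.origin_mm + (np.array(mask.shape) // 2) * mask.spacing_mm
    z = np.arange(0.0, L_MM, SPACING)
    cl = Centerline.from_points(
        np.column_stack([np.full_like(z, c[0]), np.full_like(z, c[1]), z])
    )
    segs = AirwaySegments(0.8, 1.5, 2.6, 2.9)
    fs = summarize_flow_3d(field, cl, segs, outlet_exclusion_diameters=0.3)
    assert fs.p_nasal_pa + fs.p_hard_pa + fs.p_soft_pa == pytest.approx(
        fs.pmax_pa, abs=1e-9
    )
    assert fs.pmax_pointwise_pa <= fs.pmax_pa
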