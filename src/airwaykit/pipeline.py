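"""Config-driven orchestration of the full analysis graph.

One YAML (or dict) config drives: phantom generation or volume loading ->
segmentation -> centerline + station areas -> morphometry cohort comparison
-> airflow simulation -> plethysmography -> group statistics.  Every stage
logs its parameters (the chronic irreproducibility of imaging pipelines
comes from unstated settings, so the log echoes all of them), outputs are
deterministic given (config, seed), and a stage failure leaves the outputs
of earlier stages intact.

Report bundle written to ``output_dir``:

* ``area_profile.csv``    station areas (label, mm^2)
* ``morphometry.csv``     per-measure two-group comparison
* ``flow_summary.json``   airflow report (Vmax / Pmax / segment drops ...)
* ``respiratory.json``    the seven plethysmography parameters
* ``stats.csv``           Welch comparison rows
* ``pipeline.log``        stage-by-stage parameter echo (no timestamps, so
                          reruns are byte-identical)
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .centerline import Centerline, extract_centerline
from .errors import AirwayKitError
from .flow import (FluidProperties, FlowBoundaryConditions, solve_flow_1d,
                   summarize_flow_1d, summarize_flow_3d)
from .geometry import (DEFAULT_STATION_OFFSETS_MM, area_profile,
                       partition_segments, pharyngeal_length,
                       profile_to_dataframe, segment_volumes)
from .morphometry import cohort_compare
from .phantoms import (BreathSpec, CohortSpec, MouseAirwayConfig,
                       make_breath_trace, make_morphometry_cohort,
                       make_mouse_airway_phantom)
from .plethysmography import analyze_trace
from .segmentation import invert_intensity, segment_airway
from .stats import comparison_report
from .volume import load_volume

__all__ = ["run_pipeline", "load_config"]


class PipelineError(AirwayKitError, RuntimeError):
    """A stage failed; the message names the stage."""


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


def _stage(log, name, **params):
    log.append(f"[stage {name}] " + json.dumps(params, sort_keys=True, default=str))


def run_pipeline(config) -> dict:
    """Run the full analysis; returns the dict of written report paths."""
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    out_dir = Path(cfg.get("output_dir", "airwaykit_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    log: list[str] = [f"airwaykit pipeline, seed={seed}"]
    current = "config"
    try:
        # ---------------- phantom / input volume ----------------
        current = "phantom"
        pcfg = dict(cfg.get("phantom", {}))
        if "volume_path" in pcfg:
            if "landmarks_path" not in pcfg:
                raise PipelineError(
                    "stage phantom: user volumes need a landmarks_path CSV "
                    "(name,x_mm,y_mm,z_mm with the six functional landmarks)"
                )
            _stage(log, current, source=pcfg["volume_path"],
                   landmarks=pcfg["landmarks_path"])
            volume = load_volume(pcfg["volume_path"])
            lm_df = pd.read_csv(pcfg["landmarks_path"])
            from .morphometry import LandmarkSet

            landmarks = LandmarkSet(
                points={r["name"]: (r["x_mm"], r["y_mm"], r["z_mm"])
                        for _, r in lm_df.iterrows()},
                subject_id="user_volume",
            )
            truth = None
            mouse_cfg = None
        else:
            mouse_kwargs = {
                k: v for k, v in pcfg.items()
                if k in MouseAirwayConfig.__dataclass_fields__
            }
            mouse_cfg = MouseAirwayConfig(**mouse_kwargs)
            _stage(log, current, kind="mouse_airway", **mouse_kwargs)
            volume, _true_mask, landmarks, truth = make_mouse_airway_phantom(
                mouse_cfg, seed=seed
            )

        # ---------------- segmentation ----------------
        current = "segmentation"
        scfg = dict(cfg.get("segmentation", {}))
        threshold = scfg.get("threshold", "otsu")
        if threshold in ("auto", "otsu"):
            threshold = "otsu"
        seed_lm = scfg.get("seed_landmark", "hard_palate_edge")
        seed_point = np.asarray(landmarks.get(seed_lm), dtype=float)
        _stage(log, current, threshold=threshold, seed_landmark=seed_lm,
               seed_point_mm=seed_point.tolist())
        inverted = invert_intensity(volume)
        mask = segment_airway(inverted, threshold, seed_point)

        # ---------------- centerline + areas ----------------
        current = "geometry"
        gcfg = dict(cfg.get("geometry", {}))
        offsets = tuple(gcfg.get("station_offsets_mm", DEFAULT_STATION_OFFSETS_MM))
        start = 0.5 * (np.asarray(landmarks.get("nostril_left"))
                       + np.asarray(landmarks.get("nostril_right")))
        if "end_point_mm" in gcfg:
            caudal_end = np.asarray(gcfg["end_point_mm"], dtype=float)
        elif mouse_cfg is not None:
            caudal_end = _axis_end(mask)
        else:
            raise PipelineError(
                "stage geometry: user volumes need geometry.end_point_mm"
            )
        window = float(gcfg.get("smoothing_window_mm", 0.2))
        _stage(log, current, station_offsets_mm=list(offsets),
               smoothing_window_mm=window, start_mm=start.tolist(),
               end_mm=caudal_end.tolist())
        cl = extract_centerline(mask, start, caudal_end, smoothing_window_mm=window)
        segments = partition_segments(cl, landmarks)
        sections = area_profile(mask, cl, segments.s_hard_palate, offsets)
        prof_df = profile_to_dataframe(sections)
        paths["area_profile"] = out_dir / "area_profile.csv"
        prof_df.to_csv(paths["area_profile"], index=False)
        v_nasal, v_phar, _ = segment_volumes(mask, cl, segments)
        s_ary = cl.project_point(np.asarray(landmarks.get("arytenoid")))
        phar_len = pharyngeal_length(cl, segments.s_hard_palate, s_ary)

        # ---------------- morphometry cohort ----------------
        current = "morphometry"
        mcfg = dict(cfg.get("cohort", {}))
        spec = CohortSpec.from_reference_table(
            reference.CRANIOFACIAL_MM,
            n_g1=int(mcfg.get("n_g1", 8)),
            n_g2=int(mcfg.get("n_g2", 7)),
            seed=seed,
        )
        _stage(log, current, n_g1=spec.n_g1, n_g2=spec.n_g2,
               n_measures=len(spec.measures), moments="reference_craniofacial")
        g1, g2 = make_morphometry_cohort(spec)
        morpho = cohort_compare(g1, g2)
        paths["morphometry"] = out_dir / "morphometry.csv"
        morpho.to_csv(paths["morphometry"], index=False)

        # ---------------- airflow ----------------
        current = "flow"
        fcfg = dict(cfg.get("flow", {}))
        fluid = FluidProperties(
            density=float(fcfg.get("density_kg_m3", 1.204)),
            dynamic_viscosity=float(fcfg.get("viscosity_pa_s", 1.825e-5)),
        )
        bc = FlowBoundaryConditions(
            inlet_pressure_pa=float(fcfg.get("inlet_pressure_pa", 0.0)),
            outlet_flow_ml_s=float(fcfg.get("flow_ml_s",
                                            reference.PEAK_INSPIRATORY_FLOW_ML_S)),
        )
        solver = fcfg.get("solver", "1d")
        _stage(log, current, solver=solver, flow_ml_s=bc.outlet_flow_ml_s,
               density=fluid.density, viscosity=fluid.dynamic_viscosity)
        if solver == "1d":
            ds = float(fcfg.get("profile_step_mm", 0.25))
            s_grid = np.append(np.arange(0.0, segments.s_end, ds), segments.s_end)
            fine = [
                (s, c.area_mm2)
                for s, c in (
                    (s, _section(mask, cl, s)) for s in s_grid
                )
                if not c.missing and c.area_mm2 > 0
            ]
            sol = solve_flow_1d(fine, bc, fluid)
            summary = summarize_flow_1d(sol, segments, v_nasal, v_phar, phar_len)
        elif solver == "3d":
            from .solver3d import solve_flow_3d

            field = solve_flow_3d(mask, fcfg.get("inlet_face", "z-"),
                                  fcfg.get("outlet_face", "z+"), bc, fluid)
            summary = summarize_flow_3d(field, cl, segments, v_nasal, v_phar,
                                        phar_len)
        else:
            raise PipelineError(f"unknown solver {solver!r}")
        paths["flow_summary"] = out_dir / "flow_summary.json"
        summary.to_json(paths["flow_summary"])

        # ---------------- plethysmography ----------------
        current = "plethysmography"
        bcfg = dict(cfg.get("breathing", {}))
        spec_kwargs = {k: v for k, v in bcfg.items()
                       if k in BreathSpec.__dataclass_fields__}
        spec_kwargs.setdefault("seed", seed)
        breath_spec = BreathSpec(**spec_kwargs)
        min_quiet = float(bcfg.get("min_quiet_s", 5.0))
        _stage(log, current, min_quiet_s=min_quiet, **spec_kwargs)
        trace = make_breath_trace(breath_spec)
        resp = analyze_trace(trace, min_quiet)
        paths["respiratory"] = out_dir / "respiratory.json"
        with open(paths["respiratory"], "w") as fh:
            json.dump(resp.to_dict(), fh, indent=2, sort_keys=True)

        # ---------------- statistics ----------------
        current = "stats"
        table = {**reference.RESPIRATORY, **reference.CFD, **reference.BASELINE}
        _stage(log, current, n_metrics=len(table), alpha=0.05)
        report = comparison_report(table)
        paths["stats"] = out_dir / "stats.csv"
        report.to_csv(paths["stats"], index=False)
    except PipelineError:
        _flush_log(log, out_dir, paths)
        raise
    except Exception as exc:
        _flush_log(log, out_dir, paths)
        raise PipelineError(f"stage {current} failed: {exc}") from exc

    log.append("pipeline complete")
    _flush_log(log, out_dir, paths)
    return paths


def _section(mask, cl, s):
    from .geometry import cross_section_at

    return cross_section_at(mask, cl, s)


def _axis_end(mask, near_point=None):
    """Caudal-most lumen voxel center (max z) near the axis of ``near_point``."""
    pts = mask.world_points()
    k = np.argmax(pts[:, 2])
    z_max = pts[k, 2]
    slab = pts[pts[:, 2] > z_max - 1.5 * mask.spacing_mm[2]]
    return slab.mean(axis=0)


def _flush_log(log, out_dir, paths):
    paths["log"] = out_dir / "pipeline.log"
    Path(paths["log"]).write_text("\n".join(log) + "\n")
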