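"""The two experiment recipes, bound end to end.

``run_stimuli_experiment`` contrasts the biophysical environment of the knee
under normal dynamic contraction (mid-flexion / mid-extension snapshots)
against rigid paralysis on the same mesh, materials and boundary conditions.
``run_morphology_experiment`` generates seeded phantom cohorts per treatment
arm, measures them, runs the per-measurement ANOVA stage, and simulates and
fits the proliferation counts.  Outputs are plain CSV (header row naming
units), legacy VTK fields, and a JSON flag block; config + seed fully
determine every output file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as jio
from .config import PipelineConfig, UNITS
from .counts import generate_proliferation_counts
from .glmm import GLMMError, GLMMResult, fit_binomial_glmm
from .loads import build_load_case
from .mesh import CARTILAGE, femur_elements
from .meshing import attach_muscle_sets, phantom_to_mesh
from .morphometry import joint_landmarks_mm, locate_section_planes, measure_knee
from .phantom import MEASUREMENT_IDS, generate_joint_phantom, sample_phantom_params
from .poroelastic import BoundarySpec, solve_poroelastic
from .probes import (
    ComparisonReport,
    RegimeSummary,
    compare_regimes,
    default_probe_regions,
    summarise_regime,
)
from .stats import compare_measurements

log = logging.getLogger("jointmorph")


@dataclass
class StimuliResult:
    mesh: object
    solutions: dict                   # regime -> FieldSolution
    summaries: dict                   # "normal"/"paralysis" -> RegimeSummary
    report: ComparisonReport
    landmarks: dict


@dataclass
class MorphologyResult:
    measurements: pd.DataFrame
    comparisons: pd.DataFrame | None
    counts: pd.DataFrame
    glmm: GLMMResult | None
    errors: dict


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %s: %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def build_joint_model(cfg: PipelineConfig):
    """Phantom -> section mesh with attachments, landmarks and probe regions."""
    volume = generate_joint_phantom(cfg.phantom)
    sections = locate_section_planes(volume)
    landmarks = joint_landmarks_mm(volume)
    mesh = phantom_to_mesh(volume, sections.midline, cfg.target_edge)
    attach_muscle_sets(mesh)
    regions = default_probe_regions(landmarks, band_mm=cfg.band_mm)
    # distal-femur cartilage: femoral body below the fossa floor (the shaft
    # above carries attachment/cut concentrations, not the articular
    # stimulus patterns of interest)
    femur_body = femur_elements(mesh)
    zc = mesh.centroids()[:, 1]
    femoral_mask = femur_body & (zc <= landmarks["z_fossa_floor"] + 0.02)
    return volume, sections, landmarks, mesh, regions, femoral_mask, femur_body


@_stage("stimuli")
def run_stimuli_experiment(cfg: PipelineConfig, out_dir: str | Path | None = None) -> StimuliResult:
    """Solve flexion, extension and paralysis; summarise and contrast."""
    volume, sections, landmarks, mesh, regions, femoral_mask, femur_body = build_joint_model(cfg)
    bc = BoundarySpec(fixed={"femur_cut": "both", "tibiotarsus_cut": "both"})
    muscles = list(cfg.muscles)

    solutions = {}
    for regime in ("flexion", "extension", "paralysis"):
        case = build_load_case(muscles, regime, cfg.paralysis_scale)
        scheme = cfg.paralysis_time if regime == "paralysis" else cfg.contraction
        solutions[regime] = solve_poroelastic(
            mesh, cfg.materials, case, scheme, bc,
            stabilisation=cfg.stabilisation, regime=regime)

    normal = summarise_regime("normal", regions, solutions["flexion"],
                              solutions["extension"], femoral_mask,
                              femur_body=femur_body)
    paralysis = summarise_regime("paralysis", regions, solutions["paralysis"],
                                 None, femoral_mask, femur_body=femur_body)
    report = compare_regimes(normal, paralysis,
                             cfg.compression_area_threshold,
                             cfg.tension_threshold_frac)
    result = StimuliResult(mesh, solutions, {"normal": normal, "paralysis": paralysis},
                           report, landmarks)
    if out_dir is not None:
        _write_stimuli(result, Path(out_dir))
    return result


def _write_stimuli(res: StimuliResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for regime, sol in res.solutions.items():
        jio.write_vtk(sol, out / f"fields_{regime}.vtk")
    summary = pd.concat([s.table for s in res.summaries.values()], ignore_index=True)
    summary.insert(0, "units", "kPa (stress, pressure) / mm_per_s (fluid velocity)")
    summary.to_csv(out / "region_summary.csv", index=False)
    amp = pd.concat([s.amplitude for s in res.summaries.values()], ignore_index=True)
    amp.insert(0, "units", "kPa (stress, pressure) / mm_per_s (fluid velocity)")
    amp.to_csv(out / "dynamic_amplitude.csv", index=False)
    ratios = res.report.ratios.copy()
    ratios.insert(0, "units", "dimensionless ratio paralysis/normal")
    ratios.to_csv(out / "regime_ratios.csv", index=False)
    with open(out / "comparison_flags.json", "w") as fh:
        json.dump({"flags": res.report.flags, "thresholds": res.report.thresholds},
                  fh, indent=2, sort_keys=True)


@_stage("morphology")
def run_morphology_experiment(cfg: PipelineConfig, out_dir: str | Path | None = None) -> MorphologyResult:
    """Seeded phantom cohorts -> measurements -> ANOVA; counts -> GLMM."""
    rng = np.random.default_rng(cfg.seed)
    arms = cfg.arms
    rows = []
    errors: dict[str, str] = {}
    for arm, n, simp in (("control", arms.n_control, arms.control_simplification),
                         ("immobilised", arms.n_immobilised, arms.immobilised_simplification)):
        for i in range(n):
            sid = f"{arm[:3]}{i + 1:03d}"
            try:
                p = sample_phantom_params(rng, cfg.phantom, cv=arms.cv,
                                          shape_simplification=simp)
                vol = generate_joint_phantom(p)
                ms = measure_knee(vol, specimen_id=sid, treatment=arm, day=arms.day)
                rows.append(ms.as_row())
            except Exception as exc:  # propagate per-specimen context
                errors[sid] = str(exc)
                log.warning("specimen %s failed: %s", sid, exc)
    measurements = pd.DataFrame(rows)

    comparisons = None
    try:
        comparisons = compare_measurements(measurements, day=arms.day)
    except ValueError as exc:
        errors["anova"] = str(exc)
        log.warning("ANOVA stage skipped: %s", exc)

    counts = generate_proliferation_counts(cfg.counts)
    glmm = None
    try:
        glmm = fit_binomial_glmm(counts)
    except GLMMError as exc:
        errors["glmm"] = str(exc)
        log.warning("GLMM stage skipped: %s", exc)

    result = MorphologyResult(measurements, comparisons, counts, glmm, errors)
    if out_dir is not None:
        _write_morphology(result, cfg, Path(out_dir))
    return result


def _write_morphology(res: MorphologyResult, cfg: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    meas = res.measurements.copy()
    meas.insert(0, "units", UNITS["length"])
    meas.to_csv(out / "measurements.csv", index=False)
    if res.comparisons is not None:
        comp = res.comparisons.copy()
        comp.insert(0, "units", "mm (means); percent; F dimensionless")
        comp.to_csv(out / "measurement_comparison.csv", index=False)
    counts = res.counts.copy()
    counts.insert(0, "units", "cell counts per 1.44 mm^2 box")
    counts.to_csv(out / "proliferation_counts.csv", index=False)
    if res.glmm is not None:
        with open(out / "glmm_fit.json", "w") as fh:
            json.dump(dataclasses.asdict(res.glmm), fh, indent=2, sort_keys=True)
        with open(out / "glmm_fit.log", "w") as fh:
            fh.write(res.glmm.summary() + "\n")
    if res.errors:
        with open(out / "stage_errors.json", "w") as fh:
            json.dump(res.errors, fh, indent=2, sort_keys=True)
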