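"""Case- and cohort-level orchestration.

``run_case`` executes the full chain for one eye:

topography (+ mirroring) -> clinical power/RPC maps and treatment-zone
detection -> stress-free reference geometry -> IOP inflation -> ICP lens
seating at the detected decentration -> eyelid detection and lid solid ->
staged contact FEA -> barometer field extraction and FEA RPC ->
NCC/SSIM comparison against the clinical RPC.

``run_cohort`` iterates seeded synthetic cases and aggregates band-area
statistics.  Every constant of the method (refractive index, smoothing
factor, pressures, tolerances, band edges) is surfaced as a defaulted
config key, so the reference values are defaults rather than hard-codes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import comparison as cmp
from . import fea
from .eyelid import build_eyelid_mesh, detect_eyelid_boundary, EyelidBoundary
from .maps import GridMap
from .meshing import CORNEA_PRESETS, LensDesign, build_cornea_mesh, build_lens_mesh
from .power_maps import (PowerMapConfig, ZoneAnalysis, detect_zones, rpc_map,
                         smooth_map, tangential_curvature_map,
                         tangential_power_map)
from .registration import seat_lens
from .synthetic import CohortSpec, apply_orthok_effect, generate_patient
from .topography import (TopographyRecord, extend_surface, read_topography,
                         to_right_eye_frame)

log = logging.getLogger("orthok")

BAROMETERS = ("contact_pressure", "mises", "pressure",
              "max_principal_stress", "max_principal_log_strain")


@dataclass
class CaseConfig:
    """Everything one case needs; defaults are the reference constants."""

    mesh_preset: str = "desk"
    eyelid_grid: tuple | None = None    # derived from mesh_preset if None
    eyelid_thickness_mm: float = 0.5
    eyelid_clearance_mm: float = 0.05
    seat_standoff_mm: float = 0.01
    power: PowerMapConfig = field(default_factory=PowerMapConfig)
    program: fea.LoadProgram = field(default_factory=fea.LoadProgram)
    stress_free_tol_mm: float = 1e-4
    stress_free_max_iter: int = 30
    edge_margin_mm: float = 0.5
    analysis_radius_mm: float = 5.5
    skip_fea: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "CaseConfig":
        d = dict(d)
        if "power" in d and isinstance(d["power"], dict):
            d["power"] = PowerMapConfig(**d["power"])
        if "program" in d and isinstance(d["program"], dict):
            d["program"] = fea.LoadProgram(**d["program"])
        if "eyelid_grid" in d:
            d["eyelid_grid"] = tuple(d["eyelid_grid"])
        return cls(**d)


@dataclass
class CaseReport:
    """Artefacts of one processed eye."""

    patient_id: str
    schema_version: str = "1"
    decentration_mm: tuple = (float("nan"), float("nan"))
    zone: ZoneAnalysis | None = None
    seating: dict = field(default_factory=dict)
    convergence: list = field(default_factory=list)
    clinical_rpc: GridMap | None = None
    fea_rpc: GridMap | None = None
    fields: dict = field(default_factory=dict)
    comparison: cmp.ComparisonResult | None = None
    stress_free_iterations: int = 0
    timings_s: dict = field(default_factory=dict)

    def band_table(self):
        import pandas as pd

        rows = []
        for b in self.comparison.barometers:
            for metric in ("ncc", "ssim"):
                bands = getattr(self.comparison, f"{metric}_bands")[b]
                rows.append({"barometer": b, "metric": metric, **bands})
        return pd.DataFrame(rows)


def clinical_rpc_maps(pre: TopographyRecord, post: TopographyRecord,
                      cfg: PowerMapConfig):
    """Smoothed pre/post tangential power maps and their RPC (polar)."""
    maps = []
    for rec in (pre, post):
        curv = tangential_curvature_map(rec, cfg)
        power = tangential_power_map(curv, cfg)
        maps.append(smooth_map(power, cfg))
    return maps[0], maps[1], rpc_map(maps[0], maps[1])


def run_case(
    pre: TopographyRecord,
    post: TopographyRecord,
    patient,
    lens_design: LensDesign,
    config: CaseConfig | None = None,
) -> CaseReport:
    """Process one eye end to end.  Stage failures raise with the stage name."""
    config = config or CaseConfig()
    report = CaseReport(patient_id=getattr(patient, "id", "case"))
    t0 = time.time()
    stage = "topography"
    try:
        pre = to_right_eye_frame(pre)
        post = to_right_eye_frame(post)

        stage = "power_maps"
        _, _, rpc_polar = clinical_rpc_maps(pre, post, config.power)
        zone = detect_zones(rpc_polar, edge_margin_mm=config.edge_margin_mm)
        report.zone = zone
        decent = zone.decentration if zone.found else (0.0, 0.0)
        report.decentration_mm = decent
        grid = cmp.CommonGrid.default(analysis_radius_mm=config.analysis_radius_mm)
        report.clinical_rpc = cmp.polar_to_grid(rpc_polar, grid)
        report.timings_s["maps"] = time.time() - t0
        if config.skip_fea:
            return report

        stage = "meshing"
        t1 = time.time()
        ext = extend_surface(pre)
        base, rings, layers = CORNEA_PRESETS[config.mesh_preset]
        cornea = build_cornea_mesh(ext, patient.cct, layers=layers, base=base,
                                   rings=rings)
        E_cornea = fea.young_modulus_from_age(patient.age)

        stage = "stress_free"
        cornea0, history = fea.find_stress_free_geometry(
            cornea, E_cornea, 0.49, patient.iop,
            tol_mm=config.stress_free_tol_mm,
            max_iter=config.stress_free_max_iter)
        report.stress_free_iterations = len(history)

        # inflate the stress-free eye alone to recover the worn geometry
        stage = "inflation"
        model = fea.FEModel(cornea0, E_cornea, 0.49)
        model.fix(cornea0.node_sets["rim_fixed"])
        iop_load = fea.PressureLoad(cornea0.facet_quads("inner_wall"),
                                    patient.iop * fea.MMHG_TO_MPA)
        infl = model.solve([iop_load], increments=config.program.iop_increments,
                           tol=config.program.newton_tol)
        inflated = cornea0.copy()
        inflated.nodes = cornea0.nodes + infl.u.reshape(-1, 3)

        stage = "seating"
        lens = build_lens_mesh(lens_design)
        ext_inflated = _extended_from_mesh(inflated, ext)
        radial = ext_inflated
        lens_seated, transform, seat_rep = seat_lens(
            lens, decent, radial, standoff_mm=config.seat_standoff_mm)
        report.seating = seat_rep.to_dict()

        stage = "eyelid"
        lids = detect_eyelid_boundary(pre.coverage, pre.azimuths_deg, pre.radii_mm)
        if lids is None:
            lids = EyelidBoundary((-0.0832, -0.0262, 3.5809),
                                  (0.0842, 0.0163, -3.9734))
        nx, ny = (config.eyelid_grid
                  or {"desk": (31, 25), "paper": (51, 41)}[config.mesh_preset])
        lens_front_pts = lens_seated.nodes[lens_seated.node_sets["front_nodes"]]
        eyelid = build_eyelid_mesh(
            lids, radial, thickness_mm=config.eyelid_thickness_mm,
            nx=nx, ny=ny, clearance_mm=config.eyelid_clearance_mm,
            overlay_points=lens_front_pts)

        stage = "fea"
        # parts are referenced to the stress-free state; the lens/eyelid were
        # built against the inflated surface, consistent at the IOP state
        asm = fea.build_assembly(cornea0, fea.MaterialModel(E_cornea, 0.49),
                                 lens=lens_seated, eyelid=eyelid)
        from dataclasses import replace as _replace
        program = _replace(config.program, iop_mmhg=patient.iop)
        prog = fea.run_load_program(asm, program)
        report.convergence = prog.result.convergence_log
        report.timings_s["fea"] = time.time() - t1

        stage = "fields"
        t2 = time.time()
        for name in BAROMETERS:
            xy, vals = fea.extract_field(prog, name)
            report.fields[name] = cmp.resample_to_grid(xy, vals, grid)
        rpc_fea_polar = fea.fea_rpc(prog, config.power)
        report.fea_rpc = cmp.polar_to_grid(rpc_fea_polar, grid)

        stage = "comparison"
        report.comparison = cmp.compare_fields(report.clinical_rpc,
                                               report.fields, grid)
        report.timings_s["comparison"] = time.time() - t2
        return report
    except Exception as exc:
        raise RuntimeError(f"case {report.patient_id} failed at stage "
                           f"'{stage}': {exc}") from exc


def _extended_from_mesh(inflated_mesh, ext):
    """Radial surface of the inflated anterior nodes (for seating/eyelid)."""
    from .fea.fields import surface_to_polar_record
    from .topography import extend_surface as _ext

    pts = inflated_mesh.nodes[inflated_mesh.node_sets["anterior_nodes"]]
    rec = surface_to_polar_record(pts, n_az=120, n_r=120)
    surf = _ext(rec, fit_radius_mm=min(5.5, rec.radii_mm[-1] * 1.05),
                rim_radius_mm=max(8.2, rec.radii_mm[-1] + 0.1))
    return surf.to_radial()


def run_synthetic_case(spec: CohortSpec, index: int,
                       config: CaseConfig | None = None) -> CaseReport:
    """Generate patient ``index`` of a synthetic cohort and process it."""
    patient, pre, lens, effect = generate_patient(spec, index)
    post = apply_orthok_effect(pre, effect)
    report = run_case(pre, post, patient, lens, config)
    # analysis is laterality-agnostic (left eyes mirrored at ingest), so
    # the ground-truth decentration is reported in the same mirrored frame
    dx, dy = effect.decentration
    report.true_decentration = (-dx if patient.eye == "left" else dx, dy)
    return report


@dataclass
class CohortReport:
    reports: list
    failures: list
    summary: dict
    table: object = None


def run_cohort(spec: CohortSpec, config: CaseConfig | None = None,
               outdir: str | Path | None = None) -> CohortReport:
    """Run every case of a synthetic cohort and aggregate band areas.

    Individual case failures are logged, skipped, and counted.
    """
    reports, failures = [], []
    for i in range(spec.n):
        t0 = time.time()
        try:
            rep = run_synthetic_case(spec, i, config)
            reports.append(rep)
            log.info("case %d/%d done in %.1f s", i + 1, spec.n, time.time() - t0)
        except Exception as exc:   # noqa: BLE001 - cohort robustness by contract
            log.warning("case %d failed: %s", i, exc)
            failures.append({"index": i, "error": str(exc)})
    summary = {}
    table = None
    comparisons = [r.comparison for r in reports if r.comparison is not None]
    if comparisons:
        summary = cmp.cohort_summary(comparisons)
        table = cmp.summary_table(summary)
    summary["n_failed"] = len(failures)
    out = CohortReport(reports, failures, summary, table)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if table is not None:
            table.to_csv(outdir / "band_areas.csv", index=False)
        with open(outdir / "cohort_summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
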