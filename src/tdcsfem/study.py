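"""Within-subject simulation study on a synthetic stroke cohort.

For every synthetic subject the pipeline builds a lesioned head model,
solves the conventional bi-hemispheric C3/C4 montage, optimizes the
montage on 11.11 mm candidate grids around the conventional positions
(which are always members of the grids, so the optimized ROI field can
never fall below the conventional one), and records the field,
improvement and electrode-displacement metrics.  Group statistics then
compare conventional vs optimized fields (Wilcoxon signed-rank), electrode
displacement by lesion location (Mann-Whitney), and displacement /
improvement vs the initial FMA-UE score (Spearman with Fisher-z CI).

All computation is deterministic for a fixed master seed; subject-level
seeds derive from it by a fixed counter scheme.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import head_model as hm
from .electrodes import (
    DEFAULT_CURRENT_MA,
    DEFAULT_GRID_EXTENT,
    DEFAULT_GRID_SPACING,
    DEFAULT_OVERLAP_MIN_DISTANCE,
    DEFAULT_PATCH_SIZE,
    SurfaceProjector,
    build_candidate_grid,
    conventional_montage,
)
from .exceptions import ConfigError, DegenerateDataError, TdcsFemError
from .fem import (
    DirectSolver,
    FieldSolution,
    assemble_system,
    element_fields,
)
from .head_model import (
    SubjectCovariates,
    build_layered_sphere_head,
    generate_cohort_covariates,
    insert_lesion,
    subject_seed,
)
from .metrics import (
    DEFAULT_ROI_RADIUS,
    ROISpec,
    improvement_pct,
    montage_distances,
    roi_summary,
)
from .optimize import optimize_montage
from .stats import (
    StatsReport,
    ks_normality,
    mann_whitney_u,
    spearman_ci,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One TOML file drives a whole study; defaults mirror the study
    conditions (2 mA, 5x5 cm pads, 11.11 mm grids, 2 mm ROI, 8/11/2
    lesion-location counts, standard conductivity table)."""

    n_subjects: int = 21
    class_counts: dict = field(
        default_factory=lambda: dict(hm.DEFAULT_CLASS_COUNTS))
    seed: int = 0
    effect_params: dict = field(default_factory=dict)

    layer_radii: tuple = hm.DEFAULT_LAYER_RADII
    mesh_size: float = 6.0
    conductivities: dict = field(
        default_factory=lambda: dict(hm.DEFAULT_CONDUCTIVITIES))

    solver_tol: float = 1e-9
    solver_method: str = "direct"   # direct | cg (study-internal solves)

    current_ma: float = DEFAULT_CURRENT_MA
    patch_size: tuple = DEFAULT_PATCH_SIZE
    grid_extent: float = DEFAULT_GRID_EXTENT
    grid_spacing: float = DEFAULT_GRID_SPACING
    overlap_min_distance: float = DEFAULT_OVERLAP_MIN_DISTANCE
    max_iterations: int = 10
    rel_tol: float = 1e-4

    roi_radius: float = DEFAULT_ROI_RADIUS

    out_dir: str = "results/study"
    export_meshes: bool = False
    max_failure_fraction: float = 0.2

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if sum(self.class_counts.values()) != self.n_subjects:
            raise ConfigError("class_counts must sum to n_subjects")
        if self.mesh_size <= 0 or self.roi_radius <= 0:
            raise ConfigError("mesh_size and roi_radius must be > 0")
        if self.solver_method not in ("direct", "cg"):
            raise ConfigError(f"unknown solver method {self.solver_method!r}")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        try:
            raw = tomllib.loads(Path(path).read_text())
        except (OSError, tomllib.TOMLDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        flat = {}
        known = {f.name for f in dataclasses.fields(cls)}
        for key, val in raw.items():
            if isinstance(val, dict):
                for k2, v2 in val.items():
                    name = k2 if k2 in known else f"{key}_{k2}"
                    if name not in known:
                        raise ConfigError(
                            f"unknown config key [{key}] {k2}")
                    flat[name] = v2
            else:
                if key not in known:
                    raise ConfigError(f"unknown config key {key}")
                flat[key] = val
        for tup in ("layer_radii", "patch_size"):
            if tup in flat:
                flat[tup] = tuple(flat[tup])
        return cls(**flat)

    def digest(self) -> str:
        """Hash of the scientific configuration (output paths excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        d.pop("export_meshes", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# per-subject simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortRecord:
    covariates: SubjectCovariates
    conventional: object
    optimized: object
    improvement_pct: float
    distances: object
    score_trace: list
    n_evaluated: int
    iterations: int
    status: str = "ok"
    error: str = ""


def simulate_subject(cov: SubjectCovariates, config: RunConfig,
                     master_seed: int, index: int,
                     keep_solutions: bool = False):
    """Run the full conventional-vs-optimized comparison for one subject."""
    head = build_layered_sphere_head(
        config.layer_radii, config.conductivities, config.mesh_size,
        cov.affected_side, seed=subject_seed(master_seed, index))
    head = insert_lesion(head, cov.lesion)
    proj = SurfaceProjector(head.mesh)
    roi = ROISpec(head.target, config.roi_radius)

    conv = conventional_montage(head, config.current_ma, config.patch_size,
                                projector=proj)
    system = assemble_system(head)
    solver = DirectSolver(system)

    anode_grid = build_candidate_grid(
        head, conv.anode.center, config.grid_extent, config.grid_spacing,
        projector=proj)
    cathode_grid = build_candidate_grid(
        head, conv.cathode.center, config.grid_extent, config.grid_spacing,
        projector=proj)

    opt_res = optimize_montage(
        head, roi, anode_grid, cathode_grid,
        current=config.current_ma, size=config.patch_size,
        max_iterations=config.max_iterations, rel_tol=config.rel_tol,
        overlap_min_distance=config.overlap_min_distance,
        tie_break_reference=(conv.anode.center, conv.cathode.center),
        system=system, solver=solver, projector=proj)

    def solve_for(montage) -> FieldSolution:
        from .fem import apply_montage_currents

        loaded = apply_montage_currents(system, montage)
        v = solver.solve(loaded.load)
        return FieldSolution(v, element_fields(v, head.mesh), 0.0)

    sol_conv = solve_for(conv)
    sol_opt = solve_for(opt_res.montage)
    sum_conv = roi_summary(sol_conv, head, roi)
    sum_opt = roi_summary(sol_opt, head, roi)
    record = CohortRecord(
        covariates=cov,
        conventional=sum_conv,
        optimized=sum_opt,
        improvement_pct=improvement_pct(sum_conv.mean_magnitude,
                                        sum_opt.mean_magnitude),
        distances=montage_distances(conv, opt_res.montage),
        score_trace=opt_res.trace,
        n_evaluated=opt_res.n_evaluated,
        iterations=opt_res.iterations,
    )
    if keep_solutions:
        return record, head, (conv, opt_res.montage), (sol_conv, sol_opt)
    return record


# ---------------------------------------------------------------------------
# study driver
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    table: pd.DataFrame
    stats: list[StatsReport]
    summary: str
    n_failed: int
    out_dir: Path | None


def _record_row(i: int, cov: SubjectCovariates, rec: CohortRecord | None,
                err: str = "") -> dict:
    row = {
        "subject_id": cov.subject_id,
        "class": cov.lesion.location_class,
        "affected_side": cov.affected_side,
        "lesion_x": cov.lesion.center[0],
        "lesion_y": cov.lesion.center[1],
        "lesion_z": cov.lesion.center[2],
        "lesion_r": cov.lesion.radius,
        "fma_ue": cov.fma_ue,
        "age": cov.age,
        "sex": cov.sex,
        "status": "ok" if rec else "failed",
        "error": err,
    }
    if rec is not None:
        row.update({
            "conv_field": rec.conventional.mean_magnitude,
            "conv_normal": rec.conventional.normal_component,
            "opt_field": rec.optimized.mean_magnitude,
            "opt_normal": rec.optimized.normal_component,
            "improvement_pct": rec.improvement_pct,
            "d_anode": rec.distances.d_anode,
            "d_cathode": rec.distances.d_cathode,
            "d_total": rec.distances.d_total,
            "within_conv": rec.distances.within_conventional,
            "within_opt": rec.distances.within_optimized,
            "n_evaluated": rec.n_evaluated,
            "iterations": rec.iterations,
        })
    return row


def group_statistics(table: pd.DataFrame) -> list[StatsReport]:
    """The study's statistical battery on the per-subject table."""
    ok = table[table["status"] == "ok"]
    out = []

    def attempt(fn, *args, **kwargs):
        # small or degenerate cohorts cannot support every test; record
        # the ones that apply rather than failing the whole study
        try:
            out.append(fn(*args, **kwargs))
        except DegenerateDataError:
            pass

    attempt(ks_normality, ok["conv_field"], name="ks-normality conv_field")
    attempt(wilcoxon_signed_rank, ok["conv_field"], ok["opt_field"],
            name="wilcoxon conv_vs_opt_field")
    cortical = ok[ok["class"] == "cortical"]["d_total"]
    non_cortical = ok[ok["class"] != "cortical"]["d_total"]
    if len(cortical) and len(non_cortical):
        attempt(mann_whitney_u, cortical, non_cortical,
                name="mann-whitney d_total cortical_vs_non")
    attempt(spearman_ci, ok["d_total"], ok["fma_ue"],
            name="spearman d_total_vs_fma")
    attempt(spearman_ci, ok["improvement_pct"], ok["fma_ue"],
            name="spearman improvement_vs_fma")
    return out


def run_study(config: RunConfig, write_outputs: bool = True) -> StudyReport:
    """Run the complete cohort study; optionally write the report files."""
    covs = generate_cohort_covariates(
        config.n_subjects, config.class_counts, config.effect_params,
        config.seed, config.layer_radii)
    rows = []
    n_failed = 0
    for i, cov in enumerate(covs):
        try:
            rec = simulate_subject(cov, config, config.seed, i)
            rows.append(_record_row(i, cov, rec))
        except TdcsFemError as exc:  # isolate per-subject failures
            n_failed += 1
            rows.append(_record_row(i, cov, None, err=str(exc)))
    table = pd.DataFrame(rows)
    stats = group_statistics(table)
    summary = _summary_text(config, table, stats, n_failed)
    out_dir = None
    if write_outputs:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = ("# tdcsfem study  seed=%d  config=%s\n"
                  % (config.seed, config.digest()))
        for name, df in (("results.csv", table),
                         ("cohort.csv", table[[
                             "subject_id", "class", "affected_side",
                             "lesion_x", "lesion_y", "lesion_z", "lesion_r",
                             "fma_ue", "age", "sex"]])):
            with (out_dir / name).open("w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)
        (out_dir / "stats.json").write_text(json.dumps(
            {"seed": config.seed, "config": config.digest(),
             "tests": [s.to_dict() for s in stats],
             "note": "no multiple-testing correction applied"},
            indent=1, default=float))
        (out_dir / "summary.txt").write_text(summary)
    return StudyReport(table, stats, summary, n_failed, out_dir)


def _summary_text(config, table, stats, n_failed) -> str:
    ok = table[table["status"] == "ok"]

    def med_iqr(col):
        q1, q2, q3 = np.percentile(ok[col], [25, 50, 75])
        return f"{q2:.3g} [{q1:.3g}-{q3:.3g}]"

    lines = [
        f"tdcsfem synthetic within-subject study",
        f"seed={config.seed} config={config.digest()} "
        f"n={config.n_subjects} mesh_size={config.mesh_size} mm "
        f"failed={n_failed}",
        "",
        f"conventional ROI field, median [IQR] V/m : {med_iqr('conv_field')}",
        f"optimized ROI field,    median [IQR] V/m : {med_iqr('opt_field')}",
        f"improvement %,          median [IQR]     : "
        f"{med_iqr('improvement_pct')}",
        f"D (anode+cathode shift) median [IQR] mm  : {med_iqr('d_total')}",
        "",
    ]
    for s in stats:
        eff = f" effect={s.effect:.3f}" if s.effect is not None else ""
        ci = (f" CI95=[{s.ci_low:.3f}, {s.ci_high:.3f}]"
              if s.ci_low is not None else "")
        lines.append(f"{s.name}: stat={s.statistic:.4g} "
                     f"p={s.p_value:.4g}{eff}{ci} (n={s.n}; {s.note})")
    lines.append("")
    lines.append("no multiple-testing correction applied")
    return "\n".join(lines) + "\n"
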