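"""End-to-end pipeline: simulate -> integrate -> calibrate -> validate -> NCA.

A single :class:`PipelineConfig` (loadable from YAML) defines both study
analytes, their calibration ranges, QC levels, error model, the sampling
schedule and the acceptance thresholds.  :func:`run_pipeline` executes the
stages in order, writes every table as CSV/Markdown and records a run log
with the seed and a config hash, so the same config and seed always
reproduce a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import calibration as cal
from . import chromatography as chrom
from . import nca as nca_mod
from . import simulate as sim
from . import validation as val

__all__ = [
    "PipelineConfig",
    "AnalyteConfig",
    "default_config",
    "load_config",
    "run_pipeline",
    "render_validation_tables",
    "render_markdown_table",
    "PipelineReport",
]


class ErrorConfig(BaseModel):
    proportional_cv: float = Field(0.05, ge=0)
    additive_sd: float = Field(0.0, ge=0)
    lloq: float = Field(..., gt=0)


class PKConfig(BaseModel):
    dose_ng: float = Field(..., gt=0)
    volume_over_f_ml: float = Field(..., gt=0)
    ka: float = Field(..., gt=0)
    ke: float = Field(..., gt=0)
    bioavailability: float = Field(1.0, ge=0, le=1)
    tlag: float = Field(0.0, ge=0)

    def to_params(self) -> sim.PKModelParams:
        return sim.PKModelParams(
            dose=self.dose_ng,
            volume_over_f=self.volume_over_f_ml,
            ka=self.ka,
            ke=self.ke,
            bioavailability=self.bioavailability,
            tlag=self.tlag,
        )


class RulesConfig(BaseModel):
    acc_limit: float = Field(15.0, gt=0)
    rsd_limit: float = Field(15.0, gt=0)
    lloq_acc_limit: float = Field(20.0, gt=0)
    lloq_rsd_limit: float = Field(20.0, gt=0)

    def to_rules(self) -> val.AcceptanceRules:
        return val.AcceptanceRules(
            acc_limit=self.acc_limit,
            rsd_limit=self.rsd_limit,
            lloq_acc_limit=self.lloq_acc_limit,
            lloq_rsd_limit=self.lloq_rsd_limit,
        )


class AnalyteConfig(BaseModel):
    name: str
    internal_standard: str
    calibration_levels: list[float]
    qc_levels: dict[str, float]
    true_slope: float
    true_intercept: float = 0.0
    error: ErrorConfig
    pk: PKConfig
    retention_time: float = Field(..., gt=0, le=chrom.RUN_TIME_MIN)
    is_retention_time: float = Field(..., gt=0, le=chrom.RUN_TIME_MIN)
    response_factor: float = Field(2.0, gt=0)  # counts per ng/mL in traces
    true_recovery: float = Field(0.98, gt=0, le=1.5)
    stability_bias: float = Field(-0.06, ge=-0.5, le=0.5)

    @field_validator("calibration_levels")
    @classmethod
    def _levels_positive(cls, v):
        if len(v) < 2 or any(x <= 0 for x in v):
            raise ValueError("need >= 2 positive calibration levels")
        return sorted(v)

    @field_validator("qc_levels")
    @classmethod
    def _qc_positive(cls, v):
        if any(x <= 0 for x in v.values()):
            raise ValueError("QC nominals must be positive")
        return v


class PipelineConfig(BaseModel):
    analytes: list[AnalyteConfig]
    schedule: list[float] = Field(default_factory=lambda: list(sim.STUDY_SCHEDULE.times))
    n_subjects: int = Field(2, ge=1)
    replicates: int = Field(6, ge=2)
    days: int = Field(3, ge=1)
    n_lots: int = Field(6, ge=2)
    dilution_factors: list[int] = Field(default_factory=lambda: [2, 4])
    # 1/x^2 matches the simulator's proportional error model and keeps the
    # low end of a 100-fold calibration range back-calculable
    weighting: Literal["none", "1/x", "1/x2"] = "1/x2"
    auc_method: Literal["linear_up_log_down", "linear"] = "linear_up_log_down"
    rules: RulesConfig = Field(default_factory=RulesConfig)
    chrom_noise_sd: float = Field(5.0, ge=0)
    seed: int = 0

    @field_validator("schedule")
    @classmethod
    def _schedule_ok(cls, v):
        if not v or v[0] < 0 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("schedule must be strictly increasing, starting >= 0")
        return v

    @model_validator(mode="after")
    def _analytes_present(self):
        if not self.analytes:
            raise ValueError("at least one analyte required")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_config() -> PipelineConfig:
    """Two-analyte configuration mirroring the assay's published design.

    Metformin: calibration 50-5000 ng/mL (8 standards), QC at
    50/150/1000/4000, response line Y = 0.0016 X - 0.0088.  Canagliflozin:
    10-1000 ng/mL, QC at 10/30/200/800, Y = 0.0056 X - 0.0036.  Two
    subjects sampled on the 16-point 0-72 h schedule.
    """
    met = AnalyteConfig(
        name="MET",
        internal_standard="PPL",
        calibration_levels=[50, 100, 250, 500, 1000, 2000, 4000, 5000],
        qc_levels=dict(val.MET_QC_LEVELS),
        true_slope=0.0016,
        true_intercept=-0.0088,
        error=ErrorConfig(proportional_cv=0.05, additive_sd=0.0, lloq=50.0),
        pk=PKConfig(
            dose_ng=850e6, volume_over_f_ml=5.88e5,
            ka=0.57, ke=math.log(2) / 6.03,
        ),
        retention_time=0.9,
        is_retention_time=1.1,
        response_factor=2.0,
    )
    cfz = AnalyteConfig(
        name="CFZ",
        internal_standard="TDF",
        calibration_levels=[10, 20, 50, 100, 200, 400, 800, 1000],
        qc_levels=dict(val.CFZ_QC_LEVELS),
        true_slope=0.0056,
        true_intercept=-0.0036,
        error=ErrorConfig(proportional_cv=0.05, additive_sd=0.0, lloq=10.0),
        pk=PKConfig(
            dose_ng=50e6, volume_over_f_ml=1.49e5,
            ka=0.55, ke=math.log(2) / 8.19,
        ),
        retention_time=4.5,
        is_retention_time=3.0,
        response_factor=10.0,
    )
    return PipelineConfig(analytes=[met, cfz])


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.model_validate(data)


def render_validation_tables(results: pd.DataFrame) -> str:
    """Render a validation table as CSV text.

    Emits exactly the four canonical columns
    ``level,mean_found_ng_ml,accuracy_pct,rsd_pct`` with two-decimal
    formatting, matching the layout of conventional validation reports.
    An empty input produces the header alone.
    """
    cols = ["level", "mean_found_ng_ml", "accuracy_pct", "rsd_pct"]
    lines = [",".join(cols)]
    for _, row in results.iterrows():
        lines.append(
            "{level},{mean_found_ng_ml:.2f},{accuracy_pct:.2f},{rsd_pct:.2f}".format(
                **{c: row[c] for c in cols}
            )
        )
    return "\n".join(lines) + "\n"


def render_markdown_table(df: pd.DataFrame, floatfmt: str = "{:.2f}") -> str:
    """Minimal GitHub-style Markdown table renderer."""
    def fmt(v):
        return floatfmt.format(v) if isinstance(v, float) else str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(" --- " for _ in df.columns) + "|"
    rows = ["| " + " | ".join(fmt(v) for v in row) + " |"
            for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *rows]) + "\n"


@dataclass
class StageStatus:
    name: str
    ok: bool
    detail: str = ""


@dataclass
class PipelineReport:
    """Everything :func:`run_pipeline` produced, plus where it was written."""

    outdir: Path
    seed: int
    config_hash: str
    stages: list[StageStatus] = dc_field(default_factory=list)
    curves: dict[str, cal.CalibrationResults] = dc_field(default_factory=dict)
    qc_tables: dict[str, pd.DataFrame] = dc_field(default_factory=dict)
    recovery_tables: dict[str, pd.DataFrame] = dc_field(default_factory=dict)
    stability_tables: dict[str, pd.DataFrame] = dc_field(default_factory=dict)
    dilution_tables: dict[str, pd.DataFrame] = dc_field(default_factory=dict)
    snr: dict[str, float] = dc_field(default_factory=dict)
    nca_results: pd.DataFrame | None = None
    nca_summary: pd.DataFrame | None = None

    def passed(self) -> bool:
        return all(s.ok for s in self.stages)


def _battery_frame(intra, inter) -> pd.DataFrame:
    rows = []
    for res in [*intra, *inter]:
        rows.append(
            {
                "level": res.level.name,
                "scope": res.scope,
                "n": res.n,
                "nominal_ng_ml": res.level.nominal,
                "mean_found_ng_ml": res.mean_found,
                "accuracy_pct": res.accuracy_pct,
                "rsd_pct": res.rsd_pct,
                "passed": res.passed,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    seed: int | None = None,
    outdir: str | Path = "plasmaquant_out",
) -> PipelineReport:
    """Execute every stage for every configured analyte.

    Stage order: simulation of all raw inputs; chromatographic integration
    of an LLOQ-level trace (S/N check); calibration fit and curve
    acceptance; the validation battery (accuracy/precision, recovery,
    matrix effect, dilution integrity, stability, selectivity); NCA on the
    simulated subject profiles.  A failing calibration halts the dependent
    validation/NCA stages for that analyte.
    """
    seed = config.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    report = PipelineReport(outdir=outdir, seed=seed,
                            config_hash=config.config_hash())
    rules = config.rules.to_rules()
    schedule = sim.SamplingSchedule(tuple(config.schedule))

    all_run_rows: list[pd.DataFrame] = []
    all_profiles: list[pd.DataFrame] = []
    nca_results: list[nca_mod.NCAResult] = []

    for acfg in config.analytes:
        name = acfg.name
        error = sim.AssayErrorModel(
            proportional_cv=acfg.error.proportional_cv,
            additive_sd=acfg.error.additive_sd,
            lloq=acfg.error.lloq,
            seed=seed,
        )

        # --- stage: simulate raw run data -------------------------------
        cal_design = sim.RunDesign(
            levels={name: acfg.calibration_levels},
            replicates=1,
            true_slope=acfg.true_slope,
            true_intercept=acfg.true_intercept,
        )
        cal_df = sim.simulate_run(cal_design, error, rng=rng)
        blanks = pd.DataFrame(
            [
                {"sample_id": f"{name}_blank", "analyte": name, "role": "blank",
                 "nominal_ng_ml": 0.0, "analyte_area": 0.0, "is_area": 0.0,
                 "lot": "lot1"},
                {"sample_id": f"{name}_zero", "analyte": name, "role": "zero",
                 "nominal_ng_ml": 0.0, "analyte_area": 0.0,
                 "is_area": cal_design.is_area, "lot": "lot1"},
            ]
        )
        qc_frames = []
        qc_design = sim.RunDesign(
            levels={name: sorted(acfg.qc_levels.values())},
            replicates=config.replicates,
            true_slope=acfg.true_slope,
            true_intercept=acfg.true_intercept,
            role="qc",
        )
        for day in range(1, config.days + 1):
            day_df = sim.simulate_run(qc_design, error, rng=rng)
            day_df["day"] = day
            qc_frames.append(day_df)
        qc_df = pd.concat(qc_frames, ignore_index=True)
        all_run_rows.append(pd.concat([blanks, cal_df], ignore_index=True))
        report.stages.append(StageStatus(f"simulate[{name}]", True,
                                         f"{len(cal_df)} standards, {len(qc_df)} QCs"))

        # --- stage: chromatography S/N at the LLOQ ----------------------
        transitions = {
            "MET": chrom.MET_TRANSITION, "PPL": chrom.PPL_TRANSITION,
            "CFZ": chrom.CFZ_TRANSITION, "TDF": chrom.TDF_TRANSITION,
        }
        tr = transitions.get(name) or chrom.MRMTransition(
            name, 200.0, 100.0, acfg.retention_time
        )
        traces = sim.simulate_chromatogram(
            [tr],
            {name: acfg.error.lloq},
            noise_sd=config.chrom_noise_sd,
            rng=rng,
            response_factor=acfg.response_factor,
        )
        peak = chrom.find_peak(traces[0], acfg.retention_time,
                               baseline_threshold=3 * config.chrom_noise_sd)
        if config.chrom_noise_sd > 0:
            snr_res = chrom.estimate_snr(traces[0], peak)
            report.snr[name] = snr_res.snr
            snr_ok = snr_res.lloq_supported
            detail = f"S/N={snr_res.snr:.1f}"
        else:
            report.snr[name] = math.inf
            snr_ok, detail = True, "noiseless trace"
        report.stages.append(StageStatus(f"chromatography[{name}]", snr_ok, detail))

        # --- stage: calibration -----------------------------------------
        try:
            model = cal.CalibrationModel.from_dataframe(
                pd.concat([blanks, cal_df], ignore_index=True),
                analyte=name, weighting=config.weighting,
            )
            fit = model.fit()
            assessment = fit.assess()
            report.curves[name] = fit
            (outdir / f"curve_{name}.json").write_text(
                json.dumps(fit.to_report(), indent=2, default=float) + "\n"
            )
            report.stages.append(
                StageStatus(f"calibrate[{name}]", assessment.curve_passed,
                            f"slope={fit.curve.slope:.6g} r={fit.curve.r:.4f}")
            )
            if not assessment.curve_passed:
                continue
        except ValueError as exc:
            report.stages.append(StageStatus(f"calibrate[{name}]", False, str(exc)))
            continue

        # --- stage: validation battery ----------------------------------
        nominal_to_level = {v: k for k, v in acfg.qc_levels.items()}
        qc_df["conc_found_ng_ml"] = [
            fit.back_calculate(a / i).conc
            for a, i in zip(qc_df["analyte_area"], qc_df["is_area"])
        ]
        qc_df["level"] = qc_df["nominal_ng_ml"].map(nominal_to_level)
        intra, inter, notes = val.qc_battery(qc_df, rules=rules,
                                             levels=acfg.qc_levels, analyte=name)
        battery = _battery_frame(intra, inter)
        report.qc_tables[name] = battery
        battery.to_csv(outdir / f"accuracy_{name}.csv", index=False)
        (outdir / f"accuracy_{name}.md").write_text(
            render_markdown_table(battery.drop(columns=["passed"]))
        )

        # recovery + matrix effect
        rec_rows = []
        for level in ("LQC", "MQC", "HQC"):
            nominal = acfg.qc_levels[level]
            post = (acfg.true_slope * nominal + acfg.true_intercept) * 1e5
            post_areas = post * (1 + rng.normal(0, error.proportional_cv,
                                                config.replicates))
            ext_areas = post * acfg.true_recovery * (
                1 + rng.normal(0, error.proportional_cv, config.replicates)
            )
            rec, rsd = val.recovery_percent(ext_areas, post_areas)
            rec_rows.append({"level": level, "metric": "recovery",
                             "value_pct": rec, "rsd_pct": rsd, "passed": True})
        mean_rec = val.mean_recovery([r["value_pct"] for r in rec_rows])
        for level in ("LQC", "HQC"):
            nominal = acfg.qc_levels[level]
            neat = (acfg.true_slope * nominal + acfg.true_intercept) * 1e5
            lots = {
                f"lot{i + 1}": neat * (1 + rng.normal(0, 0.05))
                for i in range(config.n_lots)
            }
            mf = val.matrix_factor(lots, neat)
            rec_rows.append({"level": level, "metric": "matrix_effect",
                             "value_pct": val.round_half_away(
                                 100 * float(np.mean(list(mf.mf_per_lot.values())))),
                             "rsd_pct": mf.rsd_pct, "passed": mf.passed})
        rec_table = pd.DataFrame(rec_rows)
        report.recovery_tables[name] = rec_table
        rec_table.to_csv(outdir / f"recovery_matrix_{name}.csv", index=False)
        report.stages.append(
            StageStatus(f"recovery[{name}]", bool(rec_table["passed"].all()),
                        f"mean recovery {mean_rec:.2f}%")
        )

        # dilution integrity
        dil_rows = []
        hqc = acfg.qc_levels["HQC"]
        for df_factor in config.dilution_factors:
            nominal_over = df_factor * hqc
            measured = (nominal_over / df_factor) * (
                1 + rng.normal(0, error.proportional_cv, config.replicates)
            )
            res = val.dilution_integrity(measured, df_factor, nominal_over)
            dil_rows.append({"dilution_factor": df_factor,
                             "nominal_ng_ml": nominal_over,
                             "accuracy_pct": res.accuracy_pct,
                             "rsd_pct": res.rsd_pct, "passed": res.passed})
        dil_table = pd.DataFrame(dil_rows)
        report.dilution_tables[name] = dil_table
        dil_table.to_csv(outdir / f"dilution_{name}.csv", index=False)
        report.stages.append(
            StageStatus(f"dilution[{name}]", bool(dil_table["passed"].all()))
        )

        # stability battery
        stab_rows = []
        for condition in val.STABILITY_CONDITIONS:
            for level in ("LQC", "HQC"):
                nominal = acfg.qc_levels[level]
                found = nominal * (1 + acfg.stability_bias) * (
                    1 + rng.normal(0, error.proportional_cv, config.replicates)
                )
                for v in found:
                    stab_rows.append({"condition": condition, "level": level,
                                      "nominal_ng_ml": nominal,
                                      "conc_found_ng_ml": v})
        stab_results = val.stability_battery(
            pd.DataFrame(stab_rows),
            fresh_reference={lv: acfg.qc_levels[lv] for lv in ("LQC", "HQC")},
            rules=rules, analyte=name,
        )
        stab_table = pd.DataFrame(
            [
                {"condition": r.condition, "level": r.level.name,
                 "nominal_ng_ml": r.level.nominal,
                 "mean_found_ng_ml": r.mean_found,
                 "accuracy_pct": r.accuracy_pct, "rsd_pct": r.rsd_pct,
                 "vs_fresh_pct": r.vs_fresh_pct, "passed": r.passed}
                for r in stab_results
            ]
        )
        report.stability_tables[name] = stab_table
        stab_table.to_csv(outdir / f"stability_{name}.csv", index=False)
        report.stages.append(
            StageStatus(f"stability[{name}]", bool(stab_table["passed"].all()))
        )

        # selectivity across plasma lots
        lloq_ratio = acfg.true_slope * acfg.error.lloq + acfg.true_intercept
        lloq_areas = lloq_ratio * 1e5 * (
            1 + rng.normal(0, error.proportional_cv, config.replicates)
        )
        blank_areas = {
            f"lot{i + 1}": abs(rng.normal(0, 0.01)) * float(np.mean(lloq_areas))
            for i in range(config.n_lots)
        }
        sel = val.selectivity_check(blank_areas, lloq_areas)
        report.stages.append(
            StageStatus(f"selectivity[{name}]", sel.passed,
                        f"max interference "
                        f"{max(sel.interference_pct.values()):.2f}%")
        )

        # --- stage: pharmacokinetics ------------------------------------
        params = acfg.pk.to_params()
        for subj in range(1, config.n_subjects + 1):
            profile = sim.simulate_profile(
                params, schedule, error,
                subject_id=f"S{subj}", analyte=name, rng=rng,
            )
            all_profiles.append(profile.to_frame())
            try:
                nca_results.append(
                    nca_mod.NCA(profile, method=config.auc_method).fit()
                )
            except ValueError as exc:
                report.stages.append(
                    StageStatus(f"nca[{name}:S{subj}]", False, str(exc))
                )
        report.stages.append(StageStatus(f"nca[{name}]", True,
                                         f"{config.n_subjects} subjects"))

    # --- bundle outputs -------------------------------------------------
    pd.concat(all_run_rows, ignore_index=True).to_csv(
        outdir / "run_data.csv", index=False
    )
    pd.concat(all_profiles, ignore_index=True).to_csv(
        outdir / "profiles.csv", index=False
    )
    if nca_results:
        report.nca_results = pd.DataFrame([r.to_dict() for r in nca_results])
        report.nca_results.to_csv(outdir / "nca_results.csv", index=False)
        report.nca_summary = nca_mod.summarize_cohort(nca_results)
        report.nca_summary.to_csv(outdir / "nca_summary.csv", index=False)
        (outdir / "nca_summary.md").write_text(
            render_markdown_table(
                report.nca_summary[["analyte", "parameter", "mean_sd"]]
            )
        )

    log = {
        "seed": seed,
        "config_hash": report.config_hash,
        "stages": [
            {"stage": s.name, "ok": s.ok, "detail": s.detail}
            for s in report.stages
        ],
        "all_passed": report.passed(),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return report
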