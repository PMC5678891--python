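"""End-to-end orchestration: preprocess → fits → summaries → averaging → contrasts.

``run_pipeline`` executes the full analysis for a configurable subset of
the three model families and the three summarization methods and writes

* ``table2.csv`` — method × family × stage estimates of the focal
  parameter plus the stage contrasts (4−2, 3−2, 4−3) with SEs and p-values;
* ``table3.csv`` — per method: family AICs, Akaike weights, the 4−2
  contrast per family, and the model-averaged row;
* ``sensitivity.csv`` — focal estimates per stage across breath-averaging
  bin widths (5/10/15/20 s by default);
* ``log.json`` — seeds, configuration, package versions, and any
  partial-failure notes.

Partial failures (typically a mixed-effects fit that does not converge)
are recorded in the report and the run continues.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .averaging import CandidateSet, akaike_weights, model_average, subgroup_selection
from .inference import DEFAULT_PAIRS, StageEstimates, all_contrasts
from .mixed_effects import NlmeSpec, fit_nlme, stage_estimates
from .models import ModelFamily
from .patient_fit import fit_cohort
from .preprocessing import (
    DEFAULT_BIN_WIDTH,
    align_to_lam_max,
    bin_cohort,
    read_cohort_csv,
)
from .synthetic import CohortSpec, generate_cohort
from .two_step import MetaInput, fit_meta, fit_weighted

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "meta_input_from_fits"]

ALL_FAMILIES = tuple(f.value for f in ModelFamily)
ALL_METHODS = ("mixed", "meta", "weighted")


@dataclass
class PipelineConfig:
    input_csv: str | None = None          # raw breath CSV; synthetic cohort if None
    cohort: CohortSpec | None = None      # synthetic spec (defaults if None)
    bin_width: float = DEFAULT_BIN_WIDTH
    families: tuple[str, ...] = ALL_FAMILIES
    methods: tuple[str, ...] = ALL_METHODS
    focal_param: str = "t_half"
    meta_method: str = "reml"
    seed: int = 0
    outdir: str | None = None
    run_sensitivity: bool = True
    sensitivity_widths: tuple[float, ...] = (5.0, 10.0, 15.0)
    run_subgroups: bool = False
    contrast_pairs: tuple = DEFAULT_PAIRS

    def validate(self):
        if not self.families or not self.methods:
            raise ValueError("need at least one family and one method")
        bad = set(self.methods) - set(ALL_METHODS)
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")
        for f in self.families:
            ModelFamily.coerce(f)


@dataclass
class PipelineResult:
    table2: pd.DataFrame
    table3: pd.DataFrame
    sensitivity: pd.DataFrame | None
    subgroups: pd.DataFrame | None
    per_patient: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def meta_input_from_fits(fits, family, param: str = "t_half") -> MetaInput:
    """Assemble step-2 input from converged per-patient fits of one family."""
    family = ModelFamily.coerce(family)
    sub = [f for f in fits if f.family == family and f.converged]
    if not sub:
        raise ValueError(f"no converged per-patient fits for {family.value}")
    return MetaInput(
        phi=np.array([f.estimate(param) for f in sub]),
        se=np.array([f.stderr(param) for f in sub]),
        stage=np.array([f.stage for f in sub]),
    )


def _summary_to_stage_estimates(summary, family, param) -> StageEstimates:
    return StageEstimates(
        method=summary.method,
        family=ModelFamily.coerce(family).value,
        param=param,
        stages=summary.stages,
        estimates=summary.theta,
        ses=summary.se,
        cov=None,
        df=summary.df_resid,
    )


def _fit_method(method, family, aligned, fits, cfg):
    """One method × family cell → (StageEstimates, aic, note)."""
    if method == "mixed":
        nlme = fit_nlme(aligned, NlmeSpec(family=family), per_patient=fits)
        est = stage_estimates(nlme, cfg.focal_param)
        note = "; ".join(nlme.notes)
        if not nlme.converged:
            raise RuntimeError(f"mixed-effects fit did not converge: {note}")
        return est, nlme.aic, note
    inp = meta_input_from_fits(fits, family, cfg.focal_param)
    if method == "meta":
        summary = fit_meta(inp, method=cfg.meta_method)
    else:
        summary = fit_weighted(inp)
    return _summary_to_stage_estimates(summary, family, cfg.focal_param), summary.aic, summary.note


def _load_series(cfg: PipelineConfig, bin_width):
    if cfg.input_csv is not None:
        records = read_cohort_csv(cfg.input_csv)
    else:
        spec = cfg.cohort or CohortSpec()
        records, _ = generate_cohort(spec, seed=cfg.seed)
    return align_to_lam_max(bin_cohort(records, bin_width))


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    cfg.validate()
    notes: list[str] = []
    aligned = _load_series(cfg, cfg.bin_width)
    families = [ModelFamily.coerce(f) for f in cfg.families]
    fits = fit_cohort(aligned, families)
    n_failed = sum(not f.converged for f in fits)
    if n_failed:
        notes.append(f"{n_failed} per-patient fits did not converge and were excluded")

    from .patient_fit import tidy_estimates

    per_patient = tidy_estimates(fits)

    table2_rows = []
    table3_rows = []
    for method in cfg.methods:
        cells = {}
        for family in families:
            try:
                est, aic_val, note = _fit_method(method, family, aligned, fits, cfg)
            except Exception as exc:
                notes.append(f"{method}/{family.value}: {exc}")
                table2_rows.append(
                    dict(method=method, family=family.value, label="failed",
                         estimate=np.nan, se=np.nan, p=np.nan, aic=np.nan)
                )
                continue
            if note:
                notes.append(f"{method}/{family.value}: {note}")
            pvals = est.pvalues
            for s, e, se_, p in zip(est.stages, est.estimates, est.ses, pvals):
                table2_rows.append(
                    dict(method=method, family=family.value, label=f"COPD {s}",
                         estimate=e, se=se_, p=p, aic=aic_val)
                )
            contrasts = all_contrasts(est, pairs=cfg.contrast_pairs)
            for c in contrasts:
                table2_rows.append(
                    dict(method=method, family=family.value, label=c.label,
                         estimate=c.estimate, se=c.se, p=c.p, aic=aic_val)
                )
            focal = contrasts[0]  # first configured pair (4−2 by default)
            cells[family.value] = dict(aic=aic_val, theta=focal.estimate, var=focal.se**2)

        if len(cells) >= 2:
            labels = list(cells)
            cand = CandidateSet(
                labels=labels,
                ic=[cells[l]["aic"] for l in labels],
                theta=[cells[l]["theta"] for l in labels],
                var=[cells[l]["var"] for l in labels],
            )
            avg = model_average(cand)
            for l, w in zip(labels, avg.weights):
                table3_rows.append(
                    dict(method=method, family=l, aic=cells[l]["aic"], weight=w,
                         estimate=cells[l]["theta"], se=np.sqrt(cells[l]["var"]))
                )
            table3_rows.append(
                dict(method=method, family="model_averaged", aic=np.nan, weight=np.nan,
                     estimate=avg.theta_ma, se=avg.se_ma)
            )
            _check_table3_consistency(table3_rows, method)
        elif len(cells) == 1:
            (l, cell), = cells.items()
            table3_rows.append(
                dict(method=method, family=l, aic=cell["aic"], weight=1.0,
                     estimate=cell["theta"], se=np.sqrt(cell["var"]))
            )

    table2 = pd.DataFrame(table2_rows)
    table3 = pd.DataFrame(table3_rows)

    sensitivity = None
    if cfg.run_sensitivity:
        sensitivity = _sensitivity_analysis(cfg, families[0], notes)

    subgroups = None
    if cfg.run_subgroups:
        subgroups = _subgroup_analysis(cfg, aligned, fits, families, notes)

    result = PipelineResult(table2, table3, sensitivity, subgroups, per_patient, notes)
    if cfg.outdir is not None:
        _write_outputs(cfg, result)
    return result


def _check_table3_consistency(rows, method):
    """The averaged row must be recomputable from its own per-family rows."""
    sub = [r for r in rows if r["method"] == method]
    fam = [r for r in sub if r["family"] != "model_averaged"]
    avg = [r for r in sub if r["family"] == "model_averaged"][-1]
    w = akaike_weights([r["aic"] for r in fam])
    theta = float(np.sum(w * np.array([r["estimate"] for r in fam])))
    if not np.isclose(theta, avg["estimate"], rtol=1e-10, atol=1e-10):
        raise AssertionError(
            f"table3 self-consistency violated for method {method}: "
            f"{theta} != {avg['estimate']}"
        )


def _sensitivity_analysis(cfg, family, notes):
    """Focal estimates per stage across bin widths (mixed effects when enabled)."""
    rows = []
    widths = tuple(dict.fromkeys((cfg.bin_width, *cfg.sensitivity_widths)))
    use_mixed = "mixed" in cfg.methods
    for w in widths:
        try:
            aligned_w = _load_series(cfg, w)
            fits_w = fit_cohort(aligned_w, [family])
            if use_mixed:
                nlme = fit_nlme(aligned_w, NlmeSpec(family=family), per_patient=fits_w)
                est = stage_estimates(nlme, cfg.focal_param)
            else:
                inp = meta_input_from_fits(fits_w, family, cfg.focal_param)
                summary = fit_meta(inp, method=cfg.meta_method)
                est = _summary_to_stage_estimates(summary, family, cfg.focal_param)
        except Exception as exc:
            notes.append(f"sensitivity/bin_width={w}: {exc}")
            continue
        for s, e, se_ in zip(est.stages, est.estimates, est.ses):
            rows.append(
                dict(bin_width=w, stage=int(s), family=family.value,
                     estimate=e, se=se_)
            )
    return pd.DataFrame(rows)


def _subgroup_analysis(cfg, aligned, fits, families, notes):
    """Per-stage AIC comparison of the families (meta/weighted; mixed may fail)."""
    aics = {}
    reasons = {}
    stages = sorted({s.stage for s in aligned})
    method = "meta" if "meta" in cfg.methods else cfg.methods[0]
    for stage in stages:
        stage_series = [s for s in aligned if s.stage == stage]
        stage_fits = [f for f in fits if f.stage == stage]
        for family in families:
            key = (stage, family.value)
            try:
                if method == "mixed":
                    nlme = fit_nlme(stage_series, NlmeSpec(family=family),
                                    per_patient=stage_fits)
                    if not nlme.converged:
                        raise RuntimeError("; ".join(nlme.notes) or "non-convergence")
                    aics[key] = nlme.aic
                else:
                    inp = meta_input_from_fits(stage_fits, family, cfg.focal_param)
                    summary = (
                        fit_meta(inp, method=cfg.meta_method)
                        if method == "meta"
                        else fit_weighted(inp)
                    )
                    aics[key] = summary.aic
            except Exception as exc:
                aics[key] = None
                reasons[key] = str(exc)
                notes.append(f"subgroup {method}/{family.value}/stage {stage}: {exc}")
    return subgroup_selection(aics, reasons)


def _write_outputs(cfg: PipelineConfig, result: PipelineResult):
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.table2.to_csv(outdir / "table2.csv", index=False)
    result.table3.to_csv(outdir / "table3.csv", index=False)
    result.per_patient.to_csv(outdir / "per_patient.csv", index=False)
    if result.sensitivity is not None:
        result.sensitivity.to_csv(outdir / "sensitivity.csv", index=False)
    if result.subgroups is not None:
        result.subgroups.to_csv(outdir / "subgroups.csv", index=False)
    cfg_dict = dataclasses.asdict(cfg)
    if cfg_dict.get("cohort") is not None:
        cfg_dict["cohort"] = {
            k: (v if not isinstance(v, dict) else {str(kk): str(vv) for kk, vv in v.items()})
            for k, v in dataclasses.asdict(cfg.cohort).items()
        }
    log = dict(
        package="vo2kinetics",
        version=__version__,
        python=sys.version,
        seed=cfg.seed,
        config={k: _jsonable(v) for k, v in cfg_dict.items()},
        notes=result.notes,
    )
    (outdir / "log.json").write_text(json.dumps(log, indent=2, default=str))


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, tuple):
        return list(v)
    return v
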