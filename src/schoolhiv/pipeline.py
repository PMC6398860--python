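"""End-to-end orchestration: simulate or ingest, build the panel, estimate.

Runs the full battery in the published sequence — descriptive association,
imposed-correlation sensitivity grid, instrumented bivariate probit,
correlated random-effects probit, linear robustness suite — and writes
both human-readable tables (delimited text) and a machine-readable JSON
summary in which every reported number also appears.

Randomness flows from one top-level seed through named per-stage
substreams, so enabling or disabling a stage never perturbs another
stage's draws.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import biprobit as bp
from . import linear as lin
from .cohort import GeneratorConfig, SyntheticCohort, default_config, generate_cohort
from .cre import add_group_means, fit_cre_probit
from .descriptives import descriptive_table
from .exceptions import InvalidParameterError
from .panel import build_design, build_panel, prune_separated
from .probit import discrete_change_at_means, fit_probit

__all__ = ["RunConfig", "run_full_analysis", "stage_seed"]

log = logging.getLogger("schoolhiv")

ALL_STAGES = ("describe", "probit", "sensitivity", "biprobit", "cre", "linear")


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Named substream: independent of which other stages run."""
    return np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])


@dataclass
class RunConfig:
    mode: str = "simulate"
    generator: GeneratorConfig | None = None
    tests_path: str | None = None
    covariates_path: str | None = None
    education_path: str | None = None
    scheme: str = "main"
    phi_grid: tuple = bp.DEFAULT_PHI_GRID
    stages: tuple = ALL_STAGES
    outdir: str = "schoolhiv_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("simulate", "ingest"):
            raise InvalidParameterError("mode must be 'simulate' or 'ingest'")
        if self.mode == "ingest" and not (self.tests_path and self.covariates_path):
            raise InvalidParameterError("ingest mode needs tests_path and covariates_path")
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig.from_dict(self.generator)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise InvalidParameterError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise InvalidParameterError("config file must set a seed")
        return cls(**raw)


def _pe_record(pe, n=None, n_persons=None, **extra):
    rec = {"estimate": pe.estimate, "se": pe.se, "ci_low": pe.ci_low,
           "ci_high": pe.ci_high, "se_estimable": pe.se_estimable}
    if n is not None:
        rec["n"] = int(n)
    if n_persons is not None:
        rec["n_persons"] = int(n_persons)
    rec.update(extra)
    return rec


def run_full_analysis(config: RunConfig) -> dict:
    """Run the configured stages; returns the machine-readable summary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "scheme": config.scheme,
                     "stages": list(config.stages), "errors": {}}

    # --- data ---
    if config.mode == "simulate":
        gen = config.generator or default_config()
        seed = int(stage_seed(config.seed, "simulate").generate_state(1)[0] % (2**31))
        cohort = generate_cohort(gen, seed=seed)
        tests = cohort.observed_tests
        covariates = cohort.covariate_frame()
        education = cohort.education_frame()
    else:
        tests = pd.read_csv(config.tests_path)
        covariates = pd.read_csv(config.covariates_path)
        education = (pd.read_csv(config.education_path)
                     if config.education_path else None)

    panel, exclusions = build_panel(tests, covariates, config.scheme,
                                    education=education)
    panel.to_csv(outdir / "panel.csv", index=False)
    with open(outdir / "exclusions.json", "w") as fh:
        json.dump(exclusions, fh, indent=2, sort_keys=True)
    summary["exclusions"] = exclusions
    summary["n_person_years"] = int(len(panel))
    summary["n_persons"] = int(panel["person_id"].nunique())

    design = build_design(panel, include_instruments=True)
    design, separation_dropped = prune_separated(design)
    summary["separation_dropped"] = separation_dropped
    n_persons = int(pd.Series(design.person_ids).nunique())
    Xs = np.column_stack([design.X, design.s])
    xs_names = design.x_names + ["attendance"]

    def _run(stage, fn):
        if stage not in config.stages:
            return
        try:
            fn()
        except Exception as exc:
            log.error("stage %s failed: %s", stage, exc)
            summary["errors"][stage] = str(exc)

    def do_describe():
        table = descriptive_table(panel)
        table.to_csv(outdir / "table1_descriptives.csv", index=False)
        summary["descriptives"] = table.where(pd.notna(table), None).to_dict("records")

    def do_probit():
        fit = fit_probit(design.y, Xs, design.cluster_ids, names=xs_names)
        pe = discrete_change_at_means(fit, "attendance")
        rec = _pe_record(pe, n=design.n, n_persons=n_persons,
                         beta_latent=fit.coef("attendance"), loglik=fit.loglik,
                         n_clusters=fit.n_clusters, converged=fit.converged)
        summary["probit"] = rec
        pd.DataFrame([rec]).to_csv(outdir / "table2_probit.csv", index=False,
                                   float_format="%.17g")

    def do_sensitivity():
        grid = bp.sensitivity_grid(design.y, design.s, design.X,
                                   design.cluster_ids, grid=config.phi_grid,
                                   x_names=design.x_names)
        rows = [dataclasses.asdict(e) for e in grid.entries]
        pd.DataFrame(rows).to_csv(outdir / "table3_sensitivity.csv",
                                  index=False, float_format="%.17g")
        summary["sensitivity"] = {"rho_upper": grid.bound.rho_upper, "entries": rows}

    def do_biprobit():
        fit = bp.fit_biprobit(design.y, design.s, design.X, design.Z,
                              design.cluster_ids, x_names=design.x_names,
                              z_names=design.z_names)
        rec = _pe_record(fit.partial_effect, n=design.n, n_persons=n_persons,
                         rho=fit.params.rho, rho_se=fit.rho_se,
                         rho_test_p=fit.rho_test_p,
                         rho_ci_low=fit.rho_ci[0], rho_ci_high=fit.rho_ci[1],
                         beta_latent=fit.params.beta, loglik=fit.loglik,
                         converged=fit.converged,
                         gamma={nm: float(g) for nm, g in
                                zip(fit.z_names, fit.params.gamma)})
        summary["biprobit"] = rec
        pd.DataFrame([{k: v for k, v in rec.items() if k != "gamma"}]).to_csv(
            outdir / "table4_biprobit.csv", index=False, float_format="%.17g")

    def do_cre():
        base = dataclasses.replace(design, Z=None, z_names=[])
        cre = add_group_means(base)
        fit, pe = fit_cre_probit(cre)
        rec = _pe_record(pe, n=design.n, n_persons=n_persons,
                         beta_latent=fit.coef("attendance"),
                         converged=fit.converged, notes=cre.notes)
        summary["cre"] = rec
        pd.DataFrame([{k: v for k, v in rec.items() if k != "notes"}]).to_csv(
            outdir / "table5_cre.csv", index=False, float_format="%.17g")

    def do_linear():
        ols = lin.fit_lpm(design.y, Xs, design.cluster_ids, names=xs_names)
        uncontrolled = lin.fit_lpm(
            design.y, np.column_stack([np.ones(design.n), design.s]),
            design.cluster_ids, names=["const", "attendance"])
        fe = lin.fit_fe_within(design.y, Xs, design.person_ids,
                               design.cluster_ids, names=xs_names)
        rows = {
            "ols": {"beta": ols.coef("attendance"), "se": ols.se("attendance"),
                    "r_squared": ols.r_squared},
            "fe": {"beta": fe.coef("attendance"), "se": fe.se("attendance"),
                   "r_squared": fe.r_squared},
        }
        if design.Z is not None and design.Z.shape[1]:
            liml = lin.fit_liml(design.y, design.s, design.X, design.Z,
                                design.cluster_ids, names=design.x_names)
            rows["liml"] = {"beta": liml.coef("attendance"),
                            "se": liml.se("attendance"),
                            "kappa": liml.kappa, "r_squared": liml.r_squared}
        try:
            ds = lin.delta_star(uncontrolled, ols)
            rows["delta_star"] = {"delta_star": ds.delta_star, "r_max": ds.r_max,
                                  "beta_target": ds.beta_target,
                                  "unbounded": ds.unbounded}
        except InvalidParameterError as exc:
            rows["delta_star"] = {"error": str(exc)}
        summary["linear"] = rows
        pd.DataFrame(rows).T.to_csv(outdir / "linear_suite.csv",
                                    float_format="%.17g")

    _run("describe", do_describe)
    _run("probit", do_probit)
    _run("sensitivity", do_sensitivity)
    _run("biprobit", do_biprobit)
    _run("cre", do_cre)
    _run("linear", do_linear)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
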