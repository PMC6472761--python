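"""End-to-end genetic-evaluation pipeline and run manifest.

Chains the stages together: read or simulate a trial, validate it, fit the
single-trait and multi-trait models by REML (and optionally MCMC), derive
genetic parameters, build the model-comparison tables (deviance/LRT, AIC,
DIC), run selection and between-method agreement, and write every table as
delimited text together with a manifest recording the seed, configuration
hash, priors and tolerances.
"""

from __future__ import annotations

import hashlib
import json
import platform
import sys
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import ModelSpec, build_design, make_sum_trait
from .genparams import (accuracy_pev, accuracy_posterior, cov_sum_trick,
                        derive_genetic_parameters, gen_correlation)
from .mcmc import McmcOpts, default_weak_priors, dic_value, run_mcmc
from .reml import aic_value, fit_reml, lrt
from .selection import agi_scores, gain_stats, rank_agreement, rank_and_select
from .synthetic import soybean_trial_params, simulate_trial
from .trial_io import PhenotypeTable, read_phenotypes, validate_table, \
    write_phenotypes


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (all randomness flows from seed)."""

    out_dir: str
    seed: int = 1
    input_path: str | None = None          # mutually exclusive with preset
    schema: dict | None = None
    preset: str | None = "soybean"
    n_progeny: int | None = None           # preset override
    missing_rate: float = 0.0
    traits: tuple[str, ...] = ()           # empty = all traits in the table
    methods: tuple[str, ...] = ("reml",)   # subset of ("reml", "mcmc")
    reduced_models: bool = True
    n_locations: int | None = None         # usually inferred from the table
    n_reps: int | None = None
    m_selected: int = 30
    b_intensity: float = 0.15
    n_boot: int = 1000
    mcmc_n_iter: int = 20000
    mcmc_burn_in: int = 10000
    mcmc_thin: int = 5
    reml_tol: float = 1e-9
    reml_max_iter: int = 5000

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for k in ("traits", "methods"):
            setattr(cfg, k, tuple(getattr(cfg, k)))
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_or_simulate(config: PipelineConfig):
    if config.input_path:
        table = read_phenotypes(config.input_path, config.schema)
        truth = None
    else:
        if config.preset != "soybean":
            raise PipelineError(f"unknown preset {config.preset!r}")
        params = soybean_trial_params(
            n_progeny=config.n_progeny or 203,
            missing_rate=config.missing_rate)
        table, truth = simulate_trial(params, seed=config.seed)
    if config.traits:
        table = table.subset_traits(list(config.traits))
    return table, truth


def _components_row(fit, trait_names):
    rows = {}
    for k, t in enumerate(trait_names):
        rows[t] = {
            "sigma_g2": float(fit.components.sigma_g[k, k]),
            "sigma_int2": float(fit.components.sigma_int[k, k]),
            "sigma_e2": float(fit.components.sigma_e[k, k]),
        }
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full evaluation; returns a dict of output tables and
    writes them (plus ``manifest.yaml``) under ``config.out_dir``.

    Any stage failure raises :class:`PipelineError` naming the stage;
    tables completed before the failure are still written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    results: dict = {}
    stage = "init"

    def persist():
        for name, obj in results.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(out / f"{name}.tsv", sep="\t", index=True)
        manifest = {
            "package_version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": asdict(config),
            "reml_tol": config.reml_tol,
            "priors": "default weak (IW 1e-3*I df=t / IG 0.001,0.001)",
            "elapsed_s": round(time.time() - t0, 2),
            "stage_reached": stage,
        }
        with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False, default_flow_style=False)

    try:
        stage = "load"
        if config.m_selected > (config.n_progeny or 203) and not config.input_path:
            raise PipelineError(
                f"m_selected={config.m_selected} exceeds the number of "
                f"progeny {config.n_progeny or 203}")
        table, truth = _load_or_simulate(config)
        if config.input_path and config.m_selected > table.n_progeny:
            raise PipelineError(
                f"m_selected={config.m_selected} exceeds the number of "
                f"progeny {table.n_progeny}")
        write_phenotypes(table, str(out / "trial.tsv"))

        stage = "validate"
        report = validate_table(table)
        results["validation"] = pd.DataFrame([{
            "n_progeny": report.n_progeny,
            "n_locations": report.n_locations,
            "n_missing_cells": report.n_missing_cells,
            "balance_flag": report.balance_flag,
        }])
        traits = table.trait_names
        n_loc = config.n_locations or report.n_locations
        n_rep = config.n_reps or max(report.n_blocks_per_location.values())

        # ---------------- frequentist fits ----------------
        stage = "fit-reml-st"
        st_fits, dev_rows, aic_rows = {}, [], []
        for trait in traits:
            spec = ModelSpec((trait,))
            d = build_design(table, spec)
            fit = fit_reml(d, tol=config.reml_tol,
                           max_iter=config.reml_max_iter)
            st_fits[trait] = fit
            if config.reduced_models:
                fit_ng = fit_reml(build_design(
                    table, ModelSpec((trait,), include_progeny=False)),
                    tol=config.reml_tol, max_iter=config.reml_max_iter)
                fit_ni = fit_reml(build_design(
                    table, ModelSpec((trait,), include_interaction=False)),
                    tol=config.reml_tol, max_iter=config.reml_max_iter)
                lam_g, p_g = lrt(fit_ng.deviance, fit.deviance)
                lam_i, p_i = lrt(fit_ni.deviance, fit.deviance)
                dev_rows += [
                    {"model": "FSTME", "trait": trait, "effect": "progeny",
                     "deviance_reduced": fit_ng.deviance,
                     "deviance_full": fit.deviance, "lrt": lam_g, "p": p_g},
                    {"model": "FSTME", "trait": trait, "effect": "gxe",
                     "deviance_reduced": fit_ni.deviance,
                     "deviance_full": fit.deviance, "lrt": lam_i, "p": p_i},
                ]
                aic_rows.append({
                    "model": "FSTME", "trait": trait,
                    "aic_full": aic_value(fit.deviance, fit.n_varparams),
                    "aic_no_progeny": aic_value(fit_ng.deviance,
                                                fit_ng.n_varparams),
                    "aic_no_gxe": aic_value(fit_ni.deviance,
                                            fit_ni.n_varparams)})

        stage = "fit-reml-mt"
        mt_fit = None
        if len(traits) > 1:
            d_mt = build_design(table, ModelSpec(traits))
            mt_fit = fit_reml(d_mt, tol=config.reml_tol,
                              max_iter=config.reml_max_iter)
            aic_rows.append({
                "model": "FMTME", "trait": ",".join(traits),
                "aic_full": aic_value(mt_fit.deviance, mt_fit.n_varparams),
                "aic_no_progeny": np.nan, "aic_no_gxe": np.nan})
        if dev_rows:
            results["deviance_lrt"] = pd.DataFrame(dev_rows)
        if aic_rows:
            results["aic"] = pd.DataFrame(aic_rows)

        stage = "genetic-parameters"
        means = {t: float(np.nanmean(table.data[t])) for t in traits}
        par_rows = []
        for trait, fit in st_fits.items():
            gp = derive_genetic_parameters(
                fit.components, [means[trait]], n_loc, n_rep, (trait,))
            acc = accuracy_pev(fit.components.sigma_g[0, 0],
                               fit.pev_g[:, 0])
            par_rows.append({
                "model": "FSTME", "trait": trait,
                "sigma_g2": fit.components.sigma_g[0, 0],
                "sigma_int2": fit.components.sigma_int[0, 0],
                "sigma_e2": fit.components.sigma_e[0, 0],
                "sigma_phen2": gp.sigma_phen[0], "h2_prog": gp.h2_prog[0],
                "c2_int": gp.c2_int[0], "cv_g": gp.cv_g[0],
                "cv_e": gp.cv_e[0], "ac_prog": float(acc.mean())})
        if mt_fit is not None:
            gp = derive_genetic_parameters(
                mt_fit.components, [means[t] for t in traits],
                n_loc, n_rep, traits)
            for k, trait in enumerate(traits):
                acc = accuracy_pev(mt_fit.components.sigma_g[k, k],
                                   mt_fit.pev_g[:, k])
                par_rows.append({
                    "model": "FMTME", "trait": trait,
                    "sigma_g2": mt_fit.components.sigma_g[k, k],
                    "sigma_int2": mt_fit.components.sigma_int[k, k],
                    "sigma_e2": mt_fit.components.sigma_e[k, k],
                    "sigma_phen2": gp.sigma_phen[k],
                    "h2_prog": gp.h2_prog[k], "c2_int": gp.c2_int[k],
                    "cv_g": gp.cv_g[k], "cv_e": gp.cv_e[k],
                    "ac_prog": float(acc.mean())})
        results["parameters"] = pd.DataFrame(par_rows)

        stage = "genetic-correlation"
        corr_rows = []
        if len(traits) > 1:
            for a in range(len(traits)):
                for b in range(a + 1, len(traits)):
                    ti, tj = traits[a], traits[b]
                    sum_tab = make_sum_trait(table, ti, tj)
                    fit_sum = fit_reml(build_design(
                        sum_tab, ModelSpec((f"sum({ti},{tj})",))),
                        tol=config.reml_tol, max_iter=config.reml_max_iter)
                    cov = cov_sum_trick(
                        st_fits[ti].components.sigma_g[0, 0],
                        st_fits[tj].components.sigma_g[0, 0],
                        fit_sum.components.sigma_g[0, 0])
                    vi = st_fits[ti].components.sigma_g[0, 0]
                    vj = st_fits[tj].components.sigma_g[0, 0]
                    rho_st = cov / np.sqrt(vi * vj)
                    row = {"pair": f"{ti},{tj}", "rho_st": rho_st,
                           "rho_st_out_of_bounds": bool(abs(rho_st) > 1)}
                    if mt_fit is not None:
                        corr, flags = gen_correlation(
                            mt_fit.components.sigma_g)
                        row["rho_mt"] = corr[a, b]
                        row["rho_mt_out_of_bounds"] = bool(flags[a, b])
                    corr_rows.append(row)
            results["correlations"] = pd.DataFrame(corr_rows)

        # ---------------- Bayesian fits ----------------
        bayes_fits = {}
        if "mcmc" in config.methods:
            stage = "fit-mcmc"
            opts = lambda off: McmcOpts(
                n_iter=config.mcmc_n_iter, burn_in=config.mcmc_burn_in,
                thin=config.mcmc_thin, seed=config.seed * 1000 + off)
            dic_rows = []
            for off, trait in enumerate(traits):
                d = build_design(table, ModelSpec((trait,)),
                                 keep_missing=True)
                sm = run_mcmc(d, default_weak_priors(1), opts(off))
                bayes_fits[trait] = (d, sm)
                if config.reduced_models:
                    d_ng = build_design(
                        table, ModelSpec((trait,), include_progeny=False),
                        keep_missing=True)
                    d_ni = build_design(
                        table, ModelSpec((trait,), include_interaction=False),
                        keep_missing=True)
                    pr = default_weak_priors(1)
                    sm_ng = run_mcmc(d_ng, pr, opts(off + 100))
                    sm_ni = run_mcmc(d_ni, pr, opts(off + 200))
                    dic_rows.append({
                        "model": "BSTME", "trait": trait,
                        "dic_full": dic_value(sm, d).dic,
                        "dic_no_progeny": dic_value(sm_ng, d_ng).dic,
                        "dic_no_gxe": dic_value(sm_ni, d_ni).dic})
            if len(traits) > 1:
                d_bmt = build_design(table, ModelSpec(traits),
                                     keep_missing=True)
                sm_bmt = run_mcmc(d_bmt, default_weak_priors(len(traits)),
                                  opts(500))
                bayes_fits["__mt__"] = (d_bmt, sm_bmt)
                dic_rows.append({
                    "model": "BMTME", "trait": ",".join(traits),
                    "dic_full": dic_value(sm_bmt, d_bmt).dic,
                    "dic_no_progeny": np.nan, "dic_no_gxe": np.nan})
            if dic_rows:
                results["dic"] = pd.DataFrame(dic_rows)

        # ---------------- selection ----------------
        stage = "selection"
        sel_rows, blup_frames = [], {}
        for model, fits in (("FSTME", st_fits), ("FMTME", {"": mt_fit})):
            if mt_fit is None and model == "FMTME":
                continue
            bv = {}
            for k, trait in enumerate(traits):
                fit = fits[trait] if model == "FSTME" else mt_fit
                col = 0 if model == "FSTME" else k
                bv[trait] = pd.Series(fit.u_plus_g[:, col],
                                      index=fit.progeny_ids)
            frame = pd.DataFrame(bv)
            blup_frames[model] = frame
            for trait in traits:
                rk = rank_and_select(frame[trait], config.m_selected)
                ga, gp_ = gain_stats(
                    frame[trait].loc[rk.selected].to_numpy(), means[trait])
                sel_rows.append({"model": model, "trait": trait,
                                 "gain_abs": ga, "gain_pct": gp_,
                                 "selected": ";".join(rk.selected)})
        results["selection"] = pd.DataFrame(sel_rows)

        if mt_fit is not None:
            agree_rows = []
            for trait in traits:
                res = rank_agreement(
                    blup_frames["FSTME"][trait], blup_frames["FMTME"][trait],
                    m=config.m_selected, b_intensity=config.b_intensity,
                    n_boot=config.n_boot, seed=config.seed)
                agree_rows.append({
                    "trait": trait, "spearman_rho": res.spearman_rho,
                    "ci_low": res.boot_ci[0], "ci_high": res.boot_ci[1],
                    "coincidence": res.coincidence,
                    "n_coincident": res.n_coincident})
            results["agreement"] = pd.DataFrame(agree_rows)

            # AGI on the multi-trait breeding values, CVg weights
            gp = derive_genetic_parameters(
                mt_fit.components, [means[t] for t in traits],
                n_loc, n_rep, traits)
            weights = {t: gp.cv_g[k] for k, t in enumerate(traits)}
            agi, rk = agi_scores(blup_frames["FMTME"], weights)
            sel = rank_and_select(agi, config.m_selected)
            results["agi"] = pd.DataFrame({
                "agi": agi.loc[sel.order],
                "selected": [p in set(sel.selected) for p in sel.order]})

        stage = "done"
        return results
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        persist()


def replicate_reported_fit(path: str, trait: str = "DM",
                           schema: dict | None = None,
                           tol: float = 1e-9):
    """Fit the single-trait full model by EM-REML on a deposited trial file
    and return the fitted :class:`~mtme.reml.FreqFit` (replication path for
    the original study's raw data, which must be supplied by the user)."""
    table = read_phenotypes(path, schema)
    d = build_design(table, ModelSpec((trait,)))
    return fit_reml(d, tol=tol)
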