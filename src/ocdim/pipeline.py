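"""Configuration-driven orchestration of the full analysis.

Stages run in order: simulate (or load) -> validate -> latent-structure
comparison -> testlet MCMC -> severity GRM -> agreement -> report. Every
stage consumes and produces plain-text files in the output directory, so any
stage can be rerun standalone from the manifest; per-stage seeds derive from
the global seed by a fixed offset scheme, and a rerun with the same config
and seed reproduces every delimited output bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import bland_altman, score_vs_raw_rank_check, write_plot_coords
from .datasets import (
    impute_zero_severity,
    read_domain_map,
    read_flags,
    read_responses,
    read_severity,
    symptom_pattern_summary,
    validate_dataset,
)
from .latent_models import (
    ModelSpec,
    compare_models,
    eap_scores_binary,
    fit_latent_model,
    leave_one_domain_out,
    standardized_loadings,
)
from .severity_grm import eap_scores, fit_grm
from .simulate import SimConfig, make_fixture
from .tables import FLOAT_FMT
from .testlet_mcmc import (
    MCMCConfig,
    convergence,
    run_mcmc,
    score_persons,
    summarize_items,
)

log = logging.getLogger("ocdim")

STAGES = (
    "simulate",
    "validate",
    "structure",
    "testlet",
    "severity",
    "agreement",
)

_SEED_STRIDE = 1_000_003


def stage_seed(global_seed: int, stage: str) -> int:
    """Fixed-offset per-stage seed derivation (documented, collision-free)."""
    return (int(global_seed) + _SEED_STRIDE * (STAGES.index(stage) + 1)) % 2**31


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    # exactly one of the two input modes
    input_paths: dict | None = None  # responses, domain_map, severity, flags
    sim: SimConfig | None = None
    # stage options
    quad_nodes: int = 21
    quad_nodes_specific: int = 9
    quad_nodes_per_dim: int = 5
    fit_tol: float = 1e-3
    run_lodo: bool = False
    mcmc_iterations: int = 4000
    mcmc_burn_in: int = 1000
    mcmc_chains: int = 2
    mcmc_person_thin: int = 1
    psrf_threshold: float = 1.2
    allow_unconverged: bool = False
    agreement_z: float = 1.96
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_paths is None) == (self.sim is None):
            raise ValueError(
                "config must supply exactly one of input_paths or a "
                "simulation block"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("sim", None)
        cfg = cls(**raw, sim=None)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg


@dataclass
class RunReport:
    config: dict
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)  # name -> status/timing
    manifest: dict = field(default_factory=dict)  # filename -> sha256
    summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "stages": self.stages,
            "manifest": self.manifest,
            "summary": self.summary,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _register(report: RunReport, out: Path, *paths) -> None:
    for p in paths:
        p = Path(p)
        report.manifest[str(p.relative_to(out))] = _sha256(p)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_full(config: RunConfig) -> RunReport:
    """Execute all stages; a stage failure halts with a partial manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    cfg_dict = {
        k: (v.to_jsonable() if isinstance(v, SimConfig) else v)
        for k, v in vars(config).items()
    }
    report = RunReport(config=cfg_dict, seed=config.seed)
    remaining = list(STAGES)
    try:
        state: dict = {}
        for stage in STAGES:
            t0 = time.perf_counter()
            log.info("stage %s", stage)
            _STAGE_FUNCS[stage](config, out, report, state)
            remaining.remove(stage)
            report.stages[stage] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
    except Exception as exc:  # noqa: BLE001 - surfaced with stage name
        failed = remaining[0]
        report.stages[failed] = {"status": "failed", "error": str(exc)}
        for stage in remaining[1:]:
            report.stages[stage] = {"status": "skipped"}
        emit_report(report, out / "run_report.json")
        raise RuntimeError(f"stage {failed!r} failed: {exc}") from exc
    emit_report(report, out / "run_report.json")
    return report


def _stage_simulate(config, out, report, state):
    if config.sim is not None:
        sim = replace(config.sim, seed=stage_seed(config.seed, "simulate"))
        paths, params = make_fixture(sim, out / "data")
        state["truth"] = params
    else:
        paths = dict(config.input_paths)
    state["paths"] = paths
    state["resp"] = read_responses(paths["responses"])
    state["dmap"] = read_domain_map(paths["domain_map"], strict=_is_strict(paths))
    state["sev"] = read_severity(paths["severity"])
    state["flags"] = read_flags(paths["flags"])
    if config.sim is not None:
        _register(report, out, *[paths[k] for k in paths])


def _is_strict(paths) -> bool:
    df = pd.read_csv(paths["domain_map"])
    return df["domain"].nunique() == 5


def _stage_validate(config, out, report, state):
    resp, dmap, sev, flags = (
        state["resp"],
        state["dmap"],
        state["sev"],
        state["flags"],
    )
    rep = validate_dataset(resp, dmap, sev, flags)
    if not rep.passed:
        raise ValueError("; ".join(rep.errors))
    sev_imputed, n_imputed = impute_zero_severity(sev, resp, flags)
    state["sev"] = sev_imputed
    patterns = symptom_pattern_summary(resp)
    rep.info["n_severity_rows_imputed"] = n_imputed
    rep.info["patterns"] = {
        k: v for k, v in patterns.items() if k != "top_patterns"
    }
    rep.info["patterns"]["top_patterns"] = [
        {"pattern": p, "count": c} for p, c in patterns["top_patterns"][:5]
    ]
    path = out / "validation.json"
    _write_json(rep.to_dict(), path)
    _register(report, out, path)
    report.summary["prop_symptomatic"] = patterns["prop_symptomatic"]
    report.summary["prop_unique_among_symptomatic"] = patterns[
        "prop_unique_among_symptomatic"
    ]


def _stage_structure(config, out, report, state):
    resp, dmap = state["resp"], state["dmap"]
    common = dict(
        n_quad=config.quad_nodes,
        n_quad_specific=config.quad_nodes_specific,
        n_quad_per_dim=config.quad_nodes_per_dim,
        tol=config.fit_tol,
    )
    fits = []
    for structure in ("unidimensional", "correlated_factors", "bifactor"):
        spec = ModelSpec(structure=structure, **common)
        fits.append(fit_latent_model(resp, dmap, spec))
        log.info("  %s loglik %.2f", structure, fits[-1].loglik)
    table = compare_models(fits)
    path = out / "model_comparison.csv"
    table.to_csv(path, index=False, float_format=FLOAT_FMT)
    files = [path]
    bif = fits[-1]
    loadings = standardized_loadings(bif)
    lpath = out / "bifactor_loadings.csv"
    loadings.to_csv(lpath, index=False, float_format=FLOAT_FMT)
    files.append(lpath)
    if config.run_lodo:
        lodo = leave_one_domain_out(
            resp, dmap, ModelSpec(structure="bifactor", **common), full_fit=bif
        )
        lodo_path = out / "leave_one_domain_out.csv"
        lodo.to_csv(lodo_path, index=False, float_format=FLOAT_FMT)
        files.append(lodo_path)
    _register(report, out, *files)
    state["fits"] = fits
    best = table.loc[table["bic"].idxmin(), "structure"]
    report.summary["best_by_bic"] = str(best)
    report.summary["n_cfa_fits"] = len(fits)


def _stage_testlet(config, out, report, state):
    resp, dmap = state["resp"], state["dmap"]
    mcfg = MCMCConfig(
        n_iterations=config.mcmc_iterations,
        burn_in=config.mcmc_burn_in,
        n_chains=config.mcmc_chains,
        person_thin=config.mcmc_person_thin,
        psrf_threshold=config.psrf_threshold,
        seed=stage_seed(config.seed, "testlet"),
    )
    post = run_mcmc(resp, dmap, mcfg)
    conv = convergence(post)
    report.summary["mcmc_converged"] = conv.passed
    report.summary["psrf_quantiles"] = list(conv.item_quantiles)
    table = summarize_items(post, conv, override=config.allow_unconverged)
    scores = score_persons(post, conv, override=config.allow_unconverged)
    ipath = out / "testlet_item_params.csv"
    spath = out / "testlet_sigmas.csv"
    ppath = out / "checklist_scores.csv"
    cpath = out / "convergence.json"
    table.write(ipath, spath)
    scores.write(ppath)
    _write_json(conv.to_dict(), cpath)
    _register(report, out, ipath, spath, ppath, cpath)
    state["checklist_scores"] = scores


def _stage_severity(config, out, report, state):
    sev = state["sev"]
    fit = fit_grm(sev)
    scores = eap_scores(fit.items, sev)
    fpath = out / "grm_item_params.csv"
    spath = out / "severity_scores.csv"
    fit.write(fpath)
    scores.write(spath)
    _register(report, out, fpath, spath)
    state["severity_scores"] = scores
    report.summary["grm_loglik"] = fit.loglik


def _stage_agreement(config, out, report, state):
    s1, s2 = state["checklist_scores"], state["severity_scores"]
    records, summary = bland_altman(s1, s2, z=config.agreement_z)
    rho_raw = score_vs_raw_rank_check(s1, state["resp"])
    summary["spearman_vs_raw_counts"] = rho_raw
    rpath = out / "agreement_records.csv"
    cpath = out / "bland_altman_coords.csv"
    jpath = out / "agreement_summary.json"
    records.to_csv(rpath, index=False, float_format=FLOAT_FMT)
    write_plot_coords(records, cpath)
    _write_json(summary, jpath)
    _register(report, out, rpath, cpath, jpath)
    report.summary["percent_agree"] = summary["percent_agree"]
    report.summary["score_spearman"] = summary["spearman"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "validate": _stage_validate,
    "structure": _stage_structure,
    "testlet": _stage_testlet,
    "severity": _stage_severity,
    "agreement": _stage_agreement,
}


def emit_report(report: RunReport, path, text: bool = True):
    """Machine-readable JSON report plus a short human-readable summary."""
    path = Path(path)
    _write_json(report.to_dict(), path)
    if text:
        lines = [f"ocdim run (version {report.version}, seed {report.seed})"]
        for stage, info in report.stages.items():
            lines.append(f"  {stage:10s} {info['status']}")
        for k, v in report.summary.items():
            lines.append(f"  {k} = {v}")
        txt = path.with_suffix(".txt")
        txt.write_text("\n".join(lines) + "\n")
    return path
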