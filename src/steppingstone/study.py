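"""End-to-end study drivers: the simulation validation and empirical mode.

``run_simulation_study`` reproduces the two halves of the validation at a
configurable scale: the F-statistic / Mantel power sweep across the lattice
parameter sets, and the seven-model coalescent model-selection experiment on
replicate simulated datasets.  ``run_empirical`` applies the archipelago
model set to any FASTA + deme-map dataset.

Every run writes a manifest (seed, fully expanded configuration) so each
output table is derivable from the manifest alone; model-selection replicates
are checkpointed per dataset so an interrupted study resumes where it
stopped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .coalmcmc import MCMCConfig, Priors, run_model_evidence
from .coalmcmc.evidence import ess, hpd, psrf
from .coalmcmc.state import effective_migrants
from .modelselect import (
    ModelEvidence,
    build_hawaii_models,
    build_simulation_models,
    posterior_slope_test,
    select_model,
)
from .popstats import ibd_power_sweep
from .simulate import (
    SimulationParams,
    parameter_set_table,
    replicate_rng,
    simulate_dataset,
)

log = logging.getLogger("steppingstone")


@dataclass
class StudyConfig:
    """Fully explicit configuration of one study run."""

    mode: str = "sim-study"                # sim-study | empirical
    scale: str = "desk"                    # desk | published | suite
    param_sets: tuple = ("all",)           # names, or ("all",)
    n_reps_power: int = 100
    n_reps_evidence: int = 10
    evidence_sets: tuple = ()              # subset run through model selection
    sample_size: int | None = None         # per-deme override (desk scaling)
    alpha: float = 0.05
    n_perm: int = 999
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    priors: Priors = field(default_factory=Priors)
    out_dir: str = "results"
    seed: int = 0

    def expanded_mcmc(self) -> MCMCConfig:
        if self.scale == "published":
            return MCMCConfig.published_scale()
        if self.scale == "suite":
            return MCMCConfig.suite_scale()
        return self.mcmc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _manifest(cfg: StudyConfig, out: Path, extra: dict | None = None) -> None:
    payload = {"config": cfg.to_dict(), "seed": cfg.seed}
    payload.update(extra or {})
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    payload["config_hash"] = digest
    sio.write_json(payload, out / "manifest.json")


def _selected_sets(cfg: StudyConfig) -> list[SimulationParams]:
    table = parameter_set_table()
    if cfg.param_sets == ("all",):
        return table
    by_name = {p.name: p for p in table}
    return [by_name[name] for name in cfg.param_sets]


def evaluate_models_on_dataset(aln, models, priors, mcmc_cfg, rng) -> list[dict]:
    """Fit every candidate model to one dataset; one evidence summary each."""
    out = []
    for model in models:
        child = rng.spawn(1)[0]
        summary = run_model_evidence(aln, model, priors, mcmc_cfg, child)
        log.info("model %-24s log m.l. %10.2f", model.name, summary["log_ml"])
        out.append(summary)
    return out


def run_simulation_study(cfg: StudyConfig) -> dict:
    """Power sweep plus (optionally) the model-selection experiment.

    Returns the result tables; also writes them under ``cfg.out_dir`` as tidy
    TSVs with a manifest.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sets = _selected_sets(cfg)
    results: dict = {}

    if cfg.n_reps_power > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,))
        )
        power = ibd_power_sweep(
            sets, n_reps=cfg.n_reps_power, alpha=cfg.alpha,
            n_perm=cfg.n_perm, rng=rng,
        )
        power.to_csv(out / "power.tsv", sep="\t", index=False)
        results["power"] = power

    evidence_rows = []
    selection_rows = []
    ckpt_dir = out / "checkpoints"
    mcmc_cfg = cfg.expanded_mcmc()
    evidence_sets = [p for p in sets if p.name in cfg.evidence_sets]
    if evidence_sets:
        ckpt_dir.mkdir(exist_ok=True)
        models = build_simulation_models(evidence_sets[0].n_demes)
    for params in evidence_sets:
        if cfg.sample_size:
            params = dataclasses.replace(params, sample_size=cfg.sample_size)
        for rep in range(cfg.n_reps_evidence):
            ckpt = ckpt_dir / f"{params.name}_rep{rep}.json"
            if ckpt.exists():
                rows = json.loads(ckpt.read_text())
            else:
                set_idx = int(params.name[3:]) if params.name.startswith("set") else 0
                rng = replicate_rng(cfg.seed, set_idx, rep)
                aln = simulate_dataset(params, rng)
                summaries = evaluate_models_on_dataset(
                    aln, models, cfg.priors, mcmc_cfg, rng
                )
                rows = [
                    {
                        "param_set": params.name,
                        "replicate": rep,
                        "model": s["model"],
                        "log_ml": s["log_ml"],
                        "n_parameters": s["n_parameters"],
                        "nem_estimate": _nem_estimate(s),
                    }
                    for s in summaries
                ]
                ckpt.write_text(json.dumps(rows))
            evidence_rows.extend(rows)
            best = max(rows, key=lambda r: r["log_ml"])
            selection_rows.append(
                {
                    "param_set": params.name,
                    "replicate": rep,
                    "winner": best["model"],
                    "log_ml": best["log_ml"],
                }
            )
    if evidence_rows:
        ev = pd.DataFrame(evidence_rows)
        ev.to_csv(out / "evidence.tsv", sep="\t", index=False)
        sel = pd.DataFrame(selection_rows)
        sel.to_csv(out / "selection.tsv", sep="\t", index=False)
        results["evidence"] = ev
        results["selection"] = sel
    _manifest(cfg, out)
    return results


def _nem_estimate(summary: dict) -> float | None:
    """Posterior-median N_e m implied by the cold chain of one model fit."""
    th = np.asarray(summary["theta_samples"])
    mm = np.asarray(summary["M_samples"])
    if mm.size == 0:
        return None
    nem = effective_migrants(th.mean(axis=1), mm.mean(axis=1))
    return float(np.median(nem))


def run_empirical(
    fasta,
    deme_tsv,
    cfg: StudyConfig,
    covariate_tsv=None,
    n_estimates: int = 3,
    custom_partition=None,
) -> dict:
    """Archipelago-style model selection on an empirical dataset.

    Builds the regional/island/stepping-stone model set over the observed
    demes (ordered by lattice position), runs ``n_estimates`` replicate
    evidence estimates per model, and reports the selection with convergence
    diagnostics; when a covariate table (island, area or census column) is
    supplied and the free stepping-stone model wins, the posterior slope test
    is run as well.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aln = sio.read_alignment(fasta, deme_tsv)
    counts = np.bincount(aln.deme_of_sample)
    if aln.n_demes < 2 or np.any(counts < 2):
        raise ValueError("empirical mode needs >= 2 demes with >= 2 samples each")
    models = build_hawaii_models(aln.deme_names, custom_partition=custom_partition)
    mcmc_cfg = cfg.expanded_mcmc()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,)))

    evidence = []
    rows = []
    diagnostics = {}
    theta_samples_best: dict = {}
    for model in models:
        log_mls = []
        ll_traces = []
        theta_reps = []
        for est in range(n_estimates):
            summary = run_model_evidence(aln, model, cfg.priors, mcmc_cfg, rng.spawn(1)[0])
            log_mls.append(summary["log_ml"])
            ll_traces.append(summary["loglik_samples"])
            theta_reps.append(summary["theta_samples"])
            rows.append(
                {
                    "model": model.name, "replicate": est,
                    "log_ml": summary["log_ml"],
                    "n_parameters": summary["n_parameters"],
                }
            )
        diagnostics[model.name] = {
            "ess_loglik": min(ess(t) for t in ll_traces),
            "psrf_loglik": psrf(ll_traces) if n_estimates >= 2 else 1.0,
        }
        evidence.append(
            ModelEvidence(model.name, log_mls,
                          model.n_theta_groups + model.n_mig_groups)
        )
        if model.name == "stepping-stone-full":
            pooled = np.vstack(theta_reps)
            theta_samples_best = {
                aln.deme_names[d]: pooled[:, model.theta_ties[model.deme_partition[d]]]
                for d in range(aln.n_demes)
            }

    selection = select_model(evidence, rng=rng)
    ev_table = pd.DataFrame(rows)
    ev_table.to_csv(out / "empirical_evidence.tsv", sep="\t", index=False)
    result = {
        "selection": selection,
        "evidence": ev_table,
        "diagnostics": diagnostics,
    }
    if covariate_tsv is not None and selection.best == "stepping-stone-full":
        cov = pd.read_csv(covariate_tsv, sep="\t")
        value_col = [c for c in cov.columns if c != "island"][0]
        covariate = dict(zip(cov["island"].astype(str), cov[value_col]))
        result["slope_test"] = posterior_slope_test(
            theta_samples_best, covariate, rng=rng
        )
    sio.write_json(
        {
            "best": selection.best, "second": selection.second,
            "p_value": selection.p_value, "ambiguous": selection.ambiguous,
            "probabilities": selection.probabilities,
            "diagnostics": diagnostics,
        },
        out / "empirical_selection.json",
    )
    _manifest(cfg, out, {"fasta": str(fasta), "deme_tsv": str(deme_tsv)})
    return result
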