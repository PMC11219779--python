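"""End-to-end study orchestration.

``run_study`` executes the full design-selection loop for every candidate
species: simulate replicate measurements at the nominal dose, infer one
constraint-filtered posterior chain per replicate, propagate each chain to
a lethality curve, evaluate the uncertainty objectives, and rank designs.

Every random stage draws its seed from a counter-based derivation of the
master seed, keyed by (design index, replicate, stage), so designs are
statistically independent and removing one never perturbs another.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boed_metrics import (DEFAULT_THRESHOLDS, DesignObjective,
                           design_objective, percent_reduction, rank_designs)
from .inference import (HMCSettings, PosteriorChain,
                        filter_chain_by_constraints, infer_posterior)
from .lethality import DEFAULT_IC50_GRID, LethalityEnsemble, lethality_ensemble
from .model_core import ReactionNetworkModel, load_model
from .priors import PriorSpec, load_prior_table, prior_from_table
from .synthetic_data import (reduced_apoptosis_model,
                             reduced_apoptosis_priors, simulate_measurements)

__all__ = ["StudyConfig", "StudyResult", "run_study", "child_seed"]

logger = logging.getLogger(__name__)

_STAGES = {"data": 0, "mcmc": 1, "subsample": 2}


def child_seed(master: int, design_index: int, replicate: int,
               stage: str) -> int:
    """Deterministic per-(design, replicate, stage) seed below 2**31."""
    ss = np.random.SeedSequence(
        [int(master), int(design_index), int(replicate), _STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class StudyConfig:
    """Study settings (desk-scale defaults; campaign-scale values accepted).

    ``model`` / ``priors`` are file paths, or None for the bundled reduced
    apoptosis fixture.  ``designs`` defaults to every measurable species.
    """
    model: str | None = None
    priors: str | None = None
    designs: list[str] | None = None
    u_grid: list[float] = field(default_factory=lambda: list(DEFAULT_IC50_GRID))
    thresholds: list[float] = field(
        default_factory=lambda: list(DEFAULT_THRESHOLDS))
    u_star: float = 0.01          # sigma_apop evaluation dose
    t_star: float = 0.90          # sigma_ic50 evaluation threshold
    w1_list: list[float] = field(default_factory=lambda: [0.01, 0.1])
    n_replicates: int = 10        # campaign-scale: 100
    chain_length: int = 2000      # campaign-scale: 50000
    warmup_frac: float = 0.2
    target_accept: float = 0.8
    max_leapfrog: int = 10
    rel_err: float = 0.10
    u_nominal: float = 1.0        # dose at which measurements are simulated
    n_sub: int = 200              # chain draws per lethality curve
    apply_bounds: bool = True
    constraint_filtering: bool = True
    u_live: float = 100.0
    u_die: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.u_star not in self.u_grid:
            raise ValueError("u_star must be on the IC50 grid")
        if self.t_star not in self.thresholds:
            raise ValueError("t_star must be among the thresholds")
        if any(not (0 < t < 1) for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")
        if any(not (0 <= w <= 1) for w in self.w1_list):
            raise ValueError("weights must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def hmc_settings(self) -> HMCSettings:
        return HMCSettings(warmup_frac=self.warmup_frac,
                           target_accept=self.target_accept,
                           max_leapfrog=self.max_leapfrog)

    def load_model(self) -> ReactionNetworkModel:
        if self.model is None:
            return reduced_apoptosis_model()
        return load_model(self.model)

    def load_priors(self) -> PriorSpec:
        if self.priors is None:
            return reduced_apoptosis_priors()
        return prior_from_table(load_prior_table(self.priors))


@dataclass
class StudyResult:
    """Everything the study computed, plus the provenance to rerun it."""
    config: dict
    objectives: list[DesignObjective]
    rankings: dict[str, pd.DataFrame]
    ensembles: dict[str, LethalityEnsemble]
    diagnostics: dict[str, list[dict]]
    excluded_designs: list[str]
    run_log: dict

    def results_dict(self) -> dict:
        """JSON-ready summary; deterministic for fixed config + seed."""
        def num(v):
            # undefined metrics (e.g. too few crossing curves) become null
            return float(v) if np.isfinite(v) else None

        out: dict = {"config": self.config, "designs": {}, "rankings": {}}
        for obj in self.objectives:
            out["designs"][obj.design] = {
                "n_curves": obj.n_curves,
                "sigma_apop": {f"{u:g}": num(v)
                               for u, v in obj.sigma_apop.items()},
                "sigma_ic50_log10": {f"{t:g}": num(v)
                                     for t, v in obj.sigma_ic50.items()},
                "sigma_ic50_excluded": {f"{t:g}": int(v)
                                        for t, v in obj.ic50_excluded.items()},
                "retained_fraction": [
                    d["retained_fraction"]
                    for d in self.diagnostics[obj.design]],
            }
        for name, table in self.rankings.items():
            out["rankings"][name] = {
                "order": table["design"].tolist(),
                "objective": [float(v) for v in table["objective"]],
                "best": table["design"].iloc[0],
                "percent_reduction_best_vs_worst": percent_reduction(table),
            }
        out["excluded_designs"] = self.excluded_designs
        return out

    def to_json(self) -> str:
        return json.dumps(self.results_dict(), indent=2, sort_keys=True)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "results.json").write_text(self.to_json() + "\n")
        (outdir / "run_log.json").write_text(
            json.dumps(self.run_log, indent=2, sort_keys=True) + "\n")
        curves = pd.concat([e.to_frame() for e in self.ensembles.values()],
                           ignore_index=True)
        curves.to_csv(outdir / "lethality_curves.csv", index=False)
        pd.concat([e.summary_frame() for e in self.ensembles.values()],
                  ignore_index=True).to_csv(
            outdir / "lethality_summary.csv", index=False)
        for name, table in self.rankings.items():
            table.to_csv(outdir / f"ranking_{name}.csv", index=False)
        (outdir / "diagnostics.json").write_text(
            json.dumps(self.diagnostics, indent=2, sort_keys=True) + "\n")


def _infer_design(model, priors, config: StudyConfig, design: str,
                  d_idx: int) -> tuple[list[PosteriorChain], list[dict]]:
    theta_true = priors.medians()
    data = simulate_measurements(
        model, theta_true, design, u=config.u_nominal,
        n=config.n_replicates, rel_err=config.rel_err,
        seed=child_seed(config.seed, d_idx, 0, "data"))
    chains, diags = [], []
    for rep, meas in enumerate(data.measurements):
        chain = infer_posterior(
            meas, model, priors, n_samples=config.chain_length,
            seed=child_seed(config.seed, d_idx, rep, "mcmc"),
            settings=config.hmc_settings(), rel_err=config.rel_err)
        if config.constraint_filtering:
            chain = filter_chain_by_constraints(
                chain, model, u_live=config.u_live, u_die=config.u_die)
        chains.append(chain)
        diags.append(chain.diagnostics())
    return chains, diags


def run_study(config: StudyConfig) -> StudyResult:
    """Simulate -> infer -> filter -> lethality -> metrics -> rank.

    A design whose filtered chains are all empty is excluded from the
    objectives and rankings with a warning; the study never aborts on a
    partial failure.
    """
    t_start = time.time()
    model = config.load_model()
    priors = config.load_priors()
    if priors.names != model.uncertain_names:
        raise ValueError("priors do not match the model's uncertain "
                         "parameters")
    designs = config.designs or model.measurable_species
    bad = set(designs) - set(model.measurable_species)
    if bad:
        raise ValueError(f"not measurable species: {sorted(bad)}")

    objectives, ensembles, diagnostics, excluded = [], {}, {}, []
    for design in sorted(designs):
        # seed key is the design's index in the *full* measurable set, so
        # dropping one design never changes another's seeds
        d_idx = model.measurable_species.index(design)
        chains, diags = _infer_design(model, priors, config, design, d_idx)
        diagnostics[design] = diags
        try:
            ens = lethality_ensemble(
                chains, model, u_grid=config.u_grid, n_sub=config.n_sub,
                design=design, apply_bounds=config.apply_bounds)
        except ValueError:
            logger.warning("design %s excluded: no feasible posterior "
                           "samples in any replicate", design)
            excluded.append(design)
            continue
        ensembles[design] = ens
        objectives.append(design_objective(ens, thresholds=config.thresholds))

    rankings: dict[str, pd.DataFrame] = {}
    if objectives:
        rankings[f"sigma_apop@u={config.u_star:g}"] = rank_designs(
            objectives, "sigma_apop", u=config.u_star)
        rankings[f"sigma_ic50@T={config.t_star:g}"] = rank_designs(
            objectives, "sigma_ic50", T=config.t_star)
        for w1 in config.w1_list:
            rankings[f"weighted@w1={w1:g}"] = rank_designs(
                objectives, "weighted", u=config.u_star, T=config.t_star,
                w1=w1)

    run_log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "master_seed": config.seed,
        "seed_scheme": "SeedSequence([master, design_index, replicate, "
                       "stage]) % 2**31",
        "wall_clock_s": round(time.time() - t_start, 3),
    }
    return StudyResult(config=asdict(config), objectives=objectives,
                       rankings=rankings, ensembles=ensembles,
                       diagnostics=diagnostics, excluded_designs=excluded,
                       run_log=run_log)
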