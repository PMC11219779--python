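"""Probabilistic lethality (dose-response) curves.

For a set of parameter draws {theta_i}, the probability that an inhibitor
of potency u triggers apoptosis is the Monte-Carlo indicator average

    P(apoptosis | u) = (1/N_s) sum_i 1[ y_Casp,i^max(u) >= threshold ],

evaluated over an IC50 grid to give a *lethality curve* — the probabilistic
analogue of a dose-response curve.  Known dose-boundary behaviour (the cell
dies at u <= 0.001 and lives at u >= 100) can be imposed on the curve ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._compile import IntegrationError
from .model_core import ReactionNetworkModel, caspase_peak

__all__ = ["DEFAULT_IC50_GRID", "LethalityCurve", "LethalityEnsemble",
           "p_apoptosis", "lethality_curve", "lethality_ensemble"]

logger = logging.getLogger(__name__)

#: study IC50 grid (log-spaced over five orders of magnitude)
DEFAULT_IC50_GRID = (0.001, 0.01, 0.032, 0.1, 0.32, 1.0, 3.2, 10.0, 100.0)
#: dose-boundary constraints: certain death below U_DIE, survival above U_LIVE
U_DIE = 0.001
U_LIVE = 100.0


@dataclass(frozen=True)
class LethalityCurve:
    """P(apoptosis) over an IC50 grid from one parameter ensemble."""
    u_grid: tuple[float, ...]
    p: tuple[float, ...]
    n_samples: int
    constrained: bool
    n_failed: int = 0            # integration failures, counted non-apoptotic

    def __post_init__(self):
        if len(self.p) != len(self.u_grid):
            raise ValueError("p and u_grid lengths differ")
        if any(not (0.0 <= v <= 1.0) for v in self.p):
            raise ValueError("probabilities must lie in [0, 1]")

    def as_series(self) -> pd.Series:
        return pd.Series(self.p, index=list(self.u_grid), name="p")


@dataclass(frozen=True)
class LethalityEnsemble:
    """One lethality curve per measurement replicate of a design."""
    design: str
    curves: tuple[LethalityCurve, ...]
    n_skipped: int = 0           # replicates with empty filtered chains

    def __post_init__(self):
        grids = {c.u_grid for c in self.curves}
        if len(grids) > 1:
            raise ValueError("ensemble curves must share the IC50 grid")

    @property
    def u_grid(self) -> tuple[float, ...]:
        return self.curves[0].u_grid

    @property
    def mean_curve(self) -> np.ndarray:
        """Pointwise arithmetic mean over the replicate curves."""
        return np.mean([c.p for c in self.curves], axis=0)

    def p_matrix(self) -> np.ndarray:
        """(n_curves, n_grid) matrix of probabilities."""
        return np.array([c.p for c in self.curves])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, c in enumerate(self.curves):
            for u, p in zip(c.u_grid, c.p):
                rows.append({"design": self.design, "replicate": r,
                             "u": u, "p": p})
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        pm = self.p_matrix()
        return pd.DataFrame({
            "design": self.design, "u": list(self.u_grid),
            "p_mean": pm.mean(axis=0),
            "p_sd": pm.std(axis=0, ddof=1) if len(self.curves) > 1 else np.nan,
        })


def _peaks(samples: pd.DataFrame, model: ReactionNetworkModel, u: float):
    """(peak caspase per row, failure count); failures count as no-apoptosis."""
    names = list(samples.columns)
    peaks = np.empty(len(samples))
    failed = 0
    for i, row in enumerate(samples.to_numpy()):
        try:
            peaks[i] = caspase_peak(model, dict(zip(names, row)), u)
        except IntegrationError:
            peaks[i] = -np.inf
            failed += 1
    return peaks, failed


def p_apoptosis(samples: pd.DataFrame, model: ReactionNetworkModel,
                u: float) -> float:
    """Monte-Carlo P(apoptosis) at one IC50 from a parameter sample table.

    Failed integrations are counted as non-apoptotic (conservative for a
    lethality claim) and logged; if *every* integration fails the estimate
    is meaningless and an error is raised.
    """
    if len(samples) < 1:
        raise ValueError("need at least one parameter sample")
    peaks, failed = _peaks(samples, model, u)
    if failed == len(samples):
        raise IntegrationError(
            f"all {failed} forward integrations failed at u={u}", u=u)
    if failed:
        logger.warning("%d/%d integrations failed at u=%g "
                       "(counted non-apoptotic)", failed, len(samples), u)
    return float(np.mean(peaks >= model.apoptosis_threshold))


def lethality_curve(samples: pd.DataFrame, model: ReactionNetworkModel,
                    u_grid=DEFAULT_IC50_GRID,
                    apply_bounds: bool = False) -> LethalityCurve:
    """P(apoptosis) at every grid IC50, sharing the sample set across u.

    With ``apply_bounds`` the dose-boundary constraints override the curve:
    p = 1 wherever u <= 0.001 and p = 0 wherever u >= 100.
    """
    u_grid = tuple(float(u) for u in u_grid)
    if len(u_grid) == 0:
        raise ValueError("u_grid must be non-empty")
    if any(b <= a for a, b in zip(u_grid, u_grid[1:])):
        raise ValueError("u_grid must be sorted strictly ascending")
    ps, n_failed = [], 0
    for u in u_grid:
        if apply_bounds and u <= U_DIE:
            ps.append(1.0)
        elif apply_bounds and u >= U_LIVE:
            ps.append(0.0)
        else:
            peaks, failed = _peaks(samples, model, u)
            if failed == len(samples):
                raise IntegrationError(
                    f"all forward integrations failed at u={u}", u=u)
            n_failed += failed
            ps.append(float(np.mean(peaks >= model.apoptosis_threshold)))
    return LethalityCurve(u_grid=u_grid, p=tuple(ps), n_samples=len(samples),
                          constrained=bool(apply_bounds), n_failed=n_failed)


def lethality_ensemble(chains, model: ReactionNetworkModel,
                       u_grid=DEFAULT_IC50_GRID, n_sub: int = 200,
                       seed=None, design: str | None = None,
                       apply_bounds: bool = True) -> LethalityEnsemble:
    """One lethality curve per (filtered) posterior chain.

    ``n_sub`` equally spaced draws are taken from each chain — a
    deterministic thinning, so ``seed`` is accepted for interface symmetry
    but unused.  Replicates whose filtered chain is empty are skipped and
    counted in ``n_skipped``.
    """
    curves, skipped = [], 0
    for chain in chains:
        if chain.is_empty:
            skipped += 1
            continue
        k = min(n_sub, len(chain))
        idx = np.unique(np.linspace(0, len(chain) - 1, k).round().astype(int))
        sub = chain.samples.iloc[idx]
        curves.append(lethality_curve(sub, model, u_grid, apply_bounds))
    if skipped:
        logger.warning("lethality ensemble: skipped %d empty chains", skipped)
    if not curves:
        raise ValueError("no non-empty chains; cannot form an ensemble")
    if design is None:
        design = getattr(chains[0], "measurement_id", "design").split("@")[0]
    return LethalityEnsemble(design=design, curves=tuple(curves),
                             n_skipped=skipped)
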