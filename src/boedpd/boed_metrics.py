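"""Design-ranking uncertainty objectives.

Two decision-relevant metrics summarise an ensemble of replicate lethality
curves for a candidate measurement xi:

* ``sigma_apop(u)``   — the spread (sample sd) of the predicted apoptosis
  probability at inhibitor potency u.  Small means the calibrated model is
  confident about how lethal a drug of that potency is.
* ``sigma_ic50(T)``   — the spread, in log10 concentration units, of the
  IC50 at which the curve crosses a target kill probability T.  Small
  means the calibrated model pins down which potency achieves the target.

The optimal design xi* minimises the chosen objective (equivalently,
maximises J = -sigma): less residual uncertainty after calibrating to that
species' data means the experiment was more informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lethality import (DEFAULT_IC50_GRID, LethalityEnsemble,
                        lethality_curve)
from .model_core import ReactionNetworkModel
from .priors import PriorSpec, sample_priors, scale_prior

__all__ = ["CrossingStats", "DesignObjective", "sigma_apop", "sigma_ic50",
           "weighted_objective", "rank_designs", "percent_reduction",
           "prior_sensitivity_study", "DEFAULT_THRESHOLDS",
           "DEFAULT_SIGMA_FACTORS"]

logger = logging.getLogger(__name__)

#: kill-probability thresholds swept for sigma_IC50
DEFAULT_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)
#: prior-sigma multipliers for the sensitivity study
DEFAULT_SIGMA_FACTORS = (1.0, 0.1, 0.01, 0.001, 0.0001)


def sigma_apop(ensemble: LethalityEnsemble, u: float) -> float:
    """Sample sd (ddof=1) of P(apoptosis | u) across replicate curves."""
    grid = ensemble.u_grid
    matches = [i for i, g in enumerate(grid) if np.isclose(g, u)]
    if not matches:
        raise ValueError(f"u={u} is not on the ensemble grid {grid}")
    if len(ensemble.curves) < 2:
        raise ValueError("need at least two curves for a spread")
    vals = ensemble.p_matrix()[:, matches[0]]
    return float(np.std(vals, ddof=1))


@dataclass(frozen=True)
class CrossingStats:
    """sigma_IC50 at one threshold plus the curve bookkeeping behind it."""
    sigma: float                 # sd of log10(crossing IC50), ddof=1
    n_used: int
    n_excluded: int              # curves that never cross T
    n_multi: int                 # curves crossing more than once
    crossings_log10: tuple[float, ...]

    @property
    def defined(self) -> bool:
        return self.n_used >= 2


def _crossing_log10(logu: np.ndarray, p: np.ndarray, T: float):
    """First downward crossing of T, interpolated linearly in (log10 u, p).

    Lethality falls with u (weaker inhibitor), so the scan looks for the
    first transition from p >= T to p < T going up the grid.  Returns
    (crossing, n_crossings); crossing is None when the curve never crosses.
    """
    first = None
    count = 0
    for i in range(len(p) - 1):
        if p[i] >= T and p[i + 1] < T:
            count += 1
            if first is None:
                if p[i + 1] == p[i]:       # unreachable; guard division
                    first = logu[i]
                else:
                    first = logu[i] + (T - p[i]) * (logu[i + 1] - logu[i]) \
                        / (p[i + 1] - p[i])
    return first, count


def sigma_ic50(ensemble: LethalityEnsemble, T: float) -> CrossingStats:
    """Spread of the T-crossing IC50 across curves, in log10 units.

    Curves that never reach/cross the threshold cannot contribute an IC50
    estimate; they are excluded (not clamped, which would deflate the
    spread) and counted.
    """
    if not (0.0 < T < 1.0):
        raise ValueError("threshold T must lie in (0, 1)")
    logu = np.log10(np.asarray(ensemble.u_grid, dtype=float))
    crossings, n_multi = [], 0
    for curve in ensemble.curves:
        c, k = _crossing_log10(logu, np.asarray(curve.p), T)
        if c is None:
            continue
        if k > 1:
            n_multi += 1
        crossings.append(c)
    n_used = len(crossings)
    n_excl = len(ensemble.curves) - n_used
    if n_multi:
        logger.info("sigma_ic50(T=%g): %d multi-crossing curves "
                    "(first crossing used)", T, n_multi)
    sigma = float(np.std(crossings, ddof=1)) if n_used >= 2 else np.nan
    return CrossingStats(sigma=sigma, n_used=n_used, n_excluded=n_excl,
                         n_multi=n_multi, crossings_log10=tuple(crossings))


def weighted_objective(sigma_ic50_val: float, sigma_apop_val: float,
                       w1: float) -> float:
    """w1 * sigma_IC50 + (1 - w1) * sigma_apop, with w1 in [0, 1]."""
    if not (0.0 <= w1 <= 1.0):
        raise ValueError("w1 must lie in [0, 1]")
    return float(w1 * sigma_ic50_val + (1.0 - w1) * sigma_apop_val)


@dataclass(frozen=True)
class DesignObjective:
    """All uncertainty objectives for one candidate design."""
    design: str
    sigma_apop: pd.Series        # indexed by u
    sigma_ic50: pd.Series        # indexed by T (log10 units)
    ic50_excluded: pd.Series     # non-crossing curve counts per T
    n_curves: int

    def value(self, criterion: str, u: float | None = None,
              T: float | None = None, w1: float | None = None) -> float:
        """Scalar objective under one of the three ranking criteria."""
        if criterion == "sigma_apop":
            return float(self.sigma_apop.loc[u])
        if criterion == "sigma_ic50":
            return float(self.sigma_ic50.loc[T])
        if criterion == "weighted":
            return weighted_objective(float(self.sigma_ic50.loc[T]),
                                      float(self.sigma_apop.loc[u]), w1)
        raise ValueError(f"unknown criterion {criterion!r}")


def design_objective(ensemble: LethalityEnsemble,
                     thresholds=DEFAULT_THRESHOLDS) -> DesignObjective:
    """Evaluate both metrics over the full u grid and threshold sweep."""
    s_apop = pd.Series({u: sigma_apop(ensemble, u) for u in ensemble.u_grid})
    stats = {T: sigma_ic50(ensemble, T) for T in thresholds}
    return DesignObjective(
        design=ensemble.design,
        sigma_apop=s_apop,
        sigma_ic50=pd.Series({T: s.sigma for T, s in stats.items()}),
        ic50_excluded=pd.Series({T: s.n_excluded for T, s in stats.items()}),
        n_curves=len(ensemble.curves))


def rank_designs(objectives, criterion: str = "sigma_apop",
                 u: float | None = None, T: float | None = None,
                 w1: float | None = None) -> pd.DataFrame:
    """Order designs by ascending uncertainty; the first row is xi*.

    Designs whose objective is undefined (e.g. too few crossing curves for
    sigma_IC50 at that threshold) are excluded with a warning.  Ties are
    broken lexicographically by design name and flagged in the ``tied``
    column.
    """
    rows = []
    for obj in objectives:
        try:
            v = obj.value(criterion, u=u, T=T, w1=w1)
        except (KeyError, ValueError):
            v = np.nan
        if np.isnan(v):
            logger.warning("design %s excluded from ranking: %s undefined",
                           obj.design, criterion)
            continue
        rows.append({"design": obj.design, "objective": v})
    if not rows:
        raise ValueError("no design has a computable objective")
    df = pd.DataFrame(rows).sort_values(
        ["objective", "design"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["tied"] = df["objective"].duplicated(keep=False)
    return df


def percent_reduction(ranking: pd.DataFrame) -> float:
    """100 * (sigma_worst - sigma_best) / sigma_worst for a ranking table."""
    worst = ranking["objective"].max()
    best = ranking["objective"].min()
    if worst == 0:
        return 0.0
    return float(100.0 * (worst - best) / worst)


def prior_sensitivity_study(model: ReactionNetworkModel, priors: PriorSpec,
                            factors=DEFAULT_SIGMA_FACTORS,
                            u_grid=DEFAULT_IC50_GRID, n: int = 1000,
                            seed: int = 0,
                            apply_bounds: bool = False) -> pd.DataFrame:
    """Lethality curves under progressively narrowed priors.

    For each multiplicative sigma factor: scale every prior sigma, draw n
    parameter samples, and evaluate the lethality curve over the grid
    (optionally with the dose-boundary constraints imposed).  Returns a
    tidy frame with columns ``factor, u, p``.  The same seed is reused for
    every factor so curves differ only through the prior width.
    """
    if any(f <= 0 for f in factors):
        raise ValueError("sigma factors must be positive")
    rows = []
    for factor in factors:
        scaled = scale_prior(priors, factor)
        samples = sample_priors(scaled, n, seed)
        curve = lethality_curve(samples, model, u_grid, apply_bounds)
        for u, p in zip(curve.u_grid, curve.p):
            rows.append({"factor": factor, "u": u, "p": p})
    return pd.DataFrame(rows)
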