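"""Log-normal priors on kinetic rate constants.

Each uncertain rate constant theta_j gets an independent log-normal prior:
ln theta_j ~ Normal(mu_j, sigma_j).  The location mu_j comes from the
nominal (literature) value, treated as the *median* of the distribution;
the scale sigma_j is recovered by inverting the stated confidence interval
on the log scale.  A global ``scale_factor`` multiplies every sigma, which
is how the prior-sensitivity study narrows all priors at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PriorEntry", "PriorSpec", "build_lognormal_prior",
           "prior_from_table", "load_prior_table", "scale_prior",
           "sample_priors"]


@dataclass(frozen=True)
class PriorEntry:
    """Log-normal prior for one parameter: ln theta ~ Normal(mu, sigma)."""
    name: str
    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma for {self.name!r} must be > 0")


@dataclass(frozen=True)
class PriorSpec:
    """Independent log-normal priors over a model's uncertain parameters."""
    entries: tuple[PriorEntry, ...]
    scale_factor: float = 1.0

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def mus(self) -> np.ndarray:
        return np.array([e.mu for e in self.entries])

    @property
    def sigmas(self) -> np.ndarray:
        """Effective scales: per-entry sigma times the global scale factor."""
        return np.array([e.sigma for e in self.entries]) * self.scale_factor

    def medians(self) -> dict[str, float]:
        """exp(mu) per parameter — invariant under sigma scaling."""
        return {e.name: float(np.exp(e.mu)) for e in self.entries}

    def log_density(self, theta: np.ndarray) -> float:
        """Log prior density of the log-normal over theta (> 0)."""
        theta = np.asarray(theta, dtype=float)
        if np.any(theta <= 0):
            return -np.inf
        z = np.log(theta)
        s = self.sigmas
        return float(np.sum(stats.norm.logpdf(z, self.mus, s)) - np.sum(z))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"name": self.names, "mu": self.mus,
                             "sigma": self.sigmas})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_lognormal_prior(name: str, nominal: float, ci_low: float,
                          ci_high: float, level: float = 0.95) -> PriorEntry:
    """Invert a nominal value + confidence interval into (mu, sigma).

    The nominal value is taken as the median, so mu = ln(nominal).  The
    scale comes from the total log-width of the interval:

        sigma = (ln ci_high - ln ci_low) / (2 z),   z = Phi^-1((1+level)/2).

    For a CI that is log-symmetric about the nominal this reproduces the
    stated interval exactly; an asymmetric CI is re-centred around the
    nominal (log-symmetrised) and a warning reports the discrepancy.
    """
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    if ci_low <= 0 or nominal <= 0:
        raise ValueError("nominal and CI bounds must be positive")
    if ci_low >= ci_high:
        raise ValueError(f"degenerate interval for {name!r}: "
                         f"[{ci_low}, {ci_high}]")
    if not (ci_low <= nominal <= ci_high):
        raise ValueError(f"nominal {nominal} outside CI [{ci_low}, {ci_high}]")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    sigma = (np.log(ci_high) - np.log(ci_low)) / (2.0 * z)
    mu = np.log(nominal)
    # asymmetry check: geometric mid-point of the CI vs the nominal
    log_mid = 0.5 * (np.log(ci_low) + np.log(ci_high))
    if abs(log_mid - mu) > 1e-9:
        warnings.warn(
            f"prior for {name!r}: CI [{ci_low}, {ci_high}] is not "
            f"log-symmetric about nominal {nominal}; the implied interval "
            f"is re-centred (geometric midpoint {np.exp(log_mid):.4g})",
            stacklevel=2)
    return PriorEntry(name=name, mu=float(mu), sigma=float(sigma))


def load_prior_table(path) -> pd.DataFrame:
    """Read a prior table CSV: columns name, nominal, ci_low, ci_high[, level]."""
    return pd.read_csv(path)


def prior_from_table(table: pd.DataFrame, default_level: float = 0.95
                     ) -> PriorSpec:
    """Build a :class:`PriorSpec` from a nominal/CI table."""
    entries = []
    for row in table.itertuples(index=False):
        level = getattr(row, "level", None)
        if level is None or pd.isna(level):
            level = default_level
        entries.append(build_lognormal_prior(
            row.name, float(row.nominal), float(row.ci_low),
            float(row.ci_high), float(level)))
    return PriorSpec(entries=tuple(entries))


def scale_prior(priors: PriorSpec, factor: float) -> PriorSpec:
    """Multiply every sigma by ``factor``; medians are unchanged."""
    if factor <= 0:
        raise ValueError("scale factor must be > 0")
    return replace(priors, scale_factor=priors.scale_factor * factor)


def sample_priors(priors: PriorSpec, n: int, seed) -> pd.DataFrame:
    """n i.i.d. draws from the joint prior; one column per parameter."""
    if n < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(priors.entries)))
    samples = np.exp(priors.mus + priors.sigmas * z)
    return pd.DataFrame(samples, columns=priors.names)
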