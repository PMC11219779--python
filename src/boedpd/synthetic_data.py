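"""Simulated experiments: the bundled fixture model and noisy measurements.

In the absence of laboratory data, candidate experiments are emulated by
running the forward model at a generating parameter vector theta_true and
observing a single species at the final time t = tau, corrupted with
Gaussian noise whose standard deviation is a fixed fraction (default 10%)
of the model prediction.  An ensemble of replicates per candidate species
stands in for the distribution of data a lab *could* produce, which is what
the design ranking marginalises over.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .model_core import ReactionNetworkModel, final_concentration, load_model
from .priors import PriorSpec, load_prior_table, prior_from_table

__all__ = ["Measurement", "Dataset", "reduced_apoptosis_model",
           "reduced_apoptosis_priors", "simulate_measurements"]

#: replicate count emulating a full measurement campaign
DEFAULT_N_REPLICATES = 100
#: relative measurement error: noise sd = 10% of the model prediction
DEFAULT_REL_ERR = 0.10
#: generating IC50 for calibration datasets (mid-grid; the switch region
#: is where a final-time observation is most informative)
DEFAULT_U_NOMINAL = 1.0


@dataclass(frozen=True)
class Measurement:
    """One simulated observation of species ``design`` at t = tau."""
    design: str
    u: float
    y_obs: float
    noise_sd: float

    def __post_init__(self):
        if not np.isfinite(self.y_obs):
            raise ValueError("observation must be finite")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(frozen=True)
class Dataset:
    """Replicated measurements of one candidate design xi."""
    design: str
    measurements: tuple[Measurement, ...]
    theta_true: dict[str, float]
    seed: int

    def __post_init__(self):
        if len(self.measurements) < 1:
            raise ValueError("a dataset needs at least one measurement")
        if any(m.design != self.design for m in self.measurements):
            raise ValueError("all measurements must share the dataset design")

    def __len__(self) -> int:
        return len(self.measurements)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "design": [m.design for m in self.measurements],
            "u": [m.u for m in self.measurements],
            "replicate": np.arange(len(self.measurements)),
            "y_obs": [m.y_obs for m in self.measurements],
            "noise_sd": [m.noise_sd for m in self.measurements],
            "seed": self.seed,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def reduced_apoptosis_model() -> ReactionNetworkModel:
    """The bundled reduced PARP1-apoptosis network (synthetic stand-in).

    10 species, 11 uncertain rate constants, 5 measurable species
    (the candidate designs), apoptosis species Casp_act with threshold
    1000 molecules/cell.  Calibrated so that at nominal parameters the
    cell dies at IC50 <= 0.001 and survives at IC50 >= 100.
    """
    ref = resources.files("boedpd").joinpath("data/reduced_apoptosis.yaml")
    with resources.as_file(ref) as path:
        return load_model(path)


def reduced_apoptosis_priors() -> PriorSpec:
    """Log-normal priors for the fixture's 11 uncertain rate constants.

    Nominal values are the fixture's rates; each 95% CI spans a factor of
    5 either side of nominal, giving sigma = ln(25)/(2 * 1.96) ~ 0.82 on
    the log scale — order-of-magnitude uncertainty, as is typical for
    literature-elicited kinetic constants.
    """
    ref = resources.files("boedpd").joinpath(
        "data/reduced_apoptosis_priors.csv")
    with resources.as_file(ref) as path:
        return prior_from_table(load_prior_table(path))


def simulate_measurements(model: ReactionNetworkModel,
                          theta_true: dict[str, float],
                          design: str,
                          u: float = DEFAULT_U_NOMINAL,
                          n: int = DEFAULT_N_REPLICATES,
                          rel_err: float = DEFAULT_REL_ERR,
                          seed: int = 0) -> Dataset:
    """Draw n replicate observations y_obs ~ Normal(y_hat, rel_err * y_hat).

    ``y_hat`` is the model prediction of ``design`` at t = tau under
    (theta_true, u).  The generating noise sd is recorded on each
    measurement so the likelihood can score it consistently.  Negative
    draws are kept: the Gaussian error model is applied honestly and the
    likelihood handles them.
    """
    if design not in model.measurable_species:
        raise ValueError(
            f"{design!r} is not a measurable species; candidates: "
            f"{', '.join(model.measurable_species)}")
    if n < 1:
        raise ValueError("need at least one replicate")
    if rel_err < 0:
        raise ValueError("rel_err must be >= 0")
    y_hat = final_concentration(model, theta_true, u, design)
    if y_hat <= 0 and rel_err > 0:
        raise ValueError(
            f"prediction for {design!r} at u={u} is {y_hat:.3g}; "
            "the relative-error noise scale is degenerate")
    rng = np.random.default_rng(seed)
    if rel_err == 0:
        y = np.full(n, y_hat)
        sd = np.finfo(float).tiny   # Measurement requires a positive sd
    else:
        sd = rel_err * y_hat
        y = rng.normal(y_hat, sd, size=n)
    ms = tuple(Measurement(design=design, u=float(u), y_obs=float(v),
                           noise_sd=float(sd)) for v in y)
    return Dataset(design=design, measurements=ms,
                   theta_true=dict(theta_true), seed=int(seed))
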