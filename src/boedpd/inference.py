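"""Posterior inference for one simulated measurement.

The likelihood of a final-time observation y_obs of the measured species is

    y_obs | theta  ~  Normal( y_hat(theta),  r * y_hat(theta) ),

with r the relative measurement error (default 10%).  Because the noise
scale follows the prediction, the Gaussian normalisation term varies with
theta and is kept.  Sampling runs in whitened log-parameter space
x = (ln theta - mu) / sigma, where the log-normal prior (including its
Jacobian) is exactly a standard normal — Hamiltonian Monte Carlo with an
identity mass matrix then sees unit prior scale in every direction.
Gradients of y_hat come from the forward-sensitivity ODE system.

Biological constraints (the cell must die at a potent dose and live at an
impotent one) are enforced by *post-hoc filtering* of the chains rather
than inside the sampler, mirroring the study workflow: samples whose
forward simulation violates either boundary are removed and the retained
fraction is reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._compile import IntegrationError
from .model_core import (ReactionNetworkModel, caspase_peak,
                         final_concentration,
                         final_concentration_and_sensitivity)
from .priors import PriorSpec
from .synthetic_data import Measurement

__all__ = ["HMCSettings", "RawChain", "PosteriorChain", "log_likelihood",
           "log_likelihood_and_grad", "log_posterior", "run_mcmc",
           "infer_posterior", "filter_chain_by_constraints",
           "effective_sample_size", "most_sensitive_parameter"]

logger = logging.getLogger(__name__)

#: relative measurement error used in the likelihood noise scale
LIKELIHOOD_REL_ERR = 0.10
#: Eq.-style constraint boundaries: the cell must live at u >= U_LIVE and
#: die at u <= U_DIE
U_LIVE = 100.0
U_DIE = 0.001


# ---------------------------------------------------------------------------
# likelihood / posterior densities
# ---------------------------------------------------------------------------

def _gauss_ll(y_obs: float, y_hat: float, rel_err: float) -> float:
    sd = rel_err * y_hat
    if not np.isfinite(y_hat) or sd <= 0:
        return -np.inf
    with np.errstate(over="ignore"):
        z = np.float64(y_obs - y_hat) / sd
        ll = -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * z * z
    return float(ll) if np.isfinite(ll) else -np.inf


def log_likelihood(theta, measurement: Measurement,
                   model: ReactionNetworkModel,
                   rel_err: float = LIKELIHOOD_REL_ERR) -> float:
    """ln Normal(y_obs; y_hat(theta), rel_err * y_hat(theta)).

    Integration failures contribute -inf (the region is rejected) with a
    logged warning, never silent NaNs.
    """
    try:
        y_hat = final_concentration(model, theta, measurement.u,
                                    measurement.design)
    except IntegrationError as err:
        logger.warning("integration failure in likelihood: %s", err)
        return -np.inf
    return _gauss_ll(measurement.y_obs, y_hat, rel_err)


def log_likelihood_and_grad(theta, measurement: Measurement,
                            model: ReactionNetworkModel,
                            rel_err: float = LIKELIHOOD_REL_ERR):
    """(log-likelihood, gradient w.r.t. theta) via forward sensitivities."""
    try:
        y_hat, dy = final_concentration_and_sensitivity(
            model, theta, measurement.u, measurement.design)
    except IntegrationError as err:
        logger.warning("integration failure in likelihood: %s", err)
        return -np.inf, None
    ll = _gauss_ll(measurement.y_obs, y_hat, rel_err)
    if not np.isfinite(ll):
        return -np.inf, None
    y = np.float64(measurement.y_obs)
    y_hat = np.float64(y_hat)
    # d/dy_hat of [-ln(r y_hat) - (y - y_hat)^2 / (2 r^2 y_hat^2)]
    with np.errstate(over="ignore"):
        dll_dyhat = -1.0 / y_hat + (y - y_hat) * y / (rel_err ** 2 * y_hat ** 3)
    grad = dll_dyhat * dy
    if not np.all(np.isfinite(grad)):
        return -np.inf, None
    return ll, grad


def log_posterior(theta, measurement: Measurement,
                  model: ReactionNetworkModel, priors: PriorSpec,
                  rel_err: float = LIKELIHOOD_REL_ERR) -> float:
    """Unnormalised log posterior: log-normal prior + Gaussian likelihood."""
    lp = priors.log_density(np.asarray(
        [theta[k] for k in priors.names] if isinstance(theta, dict) else theta))
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(theta, measurement, model, rel_err)


# ---------------------------------------------------------------------------
# Hamiltonian Monte Carlo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HMCSettings:
    """Sampler knobs.

    warmup_frac      extra warm-up iterations as a fraction of the chain
                     length; warm-up is discarded.
    target_accept    dual-averaging acceptance target.
    max_leapfrog     leapfrog path lengths are jittered uniformly on
                     [1, max_leapfrog] to avoid resonances.
    init_step        initial leapfrog step size.
    divergence_dH    energy error above which a transition is recorded as
                     divergent (and rejected).
    """
    warmup_frac: float = 0.2
    target_accept: float = 0.8
    max_leapfrog: int = 10
    init_step: float = 0.1
    divergence_dH: float = 1000.0
    adapt_mass: bool = True


@dataclass
class RawChain:
    """Posterior draws from :func:`run_mcmc` in the target's own space."""
    samples: np.ndarray          # (n_samples, dim)
    log_density: np.ndarray
    accept_rate: float
    divergences: int
    step_size: float
    seed: int


class _DualAveraging:
    """Nesterov dual averaging of the log step size (Hoffman & Gelman)."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, alpha: float) -> float:
        self.count += 1
        frac = 1.0 / (self.count + 10.0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - alpha)
        self.log_eps = self.mu - np.sqrt(self.count) / 0.05 * self.h_bar
        w = self.count ** -0.75
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def run_mcmc(target, init, n_samples: int, seed: int,
             settings: HMCSettings = HMCSettings()) -> RawChain:
    """HMC with step-size and (dense) mass-matrix adaptation.

    ``target(x)`` must return ``(log_density, gradient)`` for an
    unconstrained vector x.  Warm-up is discarded: its first half adapts
    the step size under an identity metric, then the warm-up sample
    covariance (shrunk toward a small multiple of the identity) becomes a
    dense metric via its Cholesky factor and the step size is re-tuned.
    Leapfrog path lengths are jittered uniformly on [1, max_leapfrog].
    Divergent transitions (energy error beyond ``divergence_dH`` or a
    non-finite trajectory) are rejected and counted.
    """
    x = np.asarray(init, dtype=float).copy()
    dim = x.size
    lp, grad = target(x)
    if not np.isfinite(lp):
        raise ValueError("target log-density is not finite at the initial "
                         f"point {x}")
    rng = np.random.default_rng(seed)
    n_warm = max(1, int(round(settings.warmup_frac * n_samples)))

    # preconditioner: x = A xi; HMC runs with identity mass in xi-space
    A = np.eye(dim)
    xi = x.copy()
    g_xi = grad.copy()          # A^T grad, with A = I initially

    eps = settings.init_step
    da = _DualAveraging(eps, settings.target_accept)
    mass_switch = n_warm // 2 if (settings.adapt_mass and n_warm >= 60) else -1
    warm_hist = np.empty((mass_switch, dim)) if mass_switch > 0 else None

    samples = np.empty((n_samples, dim))
    logdens = np.empty(n_samples)
    n_accept = n_div = n_warm_accept = 0

    for it in range(n_warm + n_samples):
        p = rng.standard_normal(dim)
        h0 = -lp + 0.5 * p @ p
        xin, lpn, gn, pn = xi, lp, g_xi, p
        n_leap = int(rng.integers(1, settings.max_leapfrog + 1))
        diverged = False
        pn = pn + 0.5 * eps * gn
        for step in range(n_leap):
            xin = xin + eps * pn
            lpn, g = target(A @ xin)
            if not np.isfinite(lpn) or g is None \
                    or not np.all(np.isfinite(g)):
                diverged = True
                break
            gn = A.T @ g
            pn = pn + (eps if step < n_leap - 1 else 0.5 * eps) * gn
        if diverged:
            alpha = 0.0
        else:
            d_h = (-lpn + 0.5 * pn @ pn) - h0
            if not np.isfinite(d_h) or d_h > settings.divergence_dH:
                diverged, alpha = True, 0.0
            else:
                alpha = min(1.0, float(np.exp(-d_h)))
        if alpha > 0 and rng.random() < alpha:
            xi, lp, g_xi = xin, lpn, gn
            accepted = True
        else:
            accepted = False

        if it < n_warm:
            n_warm_accept += accepted
            eps = da.update(alpha)
            if warm_hist is not None and it < mass_switch:
                warm_hist[it] = A @ xi
                if it == mass_switch - 1:
                    # dense metric from the identity-phase samples,
                    # shrunk toward a scaled identity (Stan's recipe)
                    tail = warm_hist[mass_switch // 4:]
                    k = len(tail)
                    cov = np.cov(tail, rowvar=False)
                    cov = (k / (k + 5.0)) * cov \
                        + 1e-3 * (5.0 / (k + 5.0)) * np.eye(dim)
                    try:
                        A = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        A = np.eye(dim)
                    xi = np.linalg.solve(A, warm_hist[it])
                    lp, g = target(A @ xi)
                    g_xi = A.T @ g
                    eps = settings.init_step
                    da = _DualAveraging(eps, settings.target_accept)
            if it == n_warm - 1:
                if n_warm_accept == 0:
                    raise RuntimeError(
                        "all warm-up transitions were rejected; the target "
                        "may be ill-conditioned or the initial step too "
                        "large")
                eps = da.adapted
        else:
            j = it - n_warm
            samples[j] = A @ xi
            logdens[j] = lp
            n_accept += accepted
            n_div += diverged

    if n_div:
        logger.info("HMC: %d divergent transitions out of %d kept draws",
                    n_div, n_samples)
    return RawChain(samples=samples, log_density=logdens,
                    accept_rate=n_accept / n_samples,
                    divergences=n_div, step_size=eps, seed=int(seed))


# ---------------------------------------------------------------------------
# posterior chains over model parameters
# ---------------------------------------------------------------------------

@dataclass
class PosteriorChain:
    """Positive-parameter draws with filtering and diagnostic bookkeeping."""
    samples: pd.DataFrame        # rows = iterations, cols = parameters (> 0)
    log_density: np.ndarray
    measurement_id: str
    seed: int
    divergences: int = 0
    step_size: float = np.nan
    retained_fraction: float = 1.0
    n_prefilter: int | None = None

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def is_empty(self) -> bool:
        """True when constraint filtering left no feasible samples."""
        return len(self.samples) == 0

    @property
    def names(self) -> list[str]:
        return list(self.samples.columns)

    def ess(self) -> pd.Series:
        return effective_sample_size(self)

    def diagnostics(self) -> dict:
        out = {
            "measurement_id": self.measurement_id,
            "seed": self.seed,
            "n_samples": len(self),
            "divergences": self.divergences,
            "step_size": self.step_size,
            "retained_fraction": self.retained_fraction,
        }
        if len(self) >= 10:
            out["ess"] = {k: (float(v) if np.isfinite(v) else None)
                          for k, v in self.ess().items()}
        return out


def infer_posterior(measurement: Measurement, model: ReactionNetworkModel,
                    priors: PriorSpec, n_samples: int = 2000, seed: int = 0,
                    settings: HMCSettings = HMCSettings(),
                    rel_err: float = LIKELIHOOD_REL_ERR) -> PosteriorChain:
    """Sample p(theta | y_obs, design, u) with HMC in whitened log space."""
    if priors.names != model.uncertain_names:
        raise ValueError("prior entries must match the model's "
                         "uncertain_names (same order)")
    mus, sigmas = priors.mus, priors.sigmas
    names = priors.names

    def target(x):
        # 8-sigma box in whitened space: beyond it the prior mass is
        # negligible (< 1e-15) but the ODE system turns pathologically
        # stiff; rejecting outright keeps the sampler out of dead regions
        if np.max(np.abs(x)) > 8.0:
            return -np.inf, None
        theta = np.exp(mus + sigmas * x)
        ll, gll = log_likelihood_and_grad(
            dict(zip(names, theta)), measurement, model, rel_err)
        if not np.isfinite(ll):
            return -np.inf, None
        # standard-normal prior in x absorbs the log-normal Jacobian
        return ll - 0.5 * x @ x, gll * theta * sigmas - x

    raw = run_mcmc(target, np.zeros(len(names)), n_samples, seed, settings)
    theta = np.exp(mus + sigmas * raw.samples)
    return PosteriorChain(
        samples=pd.DataFrame(theta, columns=names),
        log_density=raw.log_density,
        measurement_id=f"{measurement.design}@u={measurement.u:g}#{seed}",
        seed=int(seed), divergences=raw.divergences,
        step_size=raw.step_size)


def filter_chain_by_constraints(chain: PosteriorChain,
                                model: ReactionNetworkModel,
                                u_live: float = U_LIVE,
                                u_die: float = U_DIE) -> PosteriorChain:
    """Drop samples violating the dose-boundary constraints.

    A draw theta is feasible iff the forward model predicts *no* apoptosis
    at the impotent dose u_live and apoptosis at the potent dose u_die.
    Forward solves are deduplicated across repeated rows (MCMC rejections).
    An empty result is returned as an empty chain (``is_empty``), not an
    exception, so ensemble pipelines can skip the replicate.
    """
    if chain.is_empty:
        return chain
    thetas = chain.samples.to_numpy()
    feasible_cache: dict[bytes, bool] = {}
    keep = np.zeros(len(thetas), dtype=bool)
    thr = model.apoptosis_threshold
    names = chain.names
    for i, row in enumerate(thetas):
        key = row.tobytes()
        ok = feasible_cache.get(key)
        if ok is None:
            theta = dict(zip(names, row))
            try:
                ok = (caspase_peak(model, theta, u_live) < thr
                      and caspase_peak(model, theta, u_die) >= thr)
            except IntegrationError:
                ok = False       # unintegrable draws cannot be certified
            feasible_cache[key] = ok
        keep[i] = ok
    frac = float(keep.mean())
    if frac == 0.0:
        logger.warning("constraint filtering removed every sample of %s",
                       chain.measurement_id)
    n_pre = chain.n_prefilter if chain.n_prefilter is not None else len(chain)
    return replace(
        chain,
        samples=chain.samples.loc[keep].reset_index(drop=True),
        log_density=chain.log_density[keep],
        retained_fraction=chain.retained_fraction * frac,
        n_prefilter=n_pre)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _ess_1d(x: np.ndarray) -> float:
    n = x.size
    x = x - x.mean()
    var = x @ x / n
    if var == 0:
        return np.nan
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # Geyer initial positive sequence: sum paired autocorrelations until
    # the first negative pair
    tau = -1.0
    for k in range(0, n - 1, 2):
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
    tau = max(tau, 1.0 / n)
    return float(min(n / tau, n))


def effective_sample_size(chain) -> pd.Series:
    """Autocorrelation-based ESS per parameter (initial-positive-sequence).

    Accepts a :class:`PosteriorChain`, DataFrame or 2-D array.  Constant
    columns have undefined autocorrelation time and come back as NaN with
    a warning.
    """
    if isinstance(chain, PosteriorChain):
        df = chain.samples
    elif isinstance(chain, pd.DataFrame):
        df = chain
    else:
        a = np.atleast_2d(np.asarray(chain, dtype=float))
        if a.shape[0] == 1:
            a = a.T
        df = pd.DataFrame(a)
    if len(df) < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    out = {}
    for col in df.columns:
        v = _ess_1d(df[col].to_numpy(dtype=float))
        if np.isnan(v):
            warnings.warn(f"ESS undefined for constant column {col!r}",
                          stacklevel=2)
        out[col] = v
    return pd.Series(out, name="ess")


def most_sensitive_parameter(model: ReactionNetworkModel, priors: PriorSpec,
                             design: str, u: float) -> str:
    """Prior-based one-at-a-time sensitivity of the design's prediction.

    Each parameter is moved one prior sigma either side of its median
    (others held at their medians); the parameter with the largest
    absolute change in the final-time prediction wins.
    """
    med = priors.medians()
    best, best_delta = None, -1.0
    for name, mu, sig in zip(priors.names, priors.mus, priors.sigmas):
        hi = dict(med)
        hi[name] = float(np.exp(mu + sig))
        lo = dict(med)
        lo[name] = float(np.exp(mu - sig))
        delta = abs(final_concentration(model, hi, u, design)
                    - final_concentration(model, lo, u, design))
        if delta > best_delta:
            best, best_delta = name, delta
    return best
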