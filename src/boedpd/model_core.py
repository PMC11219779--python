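"""Reaction-network ODE models with an IC50 control input.

The pharmacodynamic model is the coupled system

    dy/dt = f(y; u, kappa),    y(t0) = y0,

where y are species concentrations (molecules per cell), kappa the kinetic
rate constants, and the control u is the inhibitor's half-maximal inhibitory
concentration (IC50).  A subset of kappa, named in ``uncertain_names``, forms
the uncertain parameter vector theta that inference targets.  Apoptosis is
declared triggered when the activated-caspase species peaks at or above a
molecule-count threshold (default 1000) anywhere on the integration horizon.

Models are declared in YAML (species, parameters, reactions with rate-law
expressions that may reference the symbol ``IC50``, observables, ``tau``) and
compiled to numba machine code on first use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp
import yaml

from ._compile import CompiledModel, IntegrationError

__all__ = [
    "SpeciesSpec", "ReactionNetworkModel", "Trajectory", "IntegrationError",
    "load_model", "integrate_model", "max_species_concentration",
    "apoptosis_triggered",
]

#: minimum number of output-grid points used for the running maximum
#: y_k^max; a coarse unit-spaced grid can miss the caspase peak
DEFAULT_GRID_POINTS = 500


@dataclass(frozen=True)
class SpeciesSpec:
    """One chemical species: name, initial concentration, design-set flag."""
    name: str
    y0: float
    measurable: bool = False

    def __post_init__(self):
        if self.y0 < 0:
            raise ValueError(f"initial concentration of {self.name!r} "
                             f"must be non-negative, got {self.y0}")


@dataclass
class ReactionNetworkModel:
    """An ODE reaction network driven by an IC50 control.

    ``reactions`` is a list of ``(rate_expression, stoichiometry)`` pairs;
    the rate expression is a string over species names, parameter names and
    the symbol ``IC50``, and the stoichiometry maps species name -> signed
    coefficient.  dy_i/dt is the stoichiometry-weighted sum of rates.
    """
    name: str
    species: list[SpeciesSpec]
    rate_params: dict[str, float]
    uncertain_names: list[str]
    reactions: list[tuple[str, dict[str, float]]]
    tau: float
    apoptosis_species: str
    apoptosis_threshold: float = 1000.0
    t0: float = 0.0
    rtol: float = 1e-6
    atol: float = 1e-9
    grid_points: int = DEFAULT_GRID_POINTS
    _backend: CompiledModel | None = field(default=None, repr=False,
                                           compare=False)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        if self.tau <= self.t0:
            raise ValueError("tau must exceed t0")
        if self.apoptosis_species not in names:
            raise ValueError(f"apoptosis_species {self.apoptosis_species!r} "
                             "is not a model species")
        unknown = set(self.uncertain_names) - set(self.rate_params)
        if unknown:
            raise ValueError(f"uncertain_names not in rate_params: {unknown}")
        for k, v in self.rate_params.items():
            if v < 0:
                raise ValueError(f"rate parameter {k!r} must be >= 0, got {v}")

    # -- structure -------------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def measurable_species(self) -> list[str]:
        """The candidate experimental designs xi in Xi."""
        return [s.name for s in self.species if s.measurable]

    @property
    def y0(self) -> np.ndarray:
        return np.array([s.y0 for s in self.species], dtype=float)

    @property
    def param_names(self) -> list[str]:
        return list(self.rate_params)

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown species {name!r}; valid choices: "
                f"{', '.join(self.species_names)}") from None

    def param_vector(self, theta: dict[str, float] | None = None) -> np.ndarray:
        """Full kappa vector with theta overriding the uncertain entries."""
        p = np.array([self.rate_params[k] for k in self.param_names])
        if theta is not None:
            missing = set(self.uncertain_names) - set(theta)
            if missing:
                raise ValueError(f"theta missing entries: {sorted(missing)}")
            for i, k in enumerate(self.param_names):
                if k in self.uncertain_names:
                    v = float(theta[k])
                    if v < 0:
                        raise ValueError(f"theta[{k!r}] must be >= 0")
                    p[i] = v
        return p

    def theta_array(self, theta: dict[str, float]) -> np.ndarray:
        return np.array([float(theta[k]) for k in self.uncertain_names])

    def nominal_theta(self) -> dict[str, float]:
        return {k: self.rate_params[k] for k in self.uncertain_names}

    # -- compilation -----------------------------------------------------

    @property
    def backend(self) -> CompiledModel:
        if self._backend is None:
            self._backend = self._compile()
        return self._backend

    def _compile(self) -> CompiledModel:
        ysyms = {n: sp.Symbol(n) for n in self.species_names}
        psyms = {n: sp.Symbol(n) for n in self.param_names}
        usym = sp.Symbol("IC50")
        local = {**ysyms, **psyms, "IC50": usym}
        f = {n: sp.Integer(0) for n in self.species_names}
        for rate_str, stoich in self.reactions:
            expr = sp.parse_expr(rate_str, local_dict=local, evaluate=True)
            extra = expr.free_symbols - set(local.values())
            if extra:
                raise ValueError(
                    f"rate law {rate_str!r} references unknown symbols "
                    f"{sorted(map(str, extra))}")
            for sp_name, coeff in stoich.items():
                if sp_name not in f:
                    raise KeyError(f"stoichiometry references unknown "
                                   f"species {sp_name!r}")
                f[sp_name] = f[sp_name] + coeff * expr
        f_exprs = [f[n] for n in self.species_names]
        uncertain_idx = [self.param_names.index(k) for k in self.uncertain_names]
        return CompiledModel(
            f_exprs,
            [ysyms[n] for n in self.species_names],
            [psyms[n] for n in self.param_names],
            usym, uncertain_idx, rtol=self.rtol, atol=self.atol)

    def default_grid(self) -> np.ndarray:
        return np.linspace(self.t0, self.tau, self.grid_points)


@dataclass(frozen=True)
class Trajectory:
    """Solution of the ODE system on an output time grid."""
    t: np.ndarray
    y: np.ndarray            # (len(t), n_species)
    species_names: tuple[str, ...]

    def __getitem__(self, species: str) -> np.ndarray:
        try:
            j = self.species_names.index(species)
        except ValueError:
            raise KeyError(
                f"unknown species {species!r}; valid choices: "
                f"{', '.join(self.species_names)}") from None
        return self.y[:, j]


def integrate_model(model: ReactionNetworkModel,
                    theta: dict[str, float] | None = None,
                    u: float = 1.0,
                    t_grid: np.ndarray | None = None) -> Trajectory:
    """Integrate dy/dt = f(y; u, kappa) with theta overriding kappa.

    Uses LSODA (adaptive, stiff-capable) with an analytic Jacobian at the
    model's configured tolerances.  Small negative excursions within the
    integrator's absolute tolerance are clipped to zero; larger negatives
    indicate a mis-specified model and raise :class:`IntegrationError`.
    """
    if u < 0:
        raise ValueError("IC50 control u must be non-negative")
    if t_grid is None:
        t_grid = model.default_grid()
    else:
        t_grid = np.asarray(t_grid, dtype=float)
        if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing, length >= 2")
        if t_grid[0] < model.t0 - 1e-12 or t_grid[-1] > model.tau + 1e-12:
            raise ValueError("t_grid must lie within [t0, tau]")
        if abs(t_grid[0] - model.t0) > 1e-12:
            raise ValueError("t_grid must start at the model's t0")
    p = model.param_vector(theta)
    y = model.backend.solve(model.y0, p, u, t_grid)
    neg_tol = 10.0 * model.atol
    worst = y.min()
    if worst < -neg_tol:
        raise IntegrationError(
            f"negative concentration {worst:.3g} beyond round-off tolerance",
            theta=theta, u=u)
    y = np.clip(y, 0.0, None)
    return Trajectory(t=t_grid, y=y, species_names=tuple(model.species_names))


def max_species_concentration(traj: Trajectory, species: str) -> float:
    """Running maximum y_k^max of one species over the output grid."""
    return float(traj[species].max())


def apoptosis_triggered(traj: Trajectory, model: ReactionNetworkModel) -> bool:
    """True iff the activated-caspase peak reaches the threshold (inclusive)."""
    peak = max_species_concentration(traj, model.apoptosis_species)
    return peak >= model.apoptosis_threshold


# -- fast scalar observables used by the likelihood and the filters --------

def final_concentration(model: ReactionNetworkModel, theta, u: float,
                        species: str) -> float:
    """Model prediction y_hat of one species at t = tau (two-point solve)."""
    j = model.species_index(species)
    p = model.param_vector(theta)
    yf = model.backend.solve_final(model.y0, p, u, model.t0, model.tau)
    return float(yf[j])


def final_concentration_and_sensitivity(model: ReactionNetworkModel, theta,
                                        u: float, species: str):
    """(y_hat, d y_hat / d theta) via the forward-sensitivity system."""
    j = model.species_index(species)
    p = model.param_vector(theta)
    yf, S = model.backend.solve_final_sens(model.y0, p, u, model.t0, model.tau)
    return float(yf[j]), S[j].copy()


def caspase_peak(model: ReactionNetworkModel, theta, u: float,
                 use_cache: bool = True) -> float:
    """y_Casp^max at (theta, u), memoised on the compiled backend.

    The same (theta, u) pair is evaluated repeatedly by constraint filtering
    and by every point of a lethality curve built from an MCMC chain (where
    rejected proposals duplicate rows), so forward solves are deduplicated.
    """
    p = model.param_vector(theta)
    key = (p.tobytes(), float(u), model.grid_points)
    cache = model.backend._cache
    if use_cache and key in cache:
        return cache[key]
    y = model.backend.solve(model.y0, p, u, model.default_grid())
    peak = float(y[:, model.species_index(model.apoptosis_species)].max())
    if use_cache:
        if len(cache) > 400_000:     # ~100 MB worst case; drop oldest half
            for k in list(cache)[:200_000]:
                del cache[k]
        cache[key] = peak
    return peak


# -- YAML model definition -------------------------------------------------

def load_model(path) -> ReactionNetworkModel:
    """Load a model definition from its YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return model_from_dict(doc)


def model_from_dict(doc: dict) -> ReactionNetworkModel:
    species = [SpeciesSpec(name=s["name"], y0=float(s["y0"]),
                           measurable=bool(s.get("measurable", False)))
               for s in doc["species"]]
    params = {p["name"]: float(p["value"]) for p in doc["parameters"]}
    uncertain = [p["name"] for p in doc["parameters"] if p.get("uncertain")]
    reactions = [(r["rate"], {k: float(v) for k, v in r["stoichiometry"].items()})
                 for r in doc["reactions"]]
    obs = doc.get("observables", {})
    return ReactionNetworkModel(
        name=doc.get("name", "model"),
        species=species,
        rate_params=params,
        uncertain_names=uncertain,
        reactions=reactions,
        tau=float(doc["tau"]),
        apoptosis_species=obs["apoptosis_species"],
        apoptosis_threshold=float(obs.get("apoptosis_threshold", 1000.0)),
        t0=float(doc.get("t0", 0.0)),
        rtol=float(doc.get("rtol", 1e-6)),
        atol=float(doc.get("atol", 1e-9)),
        grid_points=int(doc.get("grid_points", DEFAULT_GRID_POINTS)),
    )
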