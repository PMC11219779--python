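import numpy as np
import pytest

from boedpd import reduced_apoptosis_model, reduced_apoptosis_priors
from boedpd.model_core import ReactionNetworkModel, SpeciesSpec


@pytest.fixture(scope="session")
def model():
    """Bundled reduced apoptosis network, compiled once per session."""
    m = reduced_apoptosis_model()
    m.backend  # trigger JIT compilation here, not inside a timed test
    return m


@pytest.fixture(scope="session")
def priors():
    return reduced_apoptosis_priors()


def make_model(species, params, reactions, tau=1.0, apoptosis_species=None,
               threshold=1000.0, **kw) -> ReactionNetworkModel:
    """Small inline models for closed-form checks."""
    specs = [SpeciesSpec(name=n, y0=float(v), measurable=True)
             for n, v in species.items()]
    return ReactionNetworkModel(
        name="test",
        species=specs,
        rate_params={k: float(v) for k, v, _ in params},
        uncertain_names=[k for k, _, unc in params if unc],
        reactions=reactions,
        tau=tau,
        apoptosis_species=apoptosis_species or specs[0].name,
        apoptosis_threshold=threshold,
        **kw)


@pytest.fixture(scope="session")
def decay_model():
    """dA/dt = -k A with uncertain k: closed form A(t) = A0 exp(-k t)."""
    m = make_model({"A": 1.0}, [("k", 1.0, True)],
                   [("k * A", {"A": -1})], tau=1.0)
    m.backend
    return m


@pytest.fixture(scope="session")
def production_model():
    """dC/dt = k with uncertain k: peak C(tau) = k * tau, exactly linear.

    Lets a test dial the caspase peak to any value through theta.
    """
    m = make_model({"Casp": 0.0}, [("k", 1.0, True)],
                   [("k", {"Casp": 1})], tau=1.0, threshold=1000.0)
    m.backend
    return m


@pytest.fixture(scope="session")
def feasible_theta(model):
    """Nominal rates: triggers apoptosis at u=0.001, not at u=100."""
    return model.nominal_theta()


@pytest.fixture(scope="session")
def infeasible_theta(model):
    """Caspase activation shut down: never triggers apoptosis anywhere."""
    theta = model.nominal_theta()
    theta["k_act"] = 1e-8
    return theta


def as_chain(samples_df, seed=0, measurement_id="test@u=1#0"):
    """Wrap a parameter table as a PosteriorChain for filter/ensemble tests."""
    from boedpd.inference import PosteriorChain
    return PosteriorChain(samples=samples_df.reset_index(drop=True),
                          log_density=np.zeros(len(samples_df)),
                          measurement_id=measurement_id, seed=seed)
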