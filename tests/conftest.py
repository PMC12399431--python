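import warnings

import numpy as np
import pytest

import qm2ta as q

# cobra emits benign solver chatter on toy models
warnings.filterwarnings("ignore", category=UserWarning, module="cobra")


@pytest.fixture
def toy6():
    return q.make_toy6()


@pytest.fixture(scope="session")
def route_model():
    return q.make_route_model(6)


@pytest.fixture(scope="session")
def route_reference(route_model):
    """Reference flux for the 6-route model, computed once per session."""
    expr = {g.id: 10.0 for g in route_model.genes}
    cfg = q.ReferenceConfig(n_samples=200, thinning=10, seed=11)
    v_ref, restricted = q.compute_reference(route_model, expr, cfg)
    return v_ref, restricted


def rel_err(x, y, scale=1.0):
    return abs(x - y) / max(scale, abs(y))


@pytest.fixture
def random_diag_qp():
    """Factory for random diagonal QPs over random toy-model polytopes."""
    from qm2ta.model_core import model_bounds, stoichiometric_matrix
    from qm2ta.qp import DiagQP
    from qm2ta.synthetic import ToySpec

    def make(seed, n_reactions=8, curvature_floor=0.05):
        rng = np.random.default_rng(seed)
        model = q.make_random_model(
            ToySpec(seed=seed, n_reactions=n_reactions, n_internal_metabolites=3)
        )
        S = stoichiometric_matrix(model)
        lb, ub = model_bounds(model)
        n = len(lb)
        a = np.abs(rng.normal(1.0, 0.5, n)) + curvature_floor
        b = rng.normal(0.0, 3.0, n) * a
        return model, DiagQP(S, a, b, lb, ub)

    return make
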