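import numpy as np
import pytest

from methyloflux import build_methylotroph, load_core_model
from methyloflux.lp import FluxSolution, steady_state_residual
from methyloflux.synthetic import ToyNetworkSpec, generate_toy_network

TOY_KINDS = ("linear_chain", "branch", "futile_cycle", "carbon_loss")


@pytest.fixture(scope="session")
def core():
    return load_core_model()


@pytest.fixture(scope="session")
def methylotroph(core):
    return build_methylotroph(core, "ed_ta")


@pytest.fixture(params=TOY_KINDS)
def toy(request):
    return generate_toy_network(ToyNetworkSpec(kind=request.param))


def assert_solution_valid(model, solution: FluxSolution, tol: float = 1e-9):
    """Every optimal solution must satisfy S v = 0 and the bounds."""
    assert solution.optimal
    assert steady_state_residual(model, solution) <= tol
    for rid, v in solution.fluxes.items():
        rxn = model.reactions[rid]
        assert rxn.lower_bound - tol <= v <= rxn.upper_bound + tol
    total = sum(abs(v) for v in solution.fluxes.values())
    assert solution.total_abs_flux == pytest.approx(total, abs=1e-6)
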