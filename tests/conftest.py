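import pytest

from aggrecycles import ModelParams, find_limit_cycle
from aggrecycles.bifurcation import hopf_point


@pytest.fixture(scope="session")
def canonical() -> ModelParams:
    """The canonical oscillatory parameter set (r=K=d=1, lF=28, lS=16)."""
    return ModelParams()


@pytest.fixture(scope="session")
def sc_params(canonical) -> ModelParams:
    """Stable-coexistence counterpart at the same lambda_F."""
    return canonical.replace(lambda_S=10.0)


@pytest.fixture(scope="session")
def canonical_cycle(canonical):
    """Converged limit cycle at the canonical parameters (shared; ~0.5 s)."""
    summary = find_limit_cycle(canonical)
    assert summary.converged
    return summary


@pytest.fixture(scope="session")
def hopf_lambda_S(canonical) -> float:
    """Critical lambda_S of the oscillation onset at lambda_F = 28."""
    return hopf_point(canonical, "lambda_S", (7.0, 16.0))
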