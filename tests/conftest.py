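import numpy as np
import pytest

from micca import (
    Experiment,
    OdeModel,
    build_sensitivity_matrix,
    gene_expression_fixture,
    ikkk_fixture,
)


@pytest.fixture(scope="session")
def gene_fx():
    return gene_expression_fixture()


@pytest.fixture(scope="session")
def ikkk_fx():
    return ikkk_fixture()


@pytest.fixture(scope="session")
def gene_steady_S(gene_fx):
    """Log-scale sensitivity matrix of the steady-state protocol."""
    return build_sensitivity_matrix(
        gene_fx.model, [gene_fx.experiment("steady_state")], log_scale=True
    )


@pytest.fixture(scope="session")
def gene_decay_S(gene_fx):
    return build_sensitivity_matrix(
        gene_fx.model, [gene_fx.experiment("decay")], log_scale=True
    )


def make_decay_model(gamma: float = 0.7) -> OdeModel:
    """One-state linear decay dy/dt = -gamma * y, y(0) = 1 (closed form)."""
    return OdeModel(
        state_names=["y"],
        param_names=["gamma"],
        reference_params=np.array([gamma]),
        rhs=lambda t, y, th, u: np.array([-th[0] * y[0]]),
        initial_condition=lambda th: np.array([1.0]),
        jac_y=lambda t, y, th, u: np.array([[-th[0]]]),
        jac_theta=lambda t, y, th, u: np.array([[-y[0]]]),
        name="decay1",
    )


def matrix_from_columns(columns, param_names=None):
    """Build a SensitivityMatrix directly from explicit columns."""
    from micca import SensitivityMatrix

    values = np.column_stack([np.asarray(c, dtype=float) for c in columns])
    names = param_names or [f"p{i}" for i in range(values.shape[1])]
    return SensitivityMatrix(values, list(names), log_scale=True)
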