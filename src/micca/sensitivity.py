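"""Forward sensitivity analysis and the stacked sensitivity matrix.

The sensitivity of the solution to parameter ``theta_i`` is
``z_i(t) = dy(t)/dtheta_i``; it obeys the forward (variational) system

    dz_i/dt = (dF/dy) z_i + dF/dtheta_i,     z_i(0) = dy(0)/dtheta_i,

solved here jointly for all parameters as one augmented ODE of dimension
``k*(l+1)`` per experiment.  Evaluating ``z_i`` at the observed components and
times, dividing by the experiment's error scale sigma, and stacking the
per-experiment blocks row-wise gives the sensitivity matrix ``S`` whose Gram
matrix ``S^T S`` is the Fisher information under Gaussian observation noise.

With log-parametrisation (the default for identifiability work) column ``i``
is multiplied by the reference value ``theta_i*`` (chain rule for
``log theta_i``), so column norms bound *relative* estimation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    ATOL_DEFAULT,
    RTOL_DEFAULT,
    Experiment,
    OdeModel,
    SimulationError,
    Trajectory,
    simulate,
    extract_observations,
)

__all__ = [
    "SensitivityMatrix",
    "forward_sensitivities",
    "finite_difference_sensitivities",
    "build_sensitivity_matrix",
]


@dataclass
class SensitivityMatrix:
    """Stacked, sigma-scaled sensitivity matrix (R x l).

    Rows follow the documented observation order (experiments in the order
    given, time-major within each experiment); columns are parameters.
    ``row_labels`` carries ``(experiment, time, component)`` per row.
    """

    values: np.ndarray
    param_names: list[str]
    log_scale: bool
    row_labels: list[tuple[str, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.param_names):
            raise ValueError("column count must equal number of parameters")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sensitivity matrix contains non-finite entries")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_params(self) -> int:
        return self.values.shape[1]

    def param_index(self, name_or_idx) -> int:
        if isinstance(name_or_idx, str):
            return self.param_names.index(name_or_idx)
        return int(name_or_idx)

    def column(self, name_or_idx) -> np.ndarray:
        return self.values[:, self.param_index(name_or_idx)]

    def column_norms(self) -> np.ndarray:
        return np.linalg.norm(self.values, axis=0)

    def fim(self) -> np.ndarray:
        """Fisher information matrix ``S^T S``."""
        return self.values.T @ self.values

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.param_names)
        if self.row_labels:
            df.insert(
                0,
                "row",
                [f"{e}:t={t:g}:{c}" for e, t, c in self.row_labels],
            )
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, log_scale: bool = True) -> "SensitivityMatrix":
        df = pd.read_csv(path)
        labels: list[tuple[str, float, str]] = []
        if "row" in df.columns:
            for s in df.pop("row"):
                e, t, c = str(s).split(":", 2)
                labels.append((e, float(t.removeprefix("t=")), c))
        return cls(df.to_numpy(dtype=float), list(df.columns), log_scale, labels)

    def fim_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fim(), index=self.param_names, columns=self.param_names)


def _fd_jac_y(model, t, y, theta, u, h0=1e-7):
    k = y.size
    J = np.empty((k, k))
    for j in range(k):
        h = h0 * max(abs(y[j]), 1.0)
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (
            np.asarray(model.rhs(t, yp, theta, u)) - np.asarray(model.rhs(t, ym, theta, u))
        ) / (2 * h)
    return J


def _fd_jac_theta(model, t, y, theta, u, h0=1e-7):
    l = theta.size
    J = np.empty((y.size, l))
    for j in range(l):
        h = h0 * max(abs(theta[j]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (
            np.asarray(model.rhs(t, y, tp, u)) - np.asarray(model.rhs(t, y, tm, u))
        ) / (2 * h)
    return J


def forward_sensitivities(
    model: OdeModel,
    experiment: Experiment,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
    allow_fd_jacobians: bool = True,
) -> tuple[Trajectory, np.ndarray]:
    """Solve the augmented forward-sensitivity system for one experiment.

    Returns the trajectory and an array ``Z`` of shape ``(n, k, l)`` holding
    ``dy_c(t_j)/dtheta_i`` at the experiment's times, evaluated at the
    experiment's (possibly overridden) parameter point.

    Uses the model's analytic Jacobians when available, otherwise central
    finite differences of the RHS (refused if ``allow_fd_jacobians=False``).
    """
    if (model.jac_y is None or model.jac_theta is None) and not allow_fd_jacobians:
        raise ValueError("analytic Jacobians missing and finite-difference fallback disabled")

    theta = model.params_with_overrides(experiment.param_overrides)
    u = experiment.input_for(model)
    k, l = model.n_states, model.n_params
    if experiment.initial_state is not None:
        y0 = experiment.initial_state.copy()
        Z0 = np.zeros((k, l))  # fixed (parameter-independent) start state
    else:
        y0 = np.asarray(model.initial_condition(theta), dtype=float)
        if model.init_jac_theta is not None:
            Z0 = np.asarray(model.init_jac_theta(theta), dtype=float)
        else:
            Z0 = np.zeros((k, l))

    jac_y = model.jac_y
    jac_theta = model.jac_theta

    def fun(t, aug):
        y = aug[:k]
        Z = aug[k:].reshape(k, l)
        ut = u(t)
        f = np.asarray(model.rhs(t, y, theta, ut), dtype=float)
        if not np.all(np.isfinite(f)):
            raise SimulationError(f"non-finite RHS at t={t:g}")
        Jy = (
            np.asarray(jac_y(t, y, theta, ut), dtype=float)
            if jac_y is not None
            else _fd_jac_y(model, t, y, theta, ut)
        )
        Jt = (
            np.asarray(jac_theta(t, y, theta, ut), dtype=float)
            if jac_theta is not None
            else _fd_jac_theta(model, t, y, theta, ut)
        )
        dZ = Jy @ Z + Jt
        return np.concatenate([f, dZ.ravel()])

    from .model import _integrate_segments

    aug0 = np.concatenate([y0, Z0.ravel()])
    t0 = min(0.0, float(experiment.times[0]))
    out = _integrate_segments(
        fun, t0, float(experiment.times[-1]), aug0, experiment.times,
        experiment.breakpoints, rtol, atol,
    )
    traj = Trajectory(experiment.times, out[:, :k], model.state_names)
    Z = out[:, k:].reshape(experiment.n_times, k, l)
    return traj, Z


def finite_difference_sensitivities(
    model: OdeModel,
    experiment: Experiment,
    rel_step: float = 1e-6,
    rtol: float = 1e-11,
    atol: float = 1e-13,
) -> np.ndarray:
    """Central-difference sensitivities of the full state (n, k, l).

    Re-simulates at ``theta_i* (1 +/- h)``; serves as an independent oracle
    for :func:`forward_sensitivities`, not as a production path.  Default
    tolerances are tighter than the simulation defaults because the
    difference quotient amplifies solver noise by ``1/(2h)``.
    """
    theta = model.params_with_overrides(experiment.param_overrides)
    k, l = model.n_states, model.n_params
    Z = np.empty((experiment.n_times, k, l))
    base_overrides = dict(experiment.param_overrides)
    for i, name in enumerate(model.param_names):
        scale = theta[i] if theta[i] != 0 else model.reference_params[i]
        h = rel_step * abs(scale)
        if h == 0:
            raise ValueError(f"cannot form finite-difference step for {name}")
        up = dict(base_overrides, **{name: theta[i] + h})
        dn = dict(base_overrides, **{name: theta[i] - h})
        exp_up = _with_overrides(experiment, up)
        exp_dn = _with_overrides(experiment, dn)
        yp = simulate(model, exp_up, rtol=rtol, atol=atol).state_values
        ym = simulate(model, exp_dn, rtol=rtol, atol=atol).state_values
        Z[:, :, i] = (yp - ym) / (2 * h)
    return Z


def _with_overrides(experiment: Experiment, overrides: dict) -> Experiment:
    return Experiment(
        observed=experiment.observed,
        times=experiment.times,
        input_profile=experiment.input_profile,
        param_overrides=overrides,
        error_sd=experiment.error_sd,
        initial_state=experiment.initial_state,
        breakpoints=experiment.breakpoints,
        name=experiment.name,
    )


def build_sensitivity_matrix(
    model: OdeModel,
    experiments: list[Experiment],
    log_scale: bool = True,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
) -> SensitivityMatrix:
    """Stack per-experiment sensitivity blocks into one matrix.

    Each block's rows are the observed components in time-major order,
    divided by that experiment's ``error_sd``.  With ``log_scale`` column
    ``i`` is multiplied by the reference value ``theta_i*`` (always the
    model's reference, also under per-experiment overrides, so columns remain
    comparable across experiments).
    """
    if not experiments:
        raise ValueError("need at least one experiment")
    if log_scale and np.any(model.reference_params <= 0):
        raise ValueError("log-parametrisation requires strictly positive reference_params")
    blocks = []
    labels: list[tuple[str, float, str]] = []
    for exp in experiments:
        _, Z = forward_sensitivities(model, exp, rtol=rtol, atol=atol)
        idx = exp.observed_indices(model)
        block = Z[:, idx, :].reshape(exp.n_times * len(idx), model.n_params)
        blocks.append(block / exp.error_sd)
        for t in exp.times:
            for c in idx:
                labels.append((exp.name, float(t), model.state_names[c]))
    S = np.vstack(blocks)
    if log_scale:
        S = S * model.reference_params[np.newaxis, :]
    return SensitivityMatrix(S, list(model.param_names), log_scale, labels)
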