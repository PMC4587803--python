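"""ODE models, experiments and trajectory simulation.

An :class:`OdeModel` bundles the right-hand side ``dy/dt = F(y, theta)`` of a
dynamical model together with its parameter vector (at reference values), an
initial condition and an optional time-dependent input signal ``u(t)``.  An
:class:`Experiment` describes one measurement protocol: which state variables
are observed, at which times, under which stimulation and with which parameter
perturbations (e.g. a rate set to 0 for a knockout).

Observation vectors are ordered **time-major**: for times ``t_1 < ... < t_n``
and observed components ``(c_1, ..., c_q)`` the vector is

    (y_c1(t_1), ..., y_cq(t_1), y_c1(t_2), ..., y_cq(t_n)).

Every downstream module (sensitivity stacking, row labels, CSV export) relies
on this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "OdeModel",
    "Experiment",
    "Trajectory",
    "SimulationError",
    "simulate",
    "extract_observations",
    "steady_state_residual",
]

#: default solver tolerances; sensitivity columns must be accurate to >= 6
#: digits for canonical correlations near 1 to be stable.
RTOL_DEFAULT = 1e-8
ATOL_DEFAULT = 1e-10


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or produces non-finite values."""


def _zero_input(t: float) -> float:
    return 0.0


@dataclass
class OdeModel:
    """A parametrised ODE model ``dy/dt = F(t, y, theta, u(t))``.

    Parameters
    ----------
    state_names : list of str
        Names of the ``k`` state variables.
    param_names : list of str
        Names of the ``l`` parameters.
    reference_params : array of float, shape (l,)
        Reference parameter values ``theta*`` around which sensitivities are
        taken.  Must be strictly positive when log-parametrisation is used.
    rhs : callable ``(t, y, theta, u) -> dy/dt``
        Vector field.  ``u`` is the value of the input signal at ``t`` (a
        scalar or small array, as the model defines it).
    initial_condition : callable ``theta -> y(0)``
        Initial state.
    input_signal : callable ``t -> u``, optional
        Default input profile (zero if omitted); experiments may override it.
    jac_y, jac_theta : callables, optional
        Analytic Jacobians ``dF/dy`` (k x k) and ``dF/dtheta`` (k x l) with the
        same signature as ``rhs``.  When absent, forward sensitivities fall
        back to finite differences of ``rhs``.
    init_jac_theta : callable ``theta -> (k x l)``, optional
        Jacobian of the initial condition w.r.t. the parameters (zero if
        omitted).
    """

    state_names: list[str]
    param_names: list[str]
    reference_params: np.ndarray
    rhs: Callable
    initial_condition: Callable
    input_signal: Callable = _zero_input
    jac_y: Callable | None = None
    jac_theta: Callable | None = None
    init_jac_theta: Callable | None = None
    name: str = "model"

    def __post_init__(self) -> None:
        self.state_names = list(self.state_names)
        self.param_names = list(self.param_names)
        self.reference_params = np.asarray(self.reference_params, dtype=float)
        if self.n_states < 1 or self.n_params < 1:
            raise ValueError("model needs at least one state and one parameter")
        if self.reference_params.shape != (self.n_params,):
            raise ValueError(
                f"reference_params has shape {self.reference_params.shape}, "
                f"expected ({self.n_params},)"
            )
        if len(set(self.param_names)) != self.n_params:
            raise ValueError("duplicate parameter names")
        y0 = np.asarray(self.initial_condition(self.reference_params), dtype=float)
        if y0.shape != (self.n_states,):
            raise ValueError("initial_condition length does not match state count")
        f0 = np.asarray(
            self.rhs(0.0, y0, self.reference_params, self.input_signal(0.0)),
            dtype=float,
        )
        if f0.shape != (self.n_states,):
            raise ValueError("rhs output length does not match state count")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def param_index(self, name: str) -> int:
        try:
            return self.param_names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def state_index(self, name: str) -> int:
        try:
            return self.state_names.index(name)
        except ValueError:
            raise KeyError(f"unknown state {name!r}") from None

    def params_with_overrides(self, overrides: Mapping[str, float]) -> np.ndarray:
        """Reference parameters with per-experiment overrides applied."""
        theta = self.reference_params.copy()
        for name, value in overrides.items():
            theta[self.param_index(name)] = float(value)
        return theta


@dataclass
class Experiment:
    """One measurement protocol applied to an :class:`OdeModel`.

    ``observed`` may hold state names or integer indices; ``times`` must be
    strictly increasing.  ``input_profile`` (if given) overrides the model's
    default input signal; ``param_overrides`` perturbs parameters on top of
    the reference vector (e.g. ``{"k_i": 0.0}`` for a knockout);
    ``initial_state`` (if given) replaces the model's initial condition, which
    is how transient/decay protocols that start away from the nominal initial
    state are expressed.  ``breakpoints`` lists discontinuity times of the
    input profile so the solver is restarted at them.
    """

    observed: Sequence[str | int]
    times: np.ndarray
    input_profile: Callable | None = None
    param_overrides: dict[str, float] = field(default_factory=dict)
    error_sd: float = 1.0
    initial_state: np.ndarray | None = None
    breakpoints: tuple[float, ...] = ()
    name: str = "experiment"

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if self.times.size < 1:
            raise ValueError("experiment needs at least one observation time")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if len(self.observed) < 1:
            raise ValueError("experiment must observe at least one component")
        if self.error_sd <= 0:
            raise ValueError("error_sd must be positive")
        if self.initial_state is not None:
            self.initial_state = np.asarray(self.initial_state, dtype=float)

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    def observed_indices(self, model: OdeModel) -> list[int]:
        idx = []
        for c in self.observed:
            i = model.state_index(c) if isinstance(c, str) else int(c)
            if not 0 <= i < model.n_states:
                raise IndexError(
                    f"observed index {i} out of range for {model.n_states}-state model"
                )
            idx.append(i)
        return idx

    def input_for(self, model: OdeModel) -> Callable:
        return self.input_profile if self.input_profile is not None else model.input_signal


@dataclass
class Trajectory:
    """Model states evaluated on an experiment's time grid (n x k)."""

    times: np.ndarray
    state_values: np.ndarray
    state_names: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.state_values = np.asarray(self.state_values, dtype=float)
        if self.state_values.shape[0] != self.times.size:
            raise ValueError("row count does not match number of times")
        if not np.all(np.isfinite(self.state_values)):
            raise ValueError("trajectory contains non-finite values")

    def to_frame(self, experiment_id: str = ""):
        """Tidy (time, state, value, experiment_id) DataFrame."""
        import pandas as pd

        n, k = self.state_values.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, k),
                "state": np.tile(self.state_names, n),
                "value": self.state_values.ravel(),
                "experiment_id": experiment_id,
            }
        )


def _integrate_segments(fun, t0, t_end, y0, eval_times, breakpoints, rtol, atol,
                        method="LSODA"):
    """Integrate from t0 to t_end, restarting at declared breakpoints.

    Returns states at ``eval_times`` (sorted, within [t0, t_end]).
    """
    cuts = sorted({float(b) for b in breakpoints if t0 < b < t_end})
    edges = [t0, *cuts, t_end]
    out = np.empty((len(eval_times), y0.size))
    filled = np.zeros(len(eval_times), dtype=bool)
    y = np.asarray(y0, dtype=float)
    for a, b in zip(edges[:-1], edges[1:]):
        mask = (eval_times >= a) & (eval_times <= b) & ~filled
        t_eval = np.asarray(eval_times[mask], dtype=float)
        sol = solve_ivp(
            fun, (a, b), y, method=method, t_eval=t_eval if t_eval.size else None,
            rtol=rtol, atol=atol, dense_output=False,
        )
        if not sol.success:
            raise SimulationError(
                f"ODE solver failed on [{a:g}, {b:g}]: {sol.message}"
            )
        if t_eval.size:
            out[mask] = sol.y.T
            filled[mask] = True
        y = sol.y[:, -1] if sol.y.shape[1] else y
        if not np.all(np.isfinite(y)):
            raise SimulationError(f"non-finite state encountered near t={b:g}")
    if not filled.all():  # pragma: no cover - defensive
        raise SimulationError("solver did not return all requested times")
    return out


def simulate(
    model: OdeModel,
    experiment: Experiment,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
) -> Trajectory:
    """Simulate the model under an experiment's protocol.

    Integrates from ``t=0`` (or the first observation time, if negative) with
    the experiment's input profile, parameter overrides and, if given, initial
    state.  Uses a stiff-capable solver (LSODA) at tight tolerances.
    """
    theta = model.params_with_overrides(experiment.param_overrides)
    u = experiment.input_for(model)
    if experiment.initial_state is not None:
        y0 = experiment.initial_state.copy()
    else:
        y0 = np.asarray(model.initial_condition(theta), dtype=float)
    t0 = min(0.0, float(experiment.times[0]))
    t_end = float(experiment.times[-1])

    def fun(t, y):
        dy = np.asarray(model.rhs(t, y, theta, u(t)), dtype=float)
        if not np.all(np.isfinite(dy)):
            raise SimulationError(f"non-finite RHS at t={t:g}")
        return dy

    values = _integrate_segments(
        fun, t0, t_end, y0, experiment.times, experiment.breakpoints, rtol, atol
    )
    return Trajectory(experiment.times, values, model.state_names)


def steady_state_residual(
    model: OdeModel,
    experiment: Experiment,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
) -> float:
    """Relative RHS residual ``||dy/dt||_inf / ||y||_inf`` at the last
    observation time.

    Steady-state protocols are expressed as one late observation time; this
    reports how far from equilibrium the system still is there (the bundled
    steady-state fixtures keep it below 1e-10).
    """
    traj = simulate(model, experiment, rtol=rtol, atol=atol)
    theta = model.params_with_overrides(experiment.param_overrides)
    u = experiment.input_for(model)
    t_end = float(experiment.times[-1])
    y_end = traj.state_values[-1]
    dy = np.asarray(model.rhs(t_end, y_end, theta, u(t_end)), dtype=float)
    scale = max(np.max(np.abs(y_end)), atol)
    return float(np.max(np.abs(dy)) / scale)


def extract_observations(trajectory: Trajectory, experiment: Experiment,
                         model: OdeModel | None = None) -> np.ndarray:
    """Flatten a trajectory into the observation vector ``Y`` (length q*n).

    Ordering is time-major (all observed components at ``t_1``, then ``t_2``,
    ...), matching the row order of the sensitivity matrix.
    """
    if model is not None:
        idx = experiment.observed_indices(model)
    else:
        idx = []
        for c in experiment.observed:
            i = trajectory.state_names.index(c) if isinstance(c, str) else int(c)
            if not 0 <= i < trajectory.state_values.shape[1]:
                raise IndexError(f"observed index {i} out of range")
            idx.append(i)
    traj_times = trajectory.times
    pos = np.searchsorted(traj_times, experiment.times)
    if (
        np.any(pos >= traj_times.size)
        or not np.allclose(traj_times[np.minimum(pos, traj_times.size - 1)],
                           experiment.times)
    ):
        raise ValueError("trajectory does not cover all experiment times")
    return trajectory.state_values[np.ix_(pos, idx)].ravel()
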