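"""Built-in example models.

* :func:`gene_expression_fixture` — the two-stage constitutive gene
  expression model (mRNA produced at rate ``k_r``, translated at ``k_p``,
  both species degraded first-order at ``g_r`` and ``g_p``).  Its steady
  state ``(k_r/g_r, k_r k_p/(g_r g_p))`` depends on the rates only through
  two ratios, so a steady-state measurement leaves every parameter perfectly
  compensated within the pairs (k_r, g_r) and (k_p, g_p); observing the
  relaxation from an initial condition pushed above the steady state breaks
  the compensation and makes all four rates identifiable.

* :func:`ikkk_fixture` — the single-ODE sub-model of phosphorylated IKKK
  from TNF-alpha / NF-kB signalling,

      dy1/dt = ka * y16(t) * (KN - y1) * ka20/(ka20 + y9(t)) - ki * y1,

  with activated receptors ``y16`` and cytoplasmic A20 ``y9`` supplied as
  prescribed forcing time-courses.  In wild-type cells ka, KN and ki are
  nearly perfectly compensated; combining wild type, an A20 knockout
  (``y9 = 0``) and a knockout with blocked phosphatase activity (``ki`` set
  to 0) decorrelates ka, KN and ki.  The forcing shapes used here are
  documented stand-ins (a pulse of receptor activation and a delayed A20
  accumulation); the qualitative identifiability pattern, not exact
  correlation values, is the fixture's contract.

* :func:`random_model_generator` — seeded linear mass-action chains with
  optional *planted compensations*: selected transport rates are written as
  a product ``alpha * beta`` of two parameters, which therefore enter the
  observables only through their product and have exactly proportional
  sensitivity columns (canonical correlation 1 by construction).  Used as a
  ground-truthed harness for clustering/pruning properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Experiment, OdeModel

__all__ = [
    "FixtureSpec",
    "gene_expression_fixture",
    "ikkk_fixture",
    "random_model_generator",
]


@dataclass
class FixtureSpec:
    """A named model plus its canonical experiments."""

    name: str
    model: OdeModel
    experiments: dict[str, Experiment]
    notes: str = ""
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)

    def experiment(self, name: str) -> Experiment:
        try:
            return self.experiments[name]
        except KeyError:
            raise KeyError(
                f"fixture {self.name!r} has no experiment {name!r}; "
                f"available: {sorted(self.experiments)}"
            ) from None


# ---------------------------------------------------------------------------
# gene expression


#: documented reference rates (all order 1); steady state is (2, 3).
GENE_THETA = {"k_r": 2.0, "k_p": 3.0, "g_r": 1.0, "g_p": 2.0}

#: late observation time of the steady-state protocol; the slowest rate is
#: g_r = 1, so the transient has decayed below solver tolerance by t = 40.
GENE_STEADY_TIME = 40.0


def gene_expression_fixture() -> FixtureSpec:
    names = ["k_r", "k_p", "g_r", "g_p"]
    theta_star = np.array([GENE_THETA[n] for n in names])

    def rhs(t, y, th, u):
        k_r, k_p, g_r, g_p = th
        r, p = y
        return np.array([k_r - g_r * r, k_p * r - g_p * p])

    def jac_y(t, y, th, u):
        k_r, k_p, g_r, g_p = th
        return np.array([[-g_r, 0.0], [k_p, -g_p]])

    def jac_theta(t, y, th, u):
        r, p = y
        return np.array([[1.0, 0.0, -r, 0.0], [0.0, r, 0.0, -p]])

    model = OdeModel(
        state_names=["r", "p"],
        param_names=names,
        reference_params=theta_star,
        rhs=rhs,
        initial_condition=lambda th: np.zeros(2),
        jac_y=jac_y,
        jac_theta=jac_theta,
        name="gene_expression",
    )

    ss = steady_state_gene(theta_star)
    experiments = {
        # both species once, after the transient has fully decayed
        "steady_state": Experiment(
            observed=["r", "p"],
            times=[GENE_STEADY_TIME],
            name="steady_state",
        ),
        # relaxation from strong mRNA overexpression (15x steady state, as
        # after transient transfection) with protein modestly elevated
        # (1.5x); log-spaced sampling covers the fast and slow phases
        "decay": Experiment(
            observed=["r", "p"],
            times=np.geomspace(0.05, 15.0, 16),
            initial_state=np.array([15.0 * ss[0], 1.5 * ss[1]]),
            name="decay",
        ),
    }
    return FixtureSpec(
        name="gene_expression",
        model=model,
        experiments=experiments,
        notes="two-stage gene expression: dr/dt = k_r - g_r r, dp/dt = k_p r - g_p p",
    )


def steady_state_gene(theta) -> np.ndarray:
    """Closed-form steady state (k_r/g_r, k_r k_p/(g_r g_p))."""
    k_r, k_p, g_r, g_p = np.asarray(theta, dtype=float)
    return np.array([k_r / g_r, k_r * k_p / (g_r * g_p)])


# ---------------------------------------------------------------------------
# IKKK sub-model


#: documented reference values: under wild-type stimulation A20 feedback
#: keeps IKKK activation far from saturating the kinase pool KN, so ka and
#: KN enter (KN - y1) ~ KN almost only through their product; removing the
#: feedback (A20 knockout) lets y1 approach KN and decorrelates them.
IKKK_THETA = {"ka": 1.0, "KN": 10.0, "ka20": 0.5, "ki": 0.5}


def _receptor_pulse(t: float) -> float:
    """Activated-receptor time course y16(t): rise to a peak of 3 at t = 2,
    then decay (a transient TNF-alpha stimulation)."""
    return 3.0 * (t / 2.0) * np.exp(1.0 - t / 2.0) if t > 0 else 0.0


def _a20_wildtype(t: float) -> float:
    """Cytoplasmic A20 y9(t): delayed accumulation to a plateau of 5."""
    return 5.0 * (1.0 - np.exp(-0.5 * t)) if t > 0 else 0.0


def ikkk_fixture() -> FixtureSpec:
    names = ["ka", "KN", "ka20", "ki"]
    theta_star = np.array([IKKK_THETA[n] for n in names])

    def rhs(t, y, th, u):
        ka, KN, ka20, ki = th
        y16, y9 = u
        return np.array([ka * y16 * (KN - y[0]) * ka20 / (ka20 + y9) - ki * y[0]])

    def jac_y(t, y, th, u):
        ka, KN, ka20, ki = th
        y16, y9 = u
        return np.array([[-ka * y16 * ka20 / (ka20 + y9) - ki]])

    def jac_theta(t, y, th, u):
        ka, KN, ka20, ki = th
        y16, y9 = u
        f = ka20 / (ka20 + y9)
        drive = y16 * (KN - y[0])
        return np.array(
            [[drive * f, ka * y16 * f, ka * drive * y9 / (ka20 + y9) ** 2, -y[0]]]
        )

    def input_wt(t):
        return np.array([_receptor_pulse(t), _a20_wildtype(t)])

    def input_a20ko(t):
        return np.array([_receptor_pulse(t), 0.0])

    model = OdeModel(
        state_names=["y1"],
        param_names=names,
        reference_params=theta_star,
        rhs=rhs,
        initial_condition=lambda th: np.zeros(1),
        input_signal=input_wt,
        jac_y=jac_y,
        jac_theta=jac_theta,
        name="ikkk",
    )

    times = np.linspace(0.5, 12.0, 16)
    experiments = {
        "wild_type": Experiment(
            observed=["y1"], times=times, input_profile=input_wt, name="wild_type"
        ),
        "a20_knockout": Experiment(
            observed=["y1"], times=times, input_profile=input_a20ko, name="a20_knockout"
        ),
        "knockout_blocked_phosphatase": Experiment(
            observed=["y1"],
            times=times,
            input_profile=input_a20ko,
            param_overrides={"ki": 0.0},
            name="knockout_blocked_phosphatase",
        ),
    }
    return FixtureSpec(
        name="ikkk",
        model=model,
        experiments=experiments,
        notes=(
            "phosphorylated IKKK sub-model with prescribed stand-in forcings "
            "y16 (receptor pulse) and y9 (A20 accumulation)"
        ),
    )


# ---------------------------------------------------------------------------
# random chain generator


def random_model_generator(
    seed: int,
    n_states: int = 4,
    planted_pairs: int = 1,
    n_times: int = 9,
) -> FixtureSpec:
    """Seeded linear mass-action chain with planted ratio compensations.

    The chain is ``dx1/dt = b - d1 x1``, ``dxj/dt = r_{j-1} x_{j-1} - dj xj``.
    ``planted_pairs`` of the transport rates ``r_j`` are replaced by products
    ``alpha_j * beta_j`` of two parameters, which consequently have exactly
    proportional sensitivity columns (canonical correlation 1 with each
    other).  All states are observed on a fixed grid, which keeps the
    unplanted part of the model generically well-conditioned.
    """
    if n_states < 2:
        raise ValueError("need at least two states")
    if planted_pairs < 0 or planted_pairs > n_states - 1:
        raise ValueError(
            f"cannot plant {planted_pairs} pairs in a chain with "
            f"{n_states - 1} transport rates"
        )
    rng = np.random.default_rng(seed)
    planted_edges = sorted(rng.choice(n_states - 1, size=planted_pairs, replace=False))

    param_names: list[str] = ["b", "d1"]
    param_vals: list[float] = [float(rng.uniform(0.5, 2.0)), float(rng.uniform(0.3, 2.0))]
    edge_param_slices: list[tuple[str, ...]] = []
    pairs: list[tuple[str, str]] = []
    for j in range(n_states - 1):
        if j in planted_edges:
            a, b_ = f"alpha{j + 1}", f"beta{j + 1}"
            param_names += [a, b_]
            param_vals += [float(rng.uniform(0.5, 2.0)), float(rng.uniform(0.5, 2.0))]
            edge_param_slices.append((a, b_))
            pairs.append((a, b_))
        else:
            r = f"r{j + 1}"
            param_names.append(r)
            param_vals.append(float(rng.uniform(0.3, 2.0)))
            edge_param_slices.append((r,))
        d = f"d{j + 2}"
        param_names.append(d)
        param_vals.append(float(rng.uniform(0.3, 2.0)))

    idx = {n: i for i, n in enumerate(param_names)}
    theta_star = np.array(param_vals)
    k = n_states
    l = len(param_names)

    def edge_rate(th, j):
        ps = edge_param_slices[j]
        return th[idx[ps[0]]] * (th[idx[ps[1]]] if len(ps) == 2 else 1.0)

    def rhs(t, y, th, u):
        dy = np.empty(k)
        dy[0] = th[idx["b"]] - th[idx["d1"]] * y[0]
        for j in range(k - 1):
            dy[j + 1] = edge_rate(th, j) * y[j] - th[idx[f"d{j + 2}"]] * y[j + 1]
        return dy

    def jac_y(t, y, th, u):
        J = np.zeros((k, k))
        J[0, 0] = -th[idx["d1"]]
        for j in range(k - 1):
            J[j + 1, j] = edge_rate(th, j)
            J[j + 1, j + 1] = -th[idx[f"d{j + 2}"]]
        return J

    def jac_theta(t, y, th, u):
        J = np.zeros((k, l))
        J[0, idx["b"]] = 1.0
        J[0, idx["d1"]] = -y[0]
        for j in range(k - 1):
            ps = edge_param_slices[j]
            if len(ps) == 2:
                J[j + 1, idx[ps[0]]] = th[idx[ps[1]]] * y[j]
                J[j + 1, idx[ps[1]]] = th[idx[ps[0]]] * y[j]
            else:
                J[j + 1, idx[ps[0]]] = y[j]
            J[j + 1, idx[f"d{j + 2}"]] = -y[j + 1]
        return J

    model = OdeModel(
        state_names=[f"x{i + 1}" for i in range(k)],
        param_names=param_names,
        reference_params=theta_star,
        rhs=rhs,
        initial_condition=lambda th: np.zeros(k),
        jac_y=jac_y,
        jac_theta=jac_theta,
        name=f"chain{n_states}_seed{seed}",
    )
    experiments = {
        "all_states": Experiment(
            observed=model.state_names,
            times=np.linspace(0.5, 8.0, n_times),
            name="all_states",
        )
    }
    return FixtureSpec(
        name=model.name,
        model=model,
        experiments=experiments,
        notes="seeded linear mass-action chain with planted ratio pairs",
        planted_pairs=pairs,
    )


FIXTURES = {
    "gene_expression": gene_expression_fixture,
    "ikkk": ikkk_fixture,
}


def get_fixture(name: str) -> FixtureSpec:
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
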