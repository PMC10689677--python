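"""Built-in dynamic models, forward sensitivity analysis, Gaussian
measurement likelihood, and the synthetic-data generator.

The model registry ships small ODE systems (conversion reaction, exponential
decay) with hand-coded right-hand-side Jacobians so gradients can be computed
by forward sensitivity analysis — integrating the augmented system
``ds/dt = (df/dx) s + df/dp`` jointly with the states. Analytic black-box
test objectives (Rosenbrock, correlated Gaussian, bimodal mixture) are
registered through the same objective contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import rosen, rosen_der

from .objective import (
    FunctionObjective,
    Objective,
    ObjectiveValue,
    ORDER_GRAD,
    ORDER_RES,
    ORDER_VALUE,
)
from .problem import (
    ParameterSpec,
    from_estimation_scale,
    scale_gradient_chain,
)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class SimulationError(RuntimeError):
    """Integrator failure; carries the failing parameter vector."""

    def __init__(self, message, parameters=None):
        super().__init__(message)
        self.parameters = None if parameters is None else np.asarray(parameters)


@dataclass(frozen=True)
class OdeModel:
    """An ODE model with analytic Jacobians and linear observable read-out.

    ``observation_matrix`` (n_obs x n_state) maps states to observables;
    scaling/offset observation parameters are layered on top by the
    likelihood objective, not the model.
    """

    id: str
    state_dim: int
    parameter_ids: tuple
    rhs: Callable                    # (x, p, t) -> dx/dt
    jac_state: Callable              # (x, p, t) -> d rhs / d x
    jac_param: Callable              # (x, p, t) -> d rhs / d p
    initial_state: Callable          # (p) -> x0
    initial_state_jac: Optional[Callable] = None   # (p) -> d x0 / d p
    observable_ids: tuple = ()
    observation_matrix: Optional[np.ndarray] = None

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_ids)

    @property
    def n_observables(self) -> int:
        return len(self.observable_ids)


@dataclass
class SimulationResult:
    times: np.ndarray                     # (n_t,)
    states: np.ndarray                    # (n_t, n_x)
    observables: np.ndarray               # (n_t, n_obs)
    sensitivities: Optional[np.ndarray] = None   # (n_t, n_x, n_p)

    def observable_sensitivities(self, C) -> np.ndarray:
        """(n_t, n_obs, n_p) sensitivities of the linear read-out."""
        return np.einsum("oj,tjp->top", C, self.sensitivities)


def simulate(model: OdeModel, parameters, t_grid, rtol=DEFAULT_RTOL,
             atol=DEFAULT_ATOL, method="LSODA") -> SimulationResult:
    """Solve the initial value problem at ``t_grid`` (linear-scale
    parameters, increasing times)."""
    p = np.asarray(parameters, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    x0 = np.asarray(model.initial_state(p), dtype=float)
    t0 = min(0.0, t_grid[0])
    sol = solve_ivp(
        lambda t, x: model.rhs(x, p, t),
        (t0, t_grid[-1]),
        x0,
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
        method=method,
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed for model {model.id!r}: {sol.message}", p
        )
    states = sol.y.T
    C = model.observation_matrix
    obs = states @ C.T if C is not None else states
    return SimulationResult(times=t_grid, states=states, observables=obs)


def simulate_with_sensitivities(model: OdeModel, parameters, t_grid,
                                rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL,
                                method="LSODA") -> SimulationResult:
    """Solve the forward-sensitivity augmented system
    ``ds/dt = (df/dx) s + df/dp`` jointly with the states."""
    p = np.asarray(parameters, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    nx, npar = model.state_dim, model.n_parameters
    x0 = np.asarray(model.initial_state(p), dtype=float)
    s0 = (
        np.asarray(model.initial_state_jac(p), dtype=float)
        if model.initial_state_jac is not None
        else np.zeros((nx, npar))
    )

    def rhs_aug(t, y):
        x = y[:nx]
        s = y[nx:].reshape(nx, npar)
        jx = np.asarray(model.jac_state(x, p, t))
        jp = np.asarray(model.jac_param(x, p, t))
        return np.concatenate(
            [np.asarray(model.rhs(x, p, t)), (jx @ s + jp).ravel()]
        )

    t0 = min(0.0, t_grid[0])
    sol = solve_ivp(
        rhs_aug,
        (t0, t_grid[-1]),
        np.concatenate([x0, s0.ravel()]),
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
        method=method,
    )
    if not sol.success:
        raise SimulationError(
            f"sensitivity integration failed for model {model.id!r}: "
            f"{sol.message}",
            p,
        )
    y = sol.y.T
    states = y[:, :nx]
    sens = y[:, nx:].reshape(-1, nx, npar)
    C = model.observation_matrix
    obs = states @ C.T if C is not None else states
    return SimulationResult(
        times=t_grid, states=states, observables=obs, sensitivities=sens
    )


def gaussian_nllh(simulated, measured, sigma) -> float:
    """Gaussian negative log-likelihood
    ``0.5 * sum(log(2 pi sigma_i^2) + ((measured_i - simulated_i)/sigma_i)^2)``.
    """
    simulated = np.asarray(simulated, dtype=float)
    measured = np.asarray(measured, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), simulated.shape)
    if simulated.shape != measured.shape:
        raise ValueError("simulated and measured must have equal length")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    r = (measured - simulated) / sigma
    return float(0.5 * np.sum(np.log(2 * np.pi * sigma**2) + r**2))


MEASUREMENT_COLUMNS = [
    "observableId",
    "simulationConditionId",
    "time",
    "measurement",
]


def generate_synthetic_data(model: OdeModel, parameters, t_grid, sigma,
                            seed: int, condition_id: str = "c0",
                            rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL
                            ) -> pd.DataFrame:
    """Simulate the model and add i.i.d. Gaussian noise N(0, sigma^2) to
    every observable at every grid time; ``sigma=0`` yields a noise-free
    table. Deterministic given ``seed``."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    res = simulate(model, parameters, t_grid, rtol=rtol, atol=atol)
    rng = np.random.default_rng(seed)
    rows = []
    for j, oid in enumerate(model.observable_ids):
        for k, t in enumerate(res.times):
            y = res.observables[k, j]
            if sigma > 0:
                y = y + sigma * rng.standard_normal()
            rows.append((oid, condition_id, float(t), float(y)))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


# ---------------------------------------------------------------------------
# built-in ODE models (module-level functions keep models picklable)
# ---------------------------------------------------------------------------

def _conv_rhs(x, p, t):
    k1, k2 = p
    return np.array([-k1 * x[0] + k2 * x[1], k1 * x[0] - k2 * x[1]])


def _conv_jac_state(x, p, t):
    k1, k2 = p
    return np.array([[-k1, k2], [k1, -k2]])


def _conv_jac_param(x, p, t):
    return np.array([[-x[0], x[1]], [x[0], -x[1]]])


def _conv_x0(p):
    return np.array([1.0, 0.0])


CONVERSION_REACTION = OdeModel(
    id="conversion_reaction",
    state_dim=2,
    parameter_ids=("k1", "k2"),
    rhs=_conv_rhs,
    jac_state=_conv_jac_state,
    jac_param=_conv_jac_param,
    initial_state=_conv_x0,
    observable_ids=("obs_a", "obs_b"),
    observation_matrix=np.eye(2),
)


def _decay_rhs(x, p, t):
    return np.array([-p[0] * x[0]])


def _decay_jac_state(x, p, t):
    return np.array([[-p[0]]])


def _decay_jac_param(x, p, t):
    return np.array([[-x[0]]])


def _decay_x0(p):
    return np.array([1.0])


EXPONENTIAL_DECAY = OdeModel(
    id="exponential_decay",
    state_dim=1,
    parameter_ids=("lam",),
    rhs=_decay_rhs,
    jac_state=_decay_jac_state,
    jac_param=_decay_jac_param,
    initial_state=_decay_x0,
    observable_ids=("obs_x",),
    observation_matrix=np.eye(1),
)

MODEL_REGISTRY: dict[str, OdeModel] = {
    m.id: m for m in (CONVERSION_REACTION, EXPONENTIAL_DECAY)
}

#: default "true" parameters of the conversion-reaction fixture
CONVERSION_TRUE = {"k1": 0.06, "k2": 0.08}
CONVERSION_SIGMA = 0.02
CONVERSION_T_GRID = np.linspace(0.0, 30.0, 10)


# ---------------------------------------------------------------------------
# analytic black-box objectives, registered through the objective contract
# ---------------------------------------------------------------------------

_GAUSS_ND_DIM = 5


def _gauss_nd_cov() -> np.ndarray:
    """Fixed random SPD covariance for the d=5 Gaussian test target."""
    rng = np.random.default_rng(20230517)
    a = rng.standard_normal((_GAUSS_ND_DIM, _GAUSS_ND_DIM))
    return a @ a.T + _GAUSS_ND_DIM * np.eye(_GAUSS_ND_DIM)


_GAUSS_ND_COV = _gauss_nd_cov()
_GAUSS_ND_PREC = np.linalg.inv(_GAUSS_ND_COV)


def _gauss_nd_fun(x):
    return 0.5 * float(x @ _GAUSS_ND_PREC @ x)


def _gauss_nd_grad(x):
    return _GAUSS_ND_PREC @ x


_BIMODAL_MODES = (-5.0, 5.0)


def _bimodal_fun(x):
    z = np.asarray(x, dtype=float).ravel()[0]
    a = -0.5 * (z - _BIMODAL_MODES[0]) ** 2
    b = -0.5 * (z - _BIMODAL_MODES[1]) ** 2
    m = max(a, b)
    return -(m + np.log(0.5 * np.exp(a - m) + 0.5 * np.exp(b - m)))


def _bimodal_grad(x):
    z = np.asarray(x, dtype=float).ravel()[0]
    a = -0.5 * (z - _BIMODAL_MODES[0]) ** 2
    b = -0.5 * (z - _BIMODAL_MODES[1]) ** 2
    m = max(a, b)
    wa = 0.5 * np.exp(a - m)
    wb = 0.5 * np.exp(b - m)
    da = -(z - _BIMODAL_MODES[0])
    db = -(z - _BIMODAL_MODES[1])
    return np.array([-(wa * da + wb * db) / (wa + wb)])


def _make_rosenbrock():
    obj = FunctionObjective(rosen, rosen_der, name="rosenbrock_2d")
    specs = [
        ParameterSpec(id=f"x{i}", lower_bound=-5.0, upper_bound=5.0,
                      nominal=0.0)
        for i in range(2)
    ]
    return obj, specs


def _make_gaussian_nd():
    obj = FunctionObjective(_gauss_nd_fun, _gauss_nd_grad, name="gaussian_nd")
    specs = [
        ParameterSpec(id=f"x{i}", lower_bound=-10.0, upper_bound=10.0,
                      nominal=0.0)
        for i in range(_GAUSS_ND_DIM)
    ]
    return obj, specs


def _make_bimodal_1d():
    obj = FunctionObjective(_bimodal_fun, _bimodal_grad, name="bimodal_1d")
    specs = [
        ParameterSpec(id="x0", lower_bound=-20.0, upper_bound=20.0,
                      nominal=5.0)
    ]
    return obj, specs


OBJECTIVE_REGISTRY: dict[str, Callable] = {
    "rosenbrock_2d": _make_rosenbrock,
    "gaussian_nd": _make_gaussian_nd,
    "bimodal_1d": _make_bimodal_1d,
}


def get_analytic_objective(name: str):
    """Return (objective, parameter specs) for a registered analytic target."""
    if name not in OBJECTIVE_REGISTRY:
        raise KeyError(f"unknown analytic objective {name!r}")
    return OBJECTIVE_REGISTRY[name]()


# ---------------------------------------------------------------------------
# Gaussian-likelihood objective over measurement rows
# ---------------------------------------------------------------------------

SRC_CONST = -1  # sentinel for constant sources in (kind, value) pairs


@dataclass
class RowSource:
    """Per-row parameter source: either a constant or an index into the
    full problem parameter vector (linear scale values)."""

    index: int = SRC_CONST
    value: float = 0.0

    def resolve(self, x_lin):
        return self.value if self.index == SRC_CONST else x_lin[self.index]


@dataclass
class ConditionBlock:
    """Measurement rows sharing one simulation condition."""

    condition_id: str
    times: np.ndarray                 # unique sorted times of this condition
    time_index: np.ndarray            # per row, index into times
    obs_index: np.ndarray             # per row, model observable index
    measurements: np.ndarray          # per row
    offset: list                      # per row RowSource (observable offset b)
    scaling: list                     # per row RowSource (observable scale s)
    sigma: list                       # per row RowSource (noise sd)
    model_param_src: list = field(default_factory=list)  # per model parameter

    @property
    def n_rows(self) -> int:
        return len(self.measurements)


class OdeObjective(Objective):
    """Gaussian negative log-likelihood of a registered ODE model against a
    measurement table, one simulation per condition.

    Measurement rows observe ``b + s * y`` where ``y`` is the model's linear
    observable read-out; ``b``, ``s`` and the noise sd ``sigma`` are each
    either constants or entries of the (linear-scale) parameter vector.
    The gradient is exact via forward sensitivities, chained through the
    parameter estimation scales.
    """

    def __init__(self, model: OdeModel, conditions: list[ConditionBlock],
                 x_ids: list[str], scales: list[str],
                 rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL):
        super().__init__()
        self.model = model
        self.conditions = conditions
        self.x_ids = list(x_ids)
        self.scales = list(scales)
        self.rtol = rtol
        self.atol = atol
        self.capabilities = frozenset({ORDER_VALUE, ORDER_GRAD, ORDER_RES})

    # -- internals -------------------------------------------------------
    def _model_params(self, cond: ConditionBlock, x_lin) -> np.ndarray:
        return np.array([src.resolve(x_lin) for src in cond.model_param_src])

    def _simulate_condition(self, cond, x_lin, need_sens):
        p = self._model_params(cond, x_lin)
        sim_fn = simulate_with_sensitivities if need_sens else simulate
        return sim_fn(self.model, p, cond.times, rtol=self.rtol,
                      atol=self.atol)

    def row_values(self, cond: ConditionBlock, res: SimulationResult, x_lin):
        """(simulated per row incl. offset/scaling, raw read-out y, sigma)."""
        y = res.observables[cond.time_index, cond.obs_index]
        b = np.array([s.resolve(x_lin) for s in cond.offset])
        s = np.array([s.resolve(x_lin) for s in cond.scaling])
        sig = np.array([s.resolve(x_lin) for s in cond.sigma])
        return b + s * y, y, sig

    def _eval(self, x, orders):
        x_est = np.asarray(x, dtype=float)
        try:
            x_lin = from_estimation_scale(x_est, self.scales)
        except ValueError:
            return ObjectiveValue(fval=np.inf)
        need_grad = ORDER_GRAD in orders
        fval = 0.0
        grad = np.zeros_like(x_est) if need_grad else None
        residuals = [] if ORDER_RES in orders else None
        try:
            for cond in self.conditions:
                res = self._simulate_condition(cond, x_lin, need_grad)
                sim, y, sig = self.row_values(cond, res, x_lin)
                if np.any(sig <= 0):
                    return ObjectiveValue(fval=np.inf)
                r = cond.measurements - sim
                fval += float(
                    0.5 * np.sum(np.log(2 * np.pi * sig**2) + (r / sig) ** 2)
                )
                if residuals is not None:
                    residuals.append(r / sig)
                if need_grad:
                    self._accumulate_grad(cond, res, x_lin, sim, y, sig, r,
                                          grad)
        except SimulationError:
            return ObjectiveValue(fval=np.inf)
        if need_grad:
            grad *= scale_gradient_chain(x_est, self.scales)
        return ObjectiveValue(
            fval=fval,
            grad=grad,
            residuals=None if residuals is None
            else np.concatenate(residuals),
        )

    def _accumulate_grad(self, cond, res, x_lin, sim, y, sig, r, grad):
        """d nllh / d x_lin contributions of one condition."""
        C = self.model.observation_matrix
        obs_sens = res.observable_sensitivities(C)  # (n_t, n_obs, n_p_model)
        dy = obs_sens[cond.time_index, cond.obs_index, :]  # (n_rows, n_p)
        w = -r / sig**2  # d nllh / d sim_i
        s_arr = np.array([s.resolve(x_lin) for s in cond.scaling])
        # through the dynamics: d sim / d p_model = s * dy
        contrib = (w * s_arr)[:, None] * dy  # (n_rows, n_p_model)
        for j, src in enumerate(cond.model_param_src):
            if src.index != SRC_CONST:
                grad[src.index] += contrib[:, j].sum()
        # through observation parameters and noise sds
        for i in range(cond.n_rows):
            bsrc, ssrc, gsrc = cond.offset[i], cond.scaling[i], cond.sigma[i]
            if bsrc.index != SRC_CONST:
                grad[bsrc.index] += w[i]
            if ssrc.index != SRC_CONST:
                grad[ssrc.index] += w[i] * y[i]
            if gsrc.index != SRC_CONST:
                grad[gsrc.index] += 1.0 / sig[i] - r[i] ** 2 / sig[i] ** 3

    # -- reporting -------------------------------------------------------
    def simulation_frame(self, x_est) -> pd.DataFrame:
        """Measurement rows plus a ``simulation`` column evaluated at the
        estimation-scale full vector ``x_est``."""
        x_lin = from_estimation_scale(np.asarray(x_est, float), self.scales)
        frames = []
        for cond in self.conditions:
            res = self._simulate_condition(cond, x_lin, False)
            sim, _, _ = self.row_values(cond, res, x_lin)
            frames.append(pd.DataFrame({
                "observableId": [
                    self.model.observable_ids[j] for j in cond.obs_index
                ],
                "simulationConditionId": cond.condition_id,
                "time": cond.times[cond.time_index],
                "measurement": cond.measurements,
                "simulation": sim,
            }))
        return pd.concat(frames, ignore_index=True)
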