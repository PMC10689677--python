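"""Objective-function abstraction and finite-difference machinery.

Objectives map a full-length estimation-scale parameter vector to a
negative log-likelihood / negative log-posterior / least-squares value, with
optional gradients, residuals and residual Jacobians. Non-finite values are
propagated as +inf so optimizers survive infeasible trial points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .problem import ParameterSpec, PriorSpec, SCALE_LOG10, _LN10

ORDER_VALUE = "value"
ORDER_GRAD = "gradient"
ORDER_RES = "residuals"
ORDER_RESJAC = "residual_jacobian"

MODE_NLLH = "negative-log-likelihood"
MODE_NLP = "negative-log-posterior"
MODE_LSQ = "least-squares"

#: default decreasing candidate ladder for adaptive step selection
DEFAULT_FD_LADDER = tuple(10.0 ** (-k) for k in range(1, 9))


@dataclass
class ObjectiveValue:
    """Function value with optional derivative information at one point."""

    fval: float = np.inf
    grad: Optional[np.ndarray] = None
    residuals: Optional[np.ndarray] = None
    residual_jacobian: Optional[np.ndarray] = None
    inner_parameters: Optional[dict] = None


class Objective:
    """Base objective. Subclasses implement ``_eval(x, orders)``.

    ``capabilities`` lists the orders the objective supports natively;
    requesting only supported orders never raises. Evaluation counters
    (``n_fval``, ``n_grad``) are part of the contract and persisted with
    optimizer runs.
    """

    mode = MODE_NLLH
    capabilities: frozenset = frozenset({ORDER_VALUE})

    def __init__(self):
        self.n_fval = 0
        self.n_grad = 0

    def __call__(self, x, order=(ORDER_VALUE,)) -> ObjectiveValue:
        orders = {order} if isinstance(order, str) else set(order)
        unsupported = orders - self.capabilities
        if unsupported:
            raise ValueError(
                f"objective does not support orders {sorted(unsupported)}"
            )
        x = np.asarray(x, dtype=float)
        if ORDER_VALUE in orders or ORDER_RES in orders:
            self.n_fval += 1
        if ORDER_GRAD in orders or ORDER_RESJAC in orders:
            self.n_grad += 1
        try:
            val = self._eval(x, orders)
        except FloatingPointError:
            return ObjectiveValue(fval=np.inf)
        if not np.isfinite(val.fval):
            val.fval = np.inf
        return val

    def _eval(self, x, orders) -> ObjectiveValue:  # pragma: no cover
        raise NotImplementedError


class FunctionObjective(Objective):
    """Objective from a scalar callable and an optional gradient callable."""

    def __init__(self, fun: Callable, grad: Optional[Callable] = None,
                 mode: str = MODE_NLLH, name: str = ""):
        super().__init__()
        self.fun = fun
        self.grad_fun = grad
        self.mode = mode
        self.name = name
        caps = {ORDER_VALUE}
        if grad is not None:
            caps.add(ORDER_GRAD)
        self.capabilities = frozenset(caps)

    def _eval(self, x, orders):
        val = ObjectiveValue()
        if ORDER_VALUE in orders:
            with np.errstate(all="ignore"):
                val.fval = float(self.fun(x))
        if ORDER_GRAD in orders:
            with np.errstate(all="ignore"):
                val.grad = np.asarray(self.grad_fun(x), dtype=float)
        return val


class ResidualObjective(Objective):
    """Vector-valued residual objective: ``fval = 0.5 * sum(r**2)``;
    the gradient is ``J^T r`` when a Jacobian is available."""

    mode = MODE_LSQ

    def __init__(self, residual_fun: Callable,
                 jacobian: Optional[Callable] = None, name: str = ""):
        super().__init__()
        self.residual_fun = residual_fun
        self.jacobian_fun = jacobian
        self.name = name
        caps = {ORDER_VALUE, ORDER_RES}
        if jacobian is not None:
            caps |= {ORDER_GRAD, ORDER_RESJAC}
        self.capabilities = frozenset(caps)

    def _eval(self, x, orders):
        val = ObjectiveValue()
        with np.errstate(all="ignore"):
            r = np.asarray(self.residual_fun(x), dtype=float)
        val.residuals = r if ORDER_RES in orders else None
        if ORDER_VALUE in orders or ORDER_RES in orders:
            val.fval = float(0.5 * np.dot(r, r))
        if ORDER_GRAD in orders or ORDER_RESJAC in orders:
            with np.errstate(all="ignore"):
                jac = np.asarray(self.jacobian_fun(x), dtype=float)
            if ORDER_RESJAC in orders:
                val.residual_jacobian = jac
            if ORDER_GRAD in orders:
                val.grad = jac.T @ r
        return val


@dataclass(frozen=True)
class FDScheme:
    """Finite-difference scheme with strictly positive per-coordinate steps."""

    kind: str = "central"
    step: float | np.ndarray = 1e-6

    def __post_init__(self):
        if self.kind not in ("forward", "backward", "central"):
            raise ValueError(f"unknown FD kind {self.kind!r}")
        if np.any(np.asarray(self.step) <= 0):
            raise ValueError("FD step must be strictly positive")


def _fval(obj, x):
    return obj(x, (ORDER_VALUE,)).fval


def _fd_component(obj, x, i, h, kind, lb, ub):
    """One FD derivative component with bound-aware scheme degradation.

    Returns (derivative, scheme_used). Central degrades to one-sided at
    bound-adjacent points so the objective is never evaluated outside bounds.
    """
    xi = x[i]
    up_ok = ub is None or xi + h <= ub[i]
    dn_ok = lb is None or xi - h >= lb[i]
    used = kind
    if kind == "central":
        if not up_ok and dn_ok:
            used = "backward"
        elif not dn_ok and up_ok:
            used = "forward"
    elif kind == "forward" and not up_ok and dn_ok:
        used = "backward"
    elif kind == "backward" and not dn_ok and up_ok:
        used = "forward"

    xp = x.copy()
    if used == "central":
        xm = x.copy()
        xp[i] = xi + h
        xm[i] = xi - h
        d = (_fval(obj, xp) - _fval(obj, xm)) / (2 * h)
    elif used == "forward":
        xp[i] = xi + h
        d = (_fval(obj, xp) - _fval(obj, x)) / h
    else:
        xp[i] = xi - h
        d = (_fval(obj, x) - _fval(obj, xp)) / (-h)
    if not np.isfinite(d):
        d = np.nan
    return d, used


def fd_gradient(obj, x, scheme: FDScheme = FDScheme(),
                lb=None, ub=None) -> np.ndarray:
    """Finite-difference gradient; non-finite components become NaN flags,
    never exceptions. Steps degrade to one-sided at bounds."""
    x = np.asarray(x, dtype=float)
    steps = np.broadcast_to(np.asarray(scheme.step, dtype=float), x.shape)
    g = np.empty_like(x)
    for i in range(x.size):
        g[i], _ = _fd_component(obj, x, i, steps[i], scheme.kind, lb, ub)
    return g


def adapt_fd_step(obj, x, candidate_steps: Optional[Sequence[float]] = None,
                  lb=None, ub=None) -> np.ndarray:
    """Per-coordinate adaptive FD step selection.

    For each coordinate, the central-difference derivative is evaluated on a
    decreasing candidate ladder; the selected step is the larger one of the
    consecutive pair minimizing ``|d(h_k) - d(h_{k+1})|`` (stability
    criterion). Ties — differences indistinguishable from round-off, as on
    exactly quadratic functions — break toward the larger step. A coordinate
    where all candidates yield non-finite derivatives is marked failed (NaN).
    """
    x = np.asarray(x, dtype=float)
    ladder = np.asarray(
        DEFAULT_FD_LADDER if candidate_steps is None else candidate_steps,
        dtype=float,
    )
    if np.any(ladder <= 0) or np.any(np.diff(ladder) >= 0):
        raise ValueError("candidate_steps must be a decreasing positive ladder")
    out = np.empty_like(x)
    for i in range(x.size):
        ds = np.array(
            [_fd_component(obj, x, i, h, "central", lb, ub)[0] for h in ladder]
        )
        diffs = np.abs(np.diff(ds))
        if not np.any(np.isfinite(diffs)):
            out[i] = np.nan
            continue
        diffs = np.where(np.isfinite(diffs), diffs, np.inf)
        dmin = float(diffs.min())
        scale = float(np.max(np.abs(ds[np.isfinite(ds)]), initial=1.0))
        tie_band = max(dmin, 1e-9 * max(scale, 1.0))
        k = int(np.argmax(diffs <= tie_band))  # first hit = largest step
        out[i] = ladder[k]
    return out


class PosteriorObjective(Objective):
    """Negative log-posterior: nllh plus per-parameter negative log prior
    densities. ``priors`` aligns with the parameter order (None = no prior);
    ``specs`` supplies scales so priors with ``applies_on='lin'`` are
    evaluated on the linear value with the appropriate change of variables
    for the gradient."""

    mode = MODE_NLP

    def __init__(self, nllh: Objective, priors: Sequence[Optional[PriorSpec]],
                 specs: Optional[Sequence[ParameterSpec]] = None):
        super().__init__()
        self.nllh = nllh
        self.priors = list(priors)
        self.specs = list(specs) if specs is not None else None
        caps = {ORDER_VALUE}
        if ORDER_GRAD in nllh.capabilities:
            caps.add(ORDER_GRAD)
        self.capabilities = frozenset(caps)

    def _prior_value_at(self, i, x_i):
        """(value v the prior sees, dv/dx_est) for coordinate i."""
        if (
            self.priors[i].applies_on == "lin"
            and self.specs is not None
            and self.specs[i].scale == SCALE_LOG10
        ):
            v = 10.0 ** x_i
            return v, _LN10 * v
        return x_i, 1.0

    def _eval(self, x, orders):
        val = self.nllh(x, orders)
        if not np.isfinite(val.fval):
            return ObjectiveValue(fval=np.inf)
        grad = None if val.grad is None else val.grad.copy()
        f = val.fval
        for i, prior in enumerate(self.priors):
            if prior is None:
                continue
            v, dv = self._prior_value_at(i, x[i])
            nld = prior.neg_log_density(v)
            if not np.isfinite(nld):
                return ObjectiveValue(fval=np.inf)
            f += nld
            if grad is not None:
                grad[i] += prior.neg_log_density_grad(v) * dv
        return ObjectiveValue(fval=f, grad=grad)


def aggregate_posterior(nllh: Objective, priors, x,
                        specs=None) -> ObjectiveValue:
    """Evaluate the negative log-posterior (nllh minus log prior densities)
    at ``x``; gradients aggregated when the nllh supplies one."""
    post = PosteriorObjective(nllh, priors, specs)
    orders = (ORDER_VALUE, ORDER_GRAD) if ORDER_GRAD in post.capabilities \
        else (ORDER_VALUE,)
    return post(x, orders)


@dataclass
class GradientCheckReport:
    """Componentwise native-vs-FD gradient comparison."""

    grad: np.ndarray
    fd: np.ndarray
    abs_err: np.ndarray
    rel_err: np.ndarray
    passed: np.ndarray
    tol: float
    notes: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return bool(np.all(self.passed))


def check_gradient(obj, x, tol: float = 1e-5, step: float = 1e-6,
                   lb=None, ub=None) -> GradientCheckReport:
    """Compare the native gradient against central finite differences
    (one-sided at bounds, noted in the report)."""
    x = np.asarray(x, dtype=float)
    grad = obj(x, (ORDER_VALUE, ORDER_GRAD)).grad
    fd = np.empty_like(x)
    notes = []
    for i in range(x.size):
        fd[i], used = _fd_component(obj, x, i, step, "central", lb, ub)
        if used != "central":
            notes.append(
                f"component {i}: switched to one-sided ({used}) at bound"
            )
    abs_err = np.abs(grad - fd)
    denom = np.maximum(np.abs(fd), np.abs(grad))
    rel_err = abs_err / np.where(denom > 0, denom, 1.0)
    passed = (rel_err <= tol) | (abs_err <= tol)
    return GradientCheckReport(grad, fd, abs_err, rel_err, passed, tol, notes)


def fd_hessian(obj, x, step: float = 1e-4, lb=None, ub=None) -> np.ndarray:
    """FD-of-gradient Hessian (central over each coordinate), symmetrized.
    Falls back to FD-of-FD when the objective has no native gradient."""
    x = np.asarray(x, dtype=float)
    n = x.size

    if ORDER_GRAD in obj.capabilities:
        def grad_at(y):
            return obj(y, (ORDER_VALUE, ORDER_GRAD)).grad
    else:
        def grad_at(y):
            return fd_gradient(obj, y, FDScheme("central", step), lb, ub)

    H = np.empty((n, n))
    for i in range(n):
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        H[i] = (grad_at(xp) - grad_at(xm)) / (2 * step)
    return 0.5 * (H + H.T)
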