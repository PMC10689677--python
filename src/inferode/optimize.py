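"""Multi-start globalized optimization.

Local optimization is delegated to a bound-constrained quasi-Newton method
(L-BFGS-B) behind the ``local_minimize`` contract; the normative surface is
the contract, not the inner solver. The multi-start strategy samples
startpoints within bounds, runs one local optimization per start, and
returns runs sorted ascending by final value (failed starts recorded and
sorted last, never dropped) — the waterfall surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize as scipy_minimize

from .engine import EngineSpec, TaskFailure, map_parallel
from .objective import FDScheme, ORDER_GRAD, ORDER_VALUE, fd_gradient
from .problem import Problem, sample_startpoints

STATUS_CONVERGED = "converged"
STATUS_MAX_EVALS = "max_evals"
STATUS_FAILED = "failed"

DEFAULT_OPTIONS = {
    "maxiter": 1000,
    "gtol": 1e-9,
    "ftol": 1e-14,
    "fd_step": 1e-6,
}


@dataclass
class OptimizerRun:
    """One local-optimizer run (vectors full-length, estimation scale)."""

    start_index: int
    x0: np.ndarray
    x: np.ndarray
    fval: float
    grad_norm: float = np.nan
    n_fval: int = 0
    n_grad: int = 0
    exit_status: str = STATUS_CONVERGED
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.exit_status != STATUS_FAILED and np.isfinite(self.fval)


@dataclass
class OptimizeResult:
    """Runs sorted ascending by fval, failed runs last; stable tie-break by
    start index."""

    runs: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def sort(self):
        self.runs.sort(
            key=lambda r: (not r.ok, r.fval if r.ok else np.inf,
                           r.start_index)
        )

    @property
    def best(self) -> Optional[OptimizerRun]:
        if self.runs and self.runs[0].ok:
            return self.runs[0]
        return None

    @property
    def n_failed(self) -> int:
        return sum(not r.ok for r in self.runs)

    def fvals(self) -> np.ndarray:
        return np.array([r.fval for r in self.runs if r.ok])


def _objective_callable(objective, lb, ub, fd_step):
    """(fval, grad) callable for the inner solver; FD fallback when the
    objective has no native gradient."""
    has_grad = ORDER_GRAD in objective.capabilities

    def fun(x):
        if has_grad:
            val = objective(x, (ORDER_VALUE, ORDER_GRAD))
            g = val.grad
        else:
            val = objective(x, (ORDER_VALUE,))
            g = fd_gradient(objective, x, FDScheme("central", fd_step),
                            lb, ub)
        f = val.fval
        if not np.isfinite(f):
            # large finite sentinel: L-BFGS-B line search cannot digest inf
            return 1e100, np.zeros_like(x)
        g = np.where(np.isfinite(g), g, 0.0)
        return f, g

    return fun


def local_minimize(objective, x0, lb, ub, options: Optional[dict] = None,
                   start_index: int = 0) -> OptimizerRun:
    """Bound-constrained local minimization from ``x0``.

    Never raises on objective failure: a non-finite start value or solver
    exception yields a run with ``exit_status='failed'``. The returned value
    never exceeds the start value.
    """
    opts = {**DEFAULT_OPTIONS, **(options or {})}
    x0 = np.asarray(x0, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n0_f, n0_g = objective.n_fval, objective.n_grad

    f0 = objective(x0, (ORDER_VALUE,)).fval
    if not np.isfinite(f0):
        return OptimizerRun(
            start_index=start_index, x0=x0, x=x0.copy(), fval=np.inf,
            exit_status=STATUS_FAILED,
            message="objective non-finite at startpoint",
            n_fval=objective.n_fval - n0_f,
        )

    fun = _objective_callable(objective, lb, ub, opts["fd_step"])
    try:
        res = scipy_minimize(
            fun,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(lb, ub)),
            options={
                "maxiter": opts["maxiter"],
                "gtol": opts["gtol"],
                "ftol": opts["ftol"],
            },
        )
    except Exception as err:  # noqa: BLE001 - failures become records
        return OptimizerRun(
            start_index=start_index, x0=x0, x=x0.copy(), fval=np.inf,
            exit_status=STATUS_FAILED, message=f"{type(err).__name__}: {err}",
            n_fval=objective.n_fval - n0_f,
            n_grad=objective.n_grad - n0_g,
        )

    x = np.clip(res.x, lb, ub)
    fval = objective(x, (ORDER_VALUE,)).fval
    if fval > f0:  # never return worse than the start
        x, fval = x0.copy(), f0
    if res.success:
        status = STATUS_CONVERGED
    elif "ITERATIONS" in str(res.message).upper():
        status = STATUS_MAX_EVALS
    else:
        status = STATUS_FAILED if not np.isfinite(fval) else STATUS_MAX_EVALS
    grad_norm = float(np.linalg.norm(fun(x)[1]))
    return OptimizerRun(
        start_index=start_index,
        x0=x0,
        x=x,
        fval=float(fval),
        grad_norm=grad_norm,
        n_fval=objective.n_fval - n0_f,
        n_grad=objective.n_grad - n0_g,
        exit_status=status,
        message=str(res.message),
    )


def _multistart_task(payload, seed):
    """Top-level task (picklable for the multiprocess engine)."""
    problem, x0_free, options, start_index = payload
    run = local_minimize(
        _FreeObjective(problem), x0_free, problem.lb_free, problem.ub_free,
        options=options, start_index=start_index,
    )
    run.x0 = problem.insert_fixed(run.x0)
    run.x = problem.insert_fixed(run.x)
    return run


class _FreeObjective:
    """Objective view on the free subspace of a problem."""

    def __init__(self, problem: Problem):
        self.problem = problem

    @property
    def capabilities(self):
        return self.problem.objective.capabilities

    @property
    def n_fval(self):
        return self.problem.objective.n_fval

    @property
    def n_grad(self):
        return self.problem.objective.n_grad

    def __call__(self, x_free, order=(ORDER_VALUE,)):
        return self.problem.objective_free(x_free, order)


def minimize_multistart(problem: Problem, n_starts: int = 100,
                        seed: int = 0, optimizer: str = "lbfgsb",
                        options: Optional[dict] = None,
                        startpoint_method: str = "latin-hypercube",
                        engine: Optional[EngineSpec] = None,
                        startpoints: Optional[np.ndarray] = None
                        ) -> OptimizeResult:
    """Multi-start local optimization; deterministic given ``seed`` and
    independent of the execution engine."""
    if optimizer != "lbfgsb":
        raise ValueError(
            f"unknown optimizer {optimizer!r}; 'lbfgsb' ships by default"
        )
    if startpoints is None:
        startpoints = sample_startpoints(
            problem, n_starts, method=startpoint_method, seed=seed
        ).points
    payloads = [
        (problem, startpoints[i], options, i) for i in range(n_starts)
    ]
    outputs = map_parallel(_multistart_task, payloads, engine=engine,
                           seed_root=seed)
    runs = []
    for i, out in enumerate(outputs):
        if isinstance(out, TaskFailure):
            runs.append(OptimizerRun(
                start_index=i,
                x0=problem.insert_fixed(startpoints[i]),
                x=problem.insert_fixed(startpoints[i]),
                fval=np.inf,
                exit_status=STATUS_FAILED,
                message=f"{out.exception_type}: {out.message}",
            ))
        else:
            runs.append(out)
    result = OptimizeResult(
        runs=runs,
        provenance={
            "seed": seed,
            "optimizer": optimizer,
            "n_starts": n_starts,
            "startpoint_method": startpoint_method,
            "options": dict(options or {}),
        },
    )
    result.sort()
    return result


def waterfall_data(result: OptimizeResult) -> list[tuple[int, float]]:
    """Sorted (rank, fval) pairs over non-failed runs — the waterfall."""
    if not result.runs:
        raise ValueError("empty optimization result")
    return [(i, float(f)) for i, f in enumerate(result.fvals())]
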