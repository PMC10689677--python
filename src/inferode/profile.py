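"""Optimization-based profile likelihood.

For one parameter at a time, the profiler walks away from the optimum in
both directions with adaptive steps, fixing the profiled parameter and
re-optimizing all others (warm-started from the neighboring profile point),
until the likelihood ratio ``exp(fval_min - fval)`` drops below a cutoff or
a bound is reached. Confidence intervals come from the chi-square threshold
rule, with endpoints interpolated linearly in log-ratio (near-exact for
locally quadratic objectives). The profile posterior is the same machinery
applied to a negative-log-posterior objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import chi2

from .engine import EngineSpec, TaskFailure, map_parallel
from .optimize import OptimizerRun, local_minimize, _FreeObjective
from .problem import Problem

DEFAULT_PROFILE_OPTIONS = {
    "ratio_min": 0.03,       # walk past the 95% cutoff (0.1465)
    "target_delta": 0.2,     # aimed fval change per step
    "min_step": 1e-4,        # on estimation scale
    "max_step": 1.0,
    "max_points": 100,       # per leg
    "optimizer_options": None,
}


@dataclass
class ProfilePath:
    """Ordered profile points for one parameter, ascending in the profiled
    coordinate; ``fval_min`` is the global optimum's value, so the optimum
    point has ratio 1."""

    parameter_index: int
    parameter_id: str
    points: np.ndarray          # (n_points, dim_full), estimation scale
    fvals: np.ndarray
    fval_min: float
    status: dict = field(default_factory=dict)

    @property
    def parameter_values(self) -> np.ndarray:
        return self.points[:, self.parameter_index]

    @property
    def ratios(self) -> np.ndarray:
        return np.exp(self.fval_min - self.fvals)


def next_step(step: float, last_delta: float, options: dict) -> float:
    """Adaptive step control: grow geometrically when the last fval change
    was below ``target_delta/2``, shrink when above ``2*target_delta``,
    clipped to ``[min_step, max_step]``. Deterministic."""
    target = options["target_delta"]
    if abs(last_delta) < target / 2:
        step = step * 2.0
    elif abs(last_delta) > 2 * target:
        step = step * 0.5
    return float(np.clip(step, options["min_step"], options["max_step"]))


def _walk_leg(problem: Problem, x_opt: np.ndarray, f_opt: float, index: int,
              direction: int, opts: dict):
    """One profile leg; returns (points, fvals, status string)."""
    lb = problem.lb_full[index]
    ub = problem.ub_full[index]
    bound = ub if direction > 0 else lb
    span = ub - lb
    step = float(np.clip(span / 50.0, opts["min_step"], opts["max_step"]))
    points, fvals = [], []
    cur_x, cur_f = x_opt.copy(), f_opt
    status = "ratio_min"
    n_fail = 0
    n_tries = 0
    while len(points) < opts["max_points"] and n_tries < 4 * opts["max_points"]:
        n_tries += 1
        val = cur_x[index] + direction * step
        at_bound = (direction > 0 and val >= bound) or (
            direction < 0 and val <= bound
        )
        if at_bound:
            val = bound
        sub = problem.fix_parameters([index], [val])
        warm = sub.remove_fixed(cur_x)
        warm[:] = np.clip(warm, sub.lb_free, sub.ub_free)
        if sub.dim_free > 0:
            run = local_minimize(
                _FreeObjective(sub), warm, sub.lb_free, sub.ub_free,
                options=opts["optimizer_options"],
            )
            ok = run.ok
            x_new = sub.insert_fixed(run.x) if ok else None
            f_new = run.fval
        else:
            full = sub.insert_fixed(np.empty(0))
            f_new = sub.objective(full).fval
            ok = np.isfinite(f_new)
            x_new = full
        if not ok:
            n_fail += 1
            step = max(step * 0.5, opts["min_step"])
            if n_fail >= 5 or step <= opts["min_step"]:
                status = "failed"
                break
            continue
        n_fail = 0
        delta = f_new - cur_f
        # overshoot: retry the step at reduced size for accurate
        # threshold bracketing, unless already at the minimum step
        if (
            abs(delta) > 2 * opts["target_delta"]
            and not at_bound
            and step > opts["min_step"]
        ):
            step = max(step * 0.5, opts["min_step"])
            continue
        points.append(x_new)
        fvals.append(f_new)
        cur_x, cur_f = x_new, f_new
        if np.exp(f_opt - f_new) < opts["ratio_min"]:
            status = "ratio_min"
            break
        if at_bound:
            status = "bound"
            break
        step = next_step(step, delta, opts)
    else:
        status = "max_points"
    return points, fvals, status


def compute_profile(problem: Problem, best: OptimizerRun, index: int,
                    options: Optional[dict] = None) -> ProfilePath:
    """Profile parameter ``index`` (must be estimated, not fixed) around a
    converged run ``best``; both legs merged in ascending parameter order."""
    if problem.fixed_mask[index]:
        raise ValueError(
            f"parameter {problem.ids[index]!r} is fixed; cannot profile"
        )
    opts = {**DEFAULT_PROFILE_OPTIONS, **(options or {})}
    x_opt = np.asarray(best.x, dtype=float)
    f_opt = float(best.fval)
    down_pts, down_f, down_status = _walk_leg(
        problem, x_opt, f_opt, index, -1, opts
    )
    up_pts, up_f, up_status = _walk_leg(problem, x_opt, f_opt, index, +1, opts)
    points = list(reversed(down_pts)) + [x_opt] + up_pts
    fvals = list(reversed(down_f)) + [f_opt] + up_f
    return ProfilePath(
        parameter_index=index,
        parameter_id=problem.ids[index],
        points=np.array(points),
        fvals=np.array(fvals, dtype=float),
        fval_min=f_opt,
        status={"down": down_status, "up": up_status},
    )


@dataclass
class ProfileCI:
    """Ratio-threshold confidence interval; a side is open when the path
    hit a bound before crossing the threshold."""

    lower: float
    upper: float
    open_lower: bool
    open_upper: bool
    confidence_level: float
    ratio_threshold: float


def ratio_threshold(confidence_level: float) -> float:
    """Likelihood-ratio cutoff ``exp(-chi2_1(level)/2)``; 0.1465 at 95%."""
    return float(np.exp(-chi2.ppf(confidence_level, df=1) / 2))


def profile_ci(path: ProfilePath,
               confidence_level: float = 0.95) -> ProfileCI:
    """Interval where the profile ratio stays above the chi-square cutoff;
    endpoints by linear interpolation of the log-ratio between bracketing
    points."""
    thr = ratio_threshold(confidence_level)
    log_thr = np.log(thr)
    vals = path.parameter_values
    logr = path.fval_min - path.fvals  # log ratios, max 0 at the optimum
    k_opt = int(np.argmax(logr))

    def interp(i_in, i_out):
        """Crossing between an inside point (logr >= thr) and outside."""
        x1, x2 = vals[i_in], vals[i_out]
        y1, y2 = logr[i_in], logr[i_out]
        if y2 == y1:
            return x2
        t = (log_thr - y1) / (y2 - y1)
        return float(x1 + t * (x2 - x1))

    lower, upper = vals[0], vals[-1]
    open_lower = open_upper = True
    for i in range(k_opt, 0, -1):
        if logr[i] >= log_thr > logr[i - 1]:
            lower = interp(i, i - 1)
            open_lower = False
            break
    for i in range(k_opt, len(vals) - 1):
        if logr[i] >= log_thr > logr[i + 1]:
            upper = interp(i, i + 1)
            open_upper = False
            break
    return ProfileCI(
        lower=float(lower), upper=float(upper),
        open_lower=open_lower, open_upper=open_upper,
        confidence_level=confidence_level, ratio_threshold=thr,
    )


def _profile_task(payload, seed):
    problem, best, index, options = payload
    return compute_profile(problem, best, index, options)


def compute_profiles(problem: Problem, best: OptimizerRun,
                     indices=None, options: Optional[dict] = None,
                     engine: Optional[EngineSpec] = None
                     ) -> dict[str, ProfilePath]:
    """Profile several parameters (default: all free), optionally in
    parallel; returns a dict keyed by parameter id."""
    if indices is None:
        indices = list(problem.free_indices)
    payloads = [(problem, best, int(i), options) for i in indices]
    outputs = map_parallel(_profile_task, payloads, engine=engine)
    profiles = {}
    for i, out in zip(indices, outputs):
        if isinstance(out, TaskFailure):
            raise RuntimeError(
                f"profile of parameter {problem.ids[int(i)]!r} failed: "
                f"{out.message}"
            )
        profiles[problem.ids[int(i)]] = out
    return profiles
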