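"""Estimation problem definition.

A :class:`Problem` binds an objective function to an ordered parameter space
with bounds, scales (linear or log10), optional priors, and a fixing mask.
All optimizers, profilers and samplers operate on the *estimation scale*
(log10-transformed where requested) and on the *free* subspace; fixed values
are re-inserted before every objective evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

SCALE_LIN = "lin"
SCALE_LOG10 = "log10"
SCALES = (SCALE_LIN, SCALE_LOG10)

PRIOR_KINDS = ("uniform", "normal", "log-normal")

_LN10 = np.log(10.0)


class ConfigurationError(ValueError):
    """Raised when a problem or sampler configuration is unusable."""


@dataclass(frozen=True)
class PriorSpec:
    """Parameter prior: ``uniform(a, b)``, ``normal(mean, sd)`` or
    ``log-normal(mu, sd)`` (mu, sd of the underlying normal).

    ``applies_on`` selects whether the density is taken over the linear-scale
    or the estimation-scale parameter value.
    """

    kind: str
    hyperparameters: tuple[float, float]
    applies_on: str = "estimation-scale"

    def __post_init__(self):
        if self.kind not in PRIOR_KINDS:
            raise ConfigurationError(f"unknown prior kind {self.kind!r}")
        if self.applies_on not in ("lin", "estimation-scale"):
            raise ConfigurationError(
                f"unknown prior applies_on {self.applies_on!r}"
            )
        a, b = self.hyperparameters
        if self.kind == "uniform":
            if not b > a:
                raise ConfigurationError("uniform prior requires b > a")
        elif b <= 0:
            raise ConfigurationError(
                f"{self.kind} prior requires positive dispersion, got {b}"
            )

    def neg_log_density(self, v: float) -> float:
        a, b = self.hyperparameters
        if self.kind == "uniform":
            if a <= v <= b:
                return float(np.log(b - a))
            return np.inf
        if self.kind == "normal":
            return float(0.5 * np.log(2 * np.pi * b**2) + 0.5 * ((v - a) / b) ** 2)
        # log-normal
        if v <= 0:
            return np.inf
        lv = np.log(v)
        return float(
            lv + 0.5 * np.log(2 * np.pi * b**2) + 0.5 * ((lv - a) / b) ** 2
        )

    def neg_log_density_grad(self, v: float) -> float:
        """d(-log p)/dv; zero inside the support of a uniform prior."""
        a, b = self.hyperparameters
        if self.kind == "uniform":
            return 0.0
        if self.kind == "normal":
            return float((v - a) / b**2)
        if v <= 0:
            return np.nan
        lv = np.log(v)
        return float(1.0 / v + (lv - a) / (b**2 * v))


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter: bounds live on the estimation scale, the nominal
    value on the linear scale (converted on load, matching the table format).
    """

    id: str
    scale: str = SCALE_LIN
    lower_bound: float = -np.inf
    upper_bound: float = np.inf
    nominal: float = np.nan
    estimate: bool = True
    prior: Optional[PriorSpec] = None

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ConfigurationError(
                f"parameter {self.id!r}: unknown scale {self.scale!r}"
            )
        if self.estimate and not self.lower_bound < self.upper_bound:
            raise ConfigurationError(
                f"parameter {self.id!r}: lower_bound must be < upper_bound"
            )
        if (
            self.scale == SCALE_LOG10
            and np.isfinite(self.nominal)
            and self.nominal <= 0
        ):
            raise ConfigurationError(
                f"parameter {self.id!r}: log10 scale requires positive "
                f"nominal value, got {self.nominal}"
            )

    @property
    def nominal_est(self) -> float:
        """Nominal value on the estimation scale."""
        if self.scale == SCALE_LOG10:
            return float(np.log10(self.nominal))
        return float(self.nominal)


def _scales(spec: Sequence) -> list[str]:
    return [s.scale if isinstance(s, ParameterSpec) else s for s in spec]


def to_estimation_scale(x_lin, spec) -> np.ndarray:
    """Map linear-scale values to the estimation scale (log10 where set)."""
    x_lin = np.asarray(x_lin, dtype=float)
    out = x_lin.copy()
    for i, sc in enumerate(_scales(spec)):
        if sc == SCALE_LOG10:
            if x_lin[i] <= 0:
                pid = (
                    spec[i].id
                    if isinstance(spec[i], ParameterSpec)
                    else f"#{i}"
                )
                raise ValueError(
                    f"parameter {pid}: log10 scale requires a positive "
                    f"value, got {x_lin[i]}"
                )
            out[i] = np.log10(x_lin[i])
    return out


def from_estimation_scale(x_est, spec) -> np.ndarray:
    """Inverse of :func:`to_estimation_scale`."""
    x_est = np.asarray(x_est, dtype=float)
    out = x_est.copy()
    for i, sc in enumerate(_scales(spec)):
        if sc == SCALE_LOG10:
            out[i] = 10.0 ** x_est[i]
    return out


def scale_gradient_chain(x_est, spec) -> np.ndarray:
    """d x_lin / d x_est, per coordinate (ln10 * 10**x for log10, else 1)."""
    x_est = np.asarray(x_est, dtype=float)
    out = np.ones_like(x_est)
    for i, sc in enumerate(_scales(spec)):
        if sc == SCALE_LOG10:
            out[i] = _LN10 * 10.0 ** x_est[i]
    return out


class Problem:
    """Parameter space bound to an objective; the unit of all analyses.

    Parameters with ``estimate=False`` are fixed at their nominal value;
    additional parameters can be fixed with :meth:`fix_parameters` (used by
    the profile walker). Objective evaluations always receive a full-length
    estimation-scale vector after re-insertion of fixed values.
    """

    def __init__(
        self,
        objective,
        parameters: Sequence[ParameterSpec],
        fixed_mask: Optional[np.ndarray] = None,
        fixed_values: Optional[np.ndarray] = None,
    ):
        self.objective = objective
        self.parameters = list(parameters)
        ids = [p.id for p in self.parameters]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigurationError(f"duplicate parameter ids: {dup}")
        n = len(self.parameters)
        if fixed_mask is None:
            fixed_mask = np.array([not p.estimate for p in self.parameters])
        self.fixed_mask = np.asarray(fixed_mask, dtype=bool).copy()
        if fixed_values is None:
            fixed_values = np.array(
                [
                    p.nominal_est if m else np.nan
                    for p, m in zip(self.parameters, self.fixed_mask)
                ]
            )
        self.fixed_values = np.asarray(fixed_values, dtype=float).copy()
        if self.fixed_mask.shape != (n,) or self.fixed_values.shape != (n,):
            raise ConfigurationError("fixed mask/values length mismatch")

    # -- dimensions ------------------------------------------------------
    @property
    def dim_full(self) -> int:
        return len(self.parameters)

    @property
    def dim_free(self) -> int:
        return int(self.dim_full - self.fixed_mask.sum())

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.parameters]

    @property
    def scales(self) -> list[str]:
        return [p.scale for p in self.parameters]

    @property
    def free_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.fixed_mask)

    @property
    def lb_full(self) -> np.ndarray:
        return np.array([p.lower_bound for p in self.parameters])

    @property
    def ub_full(self) -> np.ndarray:
        return np.array([p.upper_bound for p in self.parameters])

    @property
    def lb_free(self) -> np.ndarray:
        return self.lb_full[self.free_indices]

    @property
    def ub_free(self) -> np.ndarray:
        return self.ub_full[self.free_indices]

    @property
    def free_ids(self) -> list[str]:
        return [self.parameters[i].id for i in self.free_indices]

    def nominal_est_full(self) -> np.ndarray:
        return np.array([p.nominal_est for p in self.parameters])

    def nominal_est_free(self) -> np.ndarray:
        return self.nominal_est_full()[self.free_indices]

    # -- fixed-value plumbing -------------------------------------------
    def insert_fixed(self, x_free) -> np.ndarray:
        x_free = np.asarray(x_free, dtype=float)
        if x_free.shape != (self.dim_free,):
            raise ValueError(
                f"expected free vector of length {self.dim_free}, "
                f"got shape {x_free.shape}"
            )
        x = self.fixed_values.copy()
        x[self.free_indices] = x_free
        return x

    def remove_fixed(self, x_full) -> np.ndarray:
        x_full = np.asarray(x_full, dtype=float)
        if x_full.shape != (self.dim_full,):
            raise ValueError(
                f"expected full vector of length {self.dim_full}, "
                f"got shape {x_full.shape}"
            )
        return x_full[self.free_indices].copy()

    def fix_parameters(self, indices, values_est) -> "Problem":
        """Return a new Problem with additional parameters fixed
        (values on the estimation scale)."""
        mask = self.fixed_mask.copy()
        vals = self.fixed_values.copy()
        for i, v in zip(np.atleast_1d(indices), np.atleast_1d(values_est)):
            mask[int(i)] = True
            vals[int(i)] = float(v)
        return Problem(self.objective, self.parameters, mask, vals)

    # -- evaluation ------------------------------------------------------
    def objective_free(self, x_free, order=("value",)):
        """Evaluate the objective on a free vector; gradient reduced to the
        free coordinates."""
        val = self.objective(self.insert_fixed(x_free), order)
        if val.grad is not None:
            val.grad = val.grad[self.free_indices]
        return val

    def __repr__(self):
        return (
            f"Problem(dim_full={self.dim_full}, dim_free={self.dim_free}, "
            f"ids={self.ids})"
        )


@dataclass
class StartpointSet:
    """Multi-start startpoints on the estimation scale, one row per start."""

    points: np.ndarray
    method: str
    seed: int


STARTPOINT_METHODS = ("uniform", "latin-hypercube")


def sample_startpoints(
    problem: Problem,
    n_starts: int,
    method: str = "latin-hypercube",
    seed: int = 0,
) -> StartpointSet:
    """Sample startpoints within the free bounds.

    Latin hypercube places, per dimension, exactly one point uniformly inside
    each of ``n_starts`` equal-width strata, with independent per-dimension
    stratum permutations. Deterministic given ``seed``.
    """
    if n_starts < 1:
        raise ConfigurationError("n_starts must be >= 1")
    if method not in STARTPOINT_METHODS:
        raise ConfigurationError(f"unknown startpoint method {method!r}")
    lb, ub = problem.lb_free, problem.ub_free
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ConfigurationError(
            "startpoint sampling requires finite bounds on all free parameters"
        )
    rng = np.random.default_rng(seed)
    d = problem.dim_free
    if method == "uniform":
        pts = rng.uniform(lb, ub, size=(n_starts, d))
    else:
        pts = np.empty((n_starts, d))
        for j in range(d):
            perm = rng.permutation(n_starts)
            u = rng.uniform(size=n_starts)
            pts[:, j] = lb[j] + (perm + u) * (ub[j] - lb[j]) / n_starts
    return StartpointSet(points=pts, method=method, seed=seed)
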