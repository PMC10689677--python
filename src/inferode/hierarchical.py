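"""Hierarchical decomposition of the Gaussian objective.

Observation-layer parameters — offsets ``b``, scalings ``s`` and noise
standard deviations ``sigma`` — do not affect the model dynamics, only the
observation function ``b + s * y``. For fixed dynamic (outer) parameters the
optimal inner values have closed forms: ``(b, s)`` solve a weighted linear
least-squares problem and ``sigma`` is the root-mean-square residual. The
hierarchical objective therefore simulates once per outer point, solves the
inner problem analytically, and returns the likelihood at the inner optimum —
an outer problem of strictly lower dimension with the same optimal value as
the joint formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .models import OdeObjective, SimulationError, SRC_CONST
from .objective import Objective, ObjectiveValue, ORDER_VALUE
from .problem import from_estimation_scale

SIGMA_FLOOR = 1e-10


class DegenerateGroupError(ValueError):
    """Inner normal equations singular (e.g. all-zero simulation)."""


def solve_inner_scaling(sim, data, weights=None) -> float:
    """Exact minimizer of ``sum w (data - s*sim)**2`` over the scaling s:
    ``s* = sum(w*data*sim) / sum(w*sim**2)``."""
    sim = np.asarray(sim, dtype=float)
    data = np.asarray(data, dtype=float)
    w = np.ones_like(sim) if weights is None else np.asarray(weights, float)
    denom = np.sum(w * sim**2)
    if denom <= 0:
        raise DegenerateGroupError(
            "scaling unidentifiable: sum(w * sim**2) == 0"
        )
    return float(np.sum(w * data * sim) / denom)


def solve_inner_offset_scaling(sim, data, weights=None) -> tuple[float, float]:
    """Exact minimizer ``(b*, s*)`` of ``sum w (data - b - s*sim)**2`` via
    the 2x2 weighted normal equations."""
    sim = np.asarray(sim, dtype=float)
    data = np.asarray(data, dtype=float)
    w = np.ones_like(sim) if weights is None else np.asarray(weights, float)
    sw = np.sum(w)
    sx = np.sum(w * sim)
    sxx = np.sum(w * sim**2)
    sy = np.sum(w * data)
    sxy = np.sum(w * sim * data)
    det = sw * sxx - sx**2
    if det <= 0 or not np.isfinite(det):
        raise DegenerateGroupError(
            "offset+scaling unidentifiable: singular normal equations "
            "(constant simulation?)"
        )
    b = (sxx * sy - sx * sxy) / det
    s = (sw * sxy - sx * sy) / det
    return float(b), float(s)


def solve_inner_offset(sim, data, s: float = 1.0, weights=None) -> float:
    """Exact minimizer of ``sum w (data - b - s*sim)**2`` over the offset b:
    the weighted mean of ``data - s*sim``."""
    sim = np.asarray(sim, dtype=float)
    data = np.asarray(data, dtype=float)
    w = np.ones_like(sim) if weights is None else np.asarray(weights, float)
    return float(np.sum(w * (data - s * sim)) / np.sum(w))


def solve_inner_sigma(sim, data, b: float = 0.0, s: float = 1.0) -> float:
    """Exact minimizer of the Gaussian nllh over sigma given residuals:
    ``sigma* = sqrt(mean((data - b - s*sim)**2))``. Zero residuals yield
    ``sigma* = 0``; callers clamp before entering log terms."""
    sim = np.asarray(sim, dtype=float)
    data = np.asarray(data, dtype=float)
    if sim.size < 1:
        raise ValueError("sigma group needs at least one measurement")
    r = data - b - s * sim
    return float(np.sqrt(np.mean(r**2)))


@dataclass(frozen=True)
class InnerGroup:
    """Rows (global measurement indices) sharing one set of inner roles."""

    group_id: str
    roles: frozenset          # subset of {"offset", "scaling", "noise"}
    row_indices: tuple
    offset_index: Optional[int] = None    # x index of b, if inner
    scaling_index: Optional[int] = None   # x index of s, if inner
    sigma_index: Optional[int] = None     # x index of sigma, if inner


@dataclass
class InnerProblem:
    """Grouping of measurements by shared inner parameters. The sequential
    structure (b, s solved before sigma) is enforced by the objective."""

    scaling_groups: list = field(default_factory=list)
    sigma_groups: list = field(default_factory=list)
    inner_ids: list = field(default_factory=list)

    def validate(self, n_rows: int):
        for groups, roles in (
            (self.scaling_groups, "offset/scaling"),
            (self.sigma_groups, "noise"),
        ):
            seen = {}
            for g in groups:
                for i in g.row_indices:
                    if i in seen:
                        raise ValueError(
                            f"measurement row {i} belongs to two {roles} "
                            f"groups ({seen[i]} and {g.group_id})"
                        )
                    seen[i] = g.group_id


def build_inner_problem(base: OdeObjective, inner_ids) -> InnerProblem:
    """Derive the inner-problem grouping from a joint objective's per-row
    parameter sources: rows sharing inner offset/scaling (resp. sigma)
    indices form one group per role."""
    inner_set = {base.x_ids.index(pid) for pid in inner_ids}
    scaling_map: dict[tuple, list] = {}
    sigma_map: dict[int, list] = {}
    row = 0
    for cond in base.conditions:
        for i in range(cond.n_rows):
            b_idx = cond.offset[i].index
            s_idx = cond.scaling[i].index
            g_idx = cond.sigma[i].index
            b_in = b_idx if b_idx in inner_set else None
            s_in = s_idx if s_idx in inner_set else None
            if b_in is not None or s_in is not None:
                scaling_map.setdefault((b_in, s_in), []).append(row)
            if g_idx in inner_set:
                sigma_map.setdefault(g_idx, []).append(row)
            row += 1
    scaling_groups = []
    for (b_in, s_in), rows in scaling_map.items():
        roles = set()
        if b_in is not None:
            roles.add("offset")
        if s_in is not None:
            roles.add("scaling")
        name = "+".join(
            base.x_ids[i] for i in (b_in, s_in) if i is not None
        )
        scaling_groups.append(InnerGroup(
            group_id=name, roles=frozenset(roles), row_indices=tuple(rows),
            offset_index=b_in, scaling_index=s_in,
        ))
    sigma_groups = [
        InnerGroup(group_id=base.x_ids[g_idx], roles=frozenset({"noise"}),
                   row_indices=tuple(rows), sigma_index=g_idx)
        for g_idx, rows in sigma_map.items()
    ]
    prob = InnerProblem(
        scaling_groups=scaling_groups,
        sigma_groups=sigma_groups,
        inner_ids=list(inner_ids),
    )
    prob.validate(sum(c.n_rows for c in base.conditions))
    return prob


class HierarchicalOdeObjective(Objective):
    """Objective over the outer (dynamic) parameters only: each evaluation
    simulates the model, solves offsets/scalings by linear least squares,
    then noise sds in closed form, and returns the Gaussian nllh at the
    inner optimum. Inner values are reported via
    ``ObjectiveValue.inner_parameters``. Gradients are left to finite
    differences in the caller."""

    def __init__(self, base: OdeObjective, inner: InnerProblem,
                 outer_ids, outer_scales):
        super().__init__()
        self.base = base
        self.inner = inner
        self.x_ids = list(outer_ids)
        self.scales = list(outer_scales)
        self.capabilities = frozenset({ORDER_VALUE})
        self._outer_to_full = [base.x_ids.index(pid) for pid in outer_ids]
        self._inner_indices = [base.x_ids.index(pid) for pid in inner.inner_ids]

    def _embed(self, outer_lin) -> np.ndarray:
        """Full linear-scale vector; inner slots get placeholders (their
        values never reach the likelihood — every row referencing an inner
        parameter has it replaced by the solved optimum)."""
        x_lin = np.ones(len(self.base.x_ids))
        x_lin[self._outer_to_full] = outer_lin
        return x_lin

    def _inner_pass(self, outer_est):
        outer_lin = from_estimation_scale(
            np.asarray(outer_est, float), self.scales
        )
        x_lin = self._embed(outer_lin)
        y_all, data_all, b_all, s_all, sig_all = [], [], [], [], []
        row_meta = []
        for cond in self.base.conditions:
            res = self.base._simulate_condition(cond, x_lin, False)
            _, y, sig = self.base.row_values(cond, res, x_lin)
            b = np.array([src.resolve(x_lin) for src in cond.offset])
            s = np.array([src.resolve(x_lin) for src in cond.scaling])
            y_all.append(y)
            data_all.append(cond.measurements)
            b_all.append(b)
            s_all.append(s)
            sig_all.append(sig)
            for i in range(cond.n_rows):
                row_meta.append((cond, i))
        y = np.concatenate(y_all)
        data = np.concatenate(data_all)
        b = np.concatenate(b_all)
        s = np.concatenate(s_all)
        sig = np.concatenate(sig_all)

        inner_values: dict[str, float] = {}
        for g in self.inner.scaling_groups:
            rows = np.array(g.row_indices)
            if g.offset_index is not None and g.scaling_index is not None:
                bv, sv = solve_inner_offset_scaling(y[rows], data[rows])
                b[rows] = bv
                s[rows] = sv
                inner_values[self.base.x_ids[g.offset_index]] = bv
                inner_values[self.base.x_ids[g.scaling_index]] = sv
            elif g.scaling_index is not None:
                sv = solve_inner_scaling(y[rows], data[rows] - b[rows])
                s[rows] = sv
                inner_values[self.base.x_ids[g.scaling_index]] = sv
            else:
                # offset-only group; rows may carry fixed per-row scalings
                bv = float(np.mean(data[rows] - s[rows] * y[rows]))
                b[rows] = bv
                inner_values[self.base.x_ids[g.offset_index]] = bv
        sim = b + s * y
        for g in self.inner.sigma_groups:
            rows = np.array(g.row_indices)
            sv = solve_inner_sigma(sim[rows], data[rows])
            sv = max(sv, SIGMA_FLOOR)
            sig[rows] = sv
            inner_values[self.base.x_ids[g.sigma_index]] = sv
        return sim, data, sig, inner_values, row_meta

    def _eval(self, x, orders):
        try:
            sim, data, sig, inner_values, _ = self._inner_pass(x)
        except (SimulationError, DegenerateGroupError) as err:
            return ObjectiveValue(
                fval=np.inf, inner_parameters={"error": str(err)}
            )
        if np.any(sig <= 0):
            return ObjectiveValue(
                fval=np.inf,
                inner_parameters={"error": "non-positive noise sd"},
            )
        r = (data - sim) / sig
        fval = float(0.5 * np.sum(np.log(2 * np.pi * sig**2) + r**2))
        return ObjectiveValue(fval=fval, inner_parameters=inner_values)

    def simulation_frame(self, x_est) -> pd.DataFrame:
        """Measurement rows plus simulations at the inner optimum."""
        sim, data, _, _, row_meta = self._inner_pass(x_est)
        records = []
        for k, (cond, i) in enumerate(row_meta):
            records.append({
                "observableId": self.base.model.observable_ids[
                    cond.obs_index[i]
                ],
                "simulationConditionId": cond.condition_id,
                "time": cond.times[cond.time_index[i]],
                "measurement": data[k],
                "simulation": sim[k],
            })
        return pd.DataFrame.from_records(records)
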