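"""HDF5 result storage with exact (bit-level) round trip.

Layout (format version 1):

- ``/meta``      — format version, tool version, options as canonical JSON
- ``/problem``   — parameter ids, bounds, scales, fixed mask/values,
  provenance; makes files self-describing
- ``/optimize/run_<k>`` — per-start vectors and scalars, failures included
- ``/profile/<parameter_id>`` — points matrix, fvals, ratios
- ``/sample/<name>`` — chain states, negative log posteriors, acceptance,
  adaptation state, betas and swap counters for tempered runs

All sections are optional; loading never requires an external problem file.
Writes go to a temporary file followed by an atomic rename so a failed save
leaves nothing behind.
"""

from __future__ import annotations

import json
import os
import pathlib
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np

from . import __version__
from .optimize import OptimizeResult, OptimizerRun
from .problem import Problem
from .profile import ProfilePath
from .sample import McmcTrace, PTTrace

FORMAT_VERSION = "1"

_STR = h5py.string_dtype(encoding="utf-8")


class StorageError(RuntimeError):
    pass


@dataclass
class ProblemInfo:
    """Self-describing snapshot of the parameter space."""

    parameter_ids: list
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    scales: list
    fixed_mask: np.ndarray
    fixed_values: np.ndarray
    provenance: str = ""

    @classmethod
    def from_problem(cls, problem: Problem, provenance: str = ""):
        return cls(
            parameter_ids=problem.ids,
            lower_bounds=problem.lb_full,
            upper_bounds=problem.ub_full,
            scales=problem.scales,
            fixed_mask=problem.fixed_mask.copy(),
            fixed_values=problem.fixed_values.copy(),
            provenance=provenance,
        )


@dataclass
class Result:
    """Everything one estimation workflow produced."""

    problem: Optional[ProblemInfo] = None
    optimize: Optional[OptimizeResult] = None
    profiles: dict = field(default_factory=dict)
    samples: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _write_json_attr(group, key, obj):
    group.attrs[key] = json.dumps(obj, sort_keys=True, default=str)


def save_result(result: Result, path) -> str:
    """Serialize a result; deterministic content, atomic replacement."""
    path = pathlib.Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    try:
        with h5py.File(tmp, "w") as fh:
            meta = fh.create_group("meta")
            meta.attrs["format_version"] = FORMAT_VERSION
            meta.attrs["tool_version"] = __version__
            _write_json_attr(meta, "options", result.meta)

            if result.problem is not None:
                g = fh.create_group("problem")
                p = result.problem
                g.create_dataset("parameter_ids", data=p.parameter_ids,
                                 dtype=_STR)
                g.create_dataset("lower_bounds", data=p.lower_bounds)
                g.create_dataset("upper_bounds", data=p.upper_bounds)
                g.create_dataset("scales", data=p.scales, dtype=_STR)
                g.create_dataset("fixed_mask",
                                 data=p.fixed_mask.astype(np.uint8))
                g.create_dataset("fixed_values", data=p.fixed_values)
                g.attrs["provenance"] = p.provenance

            if result.optimize is not None:
                g = fh.create_group("optimize")
                _write_json_attr(g, "provenance", result.optimize.provenance)
                for k, run in enumerate(result.optimize.runs):
                    rg = g.create_group(f"run_{k:05d}")
                    rg.create_dataset("x0", data=run.x0)
                    rg.create_dataset("x", data=run.x)
                    rg.attrs["fval"] = run.fval
                    rg.attrs["grad_norm"] = run.grad_norm
                    rg.attrs["n_fval"] = run.n_fval
                    rg.attrs["n_grad"] = run.n_grad
                    rg.attrs["exit_status"] = run.exit_status
                    rg.attrs["message"] = run.message
                    rg.attrs["start_index"] = run.start_index

            if result.profiles:
                g = fh.create_group("profile")
                for pid, path_obj in result.profiles.items():
                    pg = g.create_group(pid)
                    pg.create_dataset("points", data=path_obj.points)
                    pg.create_dataset("fvals", data=path_obj.fvals)
                    pg.create_dataset("ratios", data=path_obj.ratios)
                    pg.attrs["parameter_index"] = path_obj.parameter_index
                    pg.attrs["fval_min"] = path_obj.fval_min
                    _write_json_attr(pg, "status", path_obj.status)

            if result.samples:
                g = fh.create_group("sample")
                for name, trace in result.samples.items():
                    sg = g.create_group(name)
                    if isinstance(trace, PTTrace):
                        sg.attrs["kind"] = "pt"
                        sg.attrs["seed"] = trace.seed
                        sg.create_dataset("betas", data=trace.betas)
                        sg.create_dataset("betas_init", data=trace.betas_init)
                        sg.create_dataset("swap_accept_counts",
                                          data=trace.swap_accept_counts)
                        sg.create_dataset("swap_attempt_counts",
                                          data=trace.swap_attempt_counts)
                        for k, chain in enumerate(trace.traces):
                            _save_chain(sg.create_group(f"chain_{k:03d}"),
                                        chain)
                    else:
                        sg.attrs["kind"] = "am"
                        sg.attrs["seed"] = trace.seed
                        _save_chain(sg.create_group("chain_000"), trace)
        os.replace(tmp, path)
    except Exception:
        if tmp.exists():
            tmp.unlink()
        raise
    return str(path)


def _save_chain(group, trace: McmcTrace):
    group.create_dataset("states", data=trace.states)
    group.create_dataset("neg_log_posterior", data=trace.neg_log_posterior)
    group.create_dataset("acceptance",
                         data=trace.acceptance.astype(np.uint8))
    group.create_dataset("mu", data=trace.mu)
    group.create_dataset("Sigma", data=trace.Sigma)
    group.create_dataset("parameter_ids", data=trace.parameter_ids,
                         dtype=_STR)
    group.attrs["log_scale"] = trace.log_scale
    group.attrs["seed"] = trace.seed
    group.attrs["beta"] = trace.beta


def _load_chain(group) -> McmcTrace:
    return McmcTrace(
        states=group["states"][()],
        neg_log_posterior=group["neg_log_posterior"][()],
        acceptance=group["acceptance"][()].astype(bool),
        mu=group["mu"][()],
        Sigma=group["Sigma"][()],
        log_scale=float(group.attrs["log_scale"]),
        seed=int(group.attrs["seed"]),
        beta=float(group.attrs["beta"]),
        parameter_ids=[s.decode() if isinstance(s, bytes) else str(s)
                       for s in group["parameter_ids"][()]],
    )


def _decode_strs(arr):
    return [s.decode() if isinstance(s, bytes) else str(s) for s in arr]


def load_result(path) -> Result:
    """Inverse of :func:`save_result`."""
    path = pathlib.Path(path)
    result = Result()
    with h5py.File(path, "r") as fh:
        if "meta" not in fh:
            raise StorageError(f"{path}: not an inferode result file")
        meta = fh["meta"]
        version = str(meta.attrs["format_version"])
        if version.split(".")[0] != FORMAT_VERSION:
            raise StorageError(
                f"{path}: unsupported format version {version!r} "
                f"(this reader supports major {FORMAT_VERSION})"
            )
        result.meta = json.loads(meta.attrs["options"])

        if "problem" in fh:
            g = fh["problem"]
            try:
                result.problem = ProblemInfo(
                    parameter_ids=_decode_strs(g["parameter_ids"][()]),
                    lower_bounds=g["lower_bounds"][()],
                    upper_bounds=g["upper_bounds"][()],
                    scales=_decode_strs(g["scales"][()]),
                    fixed_mask=g["fixed_mask"][()].astype(bool),
                    fixed_values=g["fixed_values"][()],
                    provenance=str(g.attrs.get("provenance", "")),
                )
            except KeyError as err:
                raise StorageError(
                    f"{path}: corrupted /problem group ({err})"
                ) from err

        if "optimize" in fh:
            g = fh["optimize"]
            opt = OptimizeResult(
                provenance=json.loads(g.attrs.get("provenance", "{}"))
            )
            for name in sorted(g.keys()):
                rg = g[name]
                try:
                    opt.runs.append(OptimizerRun(
                        start_index=int(rg.attrs["start_index"]),
                        x0=rg["x0"][()],
                        x=rg["x"][()],
                        fval=float(rg.attrs["fval"]),
                        grad_norm=float(rg.attrs["grad_norm"]),
                        n_fval=int(rg.attrs["n_fval"]),
                        n_grad=int(rg.attrs["n_grad"]),
                        exit_status=str(rg.attrs["exit_status"]),
                        message=str(rg.attrs["message"]),
                    ))
                except KeyError as err:
                    raise StorageError(
                        f"{path}: corrupted /optimize/{name} ({err})"
                    ) from err
            result.optimize = opt

        if "profile" in fh:
            for pid in sorted(fh["profile"].keys()):
                pg = fh["profile"][pid]
                result.profiles[pid] = ProfilePath(
                    parameter_index=int(pg.attrs["parameter_index"]),
                    parameter_id=pid,
                    points=pg["points"][()],
                    fvals=pg["fvals"][()],
                    fval_min=float(pg.attrs["fval_min"]),
                    status=json.loads(pg.attrs.get("status", "{}")),
                )

        if "sample" in fh:
            for name in sorted(fh["sample"].keys()):
                sg = fh["sample"][name]
                kind = str(sg.attrs.get("kind", "am"))
                if kind == "pt":
                    chains = [
                        _load_chain(sg[c])
                        for c in sorted(sg.keys())
                        if c.startswith("chain_")
                    ]
                    result.samples[name] = PTTrace(
                        traces=chains,
                        betas=sg["betas"][()],
                        betas_init=sg["betas_init"][()],
                        swap_accept_counts=sg["swap_accept_counts"][()],
                        swap_attempt_counts=sg["swap_attempt_counts"][()],
                        seed=int(sg.attrs["seed"]),
                    )
                else:
                    result.samples[name] = _load_chain(sg["chain_000"])
    return result


# ---------------------------------------------------------------------------
# bit-exact equality (NaN-aware) for round-trip verification
# ---------------------------------------------------------------------------

def _arrays_equal(a, b) -> bool:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    if a.dtype.kind == "f":
        return a.tobytes() == np.asarray(b, dtype=a.dtype).tobytes()
    return bool(np.array_equal(a, b))


def _scalar_equal(a, b) -> bool:
    if isinstance(a, float) or isinstance(b, float):
        a, b = float(a), float(b)
        return (np.isnan(a) and np.isnan(b)) or a == b
    return a == b


def results_equal(a: Result, b: Result) -> bool:
    """Field-for-field comparison, floating point bit-exact (NaN == NaN)."""
    if (a.problem is None) != (b.problem is None):
        return False
    if a.problem is not None:
        pa, pb = a.problem, b.problem
        if pa.parameter_ids != pb.parameter_ids or pa.scales != pb.scales:
            return False
        for x, y in (
            (pa.lower_bounds, pb.lower_bounds),
            (pa.upper_bounds, pb.upper_bounds),
            (pa.fixed_mask, pb.fixed_mask),
            (pa.fixed_values, pb.fixed_values),
        ):
            if not _arrays_equal(x, y):
                return False
        if pa.provenance != pb.provenance:
            return False
    if (a.optimize is None) != (b.optimize is None):
        return False
    if a.optimize is not None:
        if len(a.optimize.runs) != len(b.optimize.runs):
            return False
        for ra, rb in zip(a.optimize.runs, b.optimize.runs):
            if not (
                ra.start_index == rb.start_index
                and _arrays_equal(ra.x0, rb.x0)
                and _arrays_equal(ra.x, rb.x)
                and _scalar_equal(ra.fval, rb.fval)
                and _scalar_equal(ra.grad_norm, rb.grad_norm)
                and ra.n_fval == rb.n_fval
                and ra.n_grad == rb.n_grad
                and ra.exit_status == rb.exit_status
                and ra.message == rb.message
            ):
                return False
    if set(a.profiles) != set(b.profiles):
        return False
    for pid in a.profiles:
        pa, pb = a.profiles[pid], b.profiles[pid]
        if not (
            pa.parameter_index == pb.parameter_index
            and _arrays_equal(pa.points, pb.points)
            and _arrays_equal(pa.fvals, pb.fvals)
            and _scalar_equal(pa.fval_min, pb.fval_min)
        ):
            return False
    if set(a.samples) != set(b.samples):
        return False
    for name in a.samples:
        sa, sb = a.samples[name], b.samples[name]
        if isinstance(sa, PTTrace) != isinstance(sb, PTTrace):
            return False
        chains_a = sa.traces if isinstance(sa, PTTrace) else [sa]
        chains_b = sb.traces if isinstance(sb, PTTrace) else [sb]
        if len(chains_a) != len(chains_b):
            return False
        for ca, cb in zip(chains_a, chains_b):
            if not (
                _arrays_equal(ca.states, cb.states)
                and _arrays_equal(ca.neg_log_posterior, cb.neg_log_posterior)
                and _arrays_equal(ca.acceptance, cb.acceptance)
                and _arrays_equal(ca.mu, cb.mu)
                and _arrays_equal(ca.Sigma, cb.Sigma)
                and _scalar_equal(ca.log_scale, cb.log_scale)
                and _scalar_equal(ca.beta, cb.beta)
            ):
                return False
        if isinstance(sa, PTTrace):
            if not (
                _arrays_equal(sa.betas, sb.betas)
                and _arrays_equal(sa.swap_accept_counts,
                                  sb.swap_accept_counts)
                and _arrays_equal(sa.swap_attempt_counts,
                                  sb.swap_attempt_counts)
            ):
                return False
    return a.meta == b.meta
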