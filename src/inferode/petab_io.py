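"""Reader/writer for a PEtab-subset problem bundle.

A bundle is a YAML index referencing tab-separated parameter, observable,
measurement and condition tables plus a built-in model registry id (in place
of an SBML file). Column conventions follow the PEtab standard subset:
bounds and nominal values are given on the linear scale in the tables and
converted to the estimation scale on load.

Supported observable formulas are affine read-outs of a model observable:
``<obs>``, ``<scale> * <obs>``, or ``<offset> + <scale> * <obs>``, where
``<offset>``/``<scale>`` are numeric literals or parameter ids. Noise
formulas are a numeric literal or a parameter id. Parameters flagged in an
optional ``hierarchical`` column are solved analytically in the inner
problem when the bundle is loaded in hierarchical mode.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .hierarchical import HierarchicalOdeObjective, build_inner_problem
from .models import (
    CONVERSION_SIGMA,
    CONVERSION_T_GRID,
    CONVERSION_TRUE,
    ConditionBlock,
    MEASUREMENT_COLUMNS,
    MODEL_REGISTRY,
    OdeObjective,
    RowSource,
    SRC_CONST,
    generate_synthetic_data,
    simulate,
)
from .problem import ParameterSpec, Problem, SCALE_LOG10

YAML_KEYS = (
    "model",
    "parameter_file",
    "observable_file",
    "measurement_file",
    "condition_file",
)

PARAMETER_COLUMNS = [
    "parameterId",
    "parameterScale",
    "lowerBound",
    "upperBound",
    "nominalValue",
    "estimate",
]


class BundleLoadError(ValueError):
    """Bundle cannot be assembled (unknown model, missing files)."""


class BundleValidationError(ValueError):
    """Cross-reference or value violations in the bundle tables."""

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__(
            "invalid problem bundle:\n" + "\n".join(f"- {i}" for i in issues)
        )


@dataclass
class ProblemBundle:
    """Parsed bundle tables plus the YAML index."""

    model_id: str
    parameter_table: pd.DataFrame
    observable_table: pd.DataFrame
    measurement_table: pd.DataFrame
    condition_table: pd.DataFrame
    yaml_index: dict
    base_dir: Optional[pathlib.Path] = None


def _read_tsv(path) -> pd.DataFrame:
    # round_trip parsing keeps write->load->write bit-stable
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def load_bundle(yaml_path) -> ProblemBundle:
    yaml_path = pathlib.Path(yaml_path)
    with open(yaml_path) as fh:
        index = yaml.safe_load(fh)
    missing = [k for k in YAML_KEYS if k not in index]
    if missing:
        raise BundleLoadError(f"YAML index missing keys: {missing}")
    base = yaml_path.parent
    tables = {}
    for key in YAML_KEYS[1:]:
        path = base / index[key]
        if not path.exists():
            raise BundleLoadError(f"referenced file not found: {path}")
        tables[key] = _read_tsv(path)
    return ProblemBundle(
        model_id=index["model"],
        parameter_table=tables["parameter_file"],
        observable_table=tables["observable_file"],
        measurement_table=tables["measurement_file"],
        condition_table=tables["condition_file"],
        yaml_index=dict(index),
        base_dir=base,
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def _parse_observable_formula(formula: str, model, param_ids):
    """Return (obs_index, offset_token, scale_token); tokens are None,
    a float, or a parameter id."""
    offset_tok = None
    scale_tok = None
    expr = str(formula).strip()
    if "+" in expr:
        left, expr = (t.strip() for t in expr.split("+", 1))
        offset_tok = left
    if "*" in expr:
        left, expr = (t.strip() for t in expr.split("*", 1))
        scale_tok = left
    obs = expr.strip()
    if obs not in model.observable_ids:
        raise BundleLoadError(
            f"observable formula {formula!r} does not reference a model "
            f"observable of {model.id!r}"
        )

    def norm(tok):
        if tok is None:
            return None
        if _is_number(tok):
            return float(tok)
        if tok not in param_ids:
            raise BundleLoadError(
                f"formula token {tok!r} is neither numeric nor a parameter id"
            )
        return tok
    return model.observable_ids.index(obs), norm(offset_tok), norm(scale_tok)


def validate_bundle(bundle: ProblemBundle) -> list[str]:
    """All violations as human-readable issues; empty list iff valid."""
    issues = []
    pt = bundle.parameter_table
    ot = bundle.observable_table
    mt = bundle.measurement_table
    ct = bundle.condition_table

    if bundle.model_id not in MODEL_REGISTRY:
        issues.append(f"unknown model id {bundle.model_id!r}")

    for col in PARAMETER_COLUMNS:
        if col not in pt.columns:
            issues.append(f"parameter table missing column {col!r}")
            return issues

    ids = list(pt["parameterId"])
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        issues.append(f"duplicate parameter ids: {dup}")

    for _, row in pt.iterrows():
        pid = row["parameterId"]
        if row["parameterScale"] not in ("lin", "log10"):
            issues.append(
                f"parameter {pid!r}: unsupported scale "
                f"{row['parameterScale']!r}"
            )
            continue
        lb, ub = float(row["lowerBound"]), float(row["upperBound"])
        if int(row["estimate"]) and not lb < ub:
            issues.append(
                f"parameter {pid!r}: lowerBound {lb} must be < upperBound {ub}"
            )
        if row["parameterScale"] == "log10" and (lb <= 0 or ub <= 0):
            issues.append(
                f"parameter {pid!r}: log10 scale requires positive bounds"
            )

    known_obs = set(ot["observableId"]) if "observableId" in ot else set()
    known_cond = set(ct["conditionId"]) if "conditionId" in ct else set()
    for k, row in mt.iterrows():
        if row["observableId"] not in known_obs:
            issues.append(
                f"measurement row {k}: unknown observableId "
                f"{row['observableId']!r}"
            )
        if row["simulationConditionId"] not in known_cond:
            issues.append(
                f"measurement row {k}: unknown simulationConditionId "
                f"{row['simulationConditionId']!r}"
            )
        if float(row["time"]) < 0:
            issues.append(f"measurement row {k}: negative time {row['time']}")

    param_ids = set(ids)
    for _, row in ot.iterrows():
        nf = row.get("noiseFormula", np.nan)
        if not _is_number(nf) and nf not in param_ids:
            issues.append(
                f"observable {row['observableId']!r}: noiseFormula {nf!r} "
                "is neither numeric nor a parameter id"
            )
    return issues


def _build_specs(pt: pd.DataFrame) -> list[ParameterSpec]:
    specs = []
    for _, row in pt.iterrows():
        scale = row["parameterScale"]
        lb, ub = float(row["lowerBound"]), float(row["upperBound"])
        if scale == SCALE_LOG10:
            lb, ub = np.log10(lb), np.log10(ub)
        specs.append(ParameterSpec(
            id=row["parameterId"],
            scale=scale,
            lower_bound=lb,
            upper_bound=ub,
            nominal=float(row["nominalValue"]),
            estimate=bool(int(row["estimate"])),
        ))
    return specs


def _source(token, x_ids, default) -> RowSource:
    if token is None:
        return RowSource(SRC_CONST, default)
    if isinstance(token, float):
        return RowSource(SRC_CONST, token)
    return RowSource(x_ids.index(token), 0.0)


def build_objective(bundle: ProblemBundle, rtol=None, atol=None
                    ) -> OdeObjective:
    """Assemble the joint Gaussian-likelihood objective: one simulation per
    condition, affine observable read-outs, per-row noise sds."""
    model = MODEL_REGISTRY[bundle.model_id]
    pt, ot, mt, ct = (
        bundle.parameter_table,
        bundle.observable_table,
        bundle.measurement_table,
        bundle.condition_table,
    )
    x_ids = list(pt["parameterId"])
    scales = list(pt["parameterScale"])
    param_ids = set(x_ids)

    obs_info = {}
    for _, row in ot.iterrows():
        formula = row.get("observableFormula", row["observableId"])
        if pd.isna(formula):
            formula = row["observableId"]
        obs_idx, b_tok, s_tok = _parse_observable_formula(
            formula, model, param_ids
        )
        nf = row.get("noiseFormula", np.nan)
        if _is_number(nf):
            sigma_src = RowSource(SRC_CONST, float(nf))
        else:
            sigma_src = RowSource(x_ids.index(nf), 0.0)
        obs_info[row["observableId"]] = (
            obs_idx,
            _source(b_tok, x_ids, 0.0),
            _source(s_tok, x_ids, 1.0),
            sigma_src,
        )

    overrides = {}
    for _, row in ct.iterrows():
        ov = {}
        for col in ct.columns:
            if col == "conditionId" or pd.isna(row[col]):
                continue
            ov[col] = float(row[col])
        overrides[row["conditionId"]] = ov

    conditions = []
    for cond_id, group in mt.groupby("simulationConditionId", sort=True):
        times = np.array(sorted(set(group["time"].astype(float))))
        t_index = {t: i for i, t in enumerate(times)}
        time_index, obs_index = [], []
        offset, scaling, sigma = [], [], []
        for _, row in group.iterrows():
            info = obs_info[row["observableId"]]
            time_index.append(t_index[float(row["time"])])
            obs_index.append(info[0])
            offset.append(info[1])
            scaling.append(info[2])
            sigma.append(info[3])
        ov = overrides.get(cond_id, {})
        model_param_src = []
        for pid in model.parameter_ids:
            if pid in ov:
                model_param_src.append(RowSource(SRC_CONST, ov[pid]))
            elif pid in param_ids:
                model_param_src.append(RowSource(x_ids.index(pid), 0.0))
            else:
                raise BundleLoadError(
                    f"model parameter {pid!r} neither in the parameter table "
                    f"nor overridden in condition {cond_id!r}"
                )
        conditions.append(ConditionBlock(
            condition_id=str(cond_id),
            times=times,
            time_index=np.array(time_index, dtype=int),
            obs_index=np.array(obs_index, dtype=int),
            measurements=group["measurement"].to_numpy(dtype=float),
            offset=offset,
            scaling=scaling,
            sigma=sigma,
            model_param_src=model_param_src,
        ))
    kwargs = {}
    if rtol is not None:
        kwargs["rtol"] = rtol
    if atol is not None:
        kwargs["atol"] = atol
    return OdeObjective(model, conditions, x_ids, scales, **kwargs)


def build_problem(bundle: ProblemBundle,
                  hierarchical: Optional[bool] = None) -> Problem:
    """Assemble a Problem. ``hierarchical=None`` honors the parameter
    table's ``hierarchical`` flags; ``False`` forces the joint formulation."""
    issues = validate_bundle(bundle)
    if issues:
        raise BundleValidationError(issues)
    specs = _build_specs(bundle.parameter_table)
    objective = build_objective(bundle)

    pt = bundle.parameter_table
    if "hierarchical" in pt.columns:
        flagged = [
            row["parameterId"]
            for _, row in pt.iterrows()
            if int(row.get("hierarchical", 0) or 0)
        ]
    else:
        flagged = []
    use_hier = bool(flagged) if hierarchical is None else hierarchical
    if use_hier:
        if not flagged:
            raise BundleLoadError(
                "hierarchical mode requested but no parameter is flagged "
                "hierarchical"
            )
        inner = build_inner_problem(objective, flagged)
        outer_specs = [s for s in specs if s.id not in set(flagged)]
        hier_obj = HierarchicalOdeObjective(
            objective,
            inner,
            [s.id for s in outer_specs],
            [s.scale for s in outer_specs],
        )
        return Problem(hier_obj, outer_specs)
    return Problem(objective, specs)


def load_problem_bundle(yaml_path,
                        hierarchical: Optional[bool] = None) -> Problem:
    """Load a bundle from its YAML index and assemble the Problem."""
    return build_problem(load_bundle(yaml_path), hierarchical=hierarchical)


def write_bundle(bundle: ProblemBundle, directory, name="problem") -> str:
    """Write the four TSV tables and the YAML index; returns the YAML path."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "parameter_file": ("parameters.tsv", bundle.parameter_table),
        "observable_file": ("observables.tsv", bundle.observable_table),
        "measurement_file": ("measurements.tsv", bundle.measurement_table),
        "condition_file": ("conditions.tsv", bundle.condition_table),
    }
    index = {"model": bundle.model_id}
    for key, (fname, table) in files.items():
        table.to_csv(directory / fname, sep="\t", index=False)
        index[key] = fname
    yaml_path = directory / f"{name}.yaml"
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(index, fh, sort_keys=False)
    return str(yaml_path)


def write_simulation_table(problem: Problem, x_est, path) -> str:
    """Write the measurement rows with a ``simulation`` column computed at
    the full-length estimation-scale vector ``x_est``. Deterministic."""
    frame = problem.objective.simulation_frame(np.asarray(x_est, dtype=float))
    frame.to_csv(path, sep="\t", index=False)
    return str(path)


# ---------------------------------------------------------------------------
# fixture bundles (synthetic data from the built-in generator)
# ---------------------------------------------------------------------------

def make_conversion_bundle(sigma: float = CONVERSION_SIGMA, seed: int = 1,
                           scaled: bool = False, hierarchical: bool = False
                           ) -> ProblemBundle:
    """Conversion-reaction fixture: k1=0.06, k2=0.08, x0=(1,0), ten
    equispaced time points on [0, 30], Gaussian noise sd ``sigma``.

    With ``scaled=True`` the second observable reads ``s_b * xB`` with
    s_b=2.5, and per-observable noise sds are estimated parameters
    (flagged hierarchical when requested) — the relative-data fixture for
    the hierarchical decomposition.
    """
    model = MODEL_REGISTRY["conversion_reaction"]
    truth = np.array([CONVERSION_TRUE["k1"], CONVERSION_TRUE["k2"]])
    t_grid = CONVERSION_T_GRID

    params = [
        ("k1", "log10", 1e-5, 1e2, CONVERSION_TRUE["k1"], 1, 0),
        ("k2", "log10", 1e-5, 1e2, CONVERSION_TRUE["k2"], 1, 0),
    ]
    hflag = 1 if hierarchical else 0
    if scaled:
        s_true = 2.5
        sigma_nominal = sigma if sigma > 0 else 0.02
        params += [
            ("s_b", "log10", 1e-3, 1e3, s_true, 1, hflag),
            ("sigma_a", "log10", 1e-5, 1e1, sigma_nominal, 1, hflag),
            ("sigma_b", "log10", 1e-5, 1e1, sigma_nominal, 1, hflag),
        ]
        res = simulate(model, truth, t_grid)
        rng = np.random.default_rng(seed)
        rows = []
        for j, oid in enumerate(model.observable_ids):
            scale = s_true if oid == "obs_b" else 1.0
            for k, t in enumerate(t_grid):
                y = scale * res.observables[k, j]
                if sigma > 0:
                    y = y + sigma * rng.standard_normal()
                rows.append((oid, "c0", float(t), float(y)))
        measurements = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
        observables = pd.DataFrame({
            "observableId": ["obs_a", "obs_b"],
            "observableFormula": ["obs_a", "s_b * obs_b"],
            "noiseFormula": ["sigma_a", "sigma_b"],
        })
    else:
        measurements = generate_synthetic_data(model, truth, t_grid, sigma,
                                               seed=seed)
        observables = pd.DataFrame({
            "observableId": ["obs_a", "obs_b"],
            "observableFormula": ["obs_a", "obs_b"],
            "noiseFormula": [sigma, sigma],
        })
    parameter_table = pd.DataFrame(
        params,
        columns=PARAMETER_COLUMNS + ["hierarchical"],
    )
    conditions = pd.DataFrame({"conditionId": ["c0"]})
    return ProblemBundle(
        model_id="conversion_reaction",
        parameter_table=parameter_table,
        observable_table=observables,
        measurement_table=measurements,
        condition_table=conditions,
        yaml_index={},
    )


def write_demo_bundle(directory, sigma: float = CONVERSION_SIGMA,
                      seed: int = 1, scaled: bool = False,
                      hierarchical: bool = False) -> str:
    """Write the conversion-reaction fixture bundle; returns the YAML path."""
    bundle = make_conversion_bundle(sigma=sigma, seed=seed, scaled=scaled,
                                    hierarchical=hierarchical)
    return write_bundle(bundle, directory)
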