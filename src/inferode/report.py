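"""CSV/JSON report export: waterfall, best parameters, profiles, traces.

Stored traces are complete; subsampling happens only here, in the
human-facing exports.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd

from .problem import from_estimation_scale
from .sample import PTTrace
from .store import Result

MAX_TRACE_ROWS = 10_000


def export_report(result: Result, out_dir) -> list[str]:
    """Write the report files for every populated result section; returns
    the written paths."""
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    if result.optimize is not None and result.optimize.runs:
        fvals = result.optimize.fvals()
        wf = pd.DataFrame({"rank": np.arange(len(fvals)), "fval": fvals})
        path = out_dir / "waterfall.csv"
        wf.to_csv(path, index=False)
        written.append(str(path))

        best = result.optimize.best
        if best is not None:
            info = result.problem
            scales = info.scales if info is not None else None
            entry = {
                "fval": best.fval,
                "parameter_ids": (
                    info.parameter_ids if info is not None else None
                ),
                "x_estimation_scale": list(best.x),
                "x_linear_scale": (
                    list(from_estimation_scale(best.x, scales))
                    if scales is not None
                    else list(best.x)
                ),
                "exit_status": best.exit_status,
                "n_starts": len(result.optimize.runs),
                "n_failed": result.optimize.n_failed,
            }
            path = out_dir / "parameters.json"
            path.write_text(json.dumps(entry, indent=2, sort_keys=True))
            written.append(str(path))

    for pid, prof in result.profiles.items():
        frame = pd.DataFrame({
            "value": prof.parameter_values,
            "ratio": prof.ratios,
        })
        path = out_dir / f"profiles_{pid}.csv"
        frame.to_csv(path, index=False)
        written.append(str(path))

    for name, trace in result.samples.items():
        chains = trace.traces if isinstance(trace, PTTrace) else [trace]
        for k, chain in enumerate(chains):
            n = chain.n_iter
            stride = max(1, int(np.ceil(n / MAX_TRACE_ROWS)))
            idx = np.arange(0, n, stride)
            cols = {"iteration": idx,
                    "neg_log_posterior": chain.neg_log_posterior[idx]}
            ids = chain.parameter_ids or [
                f"x{j}" for j in range(chain.states.shape[1])
            ]
            for j, pid in enumerate(ids):
                cols[pid] = chain.states[idx, j]
            frame = pd.DataFrame(cols)
            suffix = f"{name}_chain_{k:03d}" if len(chains) > 1 else name
            path = out_dir / f"trace_{suffix}.csv"
            frame.to_csv(path, index=False)
            written.append(str(path))
    return written
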