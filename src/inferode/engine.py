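"""Parallel execution engine contract.

``map_parallel`` runs pure tasks over a list of inputs with a serial,
multi-threaded, or multi-process backend. Per-task seeds are derived as
``seed_root + index``, output order always matches input order, and results
are identical across backends and worker counts — parallelism is an
execution detail, never part of the result.
"""

from __future__ import annotations

import traceback
from concurrent.futures import ProcessPoolExecutor, ThreadPoolExecutor
from dataclasses import dataclass

ENGINE_KINDS = ("serial", "multithread", "multiprocess")


@dataclass(frozen=True)
class EngineSpec:
    kind: str = "serial"
    n_workers: int = 1

    def __post_init__(self):
        if self.kind not in ENGINE_KINDS:
            raise ValueError(f"unknown engine kind {self.kind!r}")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")


@dataclass
class TaskFailure:
    """Failure record for one task slot; remaining tasks still complete."""

    message: str
    exception_type: str
    traceback: str = ""

    def __repr__(self):
        return f"TaskFailure({self.exception_type}: {self.message})"


def _safe_call(payload):
    task, item, seed = payload
    try:
        return ("ok", task(item, seed))
    except Exception as err:  # noqa: BLE001 - failures become records
        return (
            "err",
            TaskFailure(
                message=str(err),
                exception_type=type(err).__name__,
                traceback=traceback.format_exc(),
            ),
        )


def map_parallel(task, inputs, engine: EngineSpec | None = None,
                 seed_root: int = 0) -> list:
    """Apply ``task(item, seed)`` to every input; a raising task yields a
    :class:`TaskFailure` in its slot."""
    engine = engine or EngineSpec()
    payloads = [
        (task, item, seed_root + i) for i, item in enumerate(inputs)
    ]
    if engine.kind == "serial" or engine.n_workers == 1:
        raw = [_safe_call(p) for p in payloads]
    elif engine.kind == "multithread":
        with ThreadPoolExecutor(max_workers=engine.n_workers) as pool:
            raw = list(pool.map(_safe_call, payloads))
    else:
        with ProcessPoolExecutor(max_workers=engine.n_workers) as pool:
            raw = list(pool.map(_safe_call, payloads))
    return [value for _, value in raw]
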