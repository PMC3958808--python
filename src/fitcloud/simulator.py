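"""Discrete-time simulation of the elastic allocator over a request series.

The simulator applies one-step-ahead timing: the units decided after
observing interval ``t`` serve interval ``t + 1``; the first interval is
served by ``u_min`` units.  The trace records, per interval, the actual
demand, the EMA estimate computed at that interval, the units and
capacity applied during it, and whether demand exceeded capacity (a QoS
violation).

Forecast quality is summarised by the mean absolute percentage error
(MAPE) between actual requests ``A_t`` and provided capacity
``F_t = U_t * C``:

    MAPE = (100 / n') * sum |A_t - F_t| / A_t,

taken over the ``n'`` intervals with ``A_t > 0`` (capacity error is
undefined relative to zero demand).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allocator import AllocatorConfig, AllocatorState, allocate_step
from .errors import DomainError, FormatError

TRACE_COLUMNS = ("t", "requests", "lambda", "units", "capacity", "violation")


@dataclass(frozen=True)
class SimulationTrace:
    """Per-interval record of one simulation run (parallel 1-D arrays)."""

    requests: np.ndarray
    lam: np.ndarray
    units: np.ndarray
    capacity: np.ndarray
    violation: np.ndarray

    def __len__(self) -> int:
        return len(self.requests)


@dataclass(frozen=True)
class SimulationSummary:
    mape: float
    violation_count: int
    mean_units: float
    max_units: int

    def to_dict(self) -> dict:
        return {
            "mape_percent": self.mape,
            "violation_count": self.violation_count,
            "mean_units": self.mean_units,
            "max_units": self.max_units,
        }


def run(series, config: AllocatorConfig) -> SimulationTrace:
    """Drive the allocator over ``series`` and record the trace.

    Deterministic given ``(series, config)``.
    """
    q = np.asarray(series, dtype=np.int64)
    if q.ndim != 1 or len(q) == 0:
        raise DomainError("request series must be a non-empty 1-D sequence")
    if np.any(q < 0):
        raise DomainError("request counts must be non-negative")

    n = len(q)
    lam = np.empty(n, dtype=float)
    units = np.empty(n, dtype=np.int64)

    state = AllocatorState(lam=0.0, units=config.u_min, t=0)
    for t in range(n):
        units[t] = state.units  # decided from observations before t
        state = allocate_step(state, int(q[t]), config)
        lam[t] = state.lam

    capacity = units * config.C
    violation = q > capacity
    return SimulationTrace(requests=q, lam=lam, units=units, capacity=capacity, violation=violation)


def mape(actual, predicted) -> float:
    """Mean absolute percentage error, in percent.

    Intervals with zero actual value are excluded from the mean; if every
    interval is zero the error is defined as 0.
    """
    a = np.asarray(actual, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if a.shape != f.shape or a.ndim != 1 or len(a) == 0:
        raise DomainError("actual and predicted must be equal-length non-empty 1-D sequences")
    mask = a > 0
    if not mask.any():
        return 0.0
    return float(np.mean(np.abs(a[mask] - f[mask]) / a[mask]) * 100.0)


def summarize(trace: SimulationTrace) -> SimulationSummary:
    """MAPE (actual requests vs provided capacity) and QoS statistics."""
    return SimulationSummary(
        mape=mape(trace.requests, trace.capacity),
        violation_count=int(np.sum(trace.requests > trace.capacity)),
        mean_units=float(np.mean(trace.units)),
        max_units=int(np.max(trace.units)),
    )


def write_trace(trace: SimulationTrace, path) -> None:
    """Write the trace as CSV with header ``t,requests,lambda,units,capacity,violation``."""
    frame = pd.DataFrame(
        {
            "t": np.arange(1, len(trace) + 1),
            "requests": trace.requests,
            "lambda": trace.lam,
            "units": trace.units,
            "capacity": trace.capacity,
            "violation": trace.violation.astype(np.int64),
        }
    )
    frame.to_csv(path, index=False)


def read_trace(path) -> SimulationTrace:
    """Read a trace written by :func:`write_trace` (integer columns round-trip)."""
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"malformed trace CSV {path}: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing trace columns {missing}")
    return SimulationTrace(
        requests=frame["requests"].to_numpy(np.int64),
        lam=frame["lambda"].to_numpy(float),
        units=frame["units"].to_numpy(np.int64),
        capacity=frame["capacity"].to_numpy(np.int64),
        violation=frame["violation"].to_numpy(np.int64).astype(bool),
    )
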