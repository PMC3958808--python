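"""Synthetic request-count workload patterns.

A workload is a length-``n`` sequence of non-negative integer request
counts, one per time interval, used to drive the elastic allocator in
simulation.  Four canonical shapes are provided:

``linear``
    An affine ramp from ``q_min`` at the first interval to ``q_max`` at
    the last.
``logarithmic``
    Logarithmic growth ``q_min + (q_max - q_min) * ln(1+t) / ln(1+n)``,
    monotone non-decreasing and ending at ``q_max``.
``repetitive``
    A sinusoid oscillating between ``q_min`` and ``q_max`` with a fixed
    period in intervals.
``combined``
    The arithmetic mean of the linear and repetitive curves, clipped to
    ``[q_min, q_max]``.

Optionally, seeded Gaussian noise is added before rounding.  Counts are
rounded half-up to integers and clipped to the configured bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

PATTERN_KINDS = ("linear", "logarithmic", "repetitive", "combined")

#: A request series is a 1-D ``int64`` array of per-interval counts.
RequestSeries = np.ndarray


@dataclass(frozen=True)
class PatternSpec:
    """Parameters of one synthetic workload pattern.

    Parameters
    ----------
    kind
        One of :data:`PATTERN_KINDS`.
    n_intervals
        Number of time intervals (length of the series).
    q_max, q_min
        Upper and lower request bounds per interval.
    period
        Cycle length in intervals; only meaningful for the repetitive and
        combined kinds.
    noise_sd
        Standard deviation of additive Gaussian noise (requests/interval);
        0 disables noise.
    seed
        Seed for the noise generator.
    """

    kind: str
    n_intervals: int = 1000
    q_max: int = 15000
    q_min: int = 0
    period: int = 50
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise ConfigurationError(
                f"unknown pattern kind {self.kind!r}; expected one of {PATTERN_KINDS}"
            )
        if self.n_intervals < 1:
            raise ConfigurationError("n_intervals must be >= 1")
        if not 0 <= self.q_min <= self.q_max:
            raise ConfigurationError("require q_max >= q_min >= 0")
        if self.kind in ("repetitive", "combined") and self.period < 2:
            raise ConfigurationError("period must be >= 2 for periodic patterns")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


def _base_curve(spec: PatternSpec) -> np.ndarray:
    t = np.arange(1, spec.n_intervals + 1, dtype=float)
    span = float(spec.q_max - spec.q_min)
    if spec.kind == "linear":
        denom = max(spec.n_intervals - 1, 1)
        return spec.q_min + span * (t - 1.0) / denom
    if spec.kind == "logarithmic":
        return spec.q_min + span * np.log1p(t) / np.log1p(spec.n_intervals)
    if spec.kind == "repetitive":
        return spec.q_min + span * (1.0 + np.sin(2.0 * np.pi * t / spec.period)) / 2.0
    # combined: mean of the linear and repetitive curves
    linear = _base_curve(PatternSpec("linear", spec.n_intervals, spec.q_max, spec.q_min))
    rep = _base_curve(
        PatternSpec("repetitive", spec.n_intervals, spec.q_max, spec.q_min, spec.period)
    )
    return (linear + rep) / 2.0


def generate_series(spec: PatternSpec) -> RequestSeries:
    """Generate the integer request series described by ``spec``.

    Noise-free generation is deterministic; with ``noise_sd > 0`` the
    series is reproducible for equal ``(spec, seed)``.
    """
    values = _base_curve(spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    # counts: round half-up, then clip into bounds
    values = np.floor(values + 0.5)
    values = np.clip(values, spec.q_min, spec.q_max)
    return values.astype(np.int64)


def write_series(series: RequestSeries, path) -> None:
    """Persist a request series as a one-column CSV (header ``requests``)."""
    pd.DataFrame({"requests": np.asarray(series, dtype=np.int64)}).to_csv(path, index=False)


def read_series(path) -> RequestSeries:
    """Read a request series written by :func:`write_series`.

    Raises
    ------
    FormatError
        If the file is empty, lacks the ``requests`` column, or contains
        negative or non-integer counts.
    """
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"malformed request-series CSV {path}: {exc}") from exc
    if "requests" not in frame.columns:
        raise FormatError(f"{path}: missing required column 'requests'")
    if len(frame) == 0:
        raise FormatError(f"{path}: series must contain at least one interval")
    col = frame["requests"]
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.isna().any():
        raise FormatError(f"{path}: non-numeric request count")
    values = numeric.to_numpy()
    if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
        raise FormatError(f"{path}: request counts must be integers")
    if np.any(values < 0):
        raise FormatError(f"{path}: request counts must be non-negative")
    return values.astype(np.int64)
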