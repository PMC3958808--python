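"""Elastic allocation of computational units driven by a Poisson demand model.

A cloud service runs ``U`` identical computational units, each able to
process ``C`` requests per time interval.  The number of requests arriving
in the next interval is modelled as a Poisson variate whose mean is an
exponential moving average (EMA) of past observed counts:

    lambda_i = alpha * Q_i + (1 - alpha) * lambda_{i-1},   alpha = 2 / (w + 1).

Each interval, the policy evaluates — for every candidate step size
``i = 1..I`` — the probability that at least ``i`` more units are needed,

    P(X > (U + i - 1) * C | lambda),

and the probability that ``i`` units can be released while still covering
demand,

    P(X <= (U - i) * C | lambda).

The largest ``i`` whose increase probability exceeds the increase
threshold is added; otherwise the largest ``i`` whose decrease
probability exceeds the decrease threshold is removed; otherwise ``U`` is
left unchanged.  Increasing takes priority over decreasing (quality of
service over savings) and the result is clamped to ``[u_min, u_max]``.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DomainError, FormatError

__all__ = [
    "AllocatorConfig",
    "AllocatorState",
    "smoothing_alpha",
    "ema_update",
    "poisson_pmf",
    "poisson_tail",
    "prob_need_increase",
    "prob_can_decrease",
    "allocate_step",
]


@dataclass(frozen=True)
class AllocatorConfig:
    """Policy parameters.

    ``C`` requests processable per unit per interval; ``I`` the maximum
    number of units addable/removable in one step; ``thre_i`` / ``thre_d``
    the increase/decrease probability thresholds; ``w`` the EMA window
    length in intervals; ``u_min`` / ``u_max`` the unit bounds.
    """

    C: int = 100
    I: int = 150  # noqa: E741 - standard symbol for the max step size
    thre_i: float = 0.2
    thre_d: float = 0.2
    w: int = 5
    u_min: int = 1
    u_max: int = 150

    def __post_init__(self) -> None:
        if self.C < 1:
            raise ConfigurationError("C must be >= 1")
        if self.I < 1:
            raise ConfigurationError("I must be >= 1")
        if not (0.0 <= self.thre_i <= 1.0 and 0.0 <= self.thre_d <= 1.0):
            raise ConfigurationError("thresholds must lie in [0, 1]")
        if self.w < 1:
            raise ConfigurationError("w must be >= 1")
        if not 1 <= self.u_min <= self.u_max:
            raise ConfigurationError("require 1 <= u_min <= u_max")

    @classmethod
    def from_json(cls, path) -> "AllocatorConfig":
        """Load a config from a flat JSON object; unknown keys are rejected."""
        with open(path) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}: invalid JSON: {exc}") from exc
        allowed = {"C", "I", "thre_i", "thre_d", "w", "u_min", "u_max"}
        unknown = set(payload) - allowed
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**payload)


@dataclass(frozen=True)
class AllocatorState:
    """Evolving state: the EMA demand estimate, the running units, and the
    number of intervals observed so far (``t == 0`` means no observation
    yet; the first update then takes the observation as the estimate)."""

    lam: float = 0.0
    units: int = 1
    t: int = 0


def smoothing_alpha(w: float) -> float:
    """EMA smoothing factor ``alpha = 2 / (w + 1)`` for window length ``w``."""
    if w < 1:
        raise DomainError("window length w must be >= 1")
    return 2.0 / (w + 1.0)


def ema_update(q: float, lam_prev: float, alpha: float) -> float:
    """One EMA step: ``alpha * q + (1 - alpha) * lam_prev``."""
    if q < 0 or lam_prev < 0:
        raise DomainError("request count and prior estimate must be non-negative")
    if not 0.0 < alpha <= 1.0:
        raise DomainError("alpha must lie in (0, 1]")
    return alpha * q + (1.0 - alpha) * lam_prev


def _check_k_lam(k, lam) -> None:
    k = np.asarray(k)
    if np.any(k < 0) or np.any(k != np.floor(k)):
        raise DomainError("k must be a non-negative integer")
    if lam < 0:
        raise DomainError("lam must be non-negative")


def poisson_pmf(k, lam: float) -> float:
    """``P(X = k)`` for ``X ~ Poisson(lam)``, stable for large ``k``/``lam``."""
    _check_k_lam(k, lam)
    return stats.poisson.pmf(k, lam)


def poisson_tail(k, lam: float) -> float:
    """Upper tail ``P(X > k)`` for ``X ~ Poisson(lam)``, clipped to [0, 1]."""
    _check_k_lam(k, lam)
    return np.clip(stats.poisson.sf(k, lam), 0.0, 1.0)


def prob_need_increase(i: int, state: AllocatorState, config: AllocatorConfig) -> float:
    """Probability that at least ``i`` additional units are needed.

    This is the probability that demand exceeds what ``U + i - 1`` units
    can serve: ``P(X > (U + i - 1) * C | lambda)``.  Non-increasing in ``i``.
    """
    if not 1 <= i <= config.I:
        raise DomainError(f"i must lie in [1, {config.I}]")
    return float(poisson_tail((state.units + i - 1) * config.C, state.lam))


def prob_can_decrease(i: int, state: AllocatorState, config: AllocatorConfig) -> float:
    """Probability that ``U - i`` units still cover demand:
    ``P(X <= (U - i) * C | lambda)``.  Non-increasing in ``i``."""
    if not 1 <= i <= min(config.I, state.units - config.u_min):
        raise DomainError(
            f"i must lie in [1, {min(config.I, state.units - config.u_min)}]"
        )
    return float(stats.poisson.cdf((state.units - i) * config.C, state.lam))


def allocate_step(state: AllocatorState, q_observed: float, config: AllocatorConfig) -> AllocatorState:
    """Process one interval's observed request count and rescale.

    The EMA estimate is updated first (the very first observation seeds
    the estimate directly), then the candidate step sizes are scanned from
    ``I`` down to 1: the largest ``i`` whose increase probability strictly
    exceeds ``thre_i`` adds ``i`` units; failing that, the largest ``i``
    whose decrease probability strictly exceeds ``thre_d`` removes ``i``
    units; otherwise the unit count is unchanged.  The result is clamped
    to ``[u_min, u_max]``.
    """
    if q_observed < 0:
        raise DomainError("observed request count must be non-negative")
    if state.t == 0:
        lam = float(q_observed)
    else:
        lam = ema_update(q_observed, state.lam, smoothing_alpha(config.w))

    units = state.units
    # Increase branch: tails at capacities (U + i - 1) * C for i = 1..I.
    i_grid = np.arange(1, config.I + 1)
    inc_probs = np.clip(stats.poisson.sf((units + i_grid - 1) * config.C, lam), 0.0, 1.0)
    qualifying = np.nonzero(inc_probs > config.thre_i)[0]
    if qualifying.size:
        units = units + int(qualifying[-1] + 1)
    else:
        d_max = min(config.I, units - config.u_min)
        if d_max >= 1:
            d_grid = np.arange(1, d_max + 1)
            dec_probs = stats.poisson.cdf((units - d_grid) * config.C, lam)
            qualifying = np.nonzero(dec_probs > config.thre_d)[0]
            if qualifying.size:
                units = units - int(qualifying[-1] + 1)

    units = min(max(units, config.u_min), config.u_max)
    return AllocatorState(lam=lam, units=units, t=state.t + 1)
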