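"""Parallelized Gillespie direct method for unimolecular reactions.

Every worker aggregates the global per-channel propensities (``a_j = k_j N_j``
with N_j the *global* reactant count) and draws the waiting time and the
channel from the globally seeded stream, so the outcome is identical on all
workers without synchronization.  When a walk event changes reactant counts,
the scheduled firing time is rescaled by the propensity ratio instead of
redrawing, which preserves the exponential law.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "aggregate_propensities",
    "new_interval",
    "select_channel",
    "reschedule_after_walk",
]


def aggregate_propensities(rates, global_counts) -> np.ndarray:
    """Per-channel propensities a_j = k_j N_j from global reactant counts."""
    rates = np.asarray(rates, dtype=np.float64)
    global_counts = np.asarray(global_counts, dtype=np.float64)
    return rates * global_counts


def new_interval(a_g: float, rng) -> float:
    """Exponential waiting time −ln(r)/a_g; infinite when no propensity."""
    if a_g <= 0.0:
        return math.inf
    r1 = rng.random()
    while r1 <= 0.0:  # guard the measure-zero log(0)
        r1 = rng.random()
    return -math.log(r1) / a_g


def select_channel(a, rng) -> int:
    """Index u of the channel with cum_{u-1} < a_g·r2 <= cum_u (0-based)."""
    a = np.asarray(a, dtype=np.float64)
    cum = np.cumsum(a)
    a_g = cum[-1]
    if a_g <= 0:
        raise ValueError("select_channel requires positive total propensity")
    target = a_g * rng.random()
    if target == 0.0:
        return int(np.argmax(a > 0))
    return int(np.searchsorted(cum, target, side="left"))


def reschedule_after_walk(a_0: float, a_g: float, t_e: float, t_s: float):
    """New firing time after counts changed: t_s + a_0 (t_e − t_s) / a_g.

    Returns ``math.inf`` when the propensity vanished and ``None`` when it
    rose from zero (the caller must draw a fresh interval instead).
    """
    if a_g <= 0.0:
        return math.inf
    if a_0 <= 0.0 or math.isinf(t_e):
        return None
    if t_e < t_s:
        raise ValueError(f"scheduled time {t_e} precedes current time {t_s}")
    return t_s + a_0 * (t_e - t_s) / a_g
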