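"""Temporal-response classification, contingency statistics, and active-force
estimation.

Fibrosity traces are classified into the three temporal classes seen after
stretch — monotonic reinforcement, retraction followed by reinforcement,
monotonic retraction — plus "flat" for unstretched controls.  Contingency
tables of protrusion responses (extension / none / retraction) across stretch
conditions are tested with Pearson's chi-square and, for 2x2 tables, Fisher's
exact test, both written out from first principles (scipy serves as an
independent cross-check in the test suite).  Force-trace utilities estimate
the steady isometric force and the active per-cell contraction force revealed
by a ROCK-inhibitor decrement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "ResponseClass",
    "ActiveForceResult",
    "classify_trace",
    "chi_square_independence",
    "fisher_exact",
    "steady_force",
    "active_force",
]

MONOTONIC_REINFORCEMENT = "monotonic_reinforcement"
RETRACTION_THEN_REINFORCEMENT = "retraction_then_reinforcement"
MONOTONIC_RETRACTION = "monotonic_retraction"
FLAT = "flat"

#: Valid trace labels.  There is deliberately no "reinforcement followed by
#: retraction" label: growth after the stretch event is monotone in the model
#: and that sequence was never observed, so a trace matching it raises.
RESPONSE_CLASSES = (
    MONOTONIC_REINFORCEMENT,
    RETRACTION_THEN_REINFORCEMENT,
    MONOTONIC_RETRACTION,
    FLAT,
)

ResponseClass = str


class AnomalousTraceError(ValueError):
    """Trace shows reinforcement followed by retraction, a pattern outside the
    model's reachable set."""


def classify_trace(trace, delta: float = 0.10) -> str:
    """Classify a normalized fibrosity trace into a temporal response class.

    The trace is smoothed by a 3-point moving median, then with ``m`` the
    smoothed minimum and ``f`` the smoothed final value:

    * flat — every deviation from 1 is below ``delta``;
    * monotonic reinforcement — ``m >= 1 - delta`` and ``f >= 1 + delta``;
    * monotonic retraction — ``f <= 1 - delta`` and ``f <= m + delta``;
    * retraction then reinforcement — ``m <= 1 - delta`` and ``f >= m + delta``.

    A trace whose peak precedes a fall of more than ``delta`` (reinforcement
    followed by retraction) raises :class:`AnomalousTraceError`: that pattern
    never occurred and has no label.  Remaining in-between shapes (a dip with
    a recovery smaller than ``delta`` that still ends above ``1 - delta``) are
    labelled by the sign of the final deviation.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 3:
        raise ValueError("trace needs at least 3 time points")
    if delta <= 0:
        raise ValueError("delta must be positive")
    sm = ndimage.median_filter(trace, size=3, mode="nearest")
    m = float(sm.min())
    f = float(sm[-1])
    peak_idx = int(np.argmax(sm))
    if sm[peak_idx] >= 1.0 + delta and f <= sm[peak_idx] - delta:
        raise AnomalousTraceError(
            "trace rose then fell by more than delta: reinforcement followed "
            "by retraction is outside the model's response classes"
        )
    if float(np.abs(sm - 1.0).max()) < delta:
        return FLAT
    if m >= 1.0 - delta and f >= 1.0 + delta:
        return MONOTONIC_REINFORCEMENT
    if f <= 1.0 - delta and f <= m + delta:
        return MONOTONIC_RETRACTION
    if m <= 1.0 - delta and f >= m + delta:
        return RETRACTION_THEN_REINFORCEMENT
    # residual shapes: deviation exceeded delta at some point but the ending
    # is neither clearly reinforced nor clearly retracted
    return MONOTONIC_RETRACTION if f < 1.0 else FLAT


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("contingency table must hold non-negative integers")
    return np.round(t)


def chi_square_independence(table, yates: bool = False):
    """Pearson chi-square test of independence on an R x C count table.

    Expected counts come from the row/column margins; the statistic is
    ``sum((O - E)^2 / E)`` with ``df = (R - 1)(C - 1)`` and the p-value from
    the chi-square upper tail.  No continuity correction by default;
    ``yates=True`` applies the Yates correction (2x2 only).
    """
    t = _as_table(table)
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("table has a zero margin; expected counts undefined")
    expected = np.outer(row, col) / n
    resid = np.abs(t - expected)
    if yates:
        if t.shape != (2, 2):
            raise ValueError("Yates correction applies to 2x2 tables only")
        resid = np.maximum(resid - 0.5, 0.0)
    statistic = float(np.sum(resid ** 2 / expected))
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def fisher_exact(table) -> float:
    """Two-sided Fisher exact test for a 2x2 table.

    Sums hypergeometric probabilities, margins fixed, of every table whose
    probability does not exceed that of the observed table (with a small
    relative tolerance for ties, the standard convention).
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    a = int(t[0, 0])
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n = int(t.sum())
    if n == 0:
        raise ValueError("empty table")
    dist = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(np.sum(probs[probs <= p_obs * (1 + 1e-9)]))
    return min(p, 1.0)


def steady_force(force, window_points: int | None = None,
                 times=None, window_minutes: float | None = None) -> float:
    """Steady-state force: mean of the final moving-average window.

    The window may be given in samples (``window_points``) or, with ``times``,
    in minutes.  The window must be no longer than the trace.
    """
    force = np.asarray(force, dtype=float)
    if force.ndim != 1 or force.size == 0:
        raise ValueError("force trace must be a non-empty 1-D array")
    if window_points is None:
        if times is None or window_minutes is None:
            raise ValueError("give window_points, or times plus window_minutes")
        times = np.asarray(times, dtype=float)
        window_points = int(np.sum(times >= times[-1] - window_minutes))
    if not (0 < window_points <= force.size):
        raise ValueError("window longer than trace")
    return float(force[-window_points:].mean())


@dataclass(frozen=True)
class ActiveForceResult:
    """Active contraction estimate from a drug-induced force decrement.

    ``delta_f_total`` is the construct-level steady-force drop (same units as
    the input traces); ``per_cell_force`` divides by the cell count.  The
    optional ``active_stress`` scales by bar spacing and cell volume,
    ``delta_f * spacing / (n_cells * cell_volume)`` — a coarse, order-of-
    magnitude estimate kept behind an explicit opt-in.
    """

    delta_f_total: float
    n_cells: int
    per_cell_force: float
    active_stress: float | None = None


def active_force(pre_drug, post_drug, n_cells: int,
                 window_points: int = 1,
                 bar_spacing_m: float | None = None,
                 cell_volume_m3: float | None = None) -> ActiveForceResult:
    """Per-cell active contraction force from pre-/post-inhibitor steady forces.

    ``delta_F = steady(pre) - steady(post)``; a negative decrement (force rose
    after the drug) triggers a warning rather than an error.  Supplying both
    ``bar_spacing_m`` and ``cell_volume_m3`` adds the experimental
    active-stress estimate.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    delta = (steady_force(pre_drug, window_points)
             - steady_force(post_drug, window_points))
    if delta < 0:
        warnings.warn("negative decrement: force increased after the drug",
                      stacklevel=2)
    stress = None
    if bar_spacing_m is not None and cell_volume_m3 is not None:
        stress = delta * bar_spacing_m / (n_cells * cell_volume_m3)
    return ActiveForceResult(
        delta_f_total=float(delta),
        n_cells=int(n_cells),
        per_cell_force=float(delta / n_cells),
        active_stress=stress,
    )
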