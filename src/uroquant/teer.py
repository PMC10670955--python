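"""Transepithelial electrical resistance (TEER) from Ussing-chamber readings.

Net resistance is obtained by Ohm's law (when raw potential/current pairs
are supplied), blank-corrected by the fluid resistance measured without
tissue, and scaled by the exposed window area to Ohm*cm^2.  Because
absolute TEER varies strongly between tissue preparations, series are
normalized to the reading at the end of the 30 min equilibration period
and group comparisons run on the relative values at fixed time points with
an exact two-tailed Mann-Whitney U test (full enumeration at the small
group sizes typical of ex vivo work).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ElectroTrace",
    "TEERSeries",
    "TimepointComparison",
    "circular_window_area",
    "teer_from_trace",
    "relative_teer",
    "process_trace",
    "mann_whitney_u",
    "mann_whitney_exact",
    "compare_timepoint",
    "EXACT_ENUMERATION_MAX_N",
]

# all of this assay's group sizes (2-6 per group) fall under full enumeration
EXACT_ENUMERATION_MAX_N = 12


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectroTrace:
    """One chamber's raw readings.

    ``readings`` holds either ``(time_min, resistance_ohm)`` pairs or
    ``(time_min, potential_mV, current_uA)`` triples; times must be
    strictly increasing.
    """

    chamber_id: str
    sex: str
    treatment: str
    readings: tuple[tuple[float, ...], ...]
    blank_resistance_ohm: float
    window_area_cm2: float
    pll_window_min: tuple[float, float] = (30.0, 45.0)

    def __post_init__(self) -> None:
        if self.blank_resistance_ohm < 0:
            raise ValueError("blank_resistance_ohm must be non-negative")
        if self.window_area_cm2 <= 0:
            raise ValueError("window_area_cm2 must be positive")
        times = [r[0] for r in self.readings]
        if len(times) < 1:
            raise ValueError("trace has no readings")
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("reading times must be strictly increasing")

    @property
    def times_min(self) -> tuple[float, ...]:
        return tuple(r[0] for r in self.readings)


@dataclass(frozen=True)
class TEERSeries:
    """Absolute (and optionally relative) TEER per time point."""

    chamber_id: str
    sex: str
    treatment: str
    times_min: tuple[float, ...]
    teer_ohm_cm2: tuple[float, ...]
    relative_pct: tuple[float, ...] | None = None
    anchor_teer_ohm_cm2: float | None = None

    def value_at(self, time_min: float, relative: bool = False) -> float:
        values = self.relative_pct if relative else self.teer_ohm_cm2
        if relative and values is None:
            raise ValueError("relative series not computed; call relative_teer")
        for t, v in zip(self.times_min, values):
            if math.isclose(t, time_min):
                return v
        raise KeyError(f"no reading at {time_min} min")


@dataclass(frozen=True)
class TimepointComparison:
    time_min: float
    group_a: tuple[float, ...]
    group_b: tuple[float, ...]
    test_name: str
    statistic: float
    p_value: float


# --------------------------------------------------------------------------
# TEER arithmetic
# --------------------------------------------------------------------------

def circular_window_area(diameter_mm: float) -> float:
    """Area in cm^2 of a circular exposure window of the given diameter."""
    if diameter_mm < 0:
        raise ValueError("diameter must be non-negative")
    radius_cm = diameter_mm / 2 / 10
    return math.pi * radius_cm ** 2


def teer_from_trace(trace: ElectroTrace) -> TEERSeries:
    """Absolute TEER per reading: (R_total - R_blank) * window area.

    Raw ``(t, potential_mV, current_uA)`` readings are converted by Ohm's
    law first (R = dV/dI, reported as a magnitude).  A blank exceeding the
    total resistance, or a zero current, raises with the offending time
    point named.
    """
    times, teers = [], []
    for reading in trace.readings:
        if len(reading) == 2:
            t, r_total = reading
        elif len(reading) == 3:
            t, mv, ua = reading
            if ua == 0:
                raise ValueError(f"zero current at t={t} min")
            r_total = abs((mv * 1e-3) / (ua * 1e-6))
        else:
            raise ValueError("readings must be (t, R) or (t, mV, uA)")
        if trace.blank_resistance_ohm > r_total:
            raise ValueError(
                f"blank resistance exceeds total resistance at t={t} min"
            )
        times.append(float(t))
        teers.append((r_total - trace.blank_resistance_ohm) * trace.window_area_cm2)
    return TEERSeries(
        chamber_id=trace.chamber_id, sex=trace.sex, treatment=trace.treatment,
        times_min=tuple(times), teer_ohm_cm2=tuple(teers),
    )


def relative_teer(series: TEERSeries, anchor_time_min: float = 30.0) -> TEERSeries:
    """Normalize to the equilibration-end reading: 100% at the anchor.

    If no reading exists exactly at the anchor time, the nearest earlier
    reading is used and a warning is emitted.
    """
    anchor = None
    for t, v in zip(series.times_min, series.teer_ohm_cm2):
        if math.isclose(t, anchor_time_min):
            anchor = v
            break
    if anchor is None:
        earlier = [(t, v) for t, v in zip(series.times_min, series.teer_ohm_cm2)
                   if t < anchor_time_min]
        if not earlier:
            raise ValueError(f"no reading at or before {anchor_time_min} min")
        t_used, anchor = earlier[-1]
        warnings.warn(
            f"no reading at {anchor_time_min} min; anchoring at {t_used} min",
            stacklevel=2,
        )
    if anchor <= 0:
        raise ValueError("anchor TEER must be positive for normalization")
    rel = tuple(100.0 * v / anchor for v in series.teer_ohm_cm2)
    return TEERSeries(
        chamber_id=series.chamber_id, sex=series.sex, treatment=series.treatment,
        times_min=series.times_min, teer_ohm_cm2=series.teer_ohm_cm2,
        relative_pct=rel, anchor_teer_ohm_cm2=anchor,
    )


def process_trace(trace: ElectroTrace, anchor_time_min: float = 30.0) -> TEERSeries:
    """Convenience: absolute TEER then anchor normalization."""
    return relative_teer(teer_from_trace(trace), anchor_time_min)


# --------------------------------------------------------------------------
# exact Mann-Whitney U
# --------------------------------------------------------------------------

def _u_statistic(ranks_a: np.ndarray, n1: int) -> float:
    return float(ranks_a.sum() - n1 * (n1 + 1) / 2)


def mann_whitney_exact(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Exact two-tailed Mann-Whitney U by full enumeration.

    Mid-ranks handle ties.  All C(n1+n2, n1) assignments of the pooled
    ranks to group A are enumerated; the two-tailed p sums both tails at
    least as extreme as the observed U (the null distribution of U is
    symmetric about n1*n2/2 even under ties), capped at 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = _u_statistic(ranks[:n1], n1)
    u_lo = min(u_obs, n1 * n2 - u_obs)
    u_hi = n1 * n2 - u_lo

    eps = 1e-9
    total = 0
    extreme = 0
    for idx in combinations(range(n1 + n2), n1):
        u = _u_statistic(ranks[list(idx)], n1)
        total += 1
        if u <= u_lo + eps or u >= u_hi - eps:
            extreme += 1
    return u_obs, min(1.0, extreme / total)


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[str, float, float]:
    """Two-tailed Mann-Whitney U: exact enumeration for combined n <= 12,
    mid-rank normal approximation with tie correction otherwise.

    Returns ``(method_name, U, p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) + len(b) <= EXACT_ENUMERATION_MAX_N:
        u, p = mann_whitney_exact(a, b)
        return "mann_whitney_exact", u, p
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return "mann_whitney_approx", float(res.statistic), float(res.pvalue)


def compare_timepoint(
    group_a: Sequence[float], group_b: Sequence[float], time_min: float
) -> TimepointComparison:
    """Compare two groups' relative TEER values at one time point."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 values")
    name, u, p = mann_whitney_u(group_a, group_b)
    return TimepointComparison(
        time_min=float(time_min),
        group_a=tuple(float(x) for x in group_a),
        group_b=tuple(float(x) for x in group_b),
        test_name=name, statistic=u, p_value=p,
    )
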