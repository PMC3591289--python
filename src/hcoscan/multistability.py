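"""Coexistence ranges, the ten-class multistability taxonomy, and prevalence.

A case's attracting regimes are summarized by intervals on the leak
conductance axis: the robust-bursting range from the scanner and the
stable stationary-state intervals (hyp1, hyp2, dep1, dep2, ...) from the
continuation.  Multistability is detected purely by interval overlap: every
maximal sub-interval on which two or more regimes coexist becomes a
:class:`CoexistenceRange` (order 2 = bistable, 3 = tristable).

The arrangement of coexistence ranges maps onto a ten-class taxonomy
(A..J) of observed multistability patterns, e.g. class A is a single range
where bursting coexists with hyp1, class G a tristable range accompanied
by hyp1+dep1 and dep1+bursting ranges.  The *prevalence* of multistability
for a case is the fraction of its bursting range over which bursting
coexists with at least one stable stationary state; cohort prevalences are
summarized by mean/SD plus an outlier-adjusted mean/SD computed after
excluding values larger than twice the mean.

Intervals are treated as closed; zero-length overlaps (single points) are
excluded from coexistence ranges and prevalence but kept in diagnostics.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .continuation import StableInterval
from .scan import BurstingRange

__all__ = [
    "CoexistenceRange", "PrevalenceSummary", "coexistence_ranges",
    "classify_scenario", "prevalence", "summarize_prevalence",
    "multistable_at", "SCENARIO_PATTERNS", "BURSTING",
]

#: regime name used for the bursting interval
BURSTING = "bursting"


@dataclass(frozen=True)
class CoexistenceRange:
    g_min: float
    g_max: float
    regimes: frozenset          # subset of {"bursting", "hyp1", "dep1", ...}

    @property
    def order(self) -> int:
        return len(self.regimes)

    @property
    def width(self) -> float:
        return self.g_max - self.g_min

    def __contains__(self, g: float) -> bool:
        return self.g_min <= g <= self.g_max


@dataclass(frozen=True)
class PrevalenceSummary:
    values: tuple
    mean: float
    sd: float
    adjusted_mean: float
    adjusted_sd: float
    n_excluded: int
    exclusion_rule: str = "exclude values > 2 * mean"


def _named_intervals(intervals, bursting):
    named = [(iv.label, iv.g_min, iv.g_max) for iv in intervals]
    if bursting is not None:
        named.append((BURSTING, bursting.g_min, bursting.g_max))
    return named


def coexistence_ranges(intervals, bursting: BurstingRange = None,
                       keep_points: bool = False):
    """Maximal sub-intervals with a constant regime set of size >= 2.

    ``intervals`` are the labeled stable stationary-state intervals (their
    upper ends may be ``inf``); ``bursting`` the scanned bursting range.
    Includes stationary-stationary coexistences as well as those involving
    bursting; results are sorted by left edge.  Zero-width (single-point)
    overlaps are dropped unless ``keep_points`` is set.
    """
    named = _named_intervals(intervals, bursting)
    edges = sorted({e for _, lo, hi in named for e in (lo, hi) if math.isfinite(e)})
    if not edges:
        return []
    # elementary segments between consecutive edges (plus a final unbounded one)
    segments = list(zip(edges[:-1], edges[1:]))
    segments.append((edges[-1], math.inf))
    raw = []
    for lo, hi in segments:
        if hi <= lo:
            continue
        mid = lo + 0.5 * (min(hi, lo + 1.0) - lo) if math.isinf(hi) else 0.5 * (lo + hi)
        active = frozenset(name for name, a, b in named if a <= mid <= b)
        if len(active) >= 2:
            raw.append([lo, hi, active])
    # merge adjacent segments with identical regime sets
    merged = []
    for lo, hi, active in raw:
        if merged and merged[-1][2] == active and merged[-1][1] == lo:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi, active])
    out = [CoexistenceRange(lo, hi, active) for lo, hi, active in merged]
    if keep_points:
        # single-point overlaps (shared endpoints of exactly-touching ranges)
        for name_a, a0, a1 in named:
            for name_b, b0, b1 in named:
                if name_a < name_b and (a1 == b0 or b1 == a0):
                    p = a1 if a1 == b0 else b1
                    if not any(r.g_min < p < r.g_max for r in out):
                        out.append(CoexistenceRange(p, p, frozenset({name_a, name_b})))
    return sorted(out, key=lambda r: (r.g_min, r.g_max))


def _pattern(ranges) -> Counter:
    return Counter(frozenset(r.regimes) for r in ranges if r.width > 0)


def _fs(*names):
    return frozenset(names)


#: the ten canonical multistability arrangements (multisets of regime sets)
SCENARIO_PATTERNS = {
    "A": Counter([_fs(BURSTING, "hyp1")]),
    "B": Counter([_fs(BURSTING, "hyp2")]),
    "C": Counter([_fs(BURSTING, "hyp1"), _fs("dep1", "dep2")]),
    "D": Counter([_fs(BURSTING, "hyp1"), _fs(BURSTING, "dep1")]),
    "E": Counter([_fs("hyp1", "dep1"), _fs("dep1", BURSTING)]),
    "F": Counter([_fs("dep1", "dep2"), _fs("dep1", BURSTING), _fs("hyp1", BURSTING)]),
    "G": Counter([_fs(BURSTING, "hyp1", "dep1"), _fs("hyp1", "dep1"),
                  _fs("dep1", BURSTING)]),
    "H": Counter([_fs(BURSTING, "hyp1", "dep1"), _fs("hyp1", BURSTING),
                  _fs("dep1", BURSTING)]),
    "I": Counter([_fs(BURSTING, "hyp1", "dep1"), _fs("hyp1", "dep1"),
                  _fs("dep1", BURSTING), _fs("dep1", "dep2")]),
    "J": Counter([_fs("hyp1", "dep1"), _fs("hyp1", "dep1"),
                  _fs(BURSTING, "hyp1", "dep1")]),
}


def classify_scenario(ranges) -> str:
    """Map the multiset of coexistence regime-sets to its taxonomy class.

    Returns one of "A".."J", "none" (no coexistence), or "unclassified"
    for arrangements outside the taxonomy.
    """
    pat = _pattern(ranges)
    if not pat:
        return "none"
    for cls, ref in SCENARIO_PATTERNS.items():
        if pat == ref:
            return cls
    return "unclassified"


def prevalence(bursting: BurstingRange, ranges) -> float:
    """Fraction of the bursting range supporting coexistence with bursting.

    Union length of the bursting-containing coexistence ranges (clipped to
    the bursting range) divided by the bursting-range width; stationary-
    only coexistences do not count.
    """
    width = bursting.g_max - bursting.g_min
    if width <= 0:
        raise ValueError("bursting range has zero width; prevalence undefined")
    pieces = []
    for r in ranges:
        if BURSTING not in r.regimes:
            continue
        lo = max(r.g_min, bursting.g_min)
        hi = min(r.g_max, bursting.g_max)
        if hi > lo:
            pieces.append((lo, hi))
    pieces.sort()
    total = 0.0
    cur_lo, cur_hi = None, None
    for lo, hi in pieces:
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        total += cur_hi - cur_lo
    return total / width


def summarize_prevalence(values) -> PrevalenceSummary:
    """Mean/SD plus the outlier-adjusted summary.

    SDs use the sample convention (ddof=1; 0.0 for a single value).  The
    adjusted statistics are computed on the subset with value <= 2 * mean.
    """
    values = [float(v) for v in values]
    if not values:
        raise ValueError("no prevalence values supplied")
    arr = np.asarray(values)

    def _sd(a):
        return float(np.std(a, ddof=1)) if a.size > 1 else 0.0

    mean = float(arr.mean())
    kept = arr[arr <= 2.0 * mean]
    if kept.size == 0:
        kept = arr
    return PrevalenceSummary(
        values=tuple(values), mean=mean, sd=_sd(arr),
        adjusted_mean=float(kept.mean()), adjusted_sd=_sd(kept),
        n_excluded=int(arr.size - kept.size),
    )


def multistable_at(g: float, ranges):
    """Regime sets of every (closed) coexistence range containing ``g``."""
    return [frozenset(r.regimes) for r in ranges if g in r]
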