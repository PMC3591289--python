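"""Activity-regime classification of membrane-potential traces.

The taxonomy follows the screening database conventions:

* spikes are local maxima of V above a -10 mV threshold;
* a trace with no spikes is *silent* (subthreshold oscillations included);
* all interspike intervals < 1 s -> *tonic spiking*;
* at least one interspike interval beyond 1 s -> burst statistics are
  computed; coefficient of variation (CV) of the burst period > 5 %
  -> *irregular*, otherwise *bursting*;
* V continuously above -10 mV for more than 1 s with no spike maxima in
  that window -> *plateau-like* (excluded from robust bursting);
* a burster is *robust* iff CV(period) < 5 % and CV(interburst interval)
  < 10 %;
* a two-cell network is a *functional* half-center oscillator iff both
  cells burst with CV(period) < 5 % and their mean relative phase lies in
  [0.45, 0.55].

Bursts are maximal runs of spikes separated by gaps >= 1 s; burst onset and
end are the first and last spike of the run, the period is onset-to-onset.
Burst CVs use the population standard deviation (ddof=0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .integrate import Trajectory

__all__ = [
    "SPIKE_THRESHOLD_MV", "BURST_GAP_S", "CV_PERIOD_MAX", "CV_IBI_MAX",
    "PHASE_WINDOW",
    "Regime", "SpikeTrain", "BurstStats", "InsufficientCyclesError",
    "detect_spikes", "split_bursts", "burst_stats", "classify_regime",
    "is_robust_burster", "hco_functional",
]

SPIKE_THRESHOLD_MV = -10.0
BURST_GAP_S = 1.0
CV_PERIOD_MAX = 0.05
CV_IBI_MAX = 0.10
PHASE_WINDOW = (0.45, 0.55)


class Regime(str, Enum):
    SILENT = "silent"
    TONIC = "tonic_spiking"
    BURSTING = "bursting"
    IRREGULAR = "irregular"
    PLATEAU = "plateau_like"


class InsufficientCyclesError(RuntimeError):
    """Burst statistics requested on a trace with fewer than two bursts."""


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (s) with the detection threshold."""

    spike_times: np.ndarray
    detection_threshold: float = SPIKE_THRESHOLD_MV

    def __post_init__(self):
        object.__setattr__(self, "spike_times",
                           np.asarray(self.spike_times, dtype=float))
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self):
        return self.spike_times.size

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)


def _cv(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return 0.0
    m = x.mean()
    if m == 0:
        return 0.0
    return float(x.std(ddof=0) / m)


@dataclass(frozen=True)
class BurstStats:
    """Per-burst timing statistics (all in seconds)."""

    burst_onsets: np.ndarray
    burst_ends: np.ndarray
    burst_durations: np.ndarray
    interburst_intervals: np.ndarray   # end_i -> onset_{i+1}
    periods: np.ndarray                # onset-to-onset
    cv_period: float
    cv_ibi: float
    spikes_per_burst: np.ndarray = field(default=None)

    @property
    def n_bursts(self) -> int:
        return len(self.burst_onsets)

    @property
    def mean_period(self) -> float:
        return float(np.mean(self.periods)) if len(self.periods) else float("nan")


def detect_spikes(trace: Trajectory, threshold: float = SPIKE_THRESHOLD_MV) -> SpikeTrain:
    """Spike times = times of local maxima of V exceeding ``threshold``.

    A run of equal suprathreshold samples yields a single spike (at the
    first sample of the run).  An empty train is a valid result.
    """
    v = trace.v
    if v.size < 3:
        raise ValueError("need at least 3 samples to detect spikes")
    left = v[1:-1] > v[:-2]
    right = v[1:-1] >= v[2:]
    peaks = np.flatnonzero(left & right & (v[1:-1] > threshold)) + 1
    return SpikeTrain(trace.times[peaks], detection_threshold=threshold)


def split_bursts(spikes: SpikeTrain, gap: float = BURST_GAP_S):
    """Group spikes into maximal runs separated by interspike gaps >= ``gap``.

    Returns a list of (onset, end) spike-time pairs, one per burst.
    """
    t = spikes.spike_times
    if t.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) >= gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [t.size - 1]])
    return [(t[i], t[j]) for i, j in zip(starts, ends)]


def burst_stats(spikes: SpikeTrain, gap: float = BURST_GAP_S) -> BurstStats:
    """Burst timing statistics; requires at least two bursts."""
    bursts = split_bursts(spikes, gap)
    if len(bursts) < 2:
        raise InsufficientCyclesError(
            f"need >= 2 bursts for statistics, found {len(bursts)}")
    onsets = np.array([b[0] for b in bursts])
    ends = np.array([b[1] for b in bursts])
    durations = ends - onsets
    ibis = onsets[1:] - ends[:-1]
    periods = np.diff(onsets)
    t = spikes.spike_times
    counts = np.array([np.count_nonzero((t >= a) & (t <= b)) for a, b in bursts])
    return BurstStats(
        burst_onsets=onsets, burst_ends=ends, burst_durations=durations,
        interburst_intervals=ibis, periods=periods,
        cv_period=_cv(periods), cv_ibi=_cv(ibis),
        spikes_per_burst=counts,
    )


def _has_plateau(trace: Trajectory, spikes: SpikeTrain,
                 threshold: float = SPIKE_THRESHOLD_MV,
                 min_duration: float = 1.0, edge_margin: float = 0.05) -> bool:
    """True if V stays above ``threshold`` continuously for more than
    ``min_duration`` seconds with no spike maximum inside that window.

    Spike maxima within ``edge_margin`` of the window edges are ignored:
    the onset/offset of a voltage plateau is itself a local maximum of V,
    which should not disqualify the plateau."""
    above = trace.v > threshold
    if not np.any(above):
        return False
    runs = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append((trace.times[i], trace.times[j]))
            i = j + 1
        else:
            i += 1
    st = spikes.spike_times
    for t0, t1 in runs:
        if t1 - t0 > min_duration:
            if not np.any((st >= t0 + edge_margin) & (st <= t1 - edge_margin)):
                return True
    return False


def classify_regime(spikes: SpikeTrain, trace: Trajectory,
                    gap: float = BURST_GAP_S):
    """Classify a post-transient trace.

    Returns ``(Regime, BurstStats | None)``; statistics accompany both the
    bursting and the irregular labels.
    """
    if _has_plateau(trace, spikes):
        return Regime.PLATEAU, None
    if len(spikes) == 0:
        return Regime.SILENT, None
    if len(spikes) == 1 or np.all(spikes.isis < gap):
        return Regime.TONIC, None
    stats = burst_stats(spikes, gap)
    if stats.cv_period > CV_PERIOD_MAX:
        return Regime.IRREGULAR, stats
    return Regime.BURSTING, stats


def is_robust_burster(stats: BurstStats) -> bool:
    """CV(period) < 5 % and CV(interburst interval) < 10 %."""
    return stats.cv_period < CV_PERIOD_MAX and stats.cv_ibi < CV_IBI_MAX


def relative_phase(stats_a: BurstStats, stats_b: BurstStats) -> float:
    """Mean phase of b's burst onsets within a's burst cycles.

    For each consecutive pair of a-onsets defining one cycle, every b-onset
    falling inside contributes ``(onset_b - onset_a) / cycle_length``; the
    result is the average over all contributions.
    """
    phases = []
    a = stats_a.burst_onsets
    b = stats_b.burst_onsets
    for t0, t1 in zip(a[:-1], a[1:]):
        inside = b[(b >= t0) & (b < t1)]
        phases.extend((inside - t0) / (t1 - t0))
    if not phases:
        raise InsufficientCyclesError("no overlapping burst cycles to estimate phase")
    return float(np.mean(phases))


def hco_functional(spikes_a: SpikeTrain, spikes_b: SpikeTrain,
                   trace_a: Trajectory, trace_b: Trajectory):
    """Functional half-center oscillator test.

    Both cells must classify as bursting with CV(period) < 5 % and the mean
    relative phase must lie in [0.45, 0.55].  Returns
    ``(functional: bool, phase: float | None)``; raises ``ValueError`` if
    either cell is not bursting at all (precondition of the criterion).
    """
    label_a, stats_a = classify_regime(spikes_a, trace_a)
    label_b, stats_b = classify_regime(spikes_b, trace_b)
    for label in (label_a, label_b):
        if label not in (Regime.BURSTING, Regime.IRREGULAR):
            raise ValueError(f"hco_functional requires bursting cells, got {label.value}")
    if label_a is not Regime.BURSTING or label_b is not Regime.BURSTING:
        return False, None
    phase = relative_phase(stats_a, stats_b)
    lo, hi = PHASE_WINDOW
    return (lo <= phase <= hi), phase
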