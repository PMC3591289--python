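"""Per-case analysis orchestration and cohort summaries.

One *case* is a model plus its original leak conductance.  The full
analysis chain runs: settle at the original g and classify; if the case is
a robust burster, continue the stationary-state branch from g = 20 nS,
extract labeled stable intervals, scan the robust-bursting range, overlap
the two into coexistence ranges, classify the multistability scenario,
compute the prevalence, and flag whether the original g itself sits in a
bursting-containing coexistence range.  Results are written to the
relational store and summarized per cohort.

Cases that differ only in the leak conductance share one bifurcation
diagram, so they collapse to a single analysis unit; the driver groups
them by :func:`unique_burster_key` before running.

Stage failures never abort a cohort: a failing case is reported with its
failing stage and the remaining cases proceed (the screening workflow
values robustness over strictness).  Cases are independent units, so any
execution order yields identical reports.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .classify import Regime, classify_regime, detect_spikes, is_robust_burster
from .continuation import (branch_from_high_leak, continue_branch,
                           stable_intervals)
from .integrate import settle
from .multistability import (BURSTING, classify_scenario, coexistence_ranges,
                             multistable_at, prevalence, summarize_prevalence)
from .scan import scan_bursting_range
from .store import BifurcationRecord, ResultsStore, StationaryStateRecord

__all__ = ["AnalysisCase", "ArtifactCase", "CaseRow", "CohortReport",
           "run_case", "run_cohort", "unique_burster_key",
           "analyze_artifacts"]


@dataclass
class AnalysisCase:
    """A model to be analyzed end to end from its ODEs."""

    case_id: int
    system: object                 # DynamicalSystem with the g parameter axis
    original_g: float
    initial_state: np.ndarray
    settle_kwargs: dict = field(default_factory=dict)
    continuation_kwargs: dict = field(default_factory=dict)
    scan_kwargs: dict = field(default_factory=dict)
    continuation_start_g: float = 20.0


@dataclass
class ArtifactCase:
    """A case whose continuation/scan artifacts were computed upstream."""

    case_id: int
    intervals: list
    bursting: object               # BurstingRange or None
    original_g: float


@dataclass
class CaseRow:
    case_id: int
    status: str = "ok"             # "ok" | "non_qualifying" | "failed:<stage>"
    regime_at_original: str = None
    bursting_range: tuple = None
    n_bifurcations: int = None
    intervals: tuple = ()
    coexistence: tuple = ()
    scenario: str = None
    prevalence: float = None
    multistable_at_original: bool = None

    @property
    def qualifying(self) -> bool:
        return self.status == "ok"


@dataclass
class CohortReport:
    rows: list
    scenario_counts: Counter
    n_cases: int
    n_qualifying: int
    n_multistable: int
    multistable_fraction: float
    prevalence_summary: object = None
    prevalence_histogram: tuple = ()   # (bin_edges_percent, counts)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "case_id": r.case_id, "status": r.status,
            "regime": r.regime_at_original,
            "g_min": r.bursting_range[0] if r.bursting_range else None,
            "g_max": r.bursting_range[1] if r.bursting_range else None,
            "scenario": r.scenario, "prevalence": r.prevalence,
            "multistable_at_original": r.multistable_at_original,
        } for r in self.rows])


def unique_burster_key(case_params):
    """Grouping key: every varied parameter except the leak conductance."""
    return (case_params.E_leak,
            tuple(sorted(case_params.scale_factors.items())))


def analyze_artifacts(case_id, intervals, bursting, original_g):
    """Overlap analysis from precomputed intervals and bursting range."""
    ranges = coexistence_ranges(intervals, bursting)
    scenario = classify_scenario(ranges)
    prev = None
    if bursting is not None and bursting.g_max > bursting.g_min:
        prev = prevalence(bursting, ranges)
    at_orig = multistable_at(original_g, ranges)
    return CaseRow(
        case_id=case_id, status="ok",
        bursting_range=(bursting.g_min, bursting.g_max) if bursting else None,
        intervals=tuple((iv.label, iv.g_min, iv.g_max) for iv in intervals),
        coexistence=tuple((r.g_min, r.g_max, tuple(sorted(r.regimes)))
                          for r in ranges),
        scenario=scenario, prevalence=prev,
        multistable_at_original=any(BURSTING in s for s in at_orig),
    )


def _store_case(store, case_id, branch, intervals, row):
    def interval_label_for(p):
        for iv in intervals:
            if iv.g_min <= p.parameter <= iv.g_max and p.stable:
                return iv.label
        return None

    records = [StationaryStateRecord(
        case_id=case_id, point_id=i, parameter=p.parameter,
        state=tuple(p.state), stable=p.stable,
        interval_label=interval_label_for(p),
        scenario_class=row.scenario,
        coexistence_at_original=tuple(
            frozenset(s[2]) for s in row.coexistence),
    ) for i, p in enumerate(branch.points)]
    bifs = [BifurcationRecord(case_id=case_id, label=b.label, kind=b.kind,
                              parameter=b.parameter, state=tuple(b.state))
            for b in branch.bifurcations]
    store.write_case(records, bifs)


def run_case(case, store: ResultsStore = None) -> CaseRow:
    """Execute the full per-case chain; never raises on stage failure."""
    if isinstance(case, ArtifactCase):
        try:
            return analyze_artifacts(case.case_id, case.intervals,
                                     case.bursting, case.original_g)
        except Exception:
            return CaseRow(case_id=case.case_id, status="failed:overlap")

    stage = "settle"
    try:
        system = case.system.with_param(case.original_g)
        traj = settle(system, case.initial_state, **case.settle_kwargs)
        label, stats = classify_regime(detect_spikes(traj), traj)
        regime = label.value
        if not (label is Regime.BURSTING and stats is not None
                and is_robust_burster(stats)):
            return CaseRow(case_id=case.case_id, status="non_qualifying",
                           regime_at_original=regime)
        burst_endpoint = traj.final_state

        stage = "continuation"
        start = branch_from_high_leak(case.system, case.initial_state,
                                      g_start=case.continuation_start_g,
                                      settle_kwargs=case.settle_kwargs)
        branch = continue_branch(case.system, start,
                                 **case.continuation_kwargs)
        intervals = stable_intervals(branch)

        stage = "scan"
        bursting = scan_bursting_range(case.system, case.original_g,
                                       burst_endpoint,
                                       settle_kwargs=case.settle_kwargs,
                                       **case.scan_kwargs)

        stage = "overlap"
        row = analyze_artifacts(case.case_id, intervals, bursting,
                                case.original_g)
        row.regime_at_original = regime
        row.n_bifurcations = len(branch.bifurcations)

        if store is not None:
            stage = "store"
            _store_case(store, case.case_id, branch, intervals, row)
        return row
    except Exception:
        return CaseRow(case_id=case.case_id, status=f"failed:{stage}")


def run_cohort(cases, store: ResultsStore = None, *,
               histogram_bin_percent: float = 5.0) -> CohortReport:
    """Run every case and aggregate the cohort report.

    Aggregates: scenario counts, the multistable fraction (cases with at
    least one bursting-containing coexistence range), the prevalence
    mean/SD with the outlier-adjusted variant, and a prevalence histogram
    (bin width in percentage points).
    """
    cases = list(cases)
    if not cases:
        raise ValueError("empty cohort")
    rows = [run_case(c, store=store) for c in cases]
    qualifying = [r for r in rows if r.qualifying]
    scen = Counter(r.scenario for r in qualifying if r.scenario is not None)
    multistable = [r for r in qualifying
                   if r.coexistence and any(BURSTING in set(c[2])
                                            for c in r.coexistence)]
    prevalences = [r.prevalence for r in qualifying if r.prevalence is not None]
    summary = summarize_prevalence(prevalences) if prevalences else None
    edges = np.arange(0.0, 100.0 + histogram_bin_percent, histogram_bin_percent)
    counts, _ = np.histogram([100.0 * p for p in prevalences], bins=edges)
    return CohortReport(
        rows=rows, scenario_counts=scen,
        n_cases=len(rows), n_qualifying=len(qualifying),
        n_multistable=len(multistable),
        multistable_fraction=len(multistable) / len(rows),
        prevalence_summary=summary,
        prevalence_histogram=(tuple(edges), tuple(int(c) for c in counts)),
    )
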