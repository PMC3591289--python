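"""Leak-conductance range supporting robust bursting.

The scan implements the iterative step-refinement protocol: starting from a
leak conductance where the cell bursts robustly, g is incremented in 1 nS
steps, each probe integrating the full settle protocol (400 s, first 200 s
discarded) *from the endpoint of the last accepted bursting trajectory*,
until the settled trace stops being robust bursting (silence, tonic
spiking, irregular bursting, or plateau-like activity).  The initial
conditions are then reset to the endpoint of the last accepted bursting
trajectory and the process repeats with a tenfold smaller step, down to a
precision of 1e-4 nS (five refinement levels: 1, 0.1, 0.01, 1e-3, 1e-4).
The same procedure with negative steps finds the lower boundary.

Carrying the endpoint state along the sweep keeps the probe on the bursting
attractor through coexistence regions, so the scanned range tracks the
attractor's existence range rather than the basin of some fixed initial
state (hysteresis-aware scanning).  Conductances below 0 are not probed; a
sweep that reaches g = 0 still bursting reports the boundary as the domain
edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import Regime, classify_regime, detect_spikes, is_robust_burster
from .integrate import settle

__all__ = ["BurstingRange", "ScanError", "scan_bursting_range",
           "COARSE_STEP", "PRECISION"]

COARSE_STEP = 1.0    # nS
PRECISION = 1e-4     # nS


class ScanError(RuntimeError):
    pass


@dataclass
class BurstingRange:
    """Robust-bursting range of the leak conductance."""

    g_min: float
    g_max: float
    precision: float = PRECISION
    #: regime that succeeded bursting at each edge ("domain_edge" at g=0)
    boundary_labels: dict = field(default_factory=dict)
    start_g: float = float("nan")
    #: probe log: (g, label, robust) triples in probe order
    probes: list = field(default_factory=list)

    @property
    def width(self) -> float:
        return self.g_max - self.g_min

    def __contains__(self, g: float) -> bool:
        return self.g_min <= g <= self.g_max


def _classify_at(system, g, state, settle_kwargs):
    traj = settle(system.with_param(g), state, **settle_kwargs)
    label, stats = classify_regime(detect_spikes(traj), traj)
    robust = (label is Regime.BURSTING and stats is not None
              and is_robust_burster(stats))
    return robust, label, traj.final_state


def _sweep(system, start_g, state0, sign, settle_kwargs, probes,
           coarse_step=COARSE_STEP, precision=PRECISION,
           max_probes_per_level=200):
    """One directional pass; returns (boundary g, boundary label)."""
    g_ok = start_g
    state = state0
    step = coarse_step
    label_beyond = None
    while True:
        n = 0
        while True:
            g_next = g_ok + sign * step
            clamped = False
            if g_next < 0.0:
                g_next, clamped = 0.0, True
                if g_ok == 0.0:
                    return 0.0, "domain_edge"
            robust, label, endpoint = _classify_at(system, g_next, state,
                                                   settle_kwargs)
            probes.append((g_next, label.value, robust, step))
            if robust:
                g_ok, state = g_next, endpoint
                if clamped:
                    return 0.0, "domain_edge"
            else:
                label_beyond = label.value
                break
            n += 1
            if n > max_probes_per_level:
                raise ScanError(
                    f"no transition within {max_probes_per_level} probes at "
                    f"step {step} (direction {sign:+.0f})")
        if step <= precision * (1 + 1e-9):
            return g_ok, label_beyond
        step /= 10.0


def scan_bursting_range(system, start_g: float, initial_state,
                        settle_kwargs=None, coarse_step: float = COARSE_STEP,
                        precision: float = PRECISION) -> BurstingRange:
    """Robust-bursting g-range by two-sided iterative step refinement.

    ``initial_state`` must put the model into robust bursting at
    ``start_g`` under the settle protocol (precondition).  Both boundaries
    are located to within ``precision``; the returned range always contains
    ``start_g``.
    """
    kw = settle_kwargs or {}
    probes = []
    robust, label, endpoint = _classify_at(system, start_g, initial_state, kw)
    probes.append((start_g, label.value, robust, 0.0))
    if not robust:
        raise ScanError(
            f"model is not a robust burster at start_g={start_g} "
            f"(classified {label.value})")
    g_max, label_up = _sweep(system, start_g, endpoint, +1.0, kw, probes,
                             coarse_step, precision)
    g_min, label_down = _sweep(system, start_g, endpoint, -1.0, kw, probes,
                               coarse_step, precision)
    return BurstingRange(
        g_min=g_min, g_max=g_max, precision=precision,
        boundary_labels={"below": label_down, "above": label_up},
        start_g=start_g, probes=probes,
    )
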