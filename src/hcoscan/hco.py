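"""Reset-perturbation protocol for half-center oscillators.

The protocol probes whether a two-cell reciprocally inhibitory network
recovers its functional alternating bursting after one cell is dropped
into a coexisting stable rest state:

1. integrate the coupled network for 100 s (pre segment);
2. reset one cell's intrinsic state (not clamped: instantaneously
   replaced, then evolving freely) to a stable stationary state of the
   isolated cell, and remove the synaptic interactions for 5 s by setting
   the synaptic maximal conductances to 0 nS — the synaptic gating
   variables keep evolving, only the currents vanish;
3. restore the synaptic conductances and integrate for another 100 s
   (post segment).

Pre and post segments are classified independently (on their last 50 s, to
let re-entrainment transients decay): the network is *functional* when
both cells burst with CV(period) < 5 % and mean relative phase in
[0.45, 0.55].  An outcome is *recovered* iff the post segment is
functional; otherwise the dysfunction mode records what the cells were
doing instead: both stuck at rest, one resting beside an active partner
(rest with synaptically driven damped/subthreshold deflections), tonic
spiking, or irregular bursting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import (Regime, classify_regime, detect_spikes, hco_functional,
                       relative_phase)
from .integrate import Trajectory, integrate
from .models import CoupledSystem

__all__ = ["HCOOutcome", "run_perturbation", "classify_pair",
           "T_PRE", "T_BLOCK", "T_POST"]

T_PRE = 100.0
T_BLOCK = 5.0
T_POST = 100.0


@dataclass
class HCOOutcome:
    outcome: str                   # "recovered" | "dysfunctional"
    dysfunction_mode: str          # "both_at_rest" | "damped_oscillations" |
                                   # "tonic_spiking" | "irregular" | "none"
    pre_functional: bool
    pre_phase: float = None
    post_phase: float = None
    pre_labels: tuple = ()
    post_labels: tuple = ()
    pre_stats: tuple = ()
    post_stats: tuple = ()
    trajectory: Trajectory = None  # full three-phase trace when persisted

    @property
    def recovered(self) -> bool:
        return self.outcome == "recovered"


def _cell_traces(coupled: CoupledSystem, traj: Trajectory):
    sa, sb, _ = coupled.slices()
    tra = Trajectory(traj.times, traj.states[:, sa], {"state_names": list(coupled.cell_a.state_names)})
    trb = Trajectory(traj.times, traj.states[:, sb], {"state_names": list(coupled.cell_b.state_names)})
    return tra, trb


def classify_pair(coupled: CoupledSystem, traj: Trajectory):
    """Classify both cells of a coupled trace; returns labels, stats,
    functional flag and phase (None when either cell is not bursting)."""
    tra, trb = _cell_traces(coupled, traj)
    spa, spb = detect_spikes(tra), detect_spikes(trb)
    la, sa = classify_regime(spa, tra)
    lb, sb = classify_regime(spb, trb)
    functional, phase = False, None
    if la in (Regime.BURSTING, Regime.IRREGULAR) and lb in (Regime.BURSTING, Regime.IRREGULAR):
        functional, phase = hco_functional(spa, spb, tra, trb)
    return (la, lb), (sa, sb), functional, phase


def _dysfunction_mode(labels) -> str:
    la, lb = labels
    both = (la, lb)
    if all(l is Regime.SILENT for l in both):
        return "both_at_rest"
    if any(l is Regime.TONIC for l in both):
        return "tonic_spiking"
    if any(l is Regime.SILENT for l in both):
        # one cell rests beside an active partner: its trace shows the
        # synaptically driven subthreshold deflections around the rest state
        return "damped_oscillations"
    if any(l is Regime.IRREGULAR for l in both):
        return "irregular"
    return "none"


def run_perturbation(coupled: CoupledSystem, initial_state, reset_state,
                     which_cell: str = "b", *,
                     t_pre: float = T_PRE, t_block: float = T_BLOCK,
                     t_post: float = T_POST, analyze_last: float = 50.0,
                     restore: bool = True, keep_trajectory: bool = False,
                     integrate_kwargs=None) -> HCOOutcome:
    """Run the three-phase reset-perturbation experiment.

    ``reset_state`` must be a stable equilibrium of the isolated cell
    (pass an :class:`~hcoscan.continuation.EquilibriumPoint`); at blockade
    onset the chosen cell's intrinsic state vector is replaced by its
    coordinates while the other cell and the synaptic gates remain
    continuous.  ``restore=False`` runs the control variant in which the
    synapses stay blocked during the final segment.
    """
    if which_cell not in ("a", "b"):
        raise ValueError("which_cell must be 'a' or 'b'")
    if hasattr(reset_state, "stable"):
        if not reset_state.stable:
            raise ValueError("reset_state must be a stable equilibrium")
        reset_vec = np.asarray(reset_state.state, dtype=float)
    else:
        reset_vec = np.asarray(reset_state, dtype=float)
    kw = integrate_kwargs or {}
    sa, sb, _ = coupled.slices()
    cell_slice = sa if which_cell == "a" else sb
    if reset_vec.size != (cell_slice.stop - cell_slice.start):
        raise ValueError("reset state dimension does not match the cell")

    pre = integrate(coupled, np.asarray(initial_state, dtype=float), t_pre, **kw)
    y = pre.final_state
    y[cell_slice] = reset_vec
    blocked = coupled.blocked()
    block = integrate(blocked, y, t_block, t0=t_pre, **kw)
    post_system = coupled if restore else blocked
    post = integrate(post_system, block.final_state, t_post,
                     t0=t_pre + t_block, **kw)

    pre_win = pre.window(pre.times[0] + max(0.0, t_pre - analyze_last), pre.times[-1])
    post_win = post.window(post.times[0] + max(0.0, t_post - analyze_last), post.times[-1])
    pre_labels, pre_stats, pre_ok, pre_phase = classify_pair(coupled, pre_win)
    post_labels, post_stats, post_ok, post_phase = classify_pair(coupled, post_win)

    outcome = "recovered" if post_ok else "dysfunctional"
    mode = "none" if post_ok else _dysfunction_mode(post_labels)
    traj = None
    if keep_trajectory:
        times = np.concatenate([pre.times, block.times[1:], post.times[1:]])
        states = np.vstack([pre.states, block.states[1:], post.states[1:]])
        traj = Trajectory(times, states, {"phases": [t_pre, t_block, t_post]})
    return HCOOutcome(
        outcome=outcome, dysfunction_mode=mode,
        pre_functional=pre_ok, pre_phase=pre_phase, post_phase=post_phase,
        pre_labels=tuple(l.value for l in pre_labels),
        post_labels=tuple(l.value for l in post_labels),
        pre_stats=pre_stats, post_stats=post_stats,
        trajectory=traj,
    )
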