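# hcoscan

Bifurcation screening of conductance-based bursting neurons: equilibrium
continuation, activity-regime classification, leak-conductance range
scanning, multistability taxonomy, and a reset-perturbation protocol for
half-center oscillators.

## The problem

Brute-force parameter screens of single-compartment
Hodgkin–Huxley-type neurons classify each parameter combination ("case")
by the activity it produces — silent, tonic spiking, bursting, irregular —
but direct integration from a handful of initial conditions says nothing
about *which other attractors coexist* with the observed one.  A bursting
cell whose rhythm coexists with a stable rest state can be switched off by
a transient perturbation, a property with direct consequences for central
pattern generators built from such cells.

`hcoscan` extends a screened model database with stationary-state
information and systematically detects multistability:

1. **Continuation.**  For each case, the curve of stationary states
   V̇ = ẋ = 0 is traced in the leak conductance g_leak by pseudo-arclength
   continuation, starting from the hyperpolarized rest obtained by direct
   integration at g_leak = 20 nS.  Stability is read from the Jacobian
   spectrum; folds (LP: a real eigenvalue crossing 0 at a turning point)
   and Andronov–Hopf points (AH: a complex pair crossing the imaginary
   axis) are localized by test-function bisection.  Stable sub-arcs are
   labeled *hyp1, hyp2, …* (V < −35 mV) or *dep1, dep2, …* (V > −35 mV)
   along the branch.
2. **Range scanning.**  The g_leak range supporting *robust bursting*
   (CV(period) < 5 %, CV(interburst interval) < 10 %) is found by an
   iterative step-refinement sweep — 1 nS coarse steps, tenfold
   refinements down to 1e−4 nS — in which each probe integrates the full
   settle protocol (400 s, first 200 s discarded) from the endpoint of the
   last accepted bursting trajectory, so the sweep tracks the bursting
   attractor through coexistence regions.
3. **Overlap analysis.**  Coexistence ranges are intersections of the
   bursting range with the stable intervals; their arrangement maps onto a
   ten-class taxonomy (A–J), and the *prevalence* of multistability is the
   fraction of the bursting range over which bursting coexists with a
   stable rest.
4. **Network perturbation.**  Two cells coupled by reciprocal inhibition
   (spike-mediated + graded synapses) form a half-center oscillator (HCO);
   the protocol integrates it for 100 s, resets one cell to a stable
   stationary state while blocking the synapses for 5 s, restores them,
   integrates 100 s more, and classifies whether functional alternating
   bursting (both cells CV(period) < 5 %, relative phase in 0.45–0.55)
   recovers.

Model kinetics are declarative (YAML configs; see
`configs/leech_hn_template.yaml`), and every analysis stage is exercised
on shipped surrogate systems with analytic or brute-force ground truth —
including a three-dimensional fast–slow burster whose leak-like parameter
axis reproduces the tonic → bursting → silent layout with a
bursting/rest coexistence band.

## Worked example

```python
import numpy as np
from hcoscan.synthetic import MinimalBurster
from hcoscan.continuation import branch_from_high_leak, continue_branch, stable_intervals
from hcoscan.scan import scan_bursting_range
from hcoscan.multistability import coexistence_ranges, classify_scenario, prevalence
from hcoscan.integrate import settle
from hcoscan.classify import detect_spikes, classify_regime

cell = MinimalBurster()                      # leak-like axis g, default g = 2.4
traj = settle(cell, cell.rest_guess() + [5.0, 0.0, 0.0])
label, stats = classify_regime(detect_spikes(traj), traj)
print(f"regime at g=2.4: {label.value}, period {stats.mean_period:.2f} s")

start = branch_from_high_leak(cell, cell.rest_guess(), g_start=20.0)
branch = continue_branch(cell, start)
for b in branch.bifurcations[:1]:
    print(f"{b.label}: g = {b.parameter:.4f} nS, V = {b.state[0]:.1f} mV")
intervals = stable_intervals(branch)
for iv in intervals:
    print(f"{iv.label}: g in [{iv.g_min:.4f}, {iv.g_max:.4f}] nS")

rng = scan_bursting_range(cell, 2.4, traj.final_state)
print(f"robust bursting: g in [{rng.g_min:.4f}, {rng.g_max:.4f}] nS "
      f"(beyond: {rng.boundary_labels['below']} / {rng.boundary_labels['above']})")

ranges = coexistence_ranges(intervals, rng)
print(f"scenario {classify_scenario(ranges)}; "
      f"prevalence {100 * prevalence(rng, ranges):.1f}%")
```

prints

```
regime at g=2.4: bursting, period 9.99 s
AH1: g = 2.7319 nS, V = -45.7 mV
hyp1: g in [2.7319, inf] nS
robust bursting: g in [2.1619, 2.7616] nS (beyond: irregular / irregular)
scenario A; prevalence 4.9%
```

Read: at its default leak conductance the surrogate bursts with a 10 s
period.  The hyperpolarized rest state becomes stable at an Andronov–Hopf
point at g = 2.73 nS and stays stable for all larger g (*hyp1*), while
robust bursting persists up to g = 2.76 nS —
so on 4.9 % of the bursting range the cell is bistable: a strong enough
perturbation at, say, g = 2.75 nS drops it permanently into silence.
That arrangement — a single range where bursting coexists with *hyp1* —
is taxonomy class A.

A thin CLI mirrors the library (`hcoscan grid count hco`,
`hcoscan continue`, `hcoscan scan`, `hcoscan db query …`).

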