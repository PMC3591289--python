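# Methods

This note documents the models, numerical procedures and conventions the
package implements, the design choices made where the procedure was
genuinely open, and what the surrogate-based tests do and do not
demonstrate.

## Units and model representation

All quantities are in mV, nS, nF, nA and seconds; `dV/dt` is in mV/s
(nS·mV/nF), and an injected current of I nA contributes `1000·I/C` mV/s.
A neuron is a declarative `ModelSpec`: a capacitance plus ionic currents
`ḡ·m^p·h·(V−E)` whose gating variables follow first-order kinetics
`dx/dt = (x_∞(V) − x)/τ(V)` with Boltzmann steady states and constant,
sigmoid or bell-shaped time constants.  The leak conductance and reversal
come from the per-case parameters (`CaseParameters`), which also carry
scale factors applied to the canonical maximal conductances.  Jacobians
are assembled analytically from the same declarative structure and are
verified against central finite differences (relative 1e−5) in the test
suite.  No particular cell's published kinetics are bundled; the
YAML template in `configs/` shows the format with structural placeholder
values only.

The canonical screening grids are Cartesian products enumerated row-major
with sequential case ids over the included points: five leak reversal
potentials (−70…−50 mV) and eight scale factors (0–175 % in 25 % steps)
for each of seven maximal conductances.  Excluding the combinations with
both synaptic conductances zero leaves 10,321,920 network cases; pinning
both to zero gives the 163,840 isolated-neuron cases.  Structured
exclusions are counted combinatorially, so grid sizes never require
enumeration.

## Stiff integration

The integration contract is an implicit stiff method of order ≥ 5 at
relative tolerance 1e−9 and absolute tolerance 1e−12, using the analytic
Jacobian.  Two engines satisfy it: LSODA (`scipy.integrate.odeint`,
implicit BDF of order up to 5 in stiff regions, with the stepping loop in
compiled code) and Radau IIa of order 5 (`scipy.integrate.solve_ivp`).
Both pass the same closed-form error-contract tests; LSODA is the default
because its compiled loop is roughly 40× faster on the 400 s screening
protocols, which makes the range scans tractable on one CPU.  Trajectories
are sampled on a fixed 1 ms grid — over 100 samples per spike at the
surrogate's spike widths, and classifier outputs are insensitive to the
exact interval.  The standard protocol (`settle`) integrates 400 s of
model time, discards the first 200 s as transient and analyzes the last
200 s; the endpoint of the full run is retained to seed later runs.

## Regime classification

Spikes are local maxima of V strictly above −10 mV.  No spikes → silent
(subthreshold oscillations included).  All interspike intervals (ISIs)
< 1 s → tonic spiking.  Otherwise burst statistics are computed: a burst
is a maximal spike run with internal gaps < 1 s (an ISI of exactly 1 s
counts as a gap), onset/end are its first/last spike, the period is
onset-to-onset, and the interburst interval runs from burst end to the
next onset.  CV(period) > 5 % → irregular, else bursting; comparisons are
strict as stated.  Burst CVs use the population convention (ddof = 0),
which reproduces the worked boundary example of alternating 1.9 s/2.5 s
periods giving CV ≈ 0.136.  A *robust burster* additionally requires
CV(interburst interval) < 10 %.

Plateau-like activity — V continuously above −10 mV for more than 1 s
with no spike maxima inside the window (edge maxima from the plateau's
own onset/offset are ignored within 50 ms of the window edges) — is
flagged as its own label and excluded from robust bursting.  A two-cell
network is *functional* when both cells classify as bursting with
CV(period) < 5 % and the mean relative phase lies in [0.45, 0.55]
inclusive.  The phase estimator averages, over consecutive burst-onset
cycles of cell a, the fractional position of cell b's onsets within the
cycle; burst onsets are used because they are the most robust markers.
Degenerate edge: a trace with a single spike is filed under tonic spiking
(its empty ISI set vacuously satisfies the tonic rule).

## Equilibrium continuation

Stationary states are traced in g_leak with a pseudo-arclength
predictor–corrector (secant predictor, Newton corrector with
‖f‖∞ < 1e−10), started from the settled state at g_leak = 20 nS.  Because
state components (mV) and the parameter (nS) live on different scales,
the arclength metric weights state displacements by 0.02 per unit, so the
step bounds — maximum 0.02, minimum 1e−12, at most 4,000 points — act
approximately in parameter units away from folds.  The branch is followed
through folds and into negative parameter values when the curve goes
there; it terminates at the point budget, when the parameter exits
[−25, 25] nS moving outward, or on corrector failure at the minimum step.

Two test functions are monitored between consecutive points and their
sign changes bisected in arclength to a parameter bracket below 1e−8 nS:
`det J` for folds (LP) and `Re ∏_{i<j}(λ_i + λ_j)` for Hopf points (AH).
The pair-sum product is invariant to eigenvalue reordering, which keeps
the AH test robust in dimension ≥ 3; crossings whose candidate pair has
vanishing imaginary part (neutral saddles) are rejected.  Labels (LP1…,
AH1…) are assigned in arc-length order.

Stable sub-arcs become labeled intervals: hyperpolarized (*hyp*) below
−35 mV, depolarized (*dep*) above, numbered along the branch with hyp1
containing the branch start; an arc straddling −35 mV is split at the
crossing.  The arc containing the start is reported as unbounded above
(the rest state persists for arbitrarily large leak).  Reported ranges
are clipped to g ≥ 0; the continuation itself is not.

## Robust-bursting range scan

From a case's original g_leak (with a state on the bursting attractor)
the scanner steps +1 nS, settling each probe from the endpoint of the
last accepted bursting trajectory, until a probe stops being robust
bursting; it then resets to that endpoint and repeats with a tenfold
smaller step — five levels, down to the 1e−4 nS precision — and runs the
mirror-image downward pass, clipping at g = 0 (reported as a domain
edge).  The endpoint carry-over makes the sweep hysteresis-aware: inside
a coexistence band a fresh trajectory started near the rest state is
captured by it, while the carried state stays on the bursting attractor,
so the scanned range tracks the attractor's existence range.

Two caveats are inherent to this protocol and documented rather than
hidden.  First, the robust-bursting set of a fast–slow burster is
interleaved with thin non-robust slivers (period-adding/chaotic windows);
which sliver terminates a sweep depends on the probe ladder, so the
boundary is partly protocol-defined.  The test-suite oracle therefore
walks the same coarse-step/tenfold ladder in an independent minimal
implementation, refined one decade deeper (1e−5), and additionally
verifies the upper boundary's local sharpness with a dense 1e−5 grid of
fresh settles from a near-edge attractor state.  Second, near the upper
edge the attractor's basin narrows to less than the coarse probe spacing,
so oracle probes must be seeded from states harvested adiabatically near
the boundary; the manifest stores these states alongside the endpoints.

## Multistability analysis

Coexistence ranges are maximal sub-intervals with a constant regime set
of size ≥ 2, computed by exact interval arithmetic over the stable
intervals and the bursting range (closed intervals; zero-width touching
points are dropped).  The arrangement — the multiset of regime sets — is
matched against the ten canonical classes A–J (e.g. A: one
bursting+hyp1 range; G: a tristable range plus hyp1+dep1 plus
dep1+bursting; J: two hyp1+dep1 ranges plus a tristable range);
non-matching arrangements are reported as `unclassified`, absence of
coexistence as `none`.  Prevalence is the union length of the
bursting-containing coexistence ranges divided by the bursting-range
width; the robust-bursting range is used as the denominator.  Cohort
summaries report mean and sample SD (ddof = 1) plus the outlier-adjusted
pair computed after removing values greater than twice the mean.  Cases
differing only in g_leak share one bifurcation diagram and are grouped by
the remaining parameters before analysis.

## Half-center-oscillator perturbation protocol

Two identical (or leak-asymmetric) cells are reciprocally coupled with a
spike-mediated synapse (steep threshold, τ = 10 ms) and a graded synapse
(shallower threshold, slower τ), both inhibitory first-order conductances
driven by the presynaptic potential.  The protocol: 100 s coupled, then
5 s with all synaptic maximal conductances set to 0 nS — the gating
variables keep evolving, only the currents vanish — during which one
cell's intrinsic state is replaced (reset, not clamped) by a stable
equilibrium of the isolated cell, then 100 s recoupled.  Pre and post
segments are classified on their last 50 s to let entrainment transients
decay.  The outcome is *recovered* iff the post segment is functional;
otherwise the dysfunction mode records both cells silent
(`both_at_rest`), a tonic or irregular cell, or one cell resting beside
an active partner (`damped_oscillations`, after the synaptically driven
subthreshold deflections such a cell shows).

The two shipped fixtures start from documented entrained states (the
protocol's 100 s pre-segment then begins inside a locked rhythm, as the
alternation of this surrogate locks over a few hundred seconds):

* *recovered* — cells at g = 3.0 with strong inhibition (ḡ_spike = 150,
  ḡ_graded = 100, τ_graded = 0.5 s, E_syn = −80 mV): the unperturbed cell
  bursts through the blockade and its restored inhibition rebounds the
  reset cell off its rest state at every blockade phase tested;
* *both_at_rest* — same cells with ḡ_graded = 60: here the network
  rhythm is maintained by reciprocal release rather than endogenous
  bursting (in isolation the cells are monostable at rest, g being just
  above the bursting range), so with one cell reset to rest the other is
  captured by its own rest state during the blockade and the pair stays
  stuck after the synapses return.

## The surrogate burster

The minimal burster is a cubic fast subsystem with slow linear recovery
(Hindmarsh–Rose lineage) rescaled to mV/seconds, plus an ohmic leak term
whose conductance g is the bifurcation axis:

    x  = (V + 20)/20
    V' = 20κ (y − x³ + 3x² + I − z − γ g (x − x_L))
    y' = κ (1 − 5x² − y)
    z' = κ r (4 (x − x_R) − z)

with defaults I = 4, x_L = −20, x_R = −1.6, r = 0.003, κ = 25 s⁻¹,
γ = 0.05.  The large negative x_L makes the leak term mostly a linear
drive with a shallow conductance slope, which places the classic
rest/burst bistability of this model family onto the g axis; γ scales the
interesting range to a few "nS".  With these values, g sweeps the cell
from tonic/irregular spiking through robust bursting (period ~9–14 s,
2–8 spikes per burst) to silence; the hyperpolarized rest stabilizes at a
Hopf point inside the bursting range (g ≈ 2.73), giving a
bursting/rest coexistence band of ≈ 0.03 nS — the capture/escape
competition near a weakly attracting focus.  Ground truth is recomputed
at generation time by independent oracles (closed-form equilibrium curve
plus dense eigenvalue scan for the AH; the ladder boundary oracle for the
range), never transcribed.

What the surrogate does *not* emulate: multi-branch stationary-state
curves with dep1/dep2 intervals, hyp2 windows, tristability of a single
cell, or quantitative leech-interneuron waveforms.  Scenario classes
beyond A are therefore exercised on constructed interval geometries
(`tests/pattern_geometries.py`), which validates the overlap and taxonomy
logic but not the ability of any particular biophysical model to produce
those diagrams.  Passing tests show that the pipeline recovers known
bifurcation structure, tracks attractors through hysteresis, and
reproduces protocol-defined ranges to their stated precision on systems
with verifiable ground truth; they do not certify behavior on stiff
high-dimensional cells with kinetics outside the shipped functional
forms.

## Problem sizes and tolerances used by the shipped analyses

Full 400 s settle protocol throughout, including every scan probe;
continuation budget 4,000 points (the surrogate branch uses ~2,300);
range scans take ~40 settle runs per case; the perturbation fixtures
entrain for 300–600 s before the 205 s protocol.  One complete surrogate
case (settle + continuation + scan + overlap) runs in under a minute on
one CPU; `scripts/acceptance.py` repeats everything, including both
perturbation fixtures, in about a minute.

## Known limitations

* Natural-parameter grids in parameters other than g_leak, two-parameter
  continuation and periodic-orbit continuation are out of scope.
* The AH test can in principle miss pairs crossing exactly between two
  accepted branch points with equal test-function signs at both ends;
  the step bound of 0.02 nS makes this unlikely but not impossible.
* Scenario classification depends on interval labels produced by the
  continuation; branches truncated by corrector failure may yield
  incomplete interval sets (reported via `Branch.termination`).
* The relational store keeps state vectors as JSON arrays; queries filter
  on scalar columns only.
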