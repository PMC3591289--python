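"""Surrogate systems and constructed traces for exercising the pipeline.

The screening pipeline itself is agnostic to the particular cell model; the
surrogates here provide every dynamical feature the analysis stages must
handle, with ground truth that is either analytic (normal forms) or
recomputed by independent brute-force oracles at generation time:

* :class:`FoldModel` — 1-D fold normal form, LP at a known parameter;
* :class:`HopfModel` — 2-D Hopf normal form, AH at a known parameter with
  known angular frequency;
* :class:`RelaxationModel` — FitzHugh-Nagumo-style relaxation oscillator,
  AH located by a dense eigenvalue-scan oracle;
* :class:`MinimalBurster` — a three-dimensional fast-slow burster (cubic
  fast subsystem + slow linear recovery, Hindmarsh-Rose lineage) rescaled
  to mV / seconds and equipped with an ohmic leak term, so the leak-like
  conductance ``g`` is the bifurcation axis.  Across ``g`` it shows tonic
  spiking, an interior range of robust bursting, a hyperpolarized rest
  state stabilized at an Andronov-Hopf point inside that range (bursting /
  rest bistability), and silence at large ``g``;
* :func:`make_spike_trace` — piecewise-smooth voltage traces with
  prescribed spike times, for classifier tests.

Oracles (:func:`eigenvalue_scan_ah`, :func:`oracle_bursting_boundary`) are
deliberately simple and independent of the continuation / scanning code
paths they are used to check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .classify import classify_regime, detect_spikes, is_robust_burster, Regime
from .integrate import Trajectory, settle
from .systems import DynamicalSystem

__all__ = [
    "FoldModel", "HopfModel", "RelaxationModel", "MinimalBurster",
    "make_fold_model", "make_hopf_model", "make_relaxation_model",
    "make_minimal_burster", "make_spike_trace", "burst_pattern_times",
    "tonic_pattern_times", "eigenvalue_scan_ah", "burster_equilibrium_curve",
    "oracle_bursting_boundary", "BursterManifest", "characterize_minimal_burster",
]


# ---------------------------------------------------------------------------
# normal forms
# ---------------------------------------------------------------------------

class FoldModel(DynamicalSystem):
    """dx/dt = (mu - mu_c) - x^2: fold (LP) at mu = mu_c exactly.

    Equilibria x = +-sqrt(mu - mu_c); the upper branch is stable.
    """

    dim = 1
    state_names = ("x",)
    param_name = "mu"

    def __init__(self, mu_c: float = 0.0, mu: float = 1.0):
        self.mu_c = float(mu_c)
        self._mu = float(mu)

    @property
    def param(self):
        return self._mu

    def _set_param(self, value):
        self._mu = value

    def rhs(self, t, y):
        return np.array([(self._mu - self.mu_c) - y[0] ** 2])

    def jac(self, y):
        return np.array([[-2.0 * y[0]]])

    def dfdp(self, y, eps=None):
        return np.array([1.0])


class HopfModel(DynamicalSystem):
    """Supercritical Hopf normal form with frequency ``omega``.

    Equilibrium at the origin for every mu; eigenvalues
    (mu - mu_c) +- i*omega, so the AH sits exactly at mu = mu_c.  The
    post-Hopf limit cycle has radius sqrt(mu - mu_c).
    """

    dim = 2
    state_names = ("x", "y")
    param_name = "mu"

    def __init__(self, mu_c: float = 0.0, omega: float = 1.0, mu: float = -1.0):
        if omega <= 0:
            raise ValueError("omega must be > 0")
        self.mu_c = float(mu_c)
        self.omega = float(omega)
        self._mu = float(mu)

    @property
    def param(self):
        return self._mu

    def _set_param(self, value):
        self._mu = value

    def rhs(self, t, y):
        x, yy = y
        a = self._mu - self.mu_c
        r2 = x * x + yy * yy
        return np.array([a * x - self.omega * yy - x * r2,
                         self.omega * x + a * yy - yy * r2])

    def jac(self, y):
        x, yy = y
        a = self._mu - self.mu_c
        r2 = x * x + yy * yy
        return np.array([
            [a - r2 - 2 * x * x, -self.omega - 2 * x * yy],
            [self.omega - 2 * x * yy, a - r2 - 2 * yy * yy],
        ])

    def dfdp(self, y, eps=None):
        return np.array([y[0], y[1]])


class RelaxationModel(DynamicalSystem):
    """FitzHugh-Nagumo-style relaxation oscillator.

    dv/dt = v - v^3/3 - w + mu ;  dw/dt = eps * (v + a - b*w).

    The AH location is not written in closed form here; it is found by the
    dense eigenvalue-scan oracle (:func:`eigenvalue_scan_ah`).
    """

    dim = 2
    state_names = ("v", "w")
    param_name = "mu"

    def __init__(self, eps: float = 0.08, a: float = 0.7, b: float = 0.8,
                 mu: float = 0.0):
        self.eps, self.a, self.b = float(eps), float(a), float(b)
        self._mu = float(mu)

    @property
    def param(self):
        return self._mu

    def _set_param(self, value):
        self._mu = value

    def rhs(self, t, y):
        v, w = y
        return np.array([v - v**3 / 3.0 - w + self._mu,
                         self.eps * (v + self.a - self.b * w)])

    def jac(self, y):
        v = y[0]
        return np.array([[1.0 - v * v, -1.0],
                         [self.eps, -self.eps * self.b]])

    def dfdp(self, y, eps=None):
        return np.array([1.0, 0.0])

    def equilibrium_state(self, mu: float) -> np.ndarray:
        """Solve the cubic for the (unique, for b < 3) equilibrium at mu."""
        # v - v^3/3 - (v + a)/b + mu = 0
        coeffs = [-1.0 / 3.0, 0.0, 1.0 - 1.0 / self.b, mu - self.a / self.b]
        roots = np.roots(coeffs)
        real = roots[np.abs(roots.imag) < 1e-9].real
        if real.size == 0:
            raise RuntimeError("no real equilibrium found")
        v = float(real[np.argmin(np.abs(real.imag))] if real.size == 1 else real[0])
        return np.array([v, (v + self.a) / self.b])


# ---------------------------------------------------------------------------
# minimal endogenous burster
# ---------------------------------------------------------------------------

try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _burster_rhs_kernel(t, y, p):  # pragma: no cover - thin kernel
        g, I, xL, xR, s, r, kap, v0, sv, gam = (
            p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9])
        x = (y[0] - v0) / sv
        dx = y[1] - x * x * x + 3.0 * x * x + I - y[2] - gam * g * (x - xL)
        dy = 1.0 - 5.0 * x * x - y[1]
        dz = r * (s * (x - xR) - y[2])
        out = np.empty(3)
        out[0] = kap * sv * dx
        out[1] = kap * dy
        out[2] = kap * dz
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class MinimalBurster(DynamicalSystem):
    """Three-dimensional fast-slow burster with a leak-like parameter axis.

    In dimensionless fast-subsystem coordinates x = (V - V0)/sV the
    dynamics are of Hindmarsh-Rose type with an added ohmic leak:

        dx/dt' = y - x^3 + 3 x^2 + I - z - gamma * g * (x - x_L)
        dy/dt' = 1 - 5 x^2 - y
        dz/dt' = r (s (x - x_R) - z)

    with t' = kappa * t, so ``kappa`` sets how many fast time units elapse
    per second.  The membrane potential is reported as V = sV*x + V0 (mV),
    placing spike peaks near +15 mV and the hyperpolarized rest near
    -50 mV, compatible with the -10 mV spike threshold and the -35 mV
    hyp/dep split.  ``gamma`` converts the reported conductance ``g``
    ("nS", the bifurcation parameter) into fast-subsystem units, placing
    the interesting dynamics at g values of a few nS.  The leak term
    equals g*(V - E_L)/C with E_L = sV*x_L + V0 and effective capacitance
    C = 1/(gamma*kappa), which is how synaptic input is scaled when two
    cells are coupled.

    With the default parameters, increasing ``g`` sweeps the cell from
    tonic/irregular spiking through robust bursting to silence; the
    hyperpolarized equilibrium becomes stable at an Andronov-Hopf point
    inside the bursting range, so bursting coexists with the rest state on
    the upper part of the range (the capture/escape competition near a
    weakly attracting focus of the slow-fast system).
    """

    dim = 3
    state_names = ("V", "y", "z")
    param_name = "g"

    def __init__(self, g: float = 2.4, I: float = 4.0, x_L: float = -20.0,
                 x_R: float = -1.6, s: float = 4.0, r: float = 0.003,
                 kappa: float = 25.0, v0: float = -20.0, sv: float = 20.0,
                 gamma: float = 0.05):
        self.I = float(I)
        self.x_L = float(x_L)
        self.x_R = float(x_R)
        self.s = float(s)
        self.r = float(r)
        self.kappa = float(kappa)
        self.v0 = float(v0)
        self.sv = float(sv)
        self.gamma = float(gamma)
        self.capacitance = 1.0 / (self.gamma * self.kappa)
        self._p = np.array([float(g), self.I, self.x_L, self.x_R, self.s,
                            self.r, self.kappa, self.v0, self.sv, self.gamma])

    @property
    def E_leak(self) -> float:
        return self.sv * self.x_L + self.v0

    @property
    def param(self):
        return float(self._p[0])

    @property
    def _g(self):
        return float(self._p[0])

    def _set_param(self, value):
        self._p[0] = value

    if _HAVE_NUMBA:
        def rhs(self, t, y):
            return _burster_rhs_kernel(t, np.asarray(y, dtype=float), self._p)
    else:
        def rhs(self, t, y):
            v, yy, z = y
            x = (v - self.v0) / self.sv
            dx = yy - x**3 + 3.0 * x * x + self.I - z \
                - self.gamma * self._g * (x - self.x_L)
            dy = 1.0 - 5.0 * x * x - yy
            dz = self.r * (self.s * (x - self.x_R) - z)
            return np.array([self.kappa * self.sv * dx,
                             self.kappa * dy,
                             self.kappa * dz])

    def jac(self, y):
        v = y[0]
        x = (v - self.v0) / self.sv
        k = self.kappa
        return np.array([
            [k * (-3.0 * x * x + 6.0 * x - self.gamma * self._g),
             k * self.sv, -k * self.sv],
            [k * (-10.0 * x) / self.sv, -k, 0.0],
            [k * self.r * self.s / self.sv, 0.0, -k * self.r],
        ])

    def dfdp(self, y, eps=None):
        return np.array([-self.gamma * self.kappa * (y[0] - self.E_leak), 0.0, 0.0])

    def rest_guess(self) -> np.ndarray:
        """Crude hyperpolarized starting state (near x = x_R)."""
        x = self.x_R
        return np.array([self.sv * x + self.v0, 1.0 - 5.0 * x * x, 0.0])


def make_fold_model(mu_c: float = 0.0, mu: float = 1.0) -> FoldModel:
    return FoldModel(mu_c=mu_c, mu=mu)


def make_hopf_model(mu_c: float = 0.0, omega: float = 1.0,
                    mu: float = -1.0) -> HopfModel:
    return HopfModel(mu_c=mu_c, omega=omega, mu=mu)


def make_relaxation_model(**kwargs) -> RelaxationModel:
    return RelaxationModel(**kwargs)


def make_minimal_burster(**kwargs) -> MinimalBurster:
    return MinimalBurster(**kwargs)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def burster_equilibrium_curve(model: MinimalBurster, x):
    """Closed-form equilibrium branch of the burster, parametrized by x.

    Returns (g(x), state(x)): at an equilibrium y = 1 - 5x^2,
    z = s (x - x_R), and g follows from the x-equation,
    g(x) = (-x^3 - 2x^2 - s x + 1 + I + s x_R) / (x - x_L).
    """
    x = np.asarray(x, dtype=float)
    num = -x**3 - 2.0 * x**2 - model.s * x + 1.0 + model.I + model.s * model.x_R
    g = num / (model.gamma * (x - model.x_L))
    states = np.column_stack([model.sv * x + model.v0,
                              1.0 - 5.0 * x * x,
                              model.s * (x - model.x_R)])
    return g, states


def eigenvalue_scan_ah(model, mu_grid, equilibrium_at) -> float:
    """Dense-scan oracle for an AH point.

    Walks ``mu_grid``, computes the equilibrium with ``equilibrium_at(mu)``
    and the Jacobian spectrum, and returns the parameter (linearly
    interpolated on the max real part of the complex pair) where the
    leading complex pair crosses the imaginary axis.  Independent of the
    continuation engine.
    """
    prev_mu, prev_re = None, None
    for mu in mu_grid:
        state = equilibrium_at(mu)
        eig = np.linalg.eigvals(model.with_param(mu).jac(state))
        cplx = eig[np.abs(eig.imag) > 1e-9]
        if cplx.size < 2:
            prev_mu, prev_re = None, None
            continue
        re = float(np.max(cplx.real))
        if prev_re is not None and prev_re * re < 0:
            # linear interpolation of the zero crossing
            return prev_mu + (mu - prev_mu) * (-prev_re) / (re - prev_re)
        prev_mu, prev_re = mu, re
    raise RuntimeError("no AH crossing found on the scan grid")


def _robust_at(model, g, state, settle_kwargs):
    traj = settle(model.with_param(g), state, **settle_kwargs)
    label, stats = classify_regime(detect_spikes(traj), traj)
    robust = (label is Regime.BURSTING and stats is not None
              and is_robust_burster(stats))
    return robust, label, traj.final_state


def oracle_bursting_boundary(model, start_g: float, state_on_attractor,
                             sign: float, tol: float = 1e-5,
                             coarse_step: float = 1.0,
                             settle_kwargs=None):
    """Ladder oracle for a robust-bursting boundary.

    The boundary located by the step-refinement protocol is itself
    protocol-defined: the attractor's existence range is interleaved with
    thin non-robust (period-adding) slivers, and which sliver terminates
    the sweep depends on the coarse step.  The oracle therefore walks the
    same ladder — the coarse step followed by tenfold refinements — but in
    an independent, minimal implementation, carrying the endpoint state of
    each accepted settle, and continues one extra decade below the
    protocol precision (down to ``tol``).  Returns ``(g_edge, label
    beyond, state near the edge)``; the edge is the domain boundary 0 when
    bursting persists there on a downward sweep.
    """
    kw = settle_kwargs or {}
    g_ok, state = float(start_g), np.asarray(state_on_attractor, dtype=float)
    label_beyond = None
    step = coarse_step
    while step >= tol * (1 - 1e-12):
        while True:
            g_next = g_ok + sign * step
            if g_next < 0.0:
                g_next = 0.0
                if g_ok == 0.0:
                    return 0.0, "domain_edge", state
            robust, label, endpoint = _robust_at(model, g_next, state, kw)
            if robust:
                g_ok, state = g_next, endpoint
                if g_next == 0.0:
                    return 0.0, "domain_edge", state
            else:
                label_beyond = label.value
                break
        step /= 10.0
    return g_ok, label_beyond, state


def oracle_dense_edge_check(model, g_edge: float, state_near_edge,
                            sign: float, grid_step: float = 1e-5,
                            half_width: float = 1e-4,
                            settle_kwargs=None) -> float:
    """Dense-grid verification of a boundary's local sharpness.

    Classifies every g on a ``grid_step`` grid within ``half_width`` of the
    reported edge, each by a fresh settle from the same near-edge attractor
    state, and returns the outermost robust g on the grid.  A sharp,
    correctly located boundary yields a value within ``half_width`` of
    ``g_edge``.
    """
    kw = settle_kwargs or {}
    state = np.asarray(state_near_edge, dtype=float)
    offsets = np.arange(-half_width, half_width + grid_step / 2, grid_step)
    outermost = None
    for off in offsets:
        g = g_edge + sign * off
        if g < 0:
            continue
        robust, _, _ = _robust_at(model, g, state, kw)
        if robust:
            outermost = g
    if outermost is None:
        raise RuntimeError("no robust bursting found on the dense edge grid")
    return outermost


# ---------------------------------------------------------------------------
# half-center oscillator fixtures
# ---------------------------------------------------------------------------

@dataclass
class HCOFixture:
    """A coupled burster pair prepared for the reset-perturbation protocol.

    ``initial_state`` is the endpoint of a documented entrainment run, so
    the 100 s pre-segment of the protocol starts from an already locked
    alternating rhythm.  ``expected_outcome`` / ``expected_mode`` record
    the outcome the configuration was built to show; they are regression
    anchors verified against fresh protocol runs by the test suite.
    """

    name: str
    coupled: object
    initial_state: np.ndarray
    reset_state: object            # stable EquilibriumPoint of the isolated cell
    which_cell: str
    expected_outcome: str
    expected_mode: str
    g: float
    entrain_s: float


def burster_rest_equilibrium(model: MinimalBurster):
    """Stable hyperpolarized equilibrium of the isolated cell at its g."""
    from .continuation import find_equilibrium
    xs = np.linspace(model.x_R - 0.35, model.x_R + 0.55, 4000)
    gs, states = burster_equilibrium_curve(model, xs)
    mask = states[:, 0] < -40.0
    idx = np.argmin(np.abs(gs - model.param) + 1e9 * (~mask))
    eq = find_equilibrium(model.with_param(model.param), states[idx])
    if not eq.stable:
        raise RuntimeError(f"rest equilibrium at g={model.param} is not stable")
    return eq


def _hco_pair(g, gs_spike, gs_graded, tau_graded, e_syn):
    from .models import Sigmoid, SynapseSpec, assemble_hco
    cell = MinimalBurster(g=g)
    synapses = [
        SynapseSpec(kind="spike_mediated", max_conductance=gs_spike,
                    reversal_potential=e_syn,
                    activation=Sigmoid(v_half=-10.0, k=-2.0), tau=0.01),
        SynapseSpec(kind="graded", max_conductance=gs_graded,
                    reversal_potential=e_syn,
                    activation=Sigmoid(v_half=-30.0, k=-5.0), tau=tau_graded),
    ]
    return cell, assemble_hco(cell, cell, synapses)


#: frozen fixture configurations (chosen at build time, verified by the
#: protocol itself in the test suite)
HCO_FIXTURE_CONFIGS = {
    # strong reciprocal inhibition: the unperturbed cell keeps bursting
    # through the blockade, and once the synapses are restored its bursts
    # kick the reset cell off the rest state (post-inhibitory rebound), so
    # the alternating rhythm recovers at every blockade phase tested
    "recovered": dict(g=3.0, gs_spike=150.0, gs_graded=100.0,
                      tau_graded=0.5, e_syn=-80.0, entrain_s=590.0,
                      extra_s=0.0, which_cell="a",
                      outcome="recovered", mode="none"),
    # cells just above the bursting range (monostable rest): the network
    # rhythm is maintained by reciprocal release, so when one cell is reset
    # to rest during the blockade the other is captured by its own rest
    # state and the pair ends up stuck
    "both_at_rest": dict(g=3.0, gs_spike=150.0, gs_graded=60.0,
                         tau_graded=0.5, e_syn=-80.0, entrain_s=590.0,
                         extra_s=3.0, which_cell="a",
                         outcome="dysfunctional", mode="both_at_rest"),
}


def make_hco_fixture(kind: str = "recovered") -> HCOFixture:
    """Build a protocol-ready HCO fixture (runs its entrainment)."""
    from .integrate import integrate
    if kind not in HCO_FIXTURE_CONFIGS:
        raise ValueError(f"unknown HCO fixture kind {kind!r}")
    cfg = HCO_FIXTURE_CONFIGS[kind]
    cell, coupled = _hco_pair(cfg["g"], cfg["gs_spike"], cfg["gs_graded"],
                              cfg["tau_graded"], cfg["e_syn"])
    eq = burster_rest_equilibrium(cell)
    burst_cell = MinimalBurster(g=2.74)
    burst_state = settle(burst_cell,
                         burst_cell.rest_guess() + np.array([5.0, 0.0, 0.0]),
                         total=60.0, discard=30.0).final_state
    y0 = np.concatenate([burst_state, eq.state, [0.0] * 4])
    ent = integrate(coupled, y0, cfg["entrain_s"])
    state = ent.final_state
    if cfg["extra_s"] > 0:
        state = integrate(coupled, state, cfg["extra_s"]).final_state
    return HCOFixture(
        name=kind, coupled=coupled, initial_state=state, reset_state=eq,
        which_cell=cfg["which_cell"], expected_outcome=cfg["outcome"],
        expected_mode=cfg["mode"], g=cfg["g"],
        entrain_s=cfg["entrain_s"] + cfg["extra_s"],
    )


# ---------------------------------------------------------------------------
# constructed voltage traces
# ---------------------------------------------------------------------------

def tonic_pattern_times(isi: float, n_spikes: int, t0: float = 1.0) -> np.ndarray:
    return t0 + isi * np.arange(n_spikes)


def burst_pattern_times(n_bursts: int, spikes_per_burst: int, intra_isi: float,
                        gap: float, t0: float = 1.0,
                        period_jitter_sd: float = 0.0, rng=None) -> np.ndarray:
    """Spike times of a periodic burst pattern.

    ``gap`` is the quiet interval between the last spike of one burst and
    the first of the next; optional Gaussian jitter (sd in seconds, seeded
    ``rng``) is applied to burst onsets.
    """
    if intra_isi <= 0 or gap <= 0:
        raise ValueError("intra_isi and gap must be positive")
    burst_len = intra_isi * (spikes_per_burst - 1)
    period = burst_len + gap
    onsets = t0 + period * np.arange(n_bursts)
    if period_jitter_sd > 0:
        rng = np.random.default_rng(rng)
        onsets = onsets + rng.normal(0.0, period_jitter_sd, size=n_bursts)
        onsets = np.sort(onsets)
    times = (onsets[:, None] + intra_isi * np.arange(spikes_per_burst)[None, :]).ravel()
    return np.sort(times)


def make_spike_trace(spike_times, duration: float = None, dt: float = 1e-3,
                     baseline: float = -50.0, peak: float = 0.0,
                     width: float = 0.02) -> Trajectory:
    """Smooth voltage trace with one Gaussian-shaped spike per listed time.

    Spikes peak at ``peak`` mV (above the -10 mV detection threshold by
    default) on a ``baseline`` mV resting potential; ``width`` is the
    Gaussian sigma in seconds.  Overlapping spikes (separation < 4*width)
    are rejected.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    if spike_times.size > 1 and np.min(np.diff(spike_times)) < 4 * width:
        raise ValueError("spike times overlap at the requested width")
    if duration is None:
        duration = (spike_times[-1] if spike_times.size else 0.0) + 1.0
    t = np.arange(0.0, duration + dt / 2, dt)
    v = np.full_like(t, baseline)
    amp = peak - baseline
    for ts in spike_times:
        mask = np.abs(t - ts) < 6 * width
        v[mask] += amp * np.exp(-0.5 * ((t[mask] - ts) / width) ** 2)
    return Trajectory(t, v[:, None], {"state_names": ["V"]})


# ---------------------------------------------------------------------------
# fixture manifest for the minimal burster
# ---------------------------------------------------------------------------

@dataclass
class BursterManifest:
    """Oracle-derived ground truth for a MinimalBurster configuration.

    All values are recomputed at generation time by the documented oracles;
    nothing here is transcribed by hand.
    """

    parameters: dict
    ah_g: float                      # AH on the hyperpolarized branch (eigen-scan oracle)
    bursting_g_min: float            # bisection oracle, robust-bursting lower edge
    bursting_g_max: float            # bisection oracle, robust-bursting upper edge
    start_g: float                   # a g well inside the bursting range
    bursting_state: np.ndarray       # a state on the bursting attractor at start_g
    below_label: str                 # regime just below bursting_g_min
    above_label: str                 # regime just above bursting_g_max
    #: attractor states at the last accepted probe of each boundary ladder
    edge_states: dict = field(default_factory=dict)
    oracle: dict = field(default_factory=dict)

    @property
    def coexistence(self):
        """Expected bursting/rest coexistence band (scenario A)."""
        return (max(self.ah_g, self.bursting_g_min), self.bursting_g_max)

    def to_dict(self):
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items()}
        return d


def characterize_minimal_burster(model: MinimalBurster = None, *,
                                 start_g: float = None,
                                 boundary_tol: float = 1e-5,
                                 settle_kwargs=None) -> BursterManifest:
    """Compute the burster's ground truth with independent oracles.

    * AH on the hyperpolarized equilibrium branch: dense eigenvalue scan
      along the closed-form equilibrium curve, refined by bisection in x.
    * Bursting-range edges: plain bisection of the robust-bursting /
      non-bursting transition with full settle runs from a state on the
      bursting attractor (fresh at each probe).
    """
    model = model or MinimalBurster()
    start_g = model.param if start_g is None else start_g
    kw = settle_kwargs or {}

    # --- AH oracle: scan x along the hyperpolarized branch -----------------
    def ah_from_scan(x_lo, x_hi, n=4001):
        xs = np.linspace(x_lo, x_hi, n)
        gs, states = burster_equilibrium_curve(model, xs)

        def re_pair(i):
            eig = np.linalg.eigvals(model.with_param(gs[i]).jac(states[i]))
            cplx = eig[np.abs(eig.imag) > 1e-9]
            return float(np.max(cplx.real)) if cplx.size >= 2 else np.nan

        prev = re_pair(0)
        for i in range(1, n):
            cur = re_pair(i)
            if np.isfinite(prev) and np.isfinite(cur) and prev * cur < 0:
                # bisect in x
                a, b = xs[i - 1], xs[i]
                fa = prev
                for _ in range(200):
                    m = 0.5 * (a + b)
                    gm, sm = burster_equilibrium_curve(model, np.array([m]))
                    eig = np.linalg.eigvals(model.with_param(gm[0]).jac(sm[0]))
                    cplx = eig[np.abs(eig.imag) > 1e-9]
                    fm = float(np.max(cplx.real))
                    ga, _ = burster_equilibrium_curve(model, np.array([a]))
                    gb, _ = burster_equilibrium_curve(model, np.array([b]))
                    if abs(gb[0] - ga[0]) < 1e-10:
                        break
                    if fa * fm <= 0:
                        b = m
                    else:
                        a, fa = m, fm
                g_final, _ = burster_equilibrium_curve(model, np.array([0.5 * (a + b)]))
                return float(g_final[0])
            prev = cur
        raise RuntimeError("no AH found on the hyperpolarized branch scan")

    ah_g = ah_from_scan(model.x_R - 0.35, model.x_R + 0.55)

    # --- bursting attractor state at start_g -------------------------------
    sys_start = model.with_param(start_g)
    traj = settle(sys_start, model.rest_guess() + np.array([5.0, 0.0, 0.0]), **kw)
    label, stats = classify_regime(detect_spikes(traj), traj)
    if label is not Regime.BURSTING or not is_robust_burster(stats):
        raise RuntimeError(
            f"burster does not burst robustly at start_g={start_g}: {label}")
    attractor_state = traj.final_state

    # --- ladder oracle for both edges --------------------------------------
    g_max, above_label, state_up = oracle_bursting_boundary(
        model, start_g, attractor_state, +1.0, tol=boundary_tol,
        settle_kwargs=kw)
    g_min, below_label, state_dn = oracle_bursting_boundary(
        model, start_g, attractor_state, -1.0, tol=boundary_tol,
        settle_kwargs=kw)

    params = {k: getattr(model, k) for k in
              ("I", "x_L", "x_R", "s", "r", "kappa", "v0", "sv", "gamma")}
    return BursterManifest(
        parameters=params, ah_g=ah_g,
        bursting_g_min=g_min, bursting_g_max=g_max,
        start_g=start_g, bursting_state=attractor_state,
        below_label=str(below_label.value if hasattr(below_label, "value") else below_label),
        above_label=str(above_label.value if hasattr(above_label, "value") else above_label),
        edge_states={"upper": state_up, "lower": state_dn},
        oracle={
            "ah": "dense eigenvalue scan on the closed-form equilibrium curve, bisected in x",
            "range": ("protocol-ladder oracle: coarse 1 nS carry-over walk, "
                      f"tenfold refinement to {boundary_tol}"),
            "settle_kwargs": dict(kw),
        },
    )
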