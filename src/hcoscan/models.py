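"""Declarative Hodgkin–Huxley-type neuron models and two-cell networks.

A single-compartment neuron is described by a :class:`ModelSpec`: a membrane
capacitance plus a list of ionic currents, each with a reversal potential, a
maximal conductance and up to two first-order gating variables (activation
and inactivation).  Gating steady states are Boltzmann sigmoids of the
membrane potential; voltage-dependent time constants may be constant,
sigmoid or bell shaped.  One grid point of a parameter screen is a
:class:`CaseParameters`: a leak reversal potential and conductance plus
per-current scale factors applied to the canonical maximal conductances.

The kinetics themselves are free parameters of the format: the package
ships no particular cell's channel equations, and every analysis stage is
exercised on surrogate systems (see :mod:`hcoscan.synthetic`).  A template
configuration for an eight-current leech-heart-interneuron-style cell is
provided under ``configs/`` for users who want to plug in published
kinetics.

Units: mV, nS, nF, nA, seconds.  ``dV/dt`` then comes out in mV/s since
nS * mV / nF = mV/s, and an injected current in nA contributes
``1000 * I / C`` mV/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .systems import DynamicalSystem

__all__ = [
    "ConfigError",
    "Sigmoid",
    "TimeConstant",
    "GatingSpec",
    "CurrentSpec",
    "SynapseSpec",
    "ModelSpec",
    "CaseParameters",
    "NeuronSystem",
    "CoupledSystem",
    "build_vector_field",
    "build_jacobian",
    "assemble_hco",
    "load_model_config",
    "dump_model_config",
]


class ConfigError(ValueError):
    """Raised for inconsistent model, case or grid definitions."""


# ---------------------------------------------------------------------------
# parameterized voltage functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sigmoid:
    """Boltzmann steady state ``1 / (1 + exp((V - v_half) / k))``.

    Negative ``k`` gives an activation curve (increasing with V), positive
    ``k`` an inactivation curve.
    """

    v_half: float  # mV
    k: float       # mV, sign sets the orientation

    def __call__(self, v):
        return 1.0 / (1.0 + np.exp((v - self.v_half) / self.k))

    def deriv(self, v):
        s = self(v)
        return -s * (1.0 - s) / self.k


@dataclass(frozen=True)
class TimeConstant:
    """Voltage-dependent time constant, seconds.

    ``form``:
      * ``constant``:  tau = base
      * ``sigmoid``:   tau = base + amp / (1 + exp((V - v_half)/k))
      * ``bell``:      tau = base + amp / cosh((V - v_half)/k)
    """

    form: str = "constant"
    base: float = 0.1
    amp: float = 0.0
    v_half: float = 0.0
    k: float = 10.0

    def __post_init__(self):
        if self.form not in ("constant", "sigmoid", "bell"):
            raise ConfigError(f"unknown time-constant form {self.form!r}")

    def __call__(self, v):
        if self.form == "constant":
            return self.base + 0.0 * np.asarray(v)
        if self.form == "sigmoid":
            return self.base + self.amp / (1.0 + np.exp((v - self.v_half) / self.k))
        u = (np.asarray(v) - self.v_half) / self.k
        return self.base + self.amp / np.cosh(u)

    def deriv(self, v):
        if self.form == "constant":
            return 0.0 * np.asarray(v)
        if self.form == "sigmoid":
            s = 1.0 / (1.0 + np.exp((v - self.v_half) / self.k))
            return -self.amp * s * (1.0 - s) / self.k
        u = (np.asarray(v) - self.v_half) / self.k
        return -self.amp * np.tanh(u) / (np.cosh(u) * self.k)


# ---------------------------------------------------------------------------
# declarative specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GatingSpec:
    """One first-order gating variable ``dx/dt = (x_inf(V) - x) / tau(V)``."""

    name: str
    exponent: int
    steady_state: Sigmoid
    time_constant: TimeConstant

    def __post_init__(self):
        if self.exponent < 1:
            raise ConfigError(f"gating exponent must be >= 1, got {self.exponent}")
        v = np.linspace(-100.0, 60.0, 321)
        tau = np.asarray(self.time_constant(v))
        if np.any(tau <= 0):
            raise ConfigError(f"time constant of {self.name!r} not positive on [-100, 60] mV")


@dataclass(frozen=True)
class CurrentSpec:
    """One ionic current ``gbar * m^p * h * (V - E)``."""

    name: str
    reversal_potential: float  # mV
    max_conductance: float     # nS
    activation: Optional[GatingSpec] = None
    inactivation: Optional[GatingSpec] = None
    instantaneous: bool = False

    def __post_init__(self):
        if self.max_conductance < 0:
            raise ConfigError(f"max_conductance of {self.name!r} must be >= 0")
        if self.instantaneous and (self.activation or self.inactivation):
            raise ConfigError(f"instantaneous current {self.name!r} cannot have gates")


@dataclass(frozen=True)
class SynapseSpec:
    """Inhibitory synapse driven by the presynaptic membrane potential.

    Both kinds share the first-order kinetics
    ``ds/dt = (s_inf(V_pre) - s) / tau`` with a Boltzmann ``s_inf``; the
    spike-mediated kind is conventionally configured with a steeper
    threshold and a faster time constant than the graded kind.  The
    postsynaptic current is ``gbar * s * (V_post - E_syn)``.
    """

    kind: str                   # "graded" | "spike_mediated"
    max_conductance: float      # nS
    reversal_potential: float   # mV
    activation: Sigmoid = field(default_factory=lambda: Sigmoid(v_half=-30.0, k=-5.0))
    tau: float = 0.05           # s

    def __post_init__(self):
        if self.kind not in ("graded", "spike_mediated"):
            raise ConfigError(f"unknown synapse kind {self.kind!r}")
        if self.max_conductance < 0:
            raise ConfigError("synaptic max_conductance must be >= 0")
        if self.tau <= 0:
            raise ConfigError("synaptic tau must be > 0")


@dataclass(frozen=True)
class ModelSpec:
    """Single-compartment conductance-based neuron."""

    name: str
    capacitance: float                     # nF
    currents: tuple
    injected_current: float = 0.0          # nA

    def __post_init__(self):
        if self.capacitance <= 0:
            raise ConfigError("capacitance must be > 0")
        names = [c.name for c in self.currents]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate current names in {self.name!r}")

    @property
    def state_layout(self):
        """Ordered state names: V first, then gating variables."""
        layout = ["V"]
        for c in self.currents:
            if c.activation is not None:
                layout.append(f"{c.name}_{c.activation.name}")
            if c.inactivation is not None:
                layout.append(f"{c.name}_{c.inactivation.name}")
        return tuple(layout)

    @property
    def dim(self):
        return len(self.state_layout)

    def current(self, name: str) -> CurrentSpec:
        for c in self.currents:
            if c.name == name:
                return c
        raise ConfigError(f"model {self.name!r} has no current named {name!r}")


@dataclass(frozen=True)
class CaseParameters:
    """One grid point: leak parameters plus conductance scale factors."""

    case_id: int
    E_leak: float                  # mV
    g_leak: float                  # nS
    scale_factors: dict = field(default_factory=dict)

    def validated_against(self, model: ModelSpec) -> "CaseParameters":
        current_names = {c.name for c in model.currents}
        for key in self.scale_factors:
            if key not in current_names:
                raise ConfigError(
                    f"scale factor refers to unknown current {key!r} "
                    f"(model has {sorted(current_names)})"
                )
        return self


# ---------------------------------------------------------------------------
# runtime system built from the specs
# ---------------------------------------------------------------------------

class NeuronSystem(DynamicalSystem):
    """Vector field and analytic Jacobian of a ModelSpec + CaseParameters.

    The bifurcation parameter is the leak conductance ``g_leak`` (nS).
    """

    param_name = "g_leak"

    def __init__(self, model: ModelSpec, case: CaseParameters):
        case.validated_against(model)
        self.model = model
        self.case = case
        self.dim = model.dim
        self.state_names = model.state_layout
        self.capacitance = model.capacitance
        self._g_leak = float(case.g_leak)
        self._build_tables()

    def _build_tables(self):
        # flat per-current tables; gate indices point into the state vector
        self._currents = []
        idx = 1
        for c in self.model.currents:
            scale = self.case.scale_factors.get(c.name, 1.0)
            entry = {
                "g": c.max_conductance * scale,
                "E": c.reversal_potential,
                "act": None,
                "inact": None,
            }
            if c.activation is not None:
                entry["act"] = (idx, c.activation)
                idx += 1
            if c.inactivation is not None:
                entry["inact"] = (idx, c.inactivation)
                idx += 1
            self._currents.append(entry)

    # -- parameter axis ---------------------------------------------------
    @property
    def param(self):
        return self._g_leak

    def _set_param(self, value):
        self._g_leak = value

    def dfdp(self, y, eps: float = 1e-6):
        out = np.zeros(self.dim)
        out[0] = -(y[0] - self.case.E_leak) / self.capacitance
        return out

    # -- dynamics ---------------------------------------------------------
    def rhs(self, t, y):
        v = y[0]
        dy = np.empty(self.dim)
        i_total = self._g_leak * (v - self.case.E_leak)
        for cur in self._currents:
            g = cur["g"]
            if cur["act"] is not None:
                i, gs = cur["act"]
                g = g * y[i] ** gs.exponent
            if cur["inact"] is not None:
                i, _ = cur["inact"]
                g = g * y[i]
            i_total += g * (v - cur["E"])
        dy[0] = (1000.0 * self.model.injected_current - i_total) / self.capacitance
        for cur in self._currents:
            for slot in ("act", "inact"):
                if cur[slot] is not None:
                    i, gs = cur[slot]
                    dy[i] = (gs.steady_state(v) - y[i]) / gs.time_constant(v)
        return dy

    def jac(self, y):
        v = y[0]
        n = self.dim
        J = np.zeros((n, n))
        c_m = self.capacitance
        g_sum = self._g_leak
        for cur in self._currents:
            g_eff = cur["g"]
            m_term = 1.0
            h_term = 1.0
            if cur["act"] is not None:
                i, gs = cur["act"]
                m_term = y[i] ** gs.exponent
            if cur["inact"] is not None:
                i, _ = cur["inact"]
                h_term = y[i]
            g_sum += g_eff * m_term * h_term
            dv_e = v - cur["E"]
            if cur["act"] is not None:
                i, gs = cur["act"]
                dprod = gs.exponent * y[i] ** (gs.exponent - 1) * h_term
                J[0, i] = -g_eff * dprod * dv_e / c_m
            if cur["inact"] is not None:
                i, _ = cur["inact"]
                J[0, i] = -g_eff * m_term * dv_e / c_m
        J[0, 0] = -g_sum / c_m
        for cur in self._currents:
            for slot in ("act", "inact"):
                if cur[slot] is not None:
                    i, gs = cur[slot]
                    tau = gs.time_constant(v)
                    J[i, 0] = (
                        gs.steady_state.deriv(v) * tau
                        - (gs.steady_state(v) - y[i]) * gs.time_constant.deriv(v)
                    ) / tau**2
                    J[i, i] = -1.0 / tau
        return J


class CoupledSystem(DynamicalSystem):
    """Two cells coupled by voltage-driven synapses.

    State layout: cell-a states, cell-b states, then one gating variable per
    synapse instance.  Each synapse carries its presynaptic side ('a'/'b')
    and injects current into the other cell.  With all synaptic maximal
    conductances zero the two cells are exactly independent (the synaptic
    gates still evolve but drive no current).
    """

    def __init__(self, cell_a: DynamicalSystem, cell_b: DynamicalSystem,
                 synapses):
        # synapses: list of (SynapseSpec, pre) with pre in {"a","b"}
        self.cell_a = cell_a
        self.cell_b = cell_b
        self.synapses = list(synapses)
        for spec, pre in self.synapses:
            if pre not in ("a", "b"):
                raise ConfigError(f"synapse presynaptic side must be 'a' or 'b', got {pre!r}")
        self.na = cell_a.dim
        self.nb = cell_b.dim
        self.dim = self.na + self.nb + len(self.synapses)
        self.state_names = (
            tuple(f"a.{s}" for s in cell_a.state_names)
            + tuple(f"b.{s}" for s in cell_b.state_names)
            + tuple(f"syn{i}" for i in range(len(self.synapses)))
        )

    def slices(self):
        na, nb = self.na, self.nb
        return slice(0, na), slice(na, na + nb), slice(na + nb, self.dim)

    def blocked(self) -> "CoupledSystem":
        """Copy with all synaptic maximal conductances set to 0 nS.

        The synaptic gating variables keep evolving; only the currents
        vanish (synaptic blockade, not freezing).
        """
        import dataclasses
        new_syn = [(dataclasses.replace(spec, max_conductance=0.0), pre)
                   for spec, pre in self.synapses]
        return CoupledSystem(self.cell_a, self.cell_b, new_syn)

    def rhs(self, t, y):
        sa, sb, ss = self.slices()
        ya, yb, s = y[sa], y[sb], y[ss]
        dy = np.empty(self.dim)
        dy[sa] = self.cell_a.rhs(t, ya)
        dy[sb] = self.cell_b.rhs(t, yb)
        for k, (spec, pre) in enumerate(self.synapses):
            if pre == "a":
                v_pre, v_post = ya[0], yb[0]
                post_v_index, c_post = self.na, self.cell_b.capacitance
            else:
                v_pre, v_post = yb[0], ya[0]
                post_v_index, c_post = 0, self.cell_a.capacitance
            dy[post_v_index] -= spec.max_conductance * s[k] * (v_post - spec.reversal_potential) / c_post
            dy[self.na + self.nb + k] = (spec.activation(v_pre) - s[k]) / spec.tau
        return dy

    def jac(self, y):
        sa, sb, ss = self.slices()
        ya, yb, s = y[sa], y[sb], y[ss]
        J = np.zeros((self.dim, self.dim))
        J[sa, sa] = self.cell_a.jac(ya)
        J[sb, sb] = self.cell_b.jac(yb)
        for k, (spec, pre) in enumerate(self.synapses):
            sk = self.na + self.nb + k
            if pre == "a":
                v_pre_index, v_post_index = 0, self.na
                v_post, c_post = yb[0], self.cell_b.capacitance
            else:
                v_pre_index, v_post_index = self.na, 0
                v_post, c_post = ya[0], self.cell_a.capacitance
            J[v_post_index, v_post_index] -= spec.max_conductance * s[k] / c_post
            J[v_post_index, sk] -= spec.max_conductance * (v_post - spec.reversal_potential) / c_post
            J[sk, v_pre_index] = spec.activation.deriv(y[v_pre_index]) / spec.tau
            J[sk, sk] = -1.0 / spec.tau
        return J


# ---------------------------------------------------------------------------
# spec-level operations
# ---------------------------------------------------------------------------

def build_vector_field(model: ModelSpec, case: CaseParameters):
    """Time-autonomous right-hand side ``f(state, time=0) -> dstate/dt``."""
    sys = NeuronSystem(model, case)
    return lambda state, time=0.0: sys.rhs(time, np.asarray(state, dtype=float))


def build_jacobian(model: ModelSpec, case: CaseParameters):
    """Analytic Jacobian ``J(state)`` of the vector field."""
    sys = NeuronSystem(model, case)
    return lambda state: sys.jac(np.asarray(state, dtype=float))


def assemble_hco(cell_a: DynamicalSystem, cell_b: DynamicalSystem,
                 synapses) -> CoupledSystem:
    """Reciprocally couple two cells with the given synapse specs.

    Each :class:`SynapseSpec` in ``synapses`` is instantiated twice, once in
    each direction (a->b and b->a), mirroring a symmetric half-center
    oscillator.  Pass :class:`NeuronSystem` instances (or any
    :class:`DynamicalSystem` whose first state variable is V).
    """
    inst = []
    for spec in synapses:
        inst.append((spec, "a"))
        inst.append((spec, "b"))
    return CoupledSystem(cell_a, cell_b, inst)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

def _gating_from_dict(name, d):
    ss = d["steady_state"]
    tc = d.get("time_constant", {})
    return GatingSpec(
        name=name,
        exponent=int(d.get("exponent", 1)),
        steady_state=Sigmoid(v_half=float(ss["v_half_mV"]), k=float(ss["k_mV"])),
        time_constant=TimeConstant(
            form=tc.get("form", "constant"),
            base=float(tc.get("base_s", 0.1)),
            amp=float(tc.get("amp_s", 0.0)),
            v_half=float(tc.get("v_half_mV", 0.0)),
            k=float(tc.get("k_mV", 10.0)),
        ),
    )


def load_model_config(path) -> ModelSpec:
    """Load and validate a model definition from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "model" not in data:
        raise ConfigError(f"{path}: expected a top-level 'model' section")
    m = data["model"]
    try:
        currents = []
        for cd in m.get("currents", []):
            act = _gating_from_dict(cd["activation"].get("name", "m"), cd["activation"]) \
                if cd.get("activation") else None
            inact = _gating_from_dict(cd["inactivation"].get("name", "h"), cd["inactivation"]) \
                if cd.get("inactivation") else None
            currents.append(CurrentSpec(
                name=cd["name"],
                reversal_potential=float(cd["reversal_mV"]),
                max_conductance=float(cd["gbar_nS"]),
                activation=act,
                inactivation=inact,
                instantaneous=bool(cd.get("instantaneous", False)),
            ))
        return ModelSpec(
            name=m.get("name", "model"),
            capacitance=float(m["capacitance_nF"]),
            currents=tuple(currents),
            injected_current=float(m.get("injected_current_nA", 0.0)),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing required key {exc}") from exc


def dump_model_config(model: ModelSpec, path) -> None:
    def gate_dict(gs):
        if gs is None:
            return None
        return {
            "name": gs.name,
            "exponent": gs.exponent,
            "steady_state": {"v_half_mV": gs.steady_state.v_half, "k_mV": gs.steady_state.k},
            "time_constant": {
                "form": gs.time_constant.form,
                "base_s": gs.time_constant.base,
                "amp_s": gs.time_constant.amp,
                "v_half_mV": gs.time_constant.v_half,
                "k_mV": gs.time_constant.k,
            },
        }

    data = {"model": {
        "name": model.name,
        "capacitance_nF": model.capacitance,
        "injected_current_nA": model.injected_current,
        "currents": [
            {
                "name": c.name,
                "reversal_mV": c.reversal_potential,
                "gbar_nS": c.max_conductance,
                "instantaneous": c.instantaneous,
                "activation": gate_dict(c.activation),
                "inactivation": gate_dict(c.inactivation),
            }
            for c in model.currents
        ],
    }}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
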