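"""Parameter-grid definition and deterministic enumeration.

A screening grid is a Cartesian product over named axes (row-major in the
declared axis order) minus an optional exclusion rule.  Case identifiers
are assigned sequentially from 0 over the *included* cases, so the mapping
from case id to parameter values is reproducible from the grid definition
alone.

Two canonical grids are provided, mirroring an eight-parameter screen of a
half-center oscillator model: the leak reversal potential takes five
values, and seven maximal conductances (leak, four intrinsic currents, two
synaptic currents) each take eight values given as fractions of their
canonical magnitude.  Excluding the fully decoupled combinations (both
synaptic conductances zero) leaves 10,321,920 network cases; pinning both
synaptic conductances to zero gives the 163,840 isolated-neuron cases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import prod

from .models import CaseParameters, ConfigError

__all__ = [
    "ZeroExclusion",
    "GridSpec",
    "enumerate_grid",
    "grid_count",
    "hco_grid",
    "isolated_neuron_grid",
    "CONDUCTANCE_FRACTIONS",
    "E_LEAK_VALUES",
]

#: conductance scale factors used by the canonical screen (0% .. 175%)
CONDUCTANCE_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75)
#: leak reversal potentials of the canonical screen (mV)
E_LEAK_VALUES = (-70.0, -65.0, -60.0, -55.0, -50.0)


@dataclass(frozen=True)
class ZeroExclusion:
    """Exclude points where *all* listed axes are zero.

    This structured rule (rather than an opaque predicate) lets the grid
    size be computed combinatorially without enumeration.
    """

    axes: tuple

    def __call__(self, point: dict) -> bool:
        return all(point[a] == 0 for a in self.axes)

    def excluded_count(self, grid: "GridSpec") -> int:
        n = 1
        for name, values in grid.axes.items():
            if name in self.axes:
                n *= sum(1 for v in values if v == 0)
            else:
                n *= len(values)
        return n


@dataclass(frozen=True)
class GridSpec:
    """Named axes (ordered) and an optional exclusion rule."""

    axes: dict          # name -> list of values, insertion order = enumeration order
    exclusion: object = None   # ZeroExclusion or callable point->bool, or None

    def __post_init__(self):
        for name, values in self.axes.items():
            if len(values) == 0:
                raise ConfigError(f"grid axis {name!r} has an empty value list")

    def points(self):
        """Yield included grid points as dicts, row-major in axis order."""
        names = list(self.axes)
        for combo in itertools.product(*(self.axes[n] for n in names)):
            point = dict(zip(names, combo))
            if self.exclusion is not None and self.exclusion(point):
                continue
            yield point


def grid_count(grid: GridSpec) -> int:
    """Number of included cases, without materializing the grid.

    A :class:`ZeroExclusion` is counted combinatorially; an arbitrary
    callable exclusion falls back to streamed enumeration.
    """
    total = prod(len(v) for v in grid.axes.values())
    if grid.exclusion is None:
        return total
    if isinstance(grid.exclusion, ZeroExclusion):
        return total - grid.exclusion.excluded_count(grid)
    return sum(1 for _ in grid.points())


def enumerate_grid(grid: GridSpec):
    """Yield :class:`CaseParameters` for every included point.

    Axes named ``E_leak`` (mV) and ``g_leak`` (nS) map onto the leak
    parameters; every other axis value is recorded as a conductance scale
    factor under the axis name.  Case ids run sequentially from 0 in
    enumeration order.
    """
    if "E_leak" not in grid.axes or "g_leak" not in grid.axes:
        raise ConfigError("grid must define 'E_leak' and 'g_leak' axes")
    for case_id, point in enumerate(grid.points()):
        scales = {k: v for k, v in point.items() if k not in ("E_leak", "g_leak")}
        yield CaseParameters(
            case_id=case_id,
            E_leak=point["E_leak"],
            g_leak=point["g_leak"],
            scale_factors=scales,
        )


def _conductance_axes(canonical_g_leak: float):
    g_leak_values = [f * canonical_g_leak for f in CONDUCTANCE_FRACTIONS]
    axes = {
        "E_leak": list(E_LEAK_VALUES),
        "g_leak": g_leak_values,
        "P": list(CONDUCTANCE_FRACTIONS),
        "CaS": list(CONDUCTANCE_FRACTIONS),
        "h": list(CONDUCTANCE_FRACTIONS),
        "K2": list(CONDUCTANCE_FRACTIONS),
    }
    return axes


def hco_grid(canonical_g_leak: float = 8.0) -> GridSpec:
    """Eight-parameter half-center-oscillator screen.

    Five leak reversal potentials x eight values for each of seven maximal
    conductances, excluding the combinations where both synaptic
    conductances vanish: 10,321,920 cases.
    """
    axes = _conductance_axes(canonical_g_leak)
    axes["SynS"] = list(CONDUCTANCE_FRACTIONS)
    axes["SynG"] = list(CONDUCTANCE_FRACTIONS)
    return GridSpec(axes=axes, exclusion=ZeroExclusion(axes=("SynS", "SynG")))


def isolated_neuron_grid(canonical_g_leak: float = 8.0) -> GridSpec:
    """The decoupled subset: both synaptic conductances pinned to 0.

    163,840 cases.
    """
    axes = _conductance_axes(canonical_g_leak)
    axes["SynS"] = [0.0]
    axes["SynG"] = [0.0]
    return GridSpec(axes=axes, exclusion=None)
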