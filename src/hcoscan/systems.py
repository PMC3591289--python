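"""Generic autonomous dynamical-system interface.

Every object the integrator, the continuation engine and the scanners operate
on exposes the same small surface: a right-hand side ``rhs(t, y)``, an
analytic (or finite-difference) Jacobian ``jac(y)``, and a single scalar
bifurcation parameter reachable through ``with_param``.  Conductance-based
neuron models, normal-form surrogates and coupled two-cell networks all
implement this interface, so the analysis stages never need to know which
kind of model they are looking at.

Units are fixed package-wide: membrane potential in mV, conductances in nS,
capacitance in nF, currents in nA, time in seconds.  The first state
variable of any single-cell system is always the membrane potential V.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = ["DynamicalSystem", "finite_difference_jacobian"]


def finite_difference_jacobian(fun, y, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of ``fun`` at ``y``.

    Step size is scaled per component: ``eps * max(1, |y_i|)``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    f0 = np.asarray(fun(y), dtype=float)
    J = np.empty((f0.size, n))
    for i in range(n):
        h = eps * max(1.0, abs(y[i]))
        yp = y.copy()
        ym = y.copy()
        yp[i] += h
        ym[i] -= h
        J[:, i] = (np.asarray(fun(yp)) - np.asarray(fun(ym))) / (2.0 * h)
    return J


class DynamicalSystem:
    """Base class for autonomous ODE systems ``dy/dt = f(y)``.

    Subclasses must set :attr:`dim` and :attr:`state_names` and implement
    :meth:`rhs`.  ``jac`` defaults to central finite differences of ``rhs``.

    The scalar bifurcation parameter (the leak conductance for neuron
    models) is exposed through :attr:`param` / :meth:`with_param`; systems
    that have no meaningful continuation axis may leave the default no-op.
    """

    dim: int = 0
    state_names: tuple = ()
    #: name of the continuation parameter, for reporting
    param_name: str = "g_leak"
    #: effective membrane capacitance (nF) used when wiring synaptic input
    capacitance: float = 1.0

    # -- dynamics ---------------------------------------------------------
    def rhs(self, t: float, y) -> np.ndarray:
        raise NotImplementedError

    def jac(self, y) -> np.ndarray:
        return finite_difference_jacobian(lambda x: self.rhs(0.0, x), y)

    # -- continuation parameter ------------------------------------------
    @property
    def param(self) -> float:
        raise NotImplementedError(f"{type(self).__name__} has no parameter axis")

    def with_param(self, value: float) -> "DynamicalSystem":
        """Return a copy of the system with the bifurcation parameter set."""
        new = copy.deepcopy(self)
        new._set_param(float(value))
        return new

    def _set_param(self, value: float) -> None:
        raise NotImplementedError(f"{type(self).__name__} has no parameter axis")

    def dfdp(self, y, eps: float = 1e-6) -> np.ndarray:
        """Derivative of the vector field w.r.t. the bifurcation parameter.

        Central finite difference by default; subclasses with an ohmic
        parameter dependence override this analytically.
        """
        p = self.param
        h = eps * max(1.0, abs(p))
        fp = self.with_param(p + h).rhs(0.0, y)
        fm = self.with_param(p - h).rhs(0.0, y)
        return (np.asarray(fp) - np.asarray(fm)) / (2.0 * h)

    # -- convenience ------------------------------------------------------
    def check_state(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape != (self.dim,):
            raise ValueError(
                f"state has shape {y.shape}, expected ({self.dim},) for "
                f"{type(self).__name__}"
            )
        return y
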