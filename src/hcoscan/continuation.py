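"""One-parameter continuation of stationary states.

Equilibria of a model are traced in the leak conductance (or a surrogate's
bifurcation parameter) with a pseudo-arclength predictor-corrector, so
branches are followed through folds where the parameter turns around.
Along the branch, stability is read off the Jacobian spectrum and two test
functions are monitored between consecutive points:

* ``det J`` — a sign change marks a fold / limit point (LP), where a single
  real eigenvalue crosses zero and the branch turns;
* ``Re prod_{i<j} (lambda_i + lambda_j)`` — a sign change marks an
  Andronov-Hopf point (AH) where a complex-conjugate pair crosses the
  imaginary axis.  The pair-sum product is invariant to eigenvalue
  ordering, which keeps the test robust on high-dimensional systems;
  crossings whose candidate pair has a vanishing imaginary part (neutral
  saddles) are rejected.

Sign changes are localized by bisection in arclength until the parameter
bracket is below 1e-8 (nS).  Stable sub-arcs are reported as labeled
intervals: hyperpolarized (*hyp*) if the equilibrium membrane potential is
below -35 mV, depolarized (*dep*) above, numbered along the branch with
*hyp1* containing the branch start; reported parameter ranges are clipped
to g >= 0 although the continuation itself follows the curve into negative
parameter values.

Because state components (mV) and the parameter (nS) live on different
scales, arclength uses a weighted metric in which state displacements are
scaled by ``state_weight`` (default 0.02 per unit), so the step-size bounds
(max 0.02, min 1e-12, at most 4,000 points) act approximately in parameter
units away from folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .integrate import settle

__all__ = [
    "EquilibriumPoint", "BifurcationPoint", "StableInterval", "Branch",
    "RootFindError", "find_equilibrium", "continue_branch",
    "detect_bifurcations", "stable_intervals", "branch_from_high_leak",
    "NEWTON_TOL", "BIF_LOC_TOL",
]

NEWTON_TOL = 1e-10
BIF_LOC_TOL = 1e-8
HYP_DEP_SPLIT_MV = -35.0


class RootFindError(RuntimeError):
    pass


@dataclass(frozen=True)
class EquilibriumPoint:
    parameter: float
    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool

    @property
    def v(self) -> float:
        return float(self.state[0])

    @property
    def max_real_eig(self) -> float:
        return float(np.max(self.eigenvalues.real))


@dataclass(frozen=True)
class BifurcationPoint:
    kind: str          # "LP" | "AH"
    parameter: float
    state: np.ndarray
    label: str         # "LP1", "AH2", ... in arc-length order
    #: index of the branch segment (between points i and i+1) it was found in
    segment: int = -1


@dataclass(frozen=True)
class StableInterval:
    label: str             # "hyp1", "dep2", ...
    g_min: float
    g_max: float           # math.inf when the arc includes the branch start
    representative_v: float

    @property
    def kind(self) -> str:
        return "hyp" if self.representative_v < HYP_DEP_SPLIT_MV else "dep"

    def as_tuple(self):
        return (self.g_min, self.g_max)


@dataclass
class Branch:
    """Arc-length ordered equilibria with detected bifurcations."""

    points: list
    bifurcations: list = field(default_factory=list)
    termination: str = ""

    def __len__(self):
        return len(self.points)

    @property
    def parameters(self) -> np.ndarray:
        return np.array([p.parameter for p in self.points])

    def to_frame(self):
        import pandas as pd
        rows = []
        for i, p in enumerate(self.points):
            row = {"index": i, "parameter": p.parameter,
                   "max_real_eig": p.max_real_eig, "stable": p.stable}
            row.update({f"x{j}": v for j, v in enumerate(p.state)})
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# equilibrium refinement
# ---------------------------------------------------------------------------

def _make_point(system, y: np.ndarray, p: float) -> EquilibriumPoint:
    sysp = system.with_param(p)
    eig = np.linalg.eigvals(sysp.jac(y))
    return EquilibriumPoint(parameter=float(p), state=y.copy(),
                            eigenvalues=eig, stable=bool(np.max(eig.real) < 0))


def find_equilibrium(system, guess, tol: float = NEWTON_TOL,
                     max_iter: int = 60) -> EquilibriumPoint:
    """Newton refinement of an equilibrium at the system's current parameter."""
    y = np.asarray(guess, dtype=float).copy()
    if not np.all(np.isfinite(y)):
        raise RootFindError("non-finite initial guess")
    for _ in range(max_iter):
        f = system.rhs(0.0, y)
        if np.linalg.norm(f, np.inf) < tol:
            return _make_point(system, y, system.param)
        J = system.jac(y)
        try:
            dy = np.linalg.solve(J, f)
        except np.linalg.LinAlgError as exc:
            raise RootFindError(f"singular Jacobian during Newton: {exc}") from exc
        # damped step if the full step diverges
        lam = 1.0
        f_norm = np.linalg.norm(f, np.inf)
        for _ in range(8):
            y_new = y - lam * dy
            f_new = system.rhs(0.0, y_new)
            if np.all(np.isfinite(f_new)) and np.linalg.norm(f_new, np.inf) < f_norm:
                break
            lam *= 0.5
        y = y - lam * dy
    f = system.rhs(0.0, y)
    if np.linalg.norm(f, np.inf) < tol:
        return _make_point(system, y, system.param)
    raise RootFindError(
        f"Newton did not converge (||f|| = {np.linalg.norm(f, np.inf):.3e})")


def branch_from_high_leak(system, y0, g_start: float = 20.0,
                          settle_kwargs=None) -> EquilibriumPoint:
    """Starting point for continuation: settle at a large leak conductance
    and refine the endpoint to an equilibrium (the hyperpolarized rest)."""
    sysg = system.with_param(g_start)
    traj = settle(sysg, y0, **(settle_kwargs or {}))
    return find_equilibrium(sysg, traj.final_state)


# ---------------------------------------------------------------------------
# pseudo-arclength stepping
# ---------------------------------------------------------------------------

def _augmented_correct(system, y, p, t_y, t_p, y_ref, p_ref, w2,
                       tol=NEWTON_TOL, max_iter=12):
    """Newton-correct (y, p) onto {f = 0} within the hyperplane through
    (y_ref, p_ref) orthogonal (in the weighted metric) to the tangent."""
    y = y.copy()
    p = float(p)
    n = y.size
    for _ in range(max_iter):
        sysp = system.with_param(p)
        f = sysp.rhs(0.0, y)
        c = w2 * np.dot(y - y_ref, t_y) + (p - p_ref) * t_p
        if np.linalg.norm(f, np.inf) < tol and abs(c) < tol * max(1.0, abs(p)):
            return y, p, True
        J = sysp.jac(y)
        dfdp = sysp.dfdp(y)
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = J
        A[:n, n] = dfdp
        A[n, :n] = w2 * t_y
        A[n, n] = t_p
        rhs = np.concatenate([f, [c]])
        try:
            delta = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            return y, p, False
        y = y - delta[:n]
        p = p - delta[n]
        if not np.all(np.isfinite(y)) or not math.isfinite(p):
            return y, p, False
    return y, p, False


def _initial_tangent(system, point, direction, w2):
    sysp = system.with_param(point.parameter)
    J = sysp.jac(point.state)
    dfdp = sysp.dfdp(point.state)
    try:
        dydp = np.linalg.solve(J, -dfdp)
        t_y, t_p = dydp, 1.0
    except np.linalg.LinAlgError:
        t_y, t_p = np.zeros_like(point.state), 1.0
    norm = math.sqrt(w2 * np.dot(t_y, t_y) + t_p**2)
    t_y, t_p = t_y / norm, t_p / norm
    if math.copysign(1.0, t_p) != math.copysign(1.0, direction):
        t_y, t_p = -t_y, -t_p
    return t_y, t_p


def _ah_test(eigenvalues: np.ndarray) -> float:
    """Re prod_{i<j} (lambda_i + lambda_j); sign change flags a Hopf pair."""
    lam = eigenvalues
    prod = 1.0 + 0.0j
    n = lam.size
    for i in range(n):
        for j in range(i + 1, n):
            prod *= lam[i] + lam[j]
    return float(prod.real)


def _det_test(eigenvalues: np.ndarray) -> float:
    return float(np.prod(eigenvalues).real)


def continue_branch(system, start: EquilibriumPoint, *,
                    step_max: float = 0.02, step_min: float = 1e-12,
                    max_points: int = 4000, direction: float = -1.0,
                    param_max: float = 25.0, param_min: float = -25.0,
                    state_weight: float = 0.02,
                    detect: bool = True) -> Branch:
    """Pseudo-arclength continuation from a converged equilibrium.

    ``direction`` sets the initial parameter direction (-1: decreasing, the
    standard protocol starting from g = 20 nS).  The branch is followed
    through folds; it terminates after ``max_points`` points, when the
    parameter exits [param_min, param_max] moving outward, or when the
    corrector fails at the minimum step size (truncation, recorded in
    ``Branch.termination``).  Bifurcations are detected on the fly when
    ``detect`` is set.
    """
    w2 = state_weight**2
    points = [start]
    t_y, t_p = _initial_tangent(system, start, direction, w2)
    h = step_max
    termination = "max_points"
    while len(points) < max_points:
        prev = points[-1]
        converged = False
        while True:
            y_pred = prev.state + h * t_y
            p_pred = prev.parameter + h * t_p
            y_new, p_new, ok = _augmented_correct(
                system, y_pred, p_pred, t_y, t_p, y_pred, p_pred, w2)
            if ok:
                converged = True
                break
            h *= 0.5
            if h < step_min:
                break
        if not converged:
            termination = "corrector_failure"
            break
        new_point = _make_point(system, y_new, p_new)
        points.append(new_point)
        # update secant tangent
        dy = new_point.state - prev.state
        dp = new_point.parameter - prev.parameter
        norm = math.sqrt(w2 * np.dot(dy, dy) + dp**2)
        if norm > 0:
            t_y, t_p = dy / norm, dp / norm
        h = min(h * 1.5, step_max)
        if new_point.parameter > param_max and t_p > 0:
            termination = "param_max"
            break
        if new_point.parameter < param_min and t_p < 0:
            termination = "param_min"
            break
    branch = Branch(points=points, termination=termination)
    if detect and len(points) >= 2:
        branch.bifurcations = detect_bifurcations(branch, system,
                                                  state_weight=state_weight)
    return branch


# ---------------------------------------------------------------------------
# bifurcation detection
# ---------------------------------------------------------------------------

def _bisect_crossing(system, p0, p1, test, w2, loc_tol=BIF_LOC_TOL,
                     max_iter=80):
    """Bisect a test-function sign change between two branch points.

    Interpolates along the secant, correcting back onto the branch in the
    hyperplane orthogonal to the secant; returns the crossing point.
    """
    dy = p1.state - p0.state
    dp = p1.parameter - p0.parameter
    norm = math.sqrt(w2 * np.dot(dy, dy) + dp**2)
    t_y, t_p = dy / norm, dp / norm
    a, b = 0.0, 1.0
    fa = test(p0.eigenvalues)
    lo, hi = p0, p1
    for _ in range(max_iter):
        if abs(hi.parameter - lo.parameter) < loc_tol and \
                abs(b - a) * norm < max(loc_tol, 1e-10):
            break
        m = 0.5 * (a + b)
        y_m = p0.state + m * dy
        g_m = p0.parameter + m * dp
        y_c, g_c, ok = _augmented_correct(system, y_m, g_m, t_y, t_p, y_m, g_m, w2)
        if not ok:
            break
        mid = _make_point(system, y_c, g_c)
        fm = test(mid.eigenvalues)
        if fa * fm <= 0:
            b, hi = m, mid
        else:
            a, fa, lo = m, fm, mid
    return hi


def detect_bifurcations(branch: Branch, system, *,
                        state_weight: float = 0.02,
                        imag_floor: float = 1e-6) -> list:
    """Locate LP and AH points from test-function sign changes.

    Labels are assigned sequentially per kind in arc-length order.  A
    coincident LP and AH within the localization tolerance is allowed; both
    are reported.
    """
    if len(branch) < 2:
        raise ValueError("need at least 2 branch points")
    w2 = state_weight**2
    found = []
    pts = branch.points
    for k in range(len(pts) - 1):
        p0, p1 = pts[k], pts[k + 1]
        d0, d1 = _det_test(p0.eigenvalues), _det_test(p1.eigenvalues)
        if d0 * d1 < 0:
            at = _bisect_crossing(system, p0, p1, _det_test, w2)
            found.append(("LP", at, k))
        a0, a1 = _ah_test(p0.eigenvalues), _ah_test(p1.eigenvalues)
        if a0 * a1 < 0:
            at = _bisect_crossing(system, p0, p1, _ah_test, w2)
            eig = at.eigenvalues
            cand = eig[np.abs(eig.imag) > imag_floor]
            is_hopf = cand.size >= 2 and np.min(np.abs(cand.real)) < 1e-4
            # reject neutral saddles (two real eigenvalues summing to zero)
            if is_hopf:
                found.append(("AH", at, k))
    out = []
    counters = {"LP": 0, "AH": 0}
    for kind, at, seg in found:
        counters[kind] += 1
        out.append(BifurcationPoint(kind=kind, parameter=at.parameter,
                                    state=at.state,
                                    label=f"{kind}{counters[kind]}",
                                    segment=seg))
    return out


# ---------------------------------------------------------------------------
# stable intervals
# ---------------------------------------------------------------------------

def _interp_crossing_v(p0, p1, v_split):
    """Parameter where V crosses v_split between two branch points."""
    v0, v1 = p0.v, p1.v
    if v1 == v0:
        return 0.5 * (p0.parameter + p1.parameter)
    s = (v_split - v0) / (v1 - v0)
    return p0.parameter + s * (p1.parameter - p0.parameter)


def stable_intervals(branch: Branch, *, clip_at_zero: bool = True,
                     v_split: float = HYP_DEP_SPLIT_MV) -> list:
    """Maximal stable sub-arcs, classified hyp/dep and numbered along the
    branch (hyp1 contains the branch start when the start is stable).

    An arc straddling V = v_split is split at the crossing.  Interval
    bounds use detected bifurcation parameters where a stability change was
    localized within the segment.  The arc containing the branch start is
    reported as unbounded above (the rest state persists for arbitrarily
    large leak).  Ranges are clipped to parameter >= 0 when requested;
    intervals entirely below 0 are dropped.
    """
    pts = branch.points
    bif_by_segment = {b.segment: b for b in branch.bifurcations}

    # split the branch into maximal runs of constant (stable, hyp/dep side)
    runs = []   # (start_idx, end_idx, stable, side, g_lo_override, g_hi_override)
    i = 0
    n = len(pts)
    while i < n:
        stable = pts[i].stable
        side = pts[i].v < v_split
        j = i
        while j + 1 < n and pts[j + 1].stable == stable and (pts[j + 1].v < v_split) == side:
            j += 1
        runs.append((i, j, stable, side))
        i = j + 1

    intervals = []
    for r, (i, j, stable, side) in enumerate(runs):
        if not stable:
            continue
        g_vals = [pts[k].parameter for k in range(i, j + 1)]
        g_lo, g_hi = min(g_vals), max(g_vals)
        # refine boundaries using localized bifurcations / V-crossings
        if i > 0:
            if pts[i - 1].stable != stable and (i - 1) in bif_by_segment:
                g_edge = bif_by_segment[i - 1].parameter
            elif pts[i - 1].stable == stable:   # side change within stable arc
                g_edge = _interp_crossing_v(pts[i - 1], pts[i], v_split)
            else:
                g_edge = 0.5 * (pts[i - 1].parameter + pts[i].parameter)
            g_lo, g_hi = min(g_lo, g_edge), max(g_hi, g_edge)
        if j < n - 1:
            if pts[j + 1].stable != stable and j in bif_by_segment:
                g_edge = bif_by_segment[j].parameter
            elif pts[j + 1].stable == stable:
                g_edge = _interp_crossing_v(pts[j], pts[j + 1], v_split)
            else:
                g_edge = 0.5 * (pts[j].parameter + pts[j + 1].parameter)
            g_lo, g_hi = min(g_lo, g_edge), max(g_hi, g_edge)
        if i == 0:
            g_hi = math.inf   # branch start: rest persists for larger g
        v_rep = float(np.median([pts[k].v for k in range(i, j + 1)]))
        intervals.append([g_lo, g_hi, v_rep])

    if clip_at_zero:
        clipped = []
        for g_lo, g_hi, v_rep in intervals:
            if g_hi < 0:
                continue
            clipped.append([max(g_lo, 0.0), g_hi, v_rep])
        intervals = clipped

    out = []
    counters = {"hyp": 0, "dep": 0}
    for g_lo, g_hi, v_rep in intervals:
        kind = "hyp" if v_rep < v_split else "dep"
        counters[kind] += 1
        out.append(StableInterval(label=f"{kind}{counters[kind]}",
                                  g_min=g_lo, g_max=g_hi,
                                  representative_v=v_rep))
    return out
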