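"""Equilibrium refinement, branch following, bifurcation detection."""

import numpy as np
import pytest

from hcoscan.continuation import (Branch, EquilibriumPoint, RootFindError,
                                  branch_from_high_leak, continue_branch,
                                  detect_bifurcations, find_equilibrium,
                                  stable_intervals)
from hcoscan.integrate import settle
from hcoscan.synthetic import (FoldModel, HopfModel, RelaxationModel,
                               burster_equilibrium_curve, eigenvalue_scan_ah)


class TestFindEquilibrium:
    def test_fold_stable_root(self):
        eq = find_equilibrium(FoldModel(mu_c=0.0, mu=1.0), [0.9])
        assert eq.state[0] == pytest.approx(1.0, abs=1e-10)
        assert eq.eigenvalues[0].real == pytest.approx(-2.0, abs=1e-8)
        assert eq.stable

    def test_fold_unstable_root(self):
        eq = find_equilibrium(FoldModel(mu_c=0.0, mu=1.0), [-0.9])
        assert eq.state[0] == pytest.approx(-1.0, abs=1e-10)
        assert eq.eigenvalues[0].real == pytest.approx(2.0, abs=1e-8)
        assert not eq.stable

    def test_no_equilibrium_raises(self):
        # mu < mu_c: no real roots
        with pytest.raises(RootFindError):
            find_equilibrium(FoldModel(mu_c=0.0, mu=-1.0), [0.5])

    def test_residual_below_tolerance(self, burster):
        sys20 = burster.with_param(20.0)
        traj = settle(sys20, burster.rest_guess())
        eq = find_equilibrium(sys20, traj.final_state)
        assert np.linalg.norm(sys20.rhs(0.0, eq.state), np.inf) < 1e-10
        # integration endpoint already sits on the equilibrium
        assert eq.state == pytest.approx(traj.final_state, abs=1e-4)
        assert eq.stable


class TestFoldBranch:
    def branch(self):
        model = FoldModel(mu_c=0.0, mu=1.0)
        start = find_equilibrium(model, [1.0])
        return model, continue_branch(model, start, state_weight=1.0,
                                      param_min=-2.0, param_max=2.0)

    def test_lp_located_at_fold(self):
        _, branch = self.branch()
        lps = [b for b in branch.bifurcations if b.kind == "LP"]
        assert len(lps) == 1
        assert lps[0].parameter == pytest.approx(0.0, abs=1e-8)
        assert lps[0].label == "LP1"

    def test_branch_turns_and_recovers_both_halves(self):
        _, branch = self.branch()
        xs = np.array([p.state[0] for p in branch.points])
        assert xs.max() >= 1.0
        assert xs.min() < -0.5    # unstable half-branch reached

    def test_fold_symmetry(self):
        # every point satisfies mu = x^2, so the halves mirror exactly
        _, branch = self.branch()
        for p in branch.points:
            assert p.parameter == pytest.approx(p.state[0] ** 2, abs=1e-10)

    def test_stability_flags_match_eigenvalues(self):
        model, branch = self.branch()
        for p in branch.points[::10]:
            eig = np.linalg.eigvals(model.with_param(p.parameter).jac(p.state))
            assert p.stable == (np.max(eig.real) < 0)

    def test_offset_fold_location(self):
        model = FoldModel(mu_c=3.5, mu=4.5)
        start = find_equilibrium(model, [1.0])
        branch = continue_branch(model, start, state_weight=1.0,
                                 param_min=2.0, param_max=6.0)
        lp = [b for b in branch.bifurcations if b.kind == "LP"][0]
        assert lp.parameter == pytest.approx(3.5, abs=1e-8)


class TestHopfBranch:
    @pytest.mark.parametrize("mu_c", [0.0, -2.0])
    def test_ah_located(self, mu_c):
        model = HopfModel(mu_c=mu_c, omega=1.0, mu=mu_c - 1.0)
        start = find_equilibrium(model, [0.01, 0.01])
        branch = continue_branch(model, start, direction=+1.0,
                                 state_weight=1.0, param_min=mu_c - 2.0,
                                 param_max=mu_c + 1.0)
        ahs = [b for b in branch.bifurcations if b.kind == "AH"]
        assert len(ahs) == 1
        assert ahs[0].parameter == pytest.approx(mu_c, abs=1e-8)

    def test_frequency_at_crossing(self):
        model = HopfModel(mu_c=0.0, omega=2.5, mu=0.0)
        eig = np.linalg.eigvals(model.jac(np.zeros(2)))
        assert sorted(np.abs(eig.imag)) == pytest.approx([2.5, 2.5])

    def test_stability_flips_at_crossing(self):
        model = HopfModel(mu_c=0.0, omega=1.0)
        eq_m = find_equilibrium(model.with_param(-0.5), [0.0, 0.0])
        eq_p = find_equilibrium(model.with_param(0.5), [0.0, 0.0])
        assert eq_m.stable and not eq_p.stable


class TestRelaxationOracle:
    def test_ah_matches_eigenvalue_scan(self):
        model = RelaxationModel(mu=0.0)
        start = find_equilibrium(model, model.equilibrium_state(0.0))
        branch = continue_branch(model, start, direction=+1.0,
                                 state_weight=1.0, param_min=-0.5,
                                 param_max=0.8, max_points=300)
        ah = [b for b in branch.bifurcations if b.kind == "AH"][0]
        mu_oracle = eigenvalue_scan_ah(
            model, np.arange(ah.parameter - 0.01, ah.parameter + 0.01, 1e-6),
            model.equilibrium_state)
        assert ah.parameter == pytest.approx(mu_oracle, abs=1e-5)


class TestBursterBranch:
    def test_points_satisfy_equilibrium_condition(self, burster,
                                                  burster_branch):
        for p in burster_branch.points[::50]:
            f = burster.with_param(p.parameter).rhs(0.0, p.state)
            assert np.linalg.norm(f, np.inf) < 1e-9

    def test_branch_matches_closed_form_curve(self, burster, burster_branch):
        # each branch point must lie on the analytic equilibrium curve
        for p in burster_branch.points[::50]:
            x = (p.state[0] - burster.v0) / burster.sv
            g_curve, state_curve = burster_equilibrium_curve(
                burster, np.array([x]))
            assert p.parameter == pytest.approx(g_curve[0], abs=1e-6)
            assert p.state == pytest.approx(state_curve[0], abs=1e-6)

    def test_ah_matches_manifest(self, burster_branch, burster_manifest):
        ah1 = [b for b in burster_branch.bifurcations if b.kind == "AH"][0]
        assert ah1.parameter == pytest.approx(burster_manifest.ah_g, abs=1e-5)

    def test_hyp1_interval(self, burster_intervals, burster_manifest):
        hyp1 = [iv for iv in burster_intervals if iv.label == "hyp1"]
        assert len(hyp1) == 1
        assert hyp1[0].g_min == pytest.approx(burster_manifest.ah_g, abs=1e-5)
        assert np.isinf(hyp1[0].g_max)
        assert hyp1[0].representative_v < -35.0

    def test_interval_labels_stable_under_step_size(self, burster):
        start = branch_from_high_leak(burster, burster.rest_guess(),
                                      g_start=20.0)
        b1 = continue_branch(burster, start, step_max=0.02)
        b2 = continue_branch(burster, start, step_max=0.01)
        l1 = [(iv.label, round(iv.g_min, 4)) for iv in stable_intervals(b1)]
        l2 = [(iv.label, round(iv.g_min, 4)) for iv in stable_intervals(b2)]
        assert l1 == l2


def synthetic_branch(points_spec):
    """Branch of hand-made points: (parameter, V, stable)."""
    pts = []
    for g, v, stable in points_spec:
        eig = np.array([-1.0 + 0j]) if stable else np.array([1.0 + 0j])
        pts.append(EquilibriumPoint(parameter=g, state=np.array([v, 0.0]),
                                    eigenvalues=eig, stable=stable))
    return Branch(points=pts)


class TestStableIntervals:
    def test_single_hyp_interval_with_lower_ah(self):
        # stable for g >= 5 at V ~ -55; unstable below
        spec = [(g, -55.0, g >= 5.0) for g in np.arange(20.0, 2.0, -0.5)]
        ivs = stable_intervals(synthetic_branch(spec))
        assert [iv.label for iv in ivs] == ["hyp1"]
        assert ivs[0].g_max == np.inf
        assert 4.5 <= ivs[0].g_min <= 5.0

    def test_dep_interval_between_bifurcations(self):
        spec = ([(g, -55.0, True) for g in np.arange(20.0, 10.0, -0.5)]
                + [(g, -45.0, False) for g in np.arange(10.0, 6.0, -0.5)]
                + [(g, -20.0, True) for g in np.arange(6.0, 3.0, -0.5)]
                + [(g, -15.0, False) for g in np.arange(3.0, 1.0, -0.5)])
        ivs = stable_intervals(synthetic_branch(spec))
        assert [iv.label for iv in ivs] == ["hyp1", "dep1"]
        assert ivs[1].representative_v > -35.0

    def test_interval_crossing_v_split_is_divided(self):
        # one stable arc drifting from -50 to -20 mV must split at -35
        vs = np.linspace(-50.0, -20.0, 40)
        spec = [(10.0 - 0.1 * i, v, True) for i, v in enumerate(vs)]
        ivs = stable_intervals(synthetic_branch(spec))
        assert [iv.label for iv in ivs] == ["hyp1", "dep1"]
        assert ivs[0].representative_v < -35.0 < ivs[1].representative_v

    def test_negative_parameter_clipped_to_zero(self):
        spec = [(g, -20.0, True) for g in np.arange(3.0, -2.0, -0.25)]
        ivs = stable_intervals(synthetic_branch(spec))
        assert ivs[0].g_min == 0.0

    def test_interval_entirely_negative_dropped(self):
        spec = ([(g, -55.0, False) for g in np.arange(3.0, 0.0, -0.25)]
                + [(g, -55.0, True) for g in np.arange(0.0, -2.0, -0.25)])
        ivs = stable_intervals(synthetic_branch(spec))
        # the stable arc lives at g < 0 except for the single point at 0
        assert all(iv.g_max >= 0.0 for iv in ivs)
        assert all(iv.g_min == 0.0 for iv in ivs) or ivs == []
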