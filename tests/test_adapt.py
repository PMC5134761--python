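"""Adaptive placement: pair criteria, sweep modes, domain expansion."""

import numpy as np
import pytest

from lamkit import (
    AdaptParams,
    LAM,
    LAMSet,
    SyntheticOracle,
    TorsionDomain,
    adapt,
    build_grid_lamset,
    check_pair,
    expand_domain,
    quadratic_preset,
    random_spec,
    regular_grid,
    residual_violations,
)
from lamkit.oracle import DependentModel, PotentialSpec, QuadraticTerm

from _brute import ref_adapt


def pair_set_1d(extra_refs=()):
    d = TorsionDomain([-180.0], [180.0], [False], [30.0])
    mk = lambda r, e: LAM(
        np.array([r]), e, np.zeros(1), np.array([[0.01]]), np.zeros(0), np.zeros((0, 1))
    )
    lams = [mk(0.0, 0.0), mk(60.0, 10.0)] + [mk(r, e) for r, e in extra_refs]
    return LAMSet(domain=d, lams=lams)


class TestCheckPair:
    def test_exact_models_agree_everywhere(self, quad_oracle, quad_lamset):
        params = AdaptParams()
        # the (-15, +15) pair: its midpoint is the well bottom (low energy),
        # so only the zero discrepancy of the exact models rejects it
        dec = check_pair(quad_lamset.lams, 2, 3, params, quad_lamset.domain)
        assert not dec.accepted
        assert dec.blocking == "discrepancy"
        assert dec.discrepancy == pytest.approx(0.0, abs=1e-8)

    def test_hand_worked_acceptance(self):
        ls = pair_set_1d()
        dec = check_pair(ls.lams, 0, 1, AdaptParams(), ls.domain)
        assert dec.accepted and dec.blocking is None
        assert dec.midpoint[0] == pytest.approx(30.0)
        assert dec.discrepancy == pytest.approx(10.0)
        assert dec.min_pred_energy == pytest.approx(4.5)

    def test_existing_model_at_midpoint_blocks(self):
        ls = pair_set_1d(extra_refs=[(30.0, 5.0)])
        dec = check_pair(ls.lams, 0, 1, AdaptParams(), ls.domain)
        assert not dec.accepted
        # distance 0 from the midpoint: rejected before any energy is computed
        assert dec.blocking in ("duplicate", "nearer_lam")

    def test_strictly_nearer_third_model_blocks(self):
        ls = pair_set_1d(extra_refs=[(25.0, 5.0)])
        dec = check_pair(ls.lams, 0, 1, AdaptParams(), ls.domain)
        assert dec.blocking == "nearer_lam"

    def test_equidistant_third_model_does_not_block(self):
        # a third model at distance exactly equal to the pair's does not block
        ls = pair_set_1d(extra_refs=[(-30.0, 3.0)])
        dec = check_pair(ls.lams, 0, 1, AdaptParams(), ls.domain)
        assert dec.accepted

    def test_high_energy_midpoint_blocked_by_cutoff(self):
        d = TorsionDomain([-180.0], [180.0], [False], [30.0])
        mk = lambda r, e: LAM(
            np.array([r]), e, np.zeros(1), np.array([[0.01]]), np.zeros(0), np.zeros((0, 1))
        )
        ls = LAMSet(domain=d, lams=[mk(0.0, 20.0), mk(60.0, 30.0)])
        dec = check_pair(ls.lams, 0, 1, AdaptParams(), ls.domain)
        assert dec.blocking == "cutoff"
        assert dec.min_pred_energy == pytest.approx(24.5)

    def test_same_model_twice_rejected(self):
        ls = pair_set_1d()
        with pytest.raises(ValueError):
            check_pair(ls.lams, 0, 0, AdaptParams(), ls.domain)

    def test_antipodal_pair_skipped(self):
        d = TorsionDomain([0.0], [360.0], [True], [30.0])
        mk = lambda r: LAM(
            np.array([r]), 0.0, np.zeros(1), np.zeros((1, 1)), np.zeros(0), np.zeros((0, 1))
        )
        ls = LAMSet(domain=d, lams=[mk(0.0), mk(180.0)])
        dec = check_pair(ls.lams, 0, 1, AdaptParams(), ls.domain)
        assert dec.blocking == "antipodal" and dec.midpoint is None


class TestAdapt:
    def test_quadratic_surface_needs_no_refinement(self, quad_oracle, quad_lamset):
        for mode in ("single_pass", "iterate"):
            result = adapt(quad_lamset, quad_oracle, AdaptParams(mode=mode))
            assert result.n_added == 0
            assert result.converged

    def test_double_well_inserts_two_models_at_pm60(self, dw_oracle, dw_node_lamset):
        result = adapt(dw_node_lamset, dw_oracle, AdaptParams(mode="iterate"))
        assert result.n_added == 2
        assert len(result.lamset) == 6
        new_refs = sorted(float(l.theta_ref[0]) for l in result.lamset.lams[4:])
        assert new_refs == pytest.approx([-60.0, 60.0])
        # the symmetric barrier at 0 deg shows no mismatch: no model there
        assert all(abs(l.theta_ref[0]) > 1.0 for l in result.lamset.lams)

    def test_single_pass_ignores_new_models_for_decisions(self, dw_oracle, dw_node_lamset):
        single = adapt(dw_node_lamset, dw_oracle, AdaptParams(mode="single_pass"))
        assert single.n_added == 2
        assert single.sweeps == 1

    def test_input_set_not_modified(self, dw_oracle, dw_node_lamset):
        n_before = len(dw_node_lamset)
        adapt(dw_node_lamset, dw_oracle, AdaptParams(mode="iterate"))
        assert len(dw_node_lamset) == n_before

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_decision_log_matches_brute_force_reference(self, seed):
        n_indep = 1 if seed % 2 else 2
        spec = random_spec(seed, n_indep=n_indep, n_dep=1, barrier_range=(2.0, 10.0))
        domain = TorsionDomain(
            [0.0] * n_indep, [360.0] * n_indep, [True] * n_indep,
            [60.0] * n_indep if n_indep == 1 else [45.0] * n_indep,
        )
        oracle = SyntheticOracle(spec, domain, f"random:{seed}")
        ls = build_grid_lamset(oracle, domain, regular_grid(domain, "centered"))
        params = AdaptParams(mode="iterate", max_new_lams=200)
        result = adapt(ls, oracle, params)
        ref_final, ref_log = ref_adapt(ls, oracle, mode="iterate")
        assert len(result.decisions) == len(ref_log)
        for dec, (pair, accepted, blocking, mid) in zip(result.decisions, ref_log):
            assert dec.pair == pair
            assert dec.accepted == accepted
            assert dec.blocking == blocking
            if mid is not None and dec.midpoint is not None:
                assert np.allclose(dec.midpoint, mid, atol=1e-9)
        assert len(result.lamset) == len(ref_final)

    def test_iterate_mode_reaches_fixed_point(self, c2d_oracle):
        ls = build_grid_lamset(
            c2d_oracle, c2d_oracle.domain, regular_grid(c2d_oracle.domain, "centered")
        )
        result = adapt(ls, c2d_oracle, AdaptParams(mode="iterate", max_new_lams=400))
        assert result.converged
        assert residual_violations(result.lamset) == []

    def test_tighter_threshold_never_accepts_fewer(self, dw_oracle, dw_node_lamset):
        counts = []
        for delta in (4.0, 1.0, 0.25):
            res = adapt(dw_node_lamset, dw_oracle, AdaptParams(mode="single_pass", delta_e=delta))
            counts.append(sum(d.accepted for d in res.decisions))
        assert counts == sorted(counts)

    def test_added_references_inside_domain(self, c2d_oracle):
        ls = build_grid_lamset(
            c2d_oracle, c2d_oracle.domain, regular_grid(c2d_oracle.domain, "centered")
        )
        res = adapt(ls, c2d_oracle, AdaptParams(mode="iterate", max_new_lams=400))
        for lam in res.lamset.lams:
            assert c2d_oracle.domain.contains(lam.theta_ref)

    def test_single_pass_addition_bound(self, dw_oracle, dw_node_lamset):
        res = adapt(dw_node_lamset, dw_oracle, AdaptParams(mode="single_pass"))
        n = len(dw_node_lamset)
        assert res.n_added <= n * (n - 1) // 2

    def test_budget_exhaustion_flagged(self, dw_oracle, dw_node_lamset):
        res = adapt(dw_node_lamset, dw_oracle, AdaptParams(mode="iterate", max_new_lams=1))
        assert not res.converged
        assert res.n_added == 1

    def test_deterministic_decision_log(self, dw_oracle, dw_node_lamset):
        r1 = adapt(dw_node_lamset, dw_oracle, AdaptParams(mode="iterate"))
        r2 = adapt(dw_node_lamset, dw_oracle, AdaptParams(mode="iterate"))
        assert [d.as_row() for d in r1.decisions] == [d.as_row() for d in r2.decisions]


class TestExpandDomain:
    def make_oracle(self, curvature=0.02, center=90.0):
        # harmonic well centred at the upper edge of [-90, 90]
        spec = PotentialSpec(
            n_indep=1,
            quadratic=(QuadraticTerm(dim=0, curvature=curvature, center=center),),
            dependents=(DependentModel(kappa=1.0),),
            name="edge_well",
        )
        domain = TorsionDomain([-90.0], [90.0], [False], [15.0])
        return SyntheticOracle(spec, domain, "edge_well"), domain

    def test_high_edges_leave_domain_unchanged(self, dw_oracle):
        # double-well walls at +/-90 are ~45 kJ/mol, above the threshold
        new, log = expand_domain(dw_oracle, dw_oracle.domain, threshold=15.0, increment=30.0)
        assert np.allclose(new.lower, dw_oracle.domain.lower)
        assert np.allclose(new.upper, dw_oracle.domain.upper)

    def test_low_edge_extends_to_quadratic_crossing(self):
        oracle, domain = self.make_oracle(curvature=0.02, center=90.0)
        new, log = expand_domain(oracle, domain, threshold=15.0, increment=30.0, max_span=360.0)
        # dE = 0.5*0.02*(theta-90)^2 >= 15 at |theta-90| >= ~38.7 deg:
        # the upper edge (well centre, dE=0) must extend past 128.7
        crossing = 90.0 + np.sqrt(2 * 15.0 / 0.02)
        assert new.upper[0] >= crossing
        assert new.upper[0] < crossing + 30.0  # within one increment
        assert new.lower[0] == pytest.approx(-90.0)  # lower edge is already high

    def test_periodic_dimension_untouched(self):
        spec = random_spec(2, n_indep=1)
        domain = TorsionDomain([0.0], [360.0], [True], [30.0])
        oracle = SyntheticOracle(spec, domain, "random:2")
        new, log = expand_domain(oracle, domain, threshold=1e6, increment=30.0)
        assert np.allclose(new.upper, domain.upper)
        assert log["edges"][0]["skipped"] == "periodic"

    def test_span_cap_honoured(self):
        oracle, domain = self.make_oracle(curvature=1e-6, center=90.0)
        new, _ = expand_domain(oracle, domain, threshold=15.0, increment=30.0, max_span=300.0)
        assert new.span[0] <= 300.0 + 1e-9
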