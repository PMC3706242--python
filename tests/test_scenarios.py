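"""Diet switches, drug interventions, EC50 scan and robustness sampling."""

import numpy as np
import pytest

from celiacqsp import (
    DietProtocol,
    InterventionSpec,
    apply_intervention,
    dose_response,
    ec50_ratio_scan,
    intervention_endpoint,
    robustness_scan,
    run_diet_switch,
)
from celiacqsp.scenarios import INTERVENTION_KINDS


class TestInterventionMapping:
    def test_complete_tg2_inhibition_zeroes_tg2(self, params):
        p = apply_intervention(params, InterventionSpec("tg2_inhibitor", 1.0))
        assert p["tg2_level"] == 0.0

    def test_complete_dq2_block_zeroes_apc_activation(self, params):
        p = apply_intervention(params, InterventionSpec("dq2_blocker", 1.0))
        assert p["k_apc_activation"] == 0.0

    def test_complete_permeability_inhibition_zeroes_iec_activation(
            self, params):
        p = apply_intervention(
            params, InterventionSpec("permeability_inhibitor", 1.0))
        assert p["k_iec_activation"] == 0.0

    def test_cytokine_antibodies_raise_degradation(self, params):
        p = apply_intervention(params, InterventionSpec("il15_antibody", 0.5))
        assert p["kdeg_il15"] == pytest.approx(2.0 * params["kdeg_il15"])
        p = apply_intervention(params, InterventionSpec("ifng_antibody", 0.8))
        assert p["kdeg_ifng"] == pytest.approx(5.0 * params["kdeg_ifng"])
        assert p["kdeg_il21"] == pytest.approx(5.0 * params["kdeg_il21"])

    @pytest.mark.parametrize("kind", INTERVENTION_KINDS)
    def test_strength_zero_is_identity(self, params, kind):
        p = apply_intervention(params, InterventionSpec(kind, 0.0))
        assert p == params

    @pytest.mark.parametrize("kind", INTERVENTION_KINDS)
    def test_only_the_target_parameters_change(self, params, kind):
        p = apply_intervention(params, InterventionSpec(kind, 0.7))
        changed = {n for n in params if p[n] != params[n]}
        allowed = {
            "tg2_inhibitor": {"tg2_level"},
            "ifng_antibody": {"kdeg_ifng", "kdeg_il21"},
            "il15_antibody": {"kdeg_il15"},
            "permeability_inhibitor": {"k_iec_activation"},
            "dq2_blocker": {"k_apc_activation"},
        }[kind]
        assert changed == allowed

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown intervention"):
            InterventionSpec("steroid", 1.0)

    def test_strength_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="strength"):
            InterventionSpec("tg2_inhibitor", 1.5)


class TestEndpoints:
    def test_dq2_blocker_abolishes_antibodies(self, params, refs):
        obs = intervention_endpoint(
            params, InterventionSpec("dq2_blocker", 1.0), refs=refs)
        assert obs.antibody_pct == pytest.approx(0.0, abs=1e-6)

    def test_strength_zero_reproduces_untreated_state(self, params, refs):
        obs = intervention_endpoint(
            params, InterventionSpec("tg2_inhibitor", 0.0), refs=refs)
        assert obs.antibody_pct == pytest.approx(100.0, rel=1e-4)

    @pytest.mark.parametrize("kind", INTERVENTION_KINDS)
    def test_dose_response_is_monotone(self, params, refs, kind):
        """Stronger treatment: fewer antibodies, healthier villi."""
        table = dose_response(params, kind, [0.0, 0.5, 1.0], refs=refs)
        ab = table["antibody_pct"].to_numpy()
        va = table["villous_area_pct"].to_numpy()
        assert ab[0] == pytest.approx(100.0, rel=1e-4)
        assert np.all(np.diff(ab) <= 1e-6)
        assert np.all(np.diff(va) >= -1e-6)


class TestDietSwitch:
    def test_constant_protocol_stays_at_steady_state(self, params, refs):
        res = run_diet_switch(params, DietProtocol.constant("gluten"), 120,
                              refs=refs)
        ab = res.trajectory.series("Ab")
        assert np.all(np.abs(ab / refs.ref_ab - 1.0) < 1e-4)

    def test_round_trip_returns_to_gluten_steady_state(self, params, refs):
        protocol = DietProtocol([(0.0, "gluten"), (30.0, "gfd"),
                                 (400.0, "gluten")])
        res = run_diet_switch(params, protocol, 1400, refs=refs)
        scale = np.abs(refs.x_gluten) + 1e-9
        rel = np.abs(res.trajectory.final_state - refs.x_gluten) / scale
        assert rel.max() < 0.01

    def test_horizon_must_cover_switches(self, params, refs):
        with pytest.raises(ValueError, match="horizon"):
            run_diet_switch(params, DietProtocol.switch("gluten", "gfd", 50.0),
                            40, refs=refs)

    def test_switch_times_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            DietProtocol([(0.0, "gluten"), (10.0, "gfd"), (10.0, "gluten")])


class TestEc50Scan:
    def test_refit_restores_baseline_and_residual_decreases(self, params,
                                                            refs):
        from celiacqsp import PatientVariant, build_network, steady_state

        ratios = [1.0, 5.0, 40.0]
        table = ec50_ratio_scan(params, ratios, refs=refs)
        assert table["converged"].all()
        resid = table["antibody_pct"].to_numpy()
        assert np.all(np.diff(resid) <= 1e-6)
        # the re-validation restores the untreated antibody level at each ratio
        for ratio, ksab in zip(table["ratio"], table["ksab"]):
            p_r = params.with_values(
                ec50_nat=ratio * params["ec50_deam"], k_ab_syn=ksab)
            net = build_network(p_r, PatientVariant.PATIENT)
            x = steady_state(net, refs.x_gluten)
            ab = x[net.index["Ab"]]
            assert ab == pytest.approx(refs.ref_ab, rel=5e-3)

    def test_ratio_below_one_rejected(self, params):
        with pytest.raises(ValueError, match=">= 1"):
            ec50_ratio_scan(params, [0.5, 5.0])


class TestRobustness:
    def test_degenerate_boxes_reproduce_the_point_estimate(self, params,
                                                           refs):
        from celiacqsp.parameters import Parameter, ParameterSet

        frozen = ParameterSet([
            Parameter(n, params[n], params.meta(n).unit,
                      params.meta(n).source, ci_lo=params[n], ci_hi=params[n])
            for n in params
        ])
        draws = robustness_scan(frozen, InterventionSpec("tg2_inhibitor", 1.0),
                                n_draws=1, seed=7)
        point = intervention_endpoint(
            params, InterventionSpec("tg2_inhibitor", 1.0), refs=refs)
        assert draws.loc[0, "ok"]
        assert draws.loc[0, "antibody_pct"] == pytest.approx(
            point.antibody_pct, rel=1e-6)

    def test_same_seed_is_bitwise_reproducible(self, params):
        a = robustness_scan(params, InterventionSpec("il15_antibody", 1.0),
                            n_draws=3, seed=11)
        b = robustness_scan(params, InterventionSpec("il15_antibody", 1.0),
                            n_draws=3, seed=11)
        assert a.equals(b)

    def test_dq2_blocker_robust_across_draws(self, params):
        """k18 = 0 removes the only antibody-production route, whatever the
        remaining parameters are."""
        draws = robustness_scan(params, InterventionSpec("dq2_blocker", 1.0),
                                n_draws=10, seed=3)
        ok = draws[draws["ok"]]
        assert len(ok) == len(draws)
        assert (ok["antibody_pct"] < 5.0).all()
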