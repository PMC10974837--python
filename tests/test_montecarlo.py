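"""Monte Carlo procedure and sweep machinery (reduced problem sizes)."""

import numpy as np
import pytest

from dhfsim import (
    EnvState,
    NoiseSpec,
    ProbeConfig,
    SweepSpec,
    Variant,
    build_sweep_grid,
    combined_uncertainty,
    derive_channel_coefficients,
    estimate_uncertainty,
    experiment_spec,
    run_mc_trial,
    run_sweep,
)

FAST = dict(n_reps=2000, n_trials=10)


class TestTrialAndEstimate:
    @pytest.mark.parametrize("variant", [Variant.HT, Variant.TTP])
    def test_zero_noise_zero_uncertainty(self, variant, default_probe, default_env):
        res = estimate_uncertainty(variant, default_probe, default_env,
                                   NoiseSpec().zeroed(), n_reps=100, n_trials=3,
                                   seed=1)
        assert res.mu_cbt == 0.0
        assert res.su_cbt == 0.0
        assert res.nonfinite_count == 0

    def test_same_seed_identical_result(self, default_probe, default_env,
                                        default_noise):
        a = estimate_uncertainty(Variant.TTP, default_probe, default_env,
                                 default_noise, seed=7, **FAST)
        b = estimate_uncertainty(Variant.TTP, default_probe, default_env,
                                 default_noise, seed=7, **FAST)
        assert a == b

    def test_trial_requires_two_reps(self, default_probe, default_env,
                                     default_noise):
        with pytest.raises(ValueError):
            run_mc_trial(Variant.HT, default_probe, default_env, default_noise,
                         1, np.random.default_rng(0))

    def test_singular_setpoint_with_zero_noise_nonfinite(self, default_probe,
                                                         default_noise):
        sd, nonfinite = run_mc_trial(
            Variant.HT, default_probe, EnvState(cbt=37.0, t_amb=37.0),
            NoiseSpec().zeroed(), 100, np.random.default_rng(0),
        )
        assert not np.isfinite(sd)
        assert nonfinite == 100

    def test_ht_matches_closed_form_amplification(self, default_probe,
                                                  default_env):
        """With flux noise off, the HT error SD is u_T*sqrt((1+r^2)/(1-r)^2),
        r = q1/q2 (independent algebra)."""
        res = estimate_uncertainty(Variant.HT, default_probe, default_env,
                                   NoiseSpec(u_q=0.0), seed=3, **FAST)
        assert abs(res.mu_cbt - 0.2432727) <= 3 * res.su_cbt

    def test_su_shrinks_as_sqrt_reps(self, default_probe, default_env,
                                     default_noise):
        lo = estimate_uncertainty(Variant.HTP, default_probe, default_env,
                                  default_noise, n_reps=1000, n_trials=40, seed=5)
        hi = estimate_uncertainty(Variant.HTP, default_probe, default_env,
                                  default_noise, n_reps=4000, n_trials=40, seed=6)
        assert hi.su_cbt < lo.su_cbt
        assert lo.su_cbt / hi.su_cbt == pytest.approx(2.0, rel=0.30)

    def test_ambient_invariance_of_temperature_noise_only(self, default_probe,
                                                          default_noise):
        """With u_h = u_q = 0 the estimator error is ambient-independent in
        the stable region (estimates are affine in the gradient)."""
        spec = NoiseSpec(u_q=0.0, u_h=0.0)
        res = {
            t_amb: estimate_uncertainty(Variant.TT, default_probe,
                                        EnvState(37.0, t_amb), spec,
                                        seed=11, **FAST)
            for t_amb in (-15.0, 25.0)
        }
        su = max(r.su_cbt for r in res.values())
        assert abs(res[-15.0].mu_cbt - res[25.0].mu_cbt) <= 3 * su


class TestMCTaylorConsistency:
    @pytest.mark.parametrize("variant", list(Variant))
    def test_mu_close_to_first_order_budget(self, variant, default_probe,
                                            default_env, default_noise):
        """MC uncertainty tracks the first-order budget in the stable
        region.  The flux-based variants carry ~15% relative noise on
        the q_2 - q_1 denominator, whose ratio-distribution nonlinearity
        inflates the true uncertainty a few percent above first order,
        so the agreement band is 10% relative; MC never falls below the
        first-order value by more than its own repeatability."""
        res = estimate_uncertainty(variant, default_probe, default_env,
                                   default_noise, n_reps=2000, n_trials=20,
                                   seed=13)
        taylor = combined_uncertainty(variant, default_probe, default_env,
                                      default_noise).u_combined
        assert abs(res.mu_cbt - taylor) / taylor < 0.10, (res.mu_cbt, taylor)
        assert res.mu_cbt > taylor - 3 * res.su_cbt

    @pytest.mark.parametrize("variant", [Variant.TTP, Variant.TTPM])
    def test_paired_tt_variants_match_first_order_tightly(
        self, variant, default_probe, default_env, default_noise
    ):
        """The paired temperature-only variants are effectively linear at
        the defaults: MC and Taylor agree within 3 su_cbt."""
        res = estimate_uncertainty(variant, default_probe, default_env,
                                   default_noise, n_reps=2000, n_trials=20,
                                   seed=13)
        taylor = combined_uncertainty(variant, default_probe, default_env,
                                      default_noise).u_combined
        assert abs(res.mu_cbt - taylor) <= 3 * res.su_cbt, (res.mu_cbt, taylor)


class TestSweeps:
    def test_grid_validation(self):
        with pytest.raises(ValueError, match="parameter"):
            SweepSpec("humidity", (1.0, 2.0))
        with pytest.raises(ValueError, match="monotone"):
            SweepSpec("tamb", (1.0, 3.0, 2.0))

    def test_experiment_endpoints(self):
        e1 = experiment_spec("e1")
        assert e1.grid[0] == -15.0 and e1.grid[-1] == 45.0 and len(e1.grid) == 121
        e4 = experiment_spec("e4")
        assert e4.grid[0] == pytest.approx(1.25) and e4.grid[-1] == pytest.approx(10_000)
        with pytest.raises(ValueError):
            experiment_spec("e9")

    def test_hs_pair_linkage(self, default_probe, default_env):
        spec = SweepSpec("hs_pair", (0.01, 100.0))
        (p_lo, _), (p_hi, _) = build_sweep_grid(spec, default_probe, default_env)
        c_lo = derive_channel_coefficients(p_lo)
        c_hi = derive_channel_coefficients(p_hi)
        assert c_lo.h_s1 == pytest.approx(0.6667, abs=1e-3)
        assert c_hi.h_s1 == pytest.approx(6666.7, rel=1e-3)
        assert c_lo.h_s1 / c_lo.h_s2 == pytest.approx(2.0, rel=1e-12)

    def test_hs_ratio_linkage_recovers_default_probe(self, default_probe,
                                                     default_env):
        spec = SweepSpec("hs_ratio", (2.0, 10.0))
        (p2, _), (p10, _) = build_sweep_grid(spec, default_probe, default_env)
        assert p2.d_s2 == pytest.approx(0.030, rel=1e-12)  # the default probe
        c10 = derive_channel_coefficients(p10)
        assert c10.h_s1 / c10.h_s2 == pytest.approx(10.0, rel=1e-12)

    def test_sweep_cardinality_and_determinism(self, default_probe, default_env,
                                               default_noise):
        spec = SweepSpec("tamb", (5.0, 15.0, 25.0))
        kwargs = dict(n_reps=200, n_trials=3, seed=2)
        t1 = run_sweep(spec, [Variant.HT, Variant.TTP], default_probe,
                       default_env, default_noise, **kwargs)
        t2 = run_sweep(spec, [Variant.HT, Variant.TTP], default_probe,
                       default_env, default_noise, **kwargs)
        assert len(t1) == 6  # variants x grid points
        assert t1.equals(t2)

    def test_nonfinite_counted_not_dropped(self, default_probe, default_noise):
        res = estimate_uncertainty(Variant.HT, default_probe,
                                   EnvState(37.0, 37.0), NoiseSpec().zeroed(),
                                   n_reps=50, n_trials=2, seed=0)
        assert res.nonfinite_count == 100
        assert not np.isfinite(res.mu_cbt)


class TestQualitativeFindings:
    def test_instability_near_ambient_equal_cbt(self, default_probe,
                                                default_noise):
        """For the unpaired variants the uncertainty within millidegrees
        of T_amb = CBT exceeds the 25 degC value by over an order of
        magnitude (the full per-variant unstable-window check lives in
        the acceptance suite)."""
        for variant in (Variant.HT, Variant.TT):
            stable = estimate_uncertainty(variant, default_probe,
                                          EnvState(37.0, 25.0), default_noise,
                                          seed=17, **FAST)
            near = max(
                estimate_uncertainty(variant, default_probe,
                                     EnvState(37.0, t_amb), default_noise,
                                     seed=19, **FAST).mu_cbt
                for t_amb in (36.0, 36.995, 37.005)
            )
            assert near > 10 * stable.mu_cbt, variant

    def test_pairing_and_averaging_reduce_uncertainty(self, default_probe,
                                                      default_env, default_noise):
        mu = {
            v: estimate_uncertainty(v, default_probe, default_env, default_noise,
                                    seed=23, **FAST)
            for v in Variant
        }
        assert mu[Variant.HTP].mu_cbt < mu[Variant.HT].mu_cbt
        assert mu[Variant.TTP].mu_cbt < mu[Variant.TT].mu_cbt
        two_su = 2 * max(mu[Variant.HTP].su_cbt, mu[Variant.HTPM].su_cbt)
        assert mu[Variant.HTPM].mu_cbt <= mu[Variant.HTP].mu_cbt + two_su
        two_su = 2 * max(mu[Variant.TTP].su_cbt, mu[Variant.TTPM].su_cbt)
        assert mu[Variant.TTPM].mu_cbt <= mu[Variant.TTP].mu_cbt + two_su
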