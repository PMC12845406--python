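"""FOCE-I estimation: objective correctness, EBEs, and fitting."""

import numpy as np
import pandas as pd
import pytest

from cyclopk import (
    CohortConfig,
    FixedEffects,
    RandomEffectsSpec,
    TdmDataset,
    estimate_ebes,
    fit,
    foce_i_ofv,
    generate_cohort,
)
from cyclopk.estimation import FoceProblem, ModelStructure

ONE_ETA = ModelStructure(iiv_cl=True, iiv_v=False, corr_clv=False, iov_cl=False)


def one_eta_spec(om2, sig):
    return RandomEffectsSpec(
        omega2_cl=om2, omega2_v=0.0, omega_clv=0.0, pi2_iov=0.0, sigma_prop=sig
    )


class TestObjectiveFunction:
    def test_fixed_effects_only_closed_form(self, toy_dataset_factory, final_fixed):
        # no random effects: the contribution is the proportional-error
        # normal log-density of the single observation
        import cyclopk

        sig = 0.25
        re = one_eta_spec(1e-12, sig)  # variance -> 0 limit
        ds = toy_dataset_factory([(2.0, 900.0)])
        ofv = foce_i_ofv(ds, final_fixed, re, structure=ONE_ETA)
        reg = cyclopk.DosingRegimen(100.0, 12.0)
        f = cyclopk.conc_ss(reg, 2.0, 15.0, 71.1, final_fixed.ka)
        expected = (
            np.log(sig**2 * f**2) + (900.0 - f) ** 2 / (sig**2 * f**2)
            + np.log(2 * np.pi)
        )
        assert ofv == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("om2", [0.01, 0.1, 0.5])
    @pytest.mark.parametrize("sig", [0.1, 0.3])
    def test_against_quadrature_oracle(
        self, toy_dataset_factory, quadrature_oracle, final_fixed, om2, sig
    ):
        # FOCE-I within 2% of the exact marginal -2LL on 1-eta subjects
        rng = np.random.default_rng(hash((om2, int(sig * 10))) % 2**31)
        import cyclopk

        re = one_eta_spec(om2, sig)
        eta = rng.normal(0, np.sqrt(om2))
        reg = cyclopk.DosingRegimen(100.0, 12.0)
        cl = cyclopk.individual_clearance(final_fixed, 40.0, 120.0, eta, 0.0)
        v = cyclopk.individual_volume(final_fixed, 40.0, 0.0)
        obs = [
            (t, cyclopk.conc_ss(reg, t, cl, v, final_fixed.ka) * (1 + rng.normal(0, sig)))
            for t in (0.0, 2.0)
        ]
        ds = toy_dataset_factory(obs)
        foce = foce_i_ofv(ds, final_fixed, re, structure=ONE_ETA)
        exact = quadrature_oracle(ds, final_fixed, re)
        assert foce == pytest.approx(exact, rel=0.02)

    def test_subject_order_invariance(self, final_fixed, final_random, default_cohort):
        ds = default_cohort
        ofv = foce_i_ofv(ds, final_fixed, final_random)
        # reverse subject blocks
        order = list(ds.subjects)[::-1]
        df = pd.concat(
            [ds.df[ds.df["ID"] == sid] for sid in order], ignore_index=True
        )
        ofv_perm = foce_i_ofv(TdmDataset(df), final_fixed, final_random)
        assert ofv_perm == ofv  # bit-identical (contributions sorted before summing)

    def test_scale_equivariance_of_proportional_model(
        self, final_fixed, final_random, small_cohort
    ):
        # doubling DV and dose leaves etas unchanged and adds 2*N*ln(2)
        ds = small_cohort
        prob = FoceProblem(ds)
        ofv, eta = prob.evaluate(final_fixed, final_random)
        df = ds.df.copy()
        df["DV"] = df["DV"] * 2.0
        df["AMT"] = df["AMT"] * 2.0
        ds2 = TdmDataset(df, tau_h=ds.tau_h)
        prob2 = FoceProblem(ds2)
        ofv2, eta2 = prob2.evaluate(final_fixed, final_random)
        n = ds.n_observations
        assert ofv2 == pytest.approx(ofv + 2 * n * np.log(2.0), abs=1e-5)
        assert np.allclose(eta, eta2, atol=1e-6)


class TestEbes:
    def test_variances_to_zero_shrinks_etas(self, toy_dataset_factory, final_fixed):
        ds = toy_dataset_factory([(0.0, 150.0), (2.0, 1100.0)])
        re = one_eta_spec(1e-10, 0.25)
        e = estimate_ebes(ds, final_fixed, re, structure=ONE_ETA)
        assert abs(e.eta_cl) < 1e-5

    def test_exact_data_gives_zero_etas(self, toy_dataset_factory, final_fixed):
        import cyclopk

        reg = cyclopk.DosingRegimen(100.0, 12.0)
        obs = [(t, cyclopk.conc_ss(reg, t, 15.0, 71.1, 1.15)) for t in (0.0, 2.0)]
        ds = toy_dataset_factory(obs)
        re = RandomEffectsSpec(
            omega2_cl=0.1, omega2_v=0.1, omega_clv=0.0, pi2_iov=0.0, sigma_prop=1e-4
        )
        e = estimate_ebes(ds, final_fixed, re)
        assert abs(e.eta_cl) < 1e-4 and abs(e.eta_v) < 1e-4

    def test_mode_matches_grid_search(self, toy_dataset_factory, final_fixed):
        # dense 2-d grid oracle for the conditional objective
        import cyclopk

        ds = toy_dataset_factory([(0.0, 210.0), (2.0, 820.0)])
        re = RandomEffectsSpec(
            omega2_cl=0.15, omega2_v=0.2, omega_clv=0.05, pi2_iov=0.0, sigma_prop=0.2
        )
        e = estimate_ebes(ds, final_fixed, re)
        obs = ds.observation_frame()
        y = obs["DV"].to_numpy()
        tad = obs["TAD"].to_numpy()
        reg = cyclopk.DosingRegimen(100.0, 12.0)
        oinv = np.linalg.inv(re.iiv_matrix())

        def g(ec, ev):
            cl = 15.0 * np.exp(ec)
            v = 71.1 * np.exp(ev)
            f = np.array([cyclopk.conc_ss(reg, t, cl, v, 1.15) for t in tad])
            s2 = (re.sigma_prop * f) ** 2
            eta = np.array([ec, ev])
            return np.sum(np.log(s2) + (y - f) ** 2 / s2) + eta @ oinv @ eta

        grid = np.arange(-1.0, 1.0, 1e-3)
        best = min(
            ((g(ec, ev), ec, ev) for ec in grid for ev in grid[::20]), key=lambda z: z[0]
        )
        # refine around the coarse-ev winner
        ev_grid = np.arange(best[2] - 0.05, best[2] + 0.05, 1e-3)
        best = min(
            ((g(ec, ev), ec, ev) for ec in grid for ev in ev_grid), key=lambda z: z[0]
        )
        assert e.eta_cl == pytest.approx(best[1], abs=2e-3)
        assert e.eta_v == pytest.approx(best[2], abs=2e-3)


class TestFit:
    def test_self_consistency_noise_free(self, toy_dataset_factory, final_fixed):
        # data generated exactly at the typical prediction with all
        # variances ~0: refitting recovers the generating typical values
        import cyclopk

        frames = []
        for sid, wt in enumerate([20.0, 30.0, 40.0, 55.0, 70.0], start=1):
            reg = cyclopk.DosingRegimen(2.5 * wt, 12.0)
            cl = cyclopk.individual_clearance(final_fixed, wt, 120.0)
            v = cyclopk.individual_volume(final_fixed, wt)
            obs = [
                (t, cyclopk.conc_ss(reg, t, cl, v, 1.15)) for t in (0.0, 2.0)
            ]
            frames.append(
                toy_dataset_factory(obs, wt=wt, amt=2.5 * wt, sid=sid).df
            )
        ds = TdmDataset(pd.concat(frames, ignore_index=True))
        init_fe = FixedEffects(theta_cl=10.0, theta_v=50.0, theta_all=0.7, theta_hgb=0.0)
        init_re = RandomEffectsSpec(
            omega2_cl=1e-8, omega2_v=1e-8, omega_clv=0.0, pi2_iov=0.0, sigma_prop=0.05
        )
        res = fit(
            ds, init_fe, init_re,
            fixed_params={"ka", "theta_v_exp", "theta_hgb", "omega2_cl", "omega2_v",
                          "omega_clv", "pi2_iov"},
        )
        assert res.converged
        assert res.fixed.theta_cl == pytest.approx(15.0, rel=1e-2)
        assert res.fixed.theta_v == pytest.approx(71.1, rel=1e-2)
        assert res.fixed.theta_all == pytest.approx(0.89, abs=0.02)

    def test_refit_from_estimates_does_not_increase_ofv(
        self, small_cohort, final_fixed, final_random
    ):
        res = fit(small_cohort, final_fixed, final_random, maxiter=60, ftol=1e-8)
        res2 = fit(small_cohort, res.fixed, res.random, maxiter=60, ftol=1e-8)
        assert res2.ofv <= res.ofv + 0.05

    def test_row_and_subject_relabel_invariance(
        self, small_cohort, final_fixed, final_random
    ):
        res = fit(small_cohort, final_fixed, final_random, maxiter=40, ftol=1e-7)
        df = small_cohort.df.copy()
        df["ID"] = df["ID"].map({sid: 100 - sid for sid in small_cohort.subjects})
        df = pd.concat(
            [df[df["ID"] == sid] for sid in sorted(df["ID"].unique())],
            ignore_index=True,
        )
        res2 = fit(TdmDataset(df), final_fixed, final_random, maxiter=40, ftol=1e-7)
        assert res2.ofv == pytest.approx(res.ofv, abs=1e-3)
        assert res2.fixed.theta_cl == pytest.approx(res.fixed.theta_cl, rel=1e-4)

    def test_ofv_trace_progress(self, small_cohort, final_fixed, final_random):
        init_fe = FixedEffects(theta_cl=11.0, theta_v=60.0, theta_all=0.7,
                               theta_hgb=0.0)
        res = fit(small_cohort, init_fe, final_random, maxiter=60, ftol=1e-8)
        assert res.converged
        # the running best of the trace is non-increasing and ends at res.ofv
        best = np.minimum.accumulate(res.ofv_trace)
        assert best[-1] <= best[0]
        assert res.ofv == pytest.approx(best[-1], abs=1e-3)
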