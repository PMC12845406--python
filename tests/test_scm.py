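"""Stepwise covariate modelling: LRT, relevance, correlation screening."""

import numpy as np
import pytest

from cyclopk import (
    CohortConfig,
    FixedEffects,
    RandomEffectsSpec,
    clinical_relevance,
    covariate_correlations,
    generate_cohort,
    lrt_pvalue,
    run_scm,
)
from cyclopk.scm import CovariateCandidate

NO_HGB_FIXED = frozenset({"ka", "theta_v_exp", "theta_hgb"})


class TestLrt:
    @pytest.mark.parametrize(
        "dofv,df,p",
        [(3.84, 1, 0.0500), (6.63, 1, 0.0100), (0.0, 1, 1.0)],
    )
    def test_chi2_reference(self, dofv, df, p):
        assert lrt_pvalue(dofv, df) == pytest.approx(p, abs=5e-4)

    def test_negative_delta_gives_one(self):
        assert lrt_pvalue(-5.0, 1) == 1.0

    def test_df_validated(self):
        with pytest.raises(ValueError):
            lrt_pvalue(3.0, 0)


class TestClinicalRelevance:
    def test_hgb_effect_magnitude(self):
        # the linear haemoglobin effect spans 22.45% of CL/F over 73-164 g/L
        eff = CovariateCandidate("HGB", "CL", "linear", 120.0, theta=-0.00279)
        assert clinical_relevance(eff, (73.0, 164.0)) == pytest.approx(22.45, abs=0.01)

    def test_zero_coefficient(self):
        eff = CovariateCandidate("HGB", "CL", "linear", 120.0, theta=0.0)
        assert clinical_relevance(eff, (73.0, 164.0)) == 0.0

    def test_collapsed_range(self):
        eff = CovariateCandidate("HGB", "CL", "linear", 120.0, theta=-0.00279)
        assert clinical_relevance(eff, (100.0, 100.0)) == 0.0

    def test_swap_invariance(self):
        eff = CovariateCandidate("WT", "CL", "power", 40.0, theta=0.75)
        assert clinical_relevance(eff, (10.0, 100.0)) == pytest.approx(
            clinical_relevance(eff, (100.0, 10.0))
        )


class TestCovariateCorrelations:
    def test_functional_dependence_flagged(self, default_cohort):
        # CLCR is computed from HT/CREAT, so |r(CLCR, CREAT)| must flag high
        mat, flagged = covariate_correlations(
            default_cohort, ["WT", "HT", "CREAT", "CLCR", "HGB"], flag_threshold=0.6
        )
        assert mat.loc["CLCR", "CLCR"] == 1.0
        pairs = {frozenset((a, b)) for a, b, _ in flagged}
        assert frozenset(("CREAT", "CLCR")) in pairs
        assert frozenset(("WT", "HT")) in pairs

    def test_independent_covariates_uncorrelated(self):
        ds = generate_cohort(
            CohortConfig(n_subjects=5000, seed=13, sampling_days_mean=1.0,
                         sampling_days_range=(1, 1))
        )
        mat, _ = covariate_correlations(ds, ["CREAT", "HGB"])
        assert abs(mat.loc["CREAT", "HGB"]) < 0.05

    def test_constant_covariate_undefined(self, default_cohort):
        ds = default_cohort.copy()
        ds.df["TRANS"] = 1
        mat, _ = covariate_correlations(ds, ["WT", "TRANS"])
        assert np.isnan(mat.loc["WT", "TRANS"])


@pytest.fixture(scope="module")
def scm_cohort(final_fixed, final_random):
    return generate_cohort(
        CohortConfig(n_subjects=24, seed=21, sampling_days_mean=6.0),
        final_fixed, final_random,
    )


class TestRunScm:
    def test_empty_candidate_list(self, scm_cohort, final_random):
        res = run_scm(
            scm_cohort, FixedEffects(theta_hgb=0.0), final_random, [],
            fixed_params=NO_HGB_FIXED, fit_kwargs=dict(ftol=1e-7, maxiter=80),
        )
        assert res.included == []
        assert res.trace.steps == []
        assert res.final.ofv == res.base.ofv

    def test_single_candidate_reduces_to_lrt(self, scm_cohort, final_random):
        cand = CovariateCandidate("HGB", "CL", "linear", 120.0)
        res = run_scm(
            scm_cohort, FixedEffects(theta_hgb=0.0), final_random, [cand],
            forward_alpha=0.01, backward_alpha=0.01,
            fixed_params=NO_HGB_FIXED, fit_kwargs=dict(ftol=1e-7, maxiter=80),
        )
        fwd = [s for s in res.trace.steps if s.phase == "forward"]
        assert len(fwd) == 1
        # decision consistent with a plain likelihood-ratio test at alpha
        assert fwd[0].accepted == (fwd[0].p_value < 0.01)
        assert res.final.ofv <= res.base.ofv + 1e-6

    def test_final_never_worse_than_base(self, scm_cohort, final_random):
        cands = [
            CovariateCandidate("HGB", "CL", "linear", 120.0),
            CovariateCandidate("GEND", "CL", "categorical"),
        ]
        res = run_scm(
            scm_cohort, FixedEffects(theta_hgb=0.0), final_random, cands,
            fixed_params=NO_HGB_FIXED, fit_kwargs=dict(ftol=1e-7, maxiter=80),
        )
        assert res.final.ofv <= res.base.ofv + 1e-6
        # every forward acceptance satisfied the threshold
        for s in res.trace.steps:
            if s.phase == "forward" and s.accepted:
                assert s.p_value < 0.05

    def test_missing_covariate_subjects_excluded(self, scm_cohort, final_random):
        ds = scm_cohort.copy()
        # knock a 'genotype-like' covariate out for half the subjects
        half = list(ds.subjects)[::2]
        ds.df.loc[ds.df["ID"].isin(half), "TRANS"] = np.nan
        cand = CovariateCandidate("TRANS", "CL", "categorical")
        res = run_scm(
            ds, FixedEffects(theta_hgb=0.0), final_random, [cand],
            fixed_params=NO_HGB_FIXED, fit_kwargs=dict(ftol=1e-7, maxiter=80),
        )
        fwd = [s for s in res.trace.steps if s.candidate == "TRANS:CL"]
        assert fwd and "subset" in fwd[0].note
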