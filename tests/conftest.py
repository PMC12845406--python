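"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own computational paths:
the multi-dose superposition sums single-dose profiles, and the marginal
likelihood oracle integrates by adaptive Gauss-Hermite quadrature over a
scalar random effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from cyclopk import (
    CohortConfig,
    DosingRegimen,
    FixedEffects,
    RandomEffectsSpec,
    TdmDataset,
    conc_ss,
    generate_cohort,
    individual_clearance,
    individual_volume,
)


@pytest.fixture(scope="session")
def final_fixed() -> FixedEffects:
    """The final-model typical values (the package defaults)."""
    return FixedEffects()


@pytest.fixture(scope="session")
def final_random() -> RandomEffectsSpec:
    return RandomEffectsSpec()


@pytest.fixture(scope="session")
def default_cohort(final_fixed, final_random) -> TdmDataset:
    """One seeded full-size synthetic cohort, shared across tests."""
    return generate_cohort(CohortConfig(seed=1), final_fixed, final_random)


@pytest.fixture(scope="session")
def small_cohort(final_fixed, final_random) -> TdmDataset:
    return generate_cohort(
        CohortConfig(n_subjects=10, seed=7, sampling_days_mean=5.0),
        final_fixed,
        final_random,
    )


def _row(sid, time, evid, amt, dv, styp, occ, day, wt, hgb):
    return dict(
        ID=sid, TIME=time, EVID=evid, MDV=1 - evid if evid == 0 else 1,
        AMT=amt, DV=dv, STYP=styp, OCC=occ, DAY=day, PDAY=day,
        WT=wt, HGB=hgb, HT=140.0, CREAT=87.0, CLCR=55.0, AGE=12,
        GEND=1, TRANS=0,
    )


def make_toy_dataset(obs, wt=40.0, hgb=120.0, amt=100.0, sid=1, day=1):
    """Single-subject steady-state dataset: obs = [(t_after_dose, dv), ...]."""
    t0 = day * 24.0
    rows = [_row(sid, t0, 1, amt, np.nan, "dose", 1, day, wt, hgb)]
    for t, y in obs:
        rows.append(
            _row(sid, t0 + t, 0, np.nan, y, "C0" if t == 0 else "C2", 1, day, wt, hgb)
        )
    return TdmDataset(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def toy_dataset_factory():
    return make_toy_dataset


def superposition_conc(dose_mg, tau_h, t, cl, v, ka, n_doses=300):
    """Multi-dose trough-to-trough concentration by explicit superposition
    of single oral doses (the steady-state oracle)."""
    k = cl / v
    total = 0.0
    for j in range(n_doses):
        tj = t + j * tau_h  # time since the j-th previous dose
        total += (
            1000.0 * dose_mg * ka / (v * (ka - k)) * (np.exp(-k * tj) - np.exp(-ka * tj))
        )
    return total


@pytest.fixture(scope="session")
def superposition_oracle():
    return superposition_conc


def gh_marginal_m2ll(ds, fe, re, n_nodes=64):
    """Exact -2 log marginal likelihood for a single-subject dataset with
    one random effect on CL, by adaptive Gauss-Hermite quadrature."""
    obs = ds.observation_frame()
    y = obs["DV"].to_numpy(dtype=float)
    tad = obs["TAD"].to_numpy(dtype=float)
    dose = obs["DOSE_MG"].to_numpy(dtype=float)
    wt = float(obs["WT"].iloc[0])
    hgb = float(obs["HGB"].iloc[0])
    om2, sig = re.omega2_cl, re.sigma_prop
    reg = DosingRegimen(float(dose[0]), ds.tau_h)
    v = individual_volume(fe, wt, 0.0)

    def nlp(eta):
        cl = individual_clearance(fe, wt, hgb, eta, 0.0)
        f = np.array([conc_ss(reg, t, cl, v, fe.ka) for t in tad])
        s2 = (sig * f) ** 2
        return 0.5 * np.sum(np.log(2 * np.pi * s2) + (y - f) ** 2 / s2) + 0.5 * (
            eta**2 / om2 + np.log(2 * np.pi * om2)
        )

    r = minimize_scalar(nlp, bounds=(-6, 6), method="bounded", options={"xatol": 1e-11})
    mode = r.x
    h = 1e-5
    d2 = (nlp(mode + h) - 2 * nlp(mode) + nlp(mode - h)) / h**2
    s = 1.0 / np.sqrt(max(d2, 1e-12))
    xg, wg = np.polynomial.hermite_e.hermegauss(n_nodes)
    vals = np.array([np.exp(-nlp(mode + s * x) + 0.5 * x**2) for x in xg])
    return -2.0 * np.log(s * np.sum(wg * vals))


@pytest.fixture(scope="session")
def quadrature_oracle():
    return gh_marginal_m2ll
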