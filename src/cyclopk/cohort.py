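"""Synthetic TDM cohort generator.

Emulates the study design that produced the clinical dataset: 58
paediatric/young-adult renal transplant recipients on cyclosporin A at
5 mg/kg/day divided BID, with paired trough (C0, pre-dose) and 2 h
post-dose (C2) samples drawn at steady state on repeated sampling days
over the first post-transplant year.  Every sampling day is a separate
occasion; haemoglobin evolves within subject across occasions as a
stationary AR(1) process.  Covariate distributions match the published
cohort summaries (weight median 39.65 kg spanning 9.8-103 kg, haemoglobin
118.33 +/- 14.99 g/L over 73-164 g/L, and height/creatinine to scale).

The generator draws "true" concentrations from the structural model with
etas/kappas sampled from a :class:`~cyclopk.model.RandomEffectsSpec` and
multiplies by (1 + eps) proportional residual noise.  It emulates the
sampling design only: no dose titration toward target ranges, no assay
censoring, no dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import COLUMNS, TdmDataset
from .model import DosingRegimen, FixedEffects, RandomEffectsSpec, conc_ss

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "assign_occasions",
    "schwartz_clcr",
    "simulate_dv",
]

# creatinine umol/L per mg/dL
_CREAT_UMOL_PER_MGDL = 88.4

# sampling-day allocation over post-transplant periods (days <=30, 31-90, >90),
# proportional to the published per-period observation counts 132:229:611
_PERIOD_PROBS = (0.1355, 0.2351, 0.6294)
_PERIOD_BOUNDS = ((1, 30), (31, 90), (91, 365))


def schwartz_clcr(ht_cm: float | np.ndarray, creat_umolL: float | np.ndarray) -> float | np.ndarray:
    """Bedside (revised) Schwartz creatinine clearance, mL/min/1.73 m^2.

    ``CLCR = 0.413 * height / serum creatinine`` with creatinine in mg/dL;
    the input is in umol/L (the cohort's laboratory units) and is converted
    by dividing by 88.4.
    """
    ht = np.asarray(ht_cm, dtype=float)
    cr = np.asarray(creat_umolL, dtype=float)
    if np.any(ht <= 0) or np.any(cr <= 0):
        raise ValueError("height and creatinine must be positive")
    out = 0.413 * ht / (cr / _CREAT_UMOL_PER_MGDL)
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort.

    Defaults are the study conditions; ``seed`` fully determines the output.
    ``sampling_days_mean`` is the mean number of sampling days per subject
    (each contributing a C0/C2 pair with probability ``p_paired``, else a
    single sample), chosen so the default cohort lands near 974 observations
    with a C0:C2 split near 471:501.
    """

    n_subjects: int = 58
    seed: int = 0
    # weight: log-normal, median 39.65 kg, truncated to the observed range
    wt_median: float = 39.65
    wt_sigma_log: float = 0.5
    wt_range: tuple[float, float] = (9.8, 103.0)
    # haemoglobin: normal cross-section, AR(1) within subject across occasions
    hgb_mean: float = 118.33
    hgb_sd: float = 14.99
    hgb_range: tuple[float, float] = (73.0, 164.0)
    hgb_ar1: float = 0.8
    # height / creatinine marginals (height co-varies with weight)
    ht_mean: float = 137.21
    ht_sd: float = 25.20
    ht_range: tuple[float, float] = (78.0, 185.0)
    creat_median: float = 87.0
    creat_sigma_log: float = 0.55
    creat_range: tuple[float, float] = (28.0, 696.0)
    # dosing and sampling design
    daily_dose_mg_per_kg: float = 5.0
    n_daily_doses: int = 2
    dose_rounding_mg: float = 5.0
    sampling_days_mean: float = 9.3
    sampling_days_range: tuple[int, int] = (3, 33)
    p_paired: float = 0.8
    p_c2_if_single: float = 0.6
    c2_time_h: float = 2.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.sampling_days_mean <= 0 or self.sampling_days_range[0] < 1:
            raise ValueError("infeasible sampling-day configuration")
        if not 0.0 <= self.p_paired <= 1.0:
            raise ValueError("p_paired must be a probability")
        if self.n_daily_doses < 1 or self.daily_dose_mg_per_kg < 0:
            raise ValueError("infeasible dosing rule")

    @property
    def tau_h(self) -> float:
        return 24.0 / self.n_daily_doses


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (vectorised, bounded retries)."""
    x = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(x, lo, hi)


def _sample_covariates(cfg: CohortConfig, rng) -> pd.DataFrame:
    n = cfg.n_subjects
    lo, hi = np.log(cfg.wt_range[0]), np.log(cfg.wt_range[1])
    lwt = _truncated_normal(rng, np.log(cfg.wt_median), cfg.wt_sigma_log, lo, hi, n)
    wt = np.exp(lwt)
    # height rides on log-weight (r ~ 0.9) with the published marginal moments
    slope = 0.9 * cfg.ht_sd / cfg.wt_sigma_log
    ht = (
        cfg.ht_mean
        + slope * (lwt - np.log(cfg.wt_median))
        + rng.normal(0.0, cfg.ht_sd * np.sqrt(1 - 0.9**2), n)
    )
    ht = np.clip(ht, *cfg.ht_range)
    creat = np.exp(
        _truncated_normal(
            rng,
            np.log(cfg.creat_median),
            cfg.creat_sigma_log,
            np.log(cfg.creat_range[0]),
            np.log(cfg.creat_range[1]),
            n,
        )
    )
    age = np.clip(np.round(4.0 + 18.0 * (wt - 9.8) / (103.0 - 9.8) + rng.normal(0, 2.5, n)), 1, 25)
    return pd.DataFrame(
        {
            "WT": wt,
            "HT": ht,
            "CREAT": creat,
            "CLCR": schwartz_clcr(ht, creat),
            "AGE": age,
            "GEND": (rng.random(n) < 0.586).astype(int),
            "TRANS": (rng.random(n) < 30 / 58).astype(int),
        }
    )


def _sample_days(cfg: CohortConfig, rng) -> np.ndarray:
    """Distinct post-transplant sampling days for one subject, sorted."""
    lo, hi = cfg.sampling_days_range
    n_days = int(np.clip(rng.poisson(cfg.sampling_days_mean), lo, hi))
    days: set[int] = set()
    while len(days) < n_days:
        period = rng.choice(3, p=_PERIOD_PROBS)
        a, b = _PERIOD_BOUNDS[period]
        days.add(int(rng.integers(a, b + 1)))
    return np.array(sorted(days))


def _hgb_series(cfg: CohortConfig, rng, n_occ: int) -> np.ndarray:
    """Stationary AR(1) haemoglobin trajectory across occasions."""
    rho = cfg.hgb_ar1
    x = np.empty(n_occ)
    x[0] = rng.normal(cfg.hgb_mean, cfg.hgb_sd)
    innov_sd = cfg.hgb_sd * np.sqrt(1.0 - rho**2)
    for i in range(1, n_occ):
        x[i] = cfg.hgb_mean + rho * (x[i - 1] - cfg.hgb_mean) + rng.normal(0.0, innov_sd)
    return np.clip(x, *cfg.hgb_range)


def pday_period(pday: int) -> int:
    """Post-transplant period label: 1 (<=30 d), 2 (31-90 d), 3 (>90 d)."""
    if pday <= 30:
        return 1
    return 2 if pday <= 90 else 3


def generate_cohort(
    cfg: CohortConfig,
    fe: FixedEffects | None = None,
    re: RandomEffectsSpec | None = None,
) -> TdmDataset:
    """Generate a synthetic steady-state TDM dataset.

    One dose event (the morning maintenance dose) and the day's samples are
    written per sampling day; concentrations are steady-state predictions
    from ``fe`` with random effects drawn from ``re`` and proportional
    residual noise.  The same config and seed always produce the same
    dataset.
    """
    fe = fe or FixedEffects()
    re = re or RandomEffectsSpec()
    rng = np.random.default_rng(cfg.seed)
    cov = _sample_covariates(cfg, rng)
    etas = rng.multivariate_normal(np.zeros(2), re.iiv_matrix(), size=cfg.n_subjects)
    tau = cfg.tau_h
    per_admin = cfg.daily_dose_mg_per_kg / cfg.n_daily_doses

    rows: list[dict] = []
    for i in range(cfg.n_subjects):
        sid = i + 1
        wt = cov.at[i, "WT"]
        amt = max(cfg.dose_rounding_mg, np.round(per_admin * wt / cfg.dose_rounding_mg) * cfg.dose_rounding_mg)
        days = _sample_days(cfg, rng)
        hgb = _hgb_series(cfg, rng, len(days))
        kappas = rng.normal(0.0, np.sqrt(re.pi2_iov), len(days))
        v_i = fe.theta_v * (wt / fe.wt_ref) ** fe.theta_v_exp * np.exp(etas[i, 1])
        reg = DosingRegimen(dose_mg=amt, tau_h=tau)
        base = dict(
            ID=sid, WT=wt, HT=cov.at[i, "HT"], CREAT=cov.at[i, "CREAT"],
            CLCR=cov.at[i, "CLCR"], AGE=cov.at[i, "AGE"],
            GEND=int(cov.at[i, "GEND"]), TRANS=int(cov.at[i, "TRANS"]),
        )
        for occ, (day, h, kap) in enumerate(zip(days, hgb, kappas), start=1):
            t0 = float(day) * 24.0
            cl_io = (
                fe.theta_cl
                * (wt / fe.wt_ref) ** fe.theta_all
                * fe.hgb_factor(h)
                * np.exp(etas[i, 0] + kap)
            )
            common = dict(base, OCC=occ, DAY=int(day), PDAY=int(day), HGB=h)
            rows.append(
                dict(common, TIME=t0, EVID=1, MDV=1, AMT=amt, DV=np.nan, STYP="dose")
            )
            u = rng.random()
            take_c0 = u < cfg.p_paired or (u - cfg.p_paired) / (1 - cfg.p_paired + 1e-12) >= cfg.p_c2_if_single
            take_c2 = u < cfg.p_paired or not take_c0
            for take, t_off, styp in ((take_c0, 0.0, "C0"), (take_c2, cfg.c2_time_h, "C2")):
                if not take:
                    continue
                true = conc_ss(reg, t_off, cl_io, v_i, fe.ka)
                dv = true * max(1e-6, 1.0 + rng.normal(0.0, re.sigma_prop))
                rows.append(
                    dict(common, TIME=t0 + t_off, EVID=0, MDV=0, AMT=np.nan, DV=dv, STYP=styp)
                )
    df = pd.DataFrame(rows)[COLUMNS]
    df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    return TdmDataset(df, tau_h=tau, name=f"synthetic(seed={cfg.seed})")


def simulate_dv(
    ds: TdmDataset,
    fe: FixedEffects,
    re: RandomEffectsSpec,
    seed: int,
) -> TdmDataset:
    """Redraw the observations of an existing design from the model.

    Keeps every dose event, sampling time, occasion and covariate of
    ``ds`` and replaces the DV column with fresh simulated concentrations:
    new etas per subject, new kappas per occasion, new proportional
    residuals.  This is the simulation step used by the VPC and by
    operating-characteristic experiments.
    """
    rng = np.random.default_rng(seed)
    df = ds.df.copy()
    obs_frame = ds.observation_frame()
    new_dv = np.empty(len(obs_frame))
    pos = 0
    for sid, sub in obs_frame.groupby("ID", sort=False):
        eta = rng.multivariate_normal(np.zeros(2), re.iiv_matrix())
        occs = np.sort(sub["OCC"].unique())
        kap = dict(zip(occs, rng.normal(0.0, np.sqrt(re.pi2_iov), len(occs))))
        wt = sub["WT"].to_numpy(dtype=float)
        v_i = fe.theta_v * (wt / fe.wt_ref) ** fe.theta_v_exp * np.exp(eta[1])
        cl_io = (
            fe.theta_cl
            * (wt / fe.wt_ref) ** fe.theta_all
            * fe.hgb_factor(sub["HGB"].to_numpy(dtype=float))
            * np.exp(eta[0] + np.array([kap[o] for o in sub["OCC"]]))
        )
        k = cl_io / v_i
        tad = sub["TAD"].to_numpy(dtype=float)
        dose = sub["DOSE_MG"].to_numpy(dtype=float)
        ka, tau = fe.ka, ds.tau_h
        true = (
            1000.0 * dose * ka / (v_i * (ka - k))
            * (
                np.exp(-k * tad) / (1.0 - np.exp(-k * tau))
                - np.exp(-ka * tad) / (1.0 - np.exp(-ka * tau))
            )
        )
        eps = rng.normal(0.0, re.sigma_prop, len(true))
        new_dv[pos : pos + len(true)] = true * np.maximum(1e-6, 1.0 + eps)
        pos += len(true)
    df.loc[obs_frame["index"].to_numpy(), "DV"] = new_dv
    return TdmDataset(df, tau_h=ds.tau_h, name=f"{ds.name}|sim(seed={seed})")


def assign_occasions(ds: TdmDataset) -> TdmDataset:
    """Re-derive occasion ids: one occasion per sampling day, densely indexed.

    Occasions increment at each new day carrying at least one observation;
    dose-only days inherit the occasion currently in force.  Idempotent.
    """
    df = ds.df.copy()
    occ = np.ones(len(df), dtype=int)
    for _, idx in df.groupby("ID", sort=False).groups.items():
        sub = df.loc[idx]
        obs_days = np.sort(sub.loc[sub["EVID"] == 0, "DAY"].unique())
        day_to_occ = {d: j + 1 for j, d in enumerate(obs_days)}
        cur = 1
        vals = []
        for d in sub["DAY"]:
            if d in day_to_occ:
                cur = day_to_occ[d]
            vals.append(cur)
        occ[df.index.get_indexer(idx)] = vals
    df["OCC"] = occ
    return TdmDataset(df, tau_h=ds.tau_h, name=ds.name)
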