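"""Stepwise covariate modelling (SCM).

Forward inclusion / backward elimination of covariate-parameter relations
by likelihood-ratio testing on the FOCE-I objective: forward additions
require p < 0.05, backward retention requires that removal worsens the
fit at p < 0.01 (1 df per candidate coefficient; the chi-square reference
is the standard convention for nested NLME models).  A correlation screen
over the continuous covariates supports plausibility review of the
selected path, and a clinical-relevance measure quantifies each effect as
the percent change in the parameter over the covariate's observed range
(the conventional 20% threshold decides practical importance).

Subjects missing a candidate's covariate (e.g. genotypes typed in only a
subset) are excluded from that candidate's test only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import TdmDataset
from .estimation import DEFAULT_FIXED, EstimationResult, fit
from .model import CovariateEffect, FixedEffects, RandomEffectsSpec

__all__ = [
    "CovariateCandidate",
    "ScmTrace",
    "ScmResult",
    "lrt_pvalue",
    "run_scm",
    "covariate_correlations",
    "clinical_relevance",
]

# the SCM candidate unit is the generic covariate effect
CovariateCandidate = CovariateEffect


@dataclass
class ScmStep:
    phase: str  # "forward" | "backward"
    candidate: str
    delta_ofv: float
    df: int
    p_value: float
    accepted: bool
    note: str = ""


@dataclass
class ScmTrace:
    steps: list[ScmStep] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(step=i + 1, phase=s.phase, candidate=s.candidate,
                     dOFV=s.delta_ofv, df=s.df, p=s.p_value,
                     accepted=s.accepted, note=s.note)
                for i, s in enumerate(self.steps)
            ]
        )


@dataclass
class ScmResult:
    included: list[CovariateCandidate]
    final: EstimationResult
    base: EstimationResult
    trace: ScmTrace


def lrt_pvalue(delta_ofv: float, df: int = 1) -> float:
    """Upper-tail chi-square probability of a (non-negative) OFV drop."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(max(delta_ofv, 0.0), df))


def _subset_with_covariate(ds: TdmDataset, column: str) -> tuple[TdmDataset, int]:
    """Drop subjects with entirely missing values for ``column``."""
    if column not in ds.df.columns:
        raise KeyError(f"unknown covariate column {column!r}")
    good = [
        sid
        for sid, sub in ds.df.groupby("ID", sort=False)
        if sub[column].notna().any()
    ]
    n_dropped = ds.n_subjects - len(good)
    if n_dropped == 0:
        return ds, 0
    sub = ds.df[ds.df["ID"].isin(good)].copy()
    return TdmDataset(sub, tau_h=ds.tau_h, name=ds.name), n_dropped


def run_scm(
    ds: TdmDataset,
    init_fixed: FixedEffects,
    init_random: RandomEffectsSpec,
    candidates: list[CovariateCandidate],
    forward_alpha: float = 0.05,
    backward_alpha: float = 0.01,
    fixed_params: frozenset = DEFAULT_FIXED,
    fit_kwargs: dict | None = None,
) -> ScmResult:
    """Forward-inclusion / backward-elimination covariate search.

    The base model is ``init_fixed``/``init_random`` with all candidate
    coefficients at zero (the built-in haemoglobin coefficient should be
    listed as a candidate and fixed to zero via ``fixed_params`` if it is
    to be searched rather than assumed).  At each forward step every
    remaining candidate is fitted on top of the current model and the one
    with the largest significant OFV drop enters; backward elimination
    then removes any included covariate whose deletion does not worsen
    the OFV at ``backward_alpha``.  Candidates whose fit fails to
    converge are skipped and logged in the trace, never silently dropped.
    """
    fit_kwargs = dict(fit_kwargs or {})
    trace = ScmTrace()
    cache: dict[frozenset, EstimationResult] = {}

    def fit_model(
        effects: tuple[CovariateCandidate, ...],
        subset_col: str | None = None,
        start: EstimationResult | None = None,
    ):
        key = frozenset(e.key for e in effects) | ({subset_col} if subset_col else set())
        if key in cache:
            return cache[key]
        data = ds
        if subset_col is not None:
            data, _ = _subset_with_covariate(ds, subset_col)
        # warm-start from the parent model's estimates where available
        fe0 = start.fixed if start is not None else init_fixed
        re0 = start.random if start is not None else init_random
        if start is not None:
            effects = tuple(
                replace(e, theta=start.extra.get(e.key, e.theta)) for e in effects
            )
        res = fit(
            data, fe0, re0,
            fixed_params=fixed_params, extra_effects=tuple(effects), **fit_kwargs,
        )
        cache[key] = res
        return res

    def any_missing(col: str) -> bool:
        return bool(ds.df.loc[ds.df["EVID"] == 0, col].isna().any())

    base = fit_model(())
    included: list[CovariateCandidate] = []
    remaining = list(candidates)

    # forward inclusion
    while remaining:
        best = None
        current = fit_model(tuple(included))
        for cand in remaining:
            missing = any_missing(cand.covariate_name)
            subset_col = cand.covariate_name if missing else None
            ref = fit_model(tuple(included), subset_col=subset_col, start=current)
            try:
                res = fit_model(tuple(included) + (cand,), subset_col=subset_col,
                                start=ref)
            except (ValueError, FloatingPointError) as exc:
                trace.steps.append(
                    ScmStep("forward", cand.key, np.nan, 1, np.nan, False,
                            note=f"fit failed: {exc}")
                )
                continue
            if not res.converged:
                trace.steps.append(
                    ScmStep("forward", cand.key, np.nan, 1, np.nan, False,
                            note="non-convergence; candidate skipped")
                )
                continue
            dofv = ref.ofv - res.ofv
            p = lrt_pvalue(dofv, 1)
            note = "subset: subjects with covariate" if missing else ""
            trace.steps.append(ScmStep("forward", cand.key, dofv, 1, p, False, note))
            if p < forward_alpha and (best is None or dofv > best[1]):
                best = (cand, dofv, len(trace.steps) - 1)
        if best is None:
            break
        cand, _, step_idx = best
        trace.steps[step_idx].accepted = True
        fitted = fit_model(tuple(included) + (cand,),
                           subset_col=cand.covariate_name if any_missing(cand.covariate_name) else None,
                           start=current)
        theta = fitted.extra.get(cand.key, 0.0)
        included.append(CovariateCandidate(
            cand.covariate_name, cand.target_parameter, cand.form,
            cand.reference_value, theta))
        remaining = [c for c in remaining if c.key != cand.key]

    # backward elimination
    for cand in list(included):
        others = tuple(c for c in included if c.key != cand.key)
        full = fit_model(tuple(included))
        red = fit_model(others, start=full)
        dofv = red.ofv - full.ofv  # OFV worsening caused by removal
        p = lrt_pvalue(dofv, 1)
        keep = p < backward_alpha
        trace.steps.append(ScmStep("backward", cand.key, dofv, 1, p, keep))
        if not keep:
            included = [c for c in included if c.key != cand.key]

    final = fit_model(tuple(included))
    return ScmResult(included=included, final=final, base=base, trace=trace)


def covariate_correlations(
    ds: TdmDataset,
    names: list[str],
    flag_threshold: float = 0.8,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson correlations of per-subject baseline covariates.

    Uses each subject's first observed value.  Constant covariates yield
    undefined (NaN) correlations rather than zero.  Returns the matrix and
    the list of pairs whose |r| exceeds ``flag_threshold`` (collinearity
    review, not automatic exclusion).
    """
    if len(names) < 2:
        raise ValueError("need at least two covariates")
    obs = ds.df[ds.df["EVID"] == 0]
    baseline = obs.groupby("ID", sort=False)[names].first()
    mat = baseline.corr(method="pearson")
    for nm in names:
        if baseline[nm].nunique(dropna=True) <= 1:
            mat.loc[nm, :] = np.nan
            mat.loc[:, nm] = np.nan
        mat.loc[nm, nm] = 1.0 if baseline[nm].nunique(dropna=True) > 1 else np.nan
    flagged = [
        (a, b, float(mat.loc[a, b]))
        for i, a in enumerate(names)
        for b in names[i + 1 :]
        if np.isfinite(mat.loc[a, b]) and abs(mat.loc[a, b]) >= flag_threshold
    ]
    return mat, flagged


def clinical_relevance(
    effect: CovariateCandidate,
    cov_range: tuple[float, float],
    theta: float | None = None,
) -> float:
    """Percent change in the parameter over the covariate range.

    ``100 * |f(lo) - f(hi)| / max(f(lo), f(hi))`` where f is the covariate
    multiplier; symmetric in the range endpoints.  Conventionally, a
    change above 20% is considered clinically relevant.
    """
    lo, hi = cov_range
    f_lo = float(effect.multiplier(lo, theta))
    f_hi = float(effect.multiplier(hi, theta))
    if min(f_lo, f_hi) <= 0:
        raise ValueError("covariate multiplier non-positive over the range")
    return 100.0 * abs(f_lo - f_hi) / max(f_lo, f_hi)
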