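"""Structural and statistical PK model for cyclosporin A.

One-compartment disposition with first-order oral absorption and first-order
elimination, evaluated in closed form at steady state.  Individual apparent
clearance (CL/F) is built from allometrically scaled body weight, a linear
haemoglobin effect centred at the population median, and log-normal random
effects (inter-individual eta plus per-occasion kappa); apparent volume
(V/F) scales linearly with weight with its own eta.

Units: doses in mg, volumes in L, clearances in L/h, times in h,
haemoglobin in g/L, concentrations in ng/mL.  The single mg/L -> ng/mL
conversion (x1000) lives in :func:`conc_ss`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CovariateEffect",
    "FixedEffects",
    "RandomEffectsSpec",
    "IndividualEffects",
    "DosingRegimen",
    "CovariateRecord",
    "individual_clearance",
    "individual_volume",
    "conc_ss",
    "cv_to_variance",
    "variance_to_cv",
]

# HGB range observed in the study population; the linear covariate factor
# must stay positive over it for the model to be admissible.
HGB_SUPPORTED_RANGE = (73.0, 164.0)


@dataclass(frozen=True)
class FixedEffects:
    """Typical-value (population) parameters of the final covariate model.

    ``theta_cl`` and ``theta_v`` are CL/F and V/F for the reference patient
    (``wt_ref`` kg, ``hgb_ref`` g/L); ``theta_all`` is the estimated
    allometric exponent on CL/F while the V/F exponent ``theta_v_exp`` is
    fixed at 1; ``theta_hgb`` is the linear haemoglobin coefficient on CL/F
    per g/L (negative: clearance falls as haemoglobin rises).
    """

    theta_cl: float = 15.0
    theta_v: float = 71.1
    ka: float = 1.15
    theta_all: float = 0.89
    theta_v_exp: float = 1.0
    theta_hgb: float = -0.00279
    wt_ref: float = 40.0
    hgb_ref: float = 120.0

    def __post_init__(self) -> None:
        if self.theta_cl <= 0 or self.theta_v <= 0:
            raise ValueError("typical CL/F and V/F must be positive")
        if self.ka <= 0:
            raise ValueError("ka must be positive")
        if self.wt_ref <= 0:
            raise ValueError("reference weight must be positive")
        for hgb in HGB_SUPPORTED_RANGE:
            if self.hgb_factor(hgb) <= 0:
                raise ValueError(
                    f"HGB factor non-positive at HGB={hgb} g/L for "
                    f"theta_hgb={self.theta_hgb}"
                )

    def hgb_factor(self, hgb: float | np.ndarray) -> float | np.ndarray:
        """Linear haemoglobin multiplier on CL/F, 1 at the reference HGB."""
        return 1.0 + self.theta_hgb * (np.asarray(hgb, dtype=float) - self.hgb_ref)


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Variance components of the mixed-effects model.

    The 2x2 inter-individual (IIV) covariance of (log CL/F, log V/F) is
    ``[[omega2_cl, omega_clv], [omega_clv, omega2_v]]``; ``pi2_iov`` is the
    inter-occasion variance on log CL/F; ``sigma_prop`` the proportional
    residual SD (y = f * (1 + eps)).
    """

    omega2_cl: float = 0.3491**2
    omega2_v: float = 0.4305**2
    omega_clv: float = 0.136
    pi2_iov: float = 0.1225**2
    sigma_prop: float = 0.258

    def __post_init__(self) -> None:
        if self.pi2_iov < 0:
            raise ValueError("IOV variance must be non-negative")
        if self.sigma_prop <= 0:
            raise ValueError("proportional residual SD must be positive")
        m = self.iiv_matrix()
        # symmetric 2x2: PSD iff non-negative diagonal and determinant
        if m[0, 0] < 0 or m[1, 1] < 0 or np.linalg.det(m) < -1e-12:
            raise ValueError("IIV covariance matrix is not positive semi-definite")

    def iiv_matrix(self) -> np.ndarray:
        return np.array(
            [[self.omega2_cl, self.omega_clv], [self.omega_clv, self.omega2_v]]
        )

    @property
    def corr_clv(self) -> float:
        d = np.sqrt(self.omega2_cl * self.omega2_v)
        return float(self.omega_clv / d) if d > 0 else np.nan


@dataclass
class IndividualEffects:
    """A subject's empirical random effects: etas and per-occasion kappas."""

    eta_cl: float = 0.0
    eta_v: float = 0.0
    kappa: dict[int, float] = field(default_factory=dict)

    def kappa_for(self, occasion_id: int) -> float:
        return self.kappa.get(occasion_id, 0.0)


@dataclass(frozen=True)
class DosingRegimen:
    """Repeated oral dosing: ``dose_mg`` every ``tau_h`` hours."""

    dose_mg: float
    tau_h: float = 12.0
    steady_state: bool = True

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValueError("dose must be non-negative")
        if self.tau_h <= 0:
            raise ValueError("dosing interval must be positive")


@dataclass
class CovariateRecord:
    """Covariate snapshot attached to a dataset row (may vary by occasion)."""

    wt_kg: float
    hgb_gL: float
    ht_cm: float = np.nan
    creat_umolL: float = np.nan
    clcr_mLmin: float = np.nan
    age_y: float = np.nan
    gend: int = 0
    trans: int = 0
    occasion_id: int = 1
    day_index: int = 0

    def __post_init__(self) -> None:
        if self.wt_kg <= 0:
            raise ValueError("weight must be positive")
        if self.hgb_gL <= 0:
            raise ValueError("haemoglobin must be positive")


def individual_clearance(
    fe: FixedEffects,
    wt: float | np.ndarray,
    hgb: float | np.ndarray,
    eta_cl: float | np.ndarray = 0.0,
    kappa: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """Individual CL/F (L/h).

    ``theta_cl * (wt/wt_ref)**theta_all * (1 + theta_hgb*(hgb - hgb_ref))
    * exp(eta_cl + kappa)``.
    """
    wt = np.asarray(wt, dtype=float)
    if np.any(wt <= 0):
        raise ValueError("weight must be positive")
    fac = fe.hgb_factor(hgb)
    if np.any(np.asarray(fac) <= 0):
        bad = np.asarray(hgb)[np.asarray(fac) <= 0] if np.ndim(fac) else hgb
        raise ValueError(f"non-positive HGB covariate factor at HGB={bad} g/L")
    out = (
        fe.theta_cl
        * (wt / fe.wt_ref) ** fe.theta_all
        * fac
        * np.exp(np.asarray(eta_cl, dtype=float) + np.asarray(kappa, dtype=float))
    )
    return float(out) if np.ndim(out) == 0 else out


def individual_volume(
    fe: FixedEffects,
    wt: float | np.ndarray,
    eta_v: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """Individual V/F (L): ``theta_v * (wt/wt_ref)**theta_v_exp * exp(eta_v)``."""
    wt = np.asarray(wt, dtype=float)
    if np.any(wt <= 0):
        raise ValueError("weight must be positive")
    out = (
        fe.theta_v
        * (wt / fe.wt_ref) ** fe.theta_v_exp
        * np.exp(np.asarray(eta_v, dtype=float))
    )
    return float(out) if np.ndim(out) == 0 else out


# relative |ka - k| below which the limiting (ka -> k) expression is used
_KA_K_TOL = 1e-8


def conc_ss(
    reg: DosingRegimen,
    t: float | np.ndarray,
    cl: float | np.ndarray,
    v: float | np.ndarray,
    ka: float | None = None,
) -> float | np.ndarray:
    """Steady-state whole-blood concentration (ng/mL) at time ``t`` in [0, tau).

    Standard one-compartment oral superposition limit::

        C(t) = 1000 * D*ka / (V*(ka-k)) *
               [exp(-k t)/(1-exp(-k tau)) - exp(-ka t)/(1-exp(-ka tau))]

    with k = CL/V.  At t = 0 this equals the pre-dose trough (the profile is
    tau-periodic).  When ka is within tolerance of k the removable
    singularity is replaced by its analytic limit.
    """
    if not reg.steady_state:
        raise ValueError("conc_ss requires a steady-state regimen")
    if ka is None:
        ka = 1.15
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t >= reg.tau_h):
        raise ValueError(f"time must lie in [0, tau={reg.tau_h}) h")
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    k = cl / v
    tau = reg.tau_h
    near = np.abs(ka - k) < _KA_K_TOL * np.maximum(k, ka)
    # regular branch (guard the denominator where the limit applies)
    ka_k = np.where(near, 1.0, ka - k)
    regular = (
        reg.dose_mg
        * ka
        / (v * ka_k)
        * (
            np.exp(-k * t) / (1.0 - np.exp(-k * tau))
            - np.exp(-ka * t) / (1.0 - np.exp(-ka * tau))
        )
    )
    # ka -> k limit of the bracketed difference over (ka - k):
    # d/dk [exp(-k t)/(1-exp(-k tau))] with opposite sign
    ek = np.exp(-k * tau)
    limit = (
        reg.dose_mg
        * k
        / v
        * np.exp(-k * t)
        / (1.0 - ek)
        * (t + tau * ek / (1.0 - ek))
    )
    out = 1000.0 * np.where(near, limit, regular)
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class CovariateEffect:
    """A generic covariate-parameter relation (the SCM candidate unit).

    ``form`` is one of ``linear`` (1 + theta*(x - ref)), ``power``
    ((x/ref)**theta, continuous positive covariates only) or
    ``categorical`` (1 + theta*indicator).  ``theta`` carries the current
    coefficient (0 for an untested candidate).
    """

    covariate_name: str
    target_parameter: str  # "CL" or "V"
    form: str = "linear"
    reference_value: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("linear", "power", "categorical"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.target_parameter.upper() not in ("CL", "V"):
            raise ValueError("target parameter must be CL or V")
        if self.form in ("linear", "power") and self.reference_value <= 0:
            raise ValueError("continuous forms need a positive reference value")

    @property
    def key(self) -> str:
        return f"{self.covariate_name}:{self.target_parameter.upper()}"

    def multiplier(self, values, theta: float | None = None):
        """Evaluate the covariate multiplier at covariate ``values``."""
        th = self.theta if theta is None else theta
        x = np.asarray(values, dtype=float)
        if self.form == "linear":
            out = 1.0 + th * (x - self.reference_value)
        elif self.form == "power":
            out = (x / self.reference_value) ** th
        else:
            out = 1.0 + th * x
        return float(out) if np.ndim(out) == 0 else out


def cv_to_variance(cv_percent: float) -> float:
    """Convert a CV% (NONMEM reporting convention) to a log-scale variance."""
    if cv_percent < 0:
        raise ValueError("CV% must be non-negative")
    return (cv_percent / 100.0) ** 2


def variance_to_cv(variance: float) -> float:
    """Inverse of :func:`cv_to_variance`: 100*sqrt(omega^2)."""
    if variance < 0:
        raise ValueError("variance must be non-negative")
    return 100.0 * float(np.sqrt(variance))
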