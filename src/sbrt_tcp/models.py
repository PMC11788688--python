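"""Five published tumour-control-probability (TCP) models for lung SBRT.

Three are logistic dose-response models in BED10 — the Ohri model (with a
size-adjusted BED, sBED = BED10 - c*L for tumour diameter L), and the
Guckenberger ("gucken") and Santiago models (isocenter BED10 only):

    TCP = sigma((BED10 - c*L - TCD50) / k),   sigma the standard logistic.

The Liu model is a probit (Poissonian clonogen) model with post-treatment
regrowth: with surviving-fraction exponent alpha*BED reduced by a regrowth
term (ln2/T_p)*tau*delta at follow-up time tau,

    t = (exp(-[alpha*BED - (ln2/T_p)*tau*delta]) - K_cr/K0) / (sigma_k/K0)
    TCP = 1 - Phi(t),

where K0 is the initial clonogen number (here derived from tumour volume),
K_cr the critical clonogen number defining control and sigma_k the Gaussian
width of the clonogen-number distribution.

The Klement model is a Weibull cure-rate model: with covariate linear
predictor eta (covariates standardised to SD 0.5, binaries to +/-0.5),

    S(t) = exp(-t^rho * e^eta),    TCP(t) = exp(-theta * (1 - S(t))),

so TCP(0) = 1 and TCP plateaus at exp(-theta), the cured fraction.

Model/horizon admissibility follows the published usage: ohri predicts
2-year local control only, gucken and santiago 3-year only, liu and
klement both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .bed import LN2, dose_per_fraction_from_bed

__all__ = [
    "MODEL_HORIZONS",
    "MODEL_ROSTER",
    "LogisticParams",
    "LiuParams",
    "KlementParams",
    "ModelConfigError",
    "HorizonError",
    "tcp_logistic",
    "liu_t_statistic",
    "tcp_liu",
    "clonogen_number",
    "standardize_covariates",
    "tcp_klement",
    "predict_cohort",
    "predict_all",
]

#: horizons (years) each model may predict
MODEL_HORIZONS: Mapping[str, frozenset] = {
    "liu": frozenset({2, 3}),
    "klement": frozenset({2, 3}),
    "ohri": frozenset({2}),
    "gucken": frozenset({3}),
    "santiago": frozenset({3}),
}

#: the model roster per horizon used in the full validation
MODEL_ROSTER: Mapping[int, tuple] = {
    2: ("liu", "klement", "ohri"),
    3: ("liu", "klement", "gucken", "santiago"),
}


class ModelConfigError(ValueError):
    """A model parameter set is inconsistent or incomplete."""


class HorizonError(ValueError):
    """A model was requested at a follow-up horizon it does not support."""


# ---------------------------------------------------------------------------
# logistic models (ohri / gucken / santiago)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of a logistic TCP model: TCP = sigma((BED10 - c*L - TCD50)/k)."""

    model_name: str
    tcd50_gy: float
    k_gy: float
    size_coefficient_gy_per_cm: float = 0.0
    bed_column: str = "bed_dmax_gy"

    def __post_init__(self) -> None:
        if not (self.k_gy > 0):
            raise ModelConfigError(f"{self.model_name}: slope k must be > 0 Gy, got {self.k_gy!r}")
        if self.size_coefficient_gy_per_cm < 0:
            raise ModelConfigError(f"{self.model_name}: size coefficient must be >= 0")


def tcp_logistic(bed10_gy, params: LogisticParams, diameter_cm=None):
    """Logistic TCP.  ``diameter_cm`` is required iff the model carries a
    size coefficient (the Ohri sBED term); scalar or array inputs."""
    bed10 = np.asarray(bed10_gy, dtype=float)
    c = params.size_coefficient_gy_per_cm
    if c != 0.0:
        if diameter_cm is None:
            raise ModelConfigError(
                f"{params.model_name}: tumour diameter is required (size coefficient c={c} Gy/cm)"
            )
        sbed = bed10 - c * np.asarray(diameter_cm, dtype=float)
    else:
        sbed = bed10
    out = expit((sbed - params.tcd50_gy) / params.k_gy)
    return float(out) if np.isscalar(bed10_gy) and np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Liu probit model with regrowth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LiuParams:
    """Liu-model parameters.

    Either absolute clonogen quantities (``k_cr``, ``sigma_k``,
    ``cell_density_per_cm3``; K0 is then rho_cell * pi/6 * L^3 from the
    tumour diameter) or direct ratios (``k_cr_over_k0``,
    ``sigma_k_over_k0``) may be supplied — exactly one parameterisation.

    ``t_p_regrowth_days`` enters the regrowth-corrected BED during
    treatment; ``t_p_postrx_days`` enters the post-treatment regrowth term
    of the probit argument.  They are kept as separate knobs because the
    published symbol glossary defines a doubling time for each role; the
    shipped default uses the same value for both.
    """

    alpha_per_gy: float = 0.3
    alpha_beta_gy: float = 20.0
    t_p_regrowth_days: float = 3.0
    t_p_postrx_days: float = 3.0
    delta: float = 0.01
    k_cr: float | None = 1.0
    sigma_k: float | None = 0.6
    cell_density_per_cm3: float | None = 1.0e7
    k_cr_over_k0: float | None = None
    sigma_k_over_k0: float | None = None
    tau_unit_days: float = 365.25
    bed_column: str = "bed_dmax_gy"

    def __post_init__(self) -> None:
        for name in ("alpha_per_gy", "t_p_regrowth_days", "t_p_postrx_days", "tau_unit_days"):
            if not (getattr(self, name) > 0):
                raise ModelConfigError(f"liu: {name} must be > 0, got {getattr(self, name)!r}")
        ratio_mode = self.k_cr_over_k0 is not None or self.sigma_k_over_k0 is not None
        abs_mode = self.k_cr is not None and self.sigma_k is not None and self.cell_density_per_cm3 is not None
        if ratio_mode:
            if self.k_cr_over_k0 is None or self.sigma_k_over_k0 is None:
                raise ModelConfigError("liu: both k_cr_over_k0 and sigma_k_over_k0 are required")
            if not (self.sigma_k_over_k0 > 0):
                raise ModelConfigError("liu: sigma_k_over_k0 must be > 0")
        elif abs_mode:
            if not (self.sigma_k > 0):
                raise ModelConfigError("liu: sigma_k must be > 0")
            if not (self.k_cr > 0) or not (self.cell_density_per_cm3 > 0):
                raise ModelConfigError("liu: k_cr and cell_density_per_cm3 must be > 0")
        else:
            raise ModelConfigError(
                "liu: supply either (k_cr, sigma_k, cell_density_per_cm3) or "
                "(k_cr_over_k0, sigma_k_over_k0)"
            )

    @property
    def uses_ratios(self) -> bool:
        return self.k_cr_over_k0 is not None


def clonogen_number(diameter_cm, cell_density_per_cm3: float):
    """Initial clonogen number K0 for a sphere of the given diameter (cm)."""
    L = np.asarray(diameter_cm, dtype=float)
    return cell_density_per_cm3 * (math.pi / 6.0) * L**3


def liu_t_statistic(bed_gy, tau_years, params: LiuParams, diameter_cm=None):
    """Probit argument of the Liu model.

    The grouping of the regrowth exponent is isolated here:

        t = (exp(-[alpha*BED - (ln2/T_p) * tau * delta]) - K_cr/K0) / (sigma_k/K0)

    with tau converted from years to the doubling-time unit (days) via
    ``tau_unit_days``.
    """
    bed = np.asarray(bed_gy, dtype=float)
    tau_days = np.asarray(tau_years, dtype=float) * params.tau_unit_days
    log_sf = -(params.alpha_per_gy * bed - (LN2 / params.t_p_postrx_days) * tau_days * params.delta)
    if params.uses_ratios:
        kcr_ratio = params.k_cr_over_k0
        sig_ratio = params.sigma_k_over_k0
    else:
        if diameter_cm is None:
            raise ModelConfigError("liu: tumour diameter is required to derive K0")
        k0 = clonogen_number(diameter_cm, params.cell_density_per_cm3)
        kcr_ratio = params.k_cr / k0
        sig_ratio = params.sigma_k / k0
    return (np.exp(log_sf) - kcr_ratio) / sig_ratio


def tcp_liu(bed_gy, tau_years, params: LiuParams, diameter_cm=None):
    """Liu TCP = 1 - Phi(t); monotone increasing in BED, decreasing in tau.

    The survival function underflows for the model's extremely steep
    low-dose tail, so the result is kept inside the open unit interval by a
    tiny numerical floor/ceiling (1e-300 / 1 - 1e-16).
    """
    t = liu_t_statistic(bed_gy, tau_years, params, diameter_cm=diameter_cm)
    if not np.all(np.isfinite(t)):
        raise ModelConfigError("liu: non-finite probit argument (check parameter magnitudes)")
    out = np.clip(norm.sf(t), 1e-300, 1.0 - 1e-16)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Klement cure-rate model
# ---------------------------------------------------------------------------

_DEFAULT_ETA_COEFS = {
    "male": 0.10,
    "age": 0.10,
    "central": 0.30,
    "chemo_prior": 0.20,
    "diameter_cm": 0.40,
    "bed": -0.80,
}


@dataclass(frozen=True)
class KlementParams:
    """Weibull cure-rate parameters.

    ``theta`` may be a scalar cure parameter (default) or covariate-dependent
    through a log-linear link (``theta_intercept`` + ``theta_coefficients``
    on the standardised covariates).  ``covariate_refs`` maps covariate name
    to (mean, sd) reference moments for standardisation; ``None`` means
    "use the moments of the cohort being scored".
    """

    theta: float | None = 0.4
    rho: float = 1.5
    eta_intercept: float = -1.5
    eta_coefficients: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_ETA_COEFS))
    theta_intercept: float | None = None
    theta_coefficients: Mapping[str, float] | None = None
    binary_covariates: tuple = ("male", "central", "chemo_prior")
    covariate_refs: Mapping[str, tuple] | None = None
    tau_unit_scale: float = 1.0
    bed_column: str = "bed_dmax_gy"

    def __post_init__(self) -> None:
        if not (self.rho > 0):
            raise ModelConfigError(f"klement: rho must be > 0, got {self.rho!r}")
        if self.theta_intercept is None and self.theta is None:
            raise ModelConfigError("klement: supply theta (scalar) or theta_intercept (log-linear)")
        if self.theta is not None and self.theta < 0:
            raise ModelConfigError(f"klement: theta must be >= 0, got {self.theta!r}")


def standardize_covariates(
    raw: pd.DataFrame,
    binary: Sequence[str],
    refs: Mapping[str, tuple] | None = None,
):
    """Rescale covariates the way cure-rate coefficients expect.

    Binary covariates (coded 0/1) are shifted to -0.5/+0.5; continuous
    covariates are scaled as 0.5*(x - mean)/sd so they have SD 0.5 under the
    reference distribution.  Returns ``(standardised frame, refs used)`` so
    the applied reference moments are always reportable.
    """
    out = pd.DataFrame(index=raw.index)
    used: dict[str, tuple] = {}
    for col in raw.columns:
        x = raw[col].astype(float)
        if col in binary:
            bad = ~x.isin([0.0, 1.0])
            if bad.any():
                raise ModelConfigError(
                    f"binary covariate {col!r} must be coded 0/1; offending rows: "
                    f"{list(raw.index[bad][:5])}"
                )
            out[col] = x - 0.5
            used[col] = (0.5, None)
        else:
            if refs is not None and col in refs:
                mean, sd = refs[col]
            else:
                mean, sd = float(x.mean()), float(x.std(ddof=1))
            if not (sd and sd > 0):
                raise ModelConfigError(f"covariate {col!r}: reference SD must be > 0, got {sd!r}")
            out[col] = 0.5 * (x - mean) / sd
            used[col] = (mean, sd)
    return out, used


def tcp_klement(t_years, eta, params: KlementParams, theta=None):
    """Cure-rate TCP at follow-up ``t_years`` given linear predictor ``eta``.

    ``theta`` overrides the parameter-set cure parameter (used when theta is
    covariate-dependent); must be >= 0.
    """
    t = np.asarray(t_years, dtype=float) * params.tau_unit_scale
    if np.any(t < 0):
        raise ModelConfigError("klement: follow-up time must be >= 0")
    th = params.theta if theta is None else np.asarray(theta, dtype=float)
    if np.any(np.asarray(th) < 0):
        raise ModelConfigError("klement: theta must be >= 0")
    surv = np.exp(-np.power(t, params.rho) * np.exp(np.asarray(eta, dtype=float)))
    out = np.exp(-th * (1.0 - surv))
    return float(out) if np.ndim(out) == 0 else out


def _klement_design(cohort: pd.DataFrame, params: KlementParams) -> pd.DataFrame:
    """Assemble the raw covariate frame the cure-rate coefficients refer to."""
    cols = {}
    needed = set(params.eta_coefficients) | set(params.theta_coefficients or {})
    for name in needed:
        if name == "male":
            cols[name] = (cohort["sex"].astype(str).str.lower() == "male").astype(float)
        elif name == "central":
            cols[name] = (cohort["location"].astype(str).str.lower() == "central").astype(float)
        elif name == "chemo_prior":
            cols[name] = cohort["chemo_prior"].astype(float)
        elif name == "age":
            cols[name] = cohort["age"].astype(float)
        elif name == "diameter_cm":
            cols[name] = cohort["diameter_cm"].astype(float)
        elif name == "bed":
            cols[name] = cohort[params.bed_column].astype(float)
        elif name in cohort.columns:
            cols[name] = cohort[name].astype(float)
        else:
            raise ModelConfigError(f"klement: unknown covariate {name!r}")
    return pd.DataFrame(cols, index=cohort.index)


def _klement_predict(cohort: pd.DataFrame, horizon: float, params: KlementParams) -> np.ndarray:
    design = _klement_design(cohort, params)
    std, _ = standardize_covariates(design, params.binary_covariates, params.covariate_refs)
    eta = params.eta_intercept + sum(
        coef * std[name].to_numpy() for name, coef in params.eta_coefficients.items()
    )
    if params.theta_intercept is not None:
        theta = np.exp(
            params.theta_intercept
            + sum(c * std[n].to_numpy() for n, c in (params.theta_coefficients or {}).items())
        )
    else:
        theta = None
    return np.asarray(tcp_klement(horizon, eta, params, theta=theta))


# ---------------------------------------------------------------------------
# cohort-level prediction
# ---------------------------------------------------------------------------


def _liu_predict(cohort: pd.DataFrame, horizon: float, params: LiuParams) -> np.ndarray:
    # recover the per-fraction dose behind the stored BED10 column, then
    # re-express the schedule as a regrowth-corrected BED at the Liu alpha/beta
    bed10 = cohort[params.bed_column].to_numpy(dtype=float)
    n = cohort["n_fractions"].to_numpy(dtype=float)
    d = dose_per_fraction_from_bed(bed10, n, alpha_beta_gy=10.0)
    gamma = cohort["treatment_duration_days"].to_numpy(dtype=float)
    bed_liu = n * d * (1.0 + d / params.alpha_beta_gy) - (
        LN2 / (params.alpha_per_gy * params.t_p_regrowth_days)
    ) * gamma
    diam = cohort["diameter_cm"].to_numpy(dtype=float) if "diameter_cm" in cohort else None
    return np.asarray(tcp_liu(bed_liu, horizon, params, diameter_cm=diam))


def predict_cohort(
    cohort: pd.DataFrame,
    horizon: int,
    models: Sequence[str],
    config: Mapping[str, object],
) -> pd.DataFrame:
    """Per-patient TCP for each requested model at one follow-up horizon.

    ``config`` maps model name to its parameter object (see
    :func:`sbrt_tcp.config.load_params`).  Returns a DataFrame aligned with
    the cohort index, one probability column per model.
    """
    if horizon not in (2, 3):
        raise HorizonError(f"horizon must be 2 or 3 years, got {horizon!r}")
    out = pd.DataFrame(index=cohort.index)
    for name in models:
        if name not in MODEL_HORIZONS:
            raise ModelConfigError(f"unknown model {name!r}; choose from {sorted(MODEL_HORIZONS)}")
        if horizon not in MODEL_HORIZONS[name]:
            raise HorizonError(
                f"the {name} model predicts {sorted(MODEL_HORIZONS[name])}-year local control "
                f"only and cannot be used at the {horizon}-year horizon"
            )
        if name not in config:
            raise ModelConfigError(f"no parameters configured for model {name!r}")
        params = config[name]
        if isinstance(params, LogisticParams):
            diam = None
            if params.size_coefficient_gy_per_cm != 0.0:
                if "diameter_cm" not in cohort:
                    raise ModelConfigError(f"{name}: cohort lacks the diameter_cm column")
                diam = cohort["diameter_cm"].to_numpy(dtype=float)
            out[name] = tcp_logistic(
                cohort[params.bed_column].to_numpy(dtype=float), params, diameter_cm=diam
            )
        elif isinstance(params, LiuParams):
            out[name] = _liu_predict(cohort, horizon, params)
        elif isinstance(params, KlementParams):
            out[name] = _klement_predict(cohort, horizon, params)
        else:  # pragma: no cover - config layer guarantees the union
            raise ModelConfigError(f"unsupported parameter object for {name!r}: {type(params)}")
    return out


def predict_all(
    cohort: pd.DataFrame,
    config: Mapping[str, object],
    horizons: Sequence[int] = (2, 3),
) -> pd.DataFrame:
    """Prediction matrix over the full model roster.

    Columns are a (horizon, model) MultiIndex covering the standard roster:
    liu/klement/ohri at 2 years and liu/klement/gucken/santiago at 3 years.
    """
    blocks = {}
    for h in horizons:
        block = predict_cohort(cohort, h, MODEL_ROSTER[h], config)
        for col in block.columns:
            blocks[(h, col)] = block[col]
    out = pd.DataFrame(blocks, index=cohort.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["horizon", "model"])
    return out
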