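"""The four complementary two-wave models and their closed-form focal effects.

With all variables standardized, the focal effects of the first three models
are pure functions of three correlations:

* CLPM (model A): the cross-lagged effect of P1 on E2 adjusting for E1,
  ``beta = (r_P1E2 - r_P1E1 * r_E1E2) / (1 - r_P1E1**2)``.
* Reversed CLPM (model B): the effect of P1 on E1 adjusting for E2 — the
  same formula with the roles of the two outcome waves exchanged.  Under a
  genuine prospective effect, time reversal is expected to flip the sign.
* LCSM (model C): the effect of P1 on the latent change E2 - E1,
  ``beta = (r_P1E2 - r_P1E1) / sqrt(2 * (1 - r_E1E2))``, the standardized
  difference-score regression.

Model D is the artifactualness model: no direct predictor-outcome paths at
all.  P1/P2 and E1/E2 load (fixed unit loadings) on construct factors gP and
gE, which load on a single second-order "general negativity" factor gNeg
(gE loading fixed to +1 or -1 according to the sign of the observed P-E
correlations), plus one shared same-occasion state covariance.  A good fit
of this 6-df model signals that the observed cross-lagged effects could have
arisen without any direct effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ConvergenceError, DegenerateDataError, ValidationError
from .sem import SemFit, SemSpec

__all__ = [
    "EffectEstimate",
    "beta_lagged",
    "beta_change",
    "beta_reversed",
    "build_clpm",
    "build_reversed_clpm",
    "build_lcsm",
    "build_artifact_model",
    "focal_effect",
]

_MODELS = ("clpm", "reversed", "lcsm")
_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class EffectEstimate:
    """One standardized focal effect with Wald inference."""

    model: str
    b: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    significant: bool

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValidationError(f"unknown model {self.model!r}")
        if not self.ci95[0] - 1e-12 <= self.b <= self.ci95[1] + 1e-12:
            raise ValidationError("focal estimate must lie inside its own CI")


# --------------------------------------------------------------------------
# Closed-form focal effects
# --------------------------------------------------------------------------

def beta_lagged(r_xy2: float, r_xy1: float, r_y1y2: float) -> float:
    """Standardized effect of X1 on Y2 adjusting for Y1."""
    if abs(r_xy1) >= 1.0:
        raise DegenerateDataError("predictor and prior outcome are collinear (|r| = 1)")
    return (r_xy2 - r_xy1 * r_y1y2) / (1.0 - r_xy1 ** 2)


def beta_change(r_xy2: float, r_xy1: float, r_y1y2: float) -> float:
    """Standardized effect of X1 on the Y2 - Y1 difference score."""
    if r_y1y2 >= 1.0:
        raise DegenerateDataError("change score has zero variance (r_y1y2 = 1)")
    return (r_xy2 - r_xy1) / math.sqrt(2.0 * (1.0 - r_y1y2))


def beta_reversed(r_pe1: float, r_pe2: float, r_e1e2: float) -> float:
    """Standardized effect of P1 on E1 adjusting for E2 (time-reversed lagged effect)."""
    if abs(r_pe2) >= 1.0:
        raise DegenerateDataError("predictor and subsequent outcome are collinear")
    return (r_pe1 - r_pe2 * r_e1e2) / (1.0 - r_pe2 ** 2)


# --------------------------------------------------------------------------
# Model builders
# --------------------------------------------------------------------------

def build_clpm() -> SemSpec:
    """Model A: cross-lagged panel model over (P1, P2, E1, E2); saturated, df = 0."""
    v = ["P1", "P2", "E1", "E2"]
    spec = SemSpec(v, v, name="clpm")
    spec.add_path("P1", "E2", free="b_p1_e2")
    spec.add_path("E1", "E2", free="b_e1_e2")
    spec.add_path("P1", "P2", free="b_p1_p2")
    spec.add_path("E1", "P2", free="b_e1_p2")
    spec.add_variance("P1", free="v_p1")
    spec.add_variance("E1", free="v_e1")
    spec.add_covariance("P1", "E1", free="c_p1_e1")
    spec.add_variance("P2", free="rv_p2")
    spec.add_variance("E2", free="rv_e2")
    spec.add_covariance("P2", "E2", free="rc_p2_e2")
    spec.set_focal("b_p1_e2", "P1", "E2")
    return spec


def build_reversed_clpm() -> SemSpec:
    """Model B: initial outcome regressed on initial predictor and subsequent outcome.

    Uses only (P1, E1, E2); saturated over those three variables.
    """
    v = ["P1", "E1", "E2"]
    spec = SemSpec(v, v, name="reversed_clpm")
    spec.add_path("P1", "E1", free="b_p1_e1")
    spec.add_path("E2", "E1", free="b_e2_e1")
    spec.add_variance("P1", free="v_p1")
    spec.add_variance("E2", free="v_e2")
    spec.add_covariance("P1", "E2", free="c_p1_e2")
    spec.add_variance("E1", free="rv_e1")
    spec.set_focal("b_p1_e1", "P1", "E1")
    return spec


def build_lcsm(proportional_change: bool = False) -> SemSpec:
    """Model C: bivariate latent change score model; saturated, df = 0.

    Each wave-2 score is the wave-1 score plus a latent change (unit fixed
    loadings, zero wave-2 residual); each latent change is regressed on the
    other construct's wave-1 score.  By default the change disturbance
    covaries freely with its own construct's wave-1 score, which makes the
    standardized focal effect identical to the difference-score regression;
    ``proportional_change=True`` replaces those covariances with explicit
    change-on-baseline regressions (an algebraically equivalent saturated
    rotation whose focal path has a different interpretation).
    """
    obs = ["P1", "P2", "E1", "E2"]
    spec = SemSpec(obs + ["dP", "dE"], obs, name="lcsm")
    spec.add_path("E1", "E2", fixed=1.0)
    spec.add_path("dE", "E2", fixed=1.0)
    spec.add_path("P1", "P2", fixed=1.0)
    spec.add_path("dP", "P2", fixed=1.0)
    spec.add_path("P1", "dE", free="b_p1_de")
    spec.add_path("E1", "dP", free="b_e1_dp")
    spec.add_variance("P1", free="v_p1")
    spec.add_variance("E1", free="v_e1")
    spec.add_covariance("P1", "E1", free="c_p1_e1")
    spec.add_variance("dE", free="v_de")
    spec.add_variance("dP", free="v_dp")
    spec.add_covariance("dE", "dP", free="c_de_dp")
    if proportional_change:
        spec.add_path("E1", "dE", free="s_e1_de")
        spec.add_path("P1", "dP", free="s_p1_dp")
    else:
        spec.add_covariance("dE", "E1", free="c_de_e1")
        spec.add_covariance("dP", "P1", free="c_dp_p1")
    spec.set_focal("b_p1_de", "P1", "dE")
    return spec


def build_artifact_model(sign: int = 1) -> SemSpec:
    """Model D: second-order general-negativity model with no direct effects.

    Free parameters (4): the variance of the second-order factor, one
    residual variance shared by P1/P2, one shared by E1/E2, and one
    same-occasion state covariance applied to both P1-E1 and P2-E2.  All
    loadings are fixed to 1 (the gE loading to ``sign``), giving df = 6.
    """
    if sign not in (1, -1):
        raise ValidationError(f"sign must be +1 or -1, got {sign!r}")
    obs = ["P1", "P2", "E1", "E2"]
    spec = SemSpec(obs + ["gP", "gE", "gNeg"], obs,
                   name=f"artifact_sign{'+' if sign > 0 else '-'}")
    spec.add_path("gP", "P1", fixed=1.0)
    spec.add_path("gP", "P2", fixed=1.0)
    spec.add_path("gE", "E1", fixed=1.0)
    spec.add_path("gE", "E2", fixed=1.0)
    spec.add_path("gNeg", "gP", fixed=1.0)
    spec.add_path("gNeg", "gE", fixed=float(sign))
    spec.add_variance("gNeg", free="v_gneg")
    spec.add_variance("P1", free="theta_p")
    spec.add_variance("P2", free="theta_p")
    spec.add_variance("E1", free="theta_e")
    spec.add_variance("E2", free="theta_e")
    spec.add_covariance("P1", "E1", free="state_cov")
    spec.add_covariance("P2", "E2", free="state_cov")
    return spec


# --------------------------------------------------------------------------
# Focal-effect extraction
# --------------------------------------------------------------------------

def focal_effect(fit: SemFit, model: str, alpha: float = 0.05) -> EffectEstimate:
    """Standardized focal effect of a fitted model with Wald 95% CI.

    Standardization multiplies the raw path by the ratio of implied standard
    deviations of the source and target variables, both taken from the
    fitted model's implied covariance matrix (so exact-mode and stochastic
    data share one code path); the standard error follows by the delta
    method over the full free-parameter covariance.
    """
    if model not in _MODELS:
        raise ValidationError(f"unknown model {model!r}")
    if not fit.converged:
        raise ConvergenceError(
            f"refusing to extract a focal effect from a non-converged fit of "
            f"{fit.spec.name!r} ({fit.n_iter} iterations)"
        )
    if fit.spec.focal is None:
        raise ValidationError(f"spec {fit.spec.name!r} declares no focal parameter")
    label, source, target = fit.spec.focal
    comp = fit.spec.compile()
    theta = np.array([fit.theta[lab] for lab in fit.labels])
    si = comp.spec._idx[source]
    ti = comp.spec._idx[target]
    k = comp.label_pos[label]

    def standardized(vec: np.ndarray) -> float:
        full = comp.sigma_full(vec)
        return vec[k] * math.sqrt(full[si, si] / full[ti, ti])

    b = standardized(theta)
    # delta method: numeric gradient of the standardized effect
    grad = np.zeros(len(theta))
    for j in range(len(theta)):
        h = 1e-6 * (1.0 + abs(theta[j]))
        up, dn = theta.copy(), theta.copy()
        up[j] += h
        dn[j] -= h
        grad[j] = (standardized(up) - standardized(dn)) / (2.0 * h)
    var = float(grad @ fit.param_cov @ grad)
    se = math.sqrt(max(var, 0.0))
    if se > 0:
        z = b / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 0.0 if b != 0 else 1.0
    ci = (b - _Z975 * se, b + _Z975 * se)
    return EffectEstimate(model=model, b=b, se=se, ci95=ci,
                          p_value=p, significant=p < alpha)
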