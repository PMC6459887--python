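"""Leave-one-out sensitivity analysis and MR-Egger pleiotropy regression.

Leave-one-out re-pools the instruments omitting each variant in turn,
flagging single-variant dominance through the fluctuation of the pooled OR.
MR-Egger fits a weighted regression of outcome effects on exposure effects
with a free intercept: the intercept estimates the average directional
pleiotropic effect across instruments (non-zero indicates pleiotropy that
biases IVW), while the slope is a pleiotropy-adjusted causal-effect
estimate, consistent under the InSIDE assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core import PooledEstimate, Z_95, ivw_pool, wald_ratio
from .harmonize import HarmonizedInstrument, flip_instrument


@dataclass(frozen=True)
class LooResult:
    """IVW estimate with one instrument removed, plus its relative OR shift."""

    omitted_variant: str
    pooled: PooledEstimate
    fluctuation: float  # (OR_loo - OR_full) / OR_full


@dataclass(frozen=True)
class EggerResult:
    slope: float
    slope_se: float
    slope_ci_low: float
    slope_ci_high: float
    slope_p: float
    intercept: float
    intercept_se: float
    intercept_ci_low: float
    intercept_ci_high: float
    intercept_p: float
    n_instruments: int
    overdispersion: float  # multiplicative SE scale, >= 1


def orient_exposure_positive(
    instruments: Sequence[HarmonizedInstrument],
) -> list[HarmonizedInstrument]:
    """Re-express every instrument for its exposure-increasing allele.

    Instruments with negative beta_exposure have both betas negated (and the
    ``flipped`` flag toggled); Wald ratios are unchanged. MR-Egger requires
    this orientation for identifiability of the intercept sign.
    """
    return [
        flip_instrument(i) if i.beta_exposure < 0 else i for i in instruments
    ]


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    model: str = "fixed",
    se_method: str = "delta",
) -> list[LooResult]:
    """Re-estimate the IVW pooled effect omitting each instrument in turn.

    Each subset estimate is exactly ``ivw_pool`` applied to the remaining
    instruments; ``fluctuation`` is the OR shift relative to the full-set OR.
    Requires at least 3 instruments so every subset supports pooling and a
    heterogeneity assessment.
    """
    k = len(instruments)
    if k < 3:
        raise ValueError("leave-one-out requires at least 3 instruments")
    estimates = [wald_ratio(i, se_method=se_method) for i in instruments]
    or_full = ivw_pool(estimates, model=model).or_
    results = []
    for idx, inst in enumerate(instruments):
        subset = estimates[:idx] + estimates[idx + 1 :]
        pooled = ivw_pool(subset, model=model)
        results.append(
            LooResult(
                omitted_variant=inst.variant_id,
                pooled=pooled,
                fluctuation=(pooled.or_ - or_full) / or_full,
            )
        )
    return results


def weighted_linear_fit(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    fit_intercept: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares via statsmodels.

    Returns ``(params, se_unit, scale)`` where ``params`` is ``[intercept,
    slope]`` (or ``[slope]`` without intercept), ``se_unit`` the parameter
    SEs under a fixed unit residual variance, and ``scale`` the estimated
    residual variance (the WLS mean squared weighted residual).
    """
    X = sm.add_constant(x) if fit_intercept else x[:, None]
    res = sm.WLS(y, X, weights=weights).fit()
    cov_unit = res.normalized_cov_params  # (X' W X)^-1
    se_unit = np.sqrt(np.diag(cov_unit))
    return np.asarray(res.params), se_unit, float(res.scale)


def egger_regression(
    instruments: Sequence[HarmonizedInstrument],
    p_method: str = "normal",
) -> EggerResult:
    """MR-Egger regression of outcome effects on exposure effects.

    Instruments are first oriented so every beta_exposure is positive, then
    beta_outcome is regressed on beta_exposure with weights se_outcome⁻² and
    a free intercept. Standard errors use multiplicative overdispersion with
    the residual standard error floored at 1 (underdispersion is never used
    to shrink SEs). ``p_method`` selects normal (default) or t (k-2 df)
    reference distributions for the two-sided p-values and CIs.
    """
    k = len(instruments)
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    if p_method not in ("normal", "t"):
        raise ValueError("p_method must be 'normal' or 't'")
    oriented = orient_exposure_positive(instruments)
    x = np.array([i.beta_exposure for i in oriented])
    y = np.array([i.beta_outcome for i in oriented])
    w = np.array([i.se_outcome**-2 for i in oriented])
    if np.ptp(x) == 0:
        raise ValueError(
            "singular design: all exposure effects identical after orientation"
        )

    params, se_unit, scale = weighted_linear_fit(x, y, w, fit_intercept=True)
    sigma = max(1.0, math.sqrt(scale))
    se = se_unit * sigma
    intercept, slope = float(params[0]), float(params[1])
    int_se, slope_se = float(se[0]), float(se[1])

    if p_method == "normal":
        crit = Z_95
        pvals = [2 * stats.norm.sf(abs(v / s)) for v, s in ((intercept, int_se), (slope, slope_se))]
    else:
        crit = float(stats.t.ppf(0.975, k - 2))
        pvals = [2 * stats.t.sf(abs(v / s), k - 2) for v, s in ((intercept, int_se), (slope, slope_se))]

    return EggerResult(
        slope=slope,
        slope_se=slope_se,
        slope_ci_low=slope - crit * slope_se,
        slope_ci_high=slope + crit * slope_se,
        slope_p=float(pvals[1]),
        intercept=intercept,
        intercept_se=int_se,
        intercept_ci_low=intercept - crit * int_se,
        intercept_ci_high=intercept + crit * int_se,
        intercept_p=float(pvals[0]),
        n_instruments=k,
        overdispersion=sigma,
    )


def ivw_regression_slope(instruments: Sequence[HarmonizedInstrument]) -> float:
    """Slope of the zero-intercept weighted regression of outcome on exposure effects.

    With weights se_outcome⁻² this is algebraically the IVW estimate; exposed
    as the regression-route cross-check of ``ivw_pool``.
    """
    oriented = orient_exposure_positive(instruments)
    x = np.array([i.beta_exposure for i in oriented])
    y = np.array([i.beta_outcome for i in oriented])
    w = np.array([i.se_outcome**-2 for i in oriented])
    params, _, _ = weighted_linear_fit(x, y, w, fit_intercept=False)
    return float(params[0])
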