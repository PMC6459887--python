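"""Wald ratios and inverse-variance-weighted pooling with heterogeneity.

The causal effect of the exposure on the outcome is estimated per variant as
the Wald ratio beta_XY = beta_ZY / beta_ZX, with a first-order delta-method
standard error SE_XY = SE_ZY / |beta_ZX| (the exposure-side sampling error
contributes only at second order for strong instruments and is neglected).
Ratios are pooled by inverse-variance weighting; between-variant
heterogeneity is quantified by Cochran's Q and I², and a DerSimonian–Laird
random-effects model substitutes for the fixed-effect model when
heterogeneity is significant (P < 0.01 and I² > 50% under the ``auto`` rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument

#: two-sided 95% standard-normal critical value, at the precision used for CIs
Z_95 = 1.959964

SE_METHODS = ("delta", "paper-literal")


@dataclass(frozen=True)
class WaldEstimate:
    """Per-variant causal-effect ratio with its SE, 95% CI and IVW weight."""

    variant_id: str
    ratio: float
    se: float
    ci_low: float
    ci_high: float
    weight: float  # 1 / se^2


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square p-value and the I² percentage."""

    Q: float
    df: int
    p_value: float
    i_squared_pct: float


@dataclass(frozen=True)
class PooledEstimate:
    """IVW-pooled causal effect on the log-OR and OR scales."""

    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str  # "fixed" or "random"
    heterogeneity: HeterogeneityResult | None
    n_instruments: int


def wald_ratio(
    inst: HarmonizedInstrument, se_method: str = "delta"
) -> WaldEstimate:
    """Per-variant causal estimate beta_outcome / beta_exposure.

    ``se_method="delta"`` (default) uses the first-order delta-method SE
    se_outcome / |beta_exposure|. ``se_method="paper-literal"`` uses
    se_outcome / se_exposure, a formula that appears in some write-ups but
    is dimensionally inconsistent; it is provided only for comparison.
    """
    if se_method not in SE_METHODS:
        raise ValueError(f"se_method must be one of {SE_METHODS}")
    if inst.beta_exposure == 0:
        raise ValueError(
            f"{inst.variant_id}: Wald ratio undefined for zero exposure effect"
        )
    ratio = inst.beta_outcome / inst.beta_exposure
    if se_method == "delta":
        se = inst.se_outcome / abs(inst.beta_exposure)
    else:
        se = inst.se_outcome / inst.se_exposure
    return WaldEstimate(
        variant_id=inst.variant_id,
        ratio=ratio,
        se=se,
        ci_low=ratio - Z_95 * se,
        ci_high=ratio + Z_95 * se,
        weight=se**-2,
    )


def cochran_heterogeneity(
    estimates: Sequence[WaldEstimate], pooled_beta: float
) -> HeterogeneityResult:
    """Cochran's Q about the fixed-effect pooled value, with I².

    Q = sum w_i (r_i - pooled)^2 is referred to a chi-square distribution on
    k-1 degrees of freedom; I² = (Q - df)/Q × 100, floored at 0 (and 0 by
    convention when Q = 0).
    """
    k = len(estimates)
    if k < 2:
        raise ValueError("heterogeneity requires at least 2 estimates")
    r = np.array([e.ratio for e in estimates])
    w = np.array([e.weight for e in estimates])
    Q = float(np.sum(w * (r - pooled_beta) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(Q, df))
    i2 = 0.0 if Q == 0 else min(100.0, max(0.0, (Q - df) / Q * 100.0))
    return HeterogeneityResult(Q=Q, df=df, p_value=p, i_squared_pct=i2)


def _dl_tau_squared(r: np.ndarray, w: np.ndarray, Q: float) -> float:
    # DerSimonian–Laird moment estimator, truncated at zero
    df = len(r) - 1
    denom = w.sum() - (w**2).sum() / w.sum()
    return max(0.0, (Q - df) / denom) if denom > 0 else 0.0


def ivw_pool(
    estimates: Sequence[WaldEstimate],
    model: str = "auto",
    het_p_threshold: float = 0.01,
    i2_threshold_pct: float = 50.0,
) -> PooledEstimate:
    """Inverse-variance-weighted pooling of per-variant Wald ratios.

    Parameters
    ----------
    model
        ``"fixed"``: beta = sum(w_i r_i)/sum(w_i), w_i = 1/se_i², pooled
        se = (sum w_i)^(-1/2). ``"random"``: DerSimonian–Laird tau² is added
        to each variance before reweighting (requires >= 2 estimates).
        ``"auto"``: the random-effects model is used only when heterogeneity
        is significant — Q-test p below ``het_p_threshold`` AND I² above
        ``i2_threshold_pct`` — otherwise fixed.
    """
    k = len(estimates)
    if k == 0:
        raise ValueError("ivw_pool requires at least one estimate")
    if model not in ("fixed", "random", "auto"):
        raise ValueError("model must be 'fixed', 'random' or 'auto'")
    if model == "random" and k < 2:
        raise ValueError("random-effects pooling requires at least 2 estimates")

    r = np.array([e.ratio for e in estimates])
    w = np.array([e.weight for e in estimates])
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("non-finite or non-positive IVW weight")

    beta_fixed = float(np.sum(w * r) / np.sum(w))
    het = cochran_heterogeneity(estimates, beta_fixed) if k >= 2 else None

    if model == "auto":
        significant = (
            het is not None
            and het.p_value < het_p_threshold
            and het.i_squared_pct > i2_threshold_pct
        )
        model = "random" if significant else "fixed"

    if model == "fixed":
        beta, se = beta_fixed, float(np.sum(w) ** -0.5)
    else:
        tau2 = _dl_tau_squared(r, w, het.Q)
        w_star = 1.0 / (1.0 / w + tau2)
        beta = float(np.sum(w_star * r) / np.sum(w_star))
        se = float(np.sum(w_star) ** -0.5)

    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return PooledEstimate(
        beta=beta,
        se=se,
        or_=math.exp(beta),
        ci_low=math.exp(beta - Z_95 * se),
        ci_high=math.exp(beta + Z_95 * se),
        p_value=p,
        model=model,
        heterogeneity=het,
        n_instruments=k,
    )
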