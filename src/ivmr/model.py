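"""Model/Results interface over the two-sample MR estimators.

:class:`MRModel` is built from harmonized instruments (or directly from a
pair of summary-statistic datasets, which runs harmonization, the
instrument-validity filters and optional LD pruning); ``fit()`` returns an
:class:`MRResults` carrying the pooled IVW estimate, heterogeneity
diagnostics and the per-variant Wald table, with leave-one-out and MR-Egger
analyses, a text ``summary()`` and forest/LOO tables hanging off it.
"""

from __future__ import annotations

import datetime as _dt
import logging
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .core import (
    PooledEstimate,
    WaldEstimate,
    ivw_pool,
    wald_ratio,
)
from .harmonize import (
    HarmonizedInstrument,
    LdLookup,
    SelectionConfig,
    filter_instruments,
    harmonize,
    ld_prune,
)
from .io import SummaryDataset
from .sensitivity import EggerResult, LooResult, egger_regression, leave_one_out

logger = logging.getLogger("ivmr")


class MRModel:
    """Two-sample Mendelian randomization model on a set of instruments.

    Parameters
    ----------
    instruments
        Harmonized instruments (exposure and outcome effects on shared
        effect alleles). Use :meth:`from_datasets` to build them from raw
        summary statistics with the selection filters applied.
    se_method
        Wald-ratio SE method, ``"delta"`` (first-order delta method,
        default) or ``"paper-literal"`` (se_outcome/se_exposure).
    """

    def __init__(
        self,
        instruments: Sequence[HarmonizedInstrument],
        se_method: str = "delta",
    ) -> None:
        if not instruments:
            raise ValueError("MRModel requires at least one instrument")
        self.instruments: list[HarmonizedInstrument] = list(instruments)
        self.se_method = se_method
        self.provenance: str = ""

    @classmethod
    def from_datasets(
        cls,
        exposure: SummaryDataset,
        outcome: SummaryDataset,
        selection: SelectionConfig | None = None,
        ld_r2: LdLookup | None = None,
        se_method: str = "delta",
    ) -> "MRModel":
        """Harmonize, filter and (optionally) LD-prune two summary datasets.

        When ``ld_r2`` is None, pruning is skipped with a prominent warning —
        appropriate only for instrument sets whose independence was
        established upstream.
        """
        selection = selection or SelectionConfig()
        instruments = harmonize(
            exposure, outcome, palindromic_policy=selection.palindromic_policy
        )
        instruments = filter_instruments(instruments, selection)
        if ld_r2 is not None:
            instruments = ld_prune(instruments, ld_r2, selection)
        else:
            logger.warning(
                "no LD table supplied: pruning skipped; instrument "
                "independence is assumed, not checked"
            )
        if not instruments:
            raise ValueError("no instrument survived selection")
        model = cls(instruments, se_method=se_method)
        model.provenance = (
            f"exposure={exposure.trait_name!r} outcome={outcome.trait_name!r}"
        )
        return model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, se_method: str = "delta") -> "MRModel":
        """Build a model from a DataFrame of pre-harmonized effects.

        Required columns: ``beta_exposure, se_exposure, p_exposure,
        beta_outcome, se_outcome, p_outcome``; optional ``variant_id, chr,
        pos`` (defaulted when absent).
        """
        instruments = []
        for idx, row in df.reset_index(drop=True).iterrows():
            instruments.append(
                HarmonizedInstrument(
                    variant_id=str(row.get("variant_id", f"variant{idx + 1}")),
                    chromosome=str(row.get("chr", "0")),
                    position_bp=int(row.get("pos", 0)),
                    beta_exposure=float(row["beta_exposure"]),
                    se_exposure=float(row["se_exposure"]),
                    p_exposure=float(row["p_exposure"]),
                    beta_outcome=float(row["beta_outcome"]),
                    se_outcome=float(row["se_outcome"]),
                    p_outcome=float(row["p_outcome"]),
                )
            )
        return cls(instruments, se_method=se_method)

    def wald_estimates(self) -> list[WaldEstimate]:
        return [wald_ratio(i, se_method=self.se_method) for i in self.instruments]

    def fit(
        self,
        model: str = "auto",
        het_p_threshold: float = 0.01,
        i2_threshold_pct: float = 50.0,
    ) -> "MRResults":
        """Pool the per-variant Wald ratios by inverse-variance weighting."""
        pooled = ivw_pool(
            self.wald_estimates(),
            model=model,
            het_p_threshold=het_p_threshold,
            i2_threshold_pct=i2_threshold_pct,
        )
        return MRResults(self, pooled)


class MRResults:
    """Fitted two-sample MR results: pooled estimate, diagnostics, reports."""

    def __init__(self, model: MRModel, pooled: PooledEstimate) -> None:
        self.model = model
        self.pooled = pooled
        self.wald_estimates = model.wald_estimates()

    # convenience accessors
    @property
    def beta(self) -> float:
        return self.pooled.beta

    @property
    def se(self) -> float:
        return self.pooled.se

    @property
    def odds_ratio(self) -> float:
        return self.pooled.or_

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.pooled.ci_low, self.pooled.ci_high)

    @property
    def p_value(self) -> float:
        return self.pooled.p_value

    def leave_one_out(self, model: str | None = None) -> list[LooResult]:
        return leave_one_out(
            self.model.instruments,
            model=model or self.pooled.model,
            se_method=self.model.se_method,
        )

    def egger(self, p_method: str = "normal") -> EggerResult:
        return egger_regression(self.model.instruments, p_method=p_method)

    def forest_table(self) -> pd.DataFrame:
        """Per-variant OR/CI rows plus the pooled row (forest-plot data layer).

        The ``weight_pct`` column gives each variant's share of the total
        inverse-variance weight and sums to 100 over the variant rows.
        """
        total_w = sum(e.weight for e in self.wald_estimates)
        rows = [
            {
                "variant_id": e.variant_id,
                "or": _exp(e.ratio),
                "ci_low": _exp(e.ci_low),
                "ci_high": _exp(e.ci_high),
                "weight_pct": e.weight / total_w * 100.0,
            }
            for e in self.wald_estimates
        ]
        rows.append(
            {
                "variant_id": f"pooled ({self.pooled.model})",
                "or": self.pooled.or_,
                "ci_low": self.pooled.ci_low,
                "ci_high": self.pooled.ci_high,
                "weight_pct": 100.0,
            }
        )
        return pd.DataFrame(rows)

    def loo_table(self) -> pd.DataFrame:
        """One row per omitted variant: OR, CI, relative fluctuation."""
        return pd.DataFrame(
            [
                {
                    "omitted_variant": r.omitted_variant,
                    "or": r.pooled.or_,
                    "ci_low": r.pooled.ci_low,
                    "ci_high": r.pooled.ci_high,
                    "fluctuation": r.fluctuation,
                }
                for r in self.leave_one_out()
            ]
        )

    def to_report(self, include_sensitivity: bool = True) -> dict[str, Any]:
        """Full JSON-serializable report (validates against the shipped schema)."""
        het = self.pooled.heterogeneity
        report: dict[str, Any] = {
            "generated_at": _dt.datetime.now(_dt.timezone.utc).isoformat(),
            "package_version": __version__,
            "provenance": self.model.provenance,
            "se_method": self.model.se_method,
            "n_instruments": self.pooled.n_instruments,
            "pooled": {
                "beta": self.pooled.beta,
                "se": self.pooled.se,
                "or": self.pooled.or_,
                "ci_low": self.pooled.ci_low,
                "ci_high": self.pooled.ci_high,
                "p_value": self.pooled.p_value,
                "model": self.pooled.model,
            },
            "heterogeneity": None
            if het is None
            else {
                "Q": het.Q,
                "df": het.df,
                "p_value": het.p_value,
                "i_squared_pct": het.i_squared_pct,
            },
            "variants": [
                {
                    "variant_id": e.variant_id,
                    "ratio": e.ratio,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "weight": e.weight,
                }
                for e in self.wald_estimates
            ],
            "leave_one_out": None,
            "egger": None,
        }
        if include_sensitivity and self.pooled.n_instruments >= 3:
            report["leave_one_out"] = [
                {
                    "omitted_variant": r.omitted_variant,
                    "or": r.pooled.or_,
                    "ci_low": r.pooled.ci_low,
                    "ci_high": r.pooled.ci_high,
                    "fluctuation": r.fluctuation,
                }
                for r in self.leave_one_out()
            ]
            eg = self.egger()
            report["egger"] = {
                "slope": eg.slope,
                "slope_se": eg.slope_se,
                "slope_ci_low": eg.slope_ci_low,
                "slope_ci_high": eg.slope_ci_high,
                "slope_p": eg.slope_p,
                "intercept": eg.intercept,
                "intercept_se": eg.intercept_se,
                "intercept_ci_low": eg.intercept_ci_low,
                "intercept_ci_high": eg.intercept_ci_high,
                "intercept_p": eg.intercept_p,
                "n_instruments": eg.n_instruments,
                "overdispersion": eg.overdispersion,
            }
        return report

    def summary(self) -> str:
        """Human-readable summary table."""
        het = self.pooled.heterogeneity
        lines = [
            "Two-sample Mendelian randomization (IVW)",
            "=" * 56,
            f"instruments: {self.pooled.n_instruments}    "
            f"model: {self.pooled.model}    SE method: {self.model.se_method}",
            f"beta (log-OR per SD exposure): {self.pooled.beta:.6f}  "
            f"(SE {self.pooled.se:.6f})",
            f"OR: {self.pooled.or_:.4f}  95% CI ({self.pooled.ci_low:.4f}, "
            f"{self.pooled.ci_high:.4f})  P = {self.pooled.p_value:.4g}",
        ]
        if het is not None:
            lines.append(
                f"heterogeneity: Q = {het.Q:.4f} (df {het.df}), "
                f"P = {het.p_value:.4g}, I² = {het.i_squared_pct:.1f}%"
            )
        lines.append("-" * 56)
        lines.append(f"{'variant':<12}{'OR':>10}{'95% CI':>24}{'weight %':>10}")
        forest = self.forest_table()
        for _, row in forest.iterrows():
            lines.append(
                f"{row['variant_id']:<12}{row['or']:>10.4f}"
                f"{'(' + format(row['ci_low'], '.4f') + ', ' + format(row['ci_high'], '.4f') + ')':>24}"
                f"{row['weight_pct']:>10.2f}"
            )
        return "\n".join(lines)


def _exp(x: float) -> float:
    import math

    return math.exp(x)
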