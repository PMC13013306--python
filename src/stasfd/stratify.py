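"""Cutoff-based risk stratification.

Patients are dichotomized at a probability cutoff (rule: predicted
probability >= cutoff puts a patient in the high-risk group), and the
stratification is summarized by group sizes, STAS prevalence per group,
positive/negative predictive values, and a continuity-corrected chi-square
comparison of STAS prevalence between groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .cohort_stats import Chi2Result, ContingencyTable2x2, pearson_chi2

__all__ = ["RiskStratification", "stratify_by_cutoff", "round_half_up"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as in the printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RiskStratification:
    cutoff: float
    n_high: int
    n_low: int
    stas_high: int
    stas_low: int
    chi2: Chi2Result

    @property
    def n(self) -> int:
        return self.n_high + self.n_low

    @property
    def ppv(self) -> float:
        """Fraction of high-risk patients who are STAS-positive."""
        return self.stas_high / self.n_high

    @property
    def npv(self) -> float:
        """Fraction of low-risk patients who are STAS-negative."""
        return (self.n_low - self.stas_low) / self.n_low

    @property
    def prevalence_high(self) -> float:
        return self.stas_high / self.n_high

    @property
    def prevalence_low(self) -> float:
        return self.stas_low / self.n_low

    @property
    def prevalence_overall(self) -> float:
        return (self.stas_high + self.stas_low) / self.n

    def to_table(self) -> pd.DataFrame:
        """Report table with percentages rounded half-up to 2 decimals."""
        pct = lambda v: round_half_up(100.0 * v, 2)
        return pd.DataFrame([
            {"group": "overall", "n": self.n, "stas_positive": self.stas_high + self.stas_low,
             "stas_prevalence_pct": pct(self.prevalence_overall), "ppv_pct": None, "npv_pct": None},
            {"group": f"high_risk(>={self.cutoff:g})", "n": self.n_high, "stas_positive": self.stas_high,
             "stas_prevalence_pct": pct(self.prevalence_high), "ppv_pct": pct(self.ppv), "npv_pct": None},
            {"group": f"low_risk(<{self.cutoff:g})", "n": self.n_low, "stas_positive": self.stas_low,
             "stas_prevalence_pct": pct(self.prevalence_low), "ppv_pct": None, "npv_pct": pct(self.npv)},
        ])

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "n_high": self.n_high, "n_low": self.n_low,
            "stas_high": self.stas_high, "stas_low": self.stas_low,
            "ppv_pct": round_half_up(100 * self.ppv),
            "npv_pct": round_half_up(100 * self.npv),
            "prevalence_high_pct": round_half_up(100 * self.prevalence_high),
            "prevalence_low_pct": round_half_up(100 * self.prevalence_low),
            "prevalence_overall_pct": round_half_up(100 * self.prevalence_overall),
            "chi2_statistic": self.chi2.statistic,
            "chi2_p_value": self.chi2.p_value,
            "chi2_continuity_corrected": self.chi2.continuity_corrected,
        }


def stratify_by_cutoff(probabilities, labels, cutoff: float, yates: bool = True) -> RiskStratification:
    """Dichotomize at ``cutoff`` and compare STAS prevalence between groups.

    High-risk means predicted probability >= cutoff.  The group comparison
    uses the Yates continuity-corrected chi-square by default (``yates=False``
    gives the uncorrected statistic).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    if len(p) != len(y):
        raise ValueError("probabilities and labels must have the same length")
    high = p >= cutoff
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError(
            "one risk group is empty; review the cutoff against the score distribution"
        )
    stas_high = int(y[high].sum())
    stas_low = int(y[~high].sum())
    table = ContingencyTable2x2(
        a=stas_high, b=stas_low,
        c=n_high - stas_high, d=n_low - stas_low,
    )
    chi2 = pearson_chi2(table, yates=yates)
    return RiskStratification(
        cutoff=float(cutoff),
        n_high=n_high, n_low=n_low,
        stas_high=stas_high, stas_low=stas_low,
        chi2=chi2,
    )
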