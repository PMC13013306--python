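"""Nomogram construction and model evaluation.

A nomogram renders a fitted logistic model as a points system: each
predictor's value maps linearly to 0-100 points (the predictor with the
largest coefficient-times-range product spans the full 100), and the summed
points map monotonically back to a predicted probability through the fitted
linear predictor.  Evaluation covers discrimination (empirical ROC with a
percentile-bootstrap AUC interval and the Youden-index cutoff), calibration
(Hosmer-Lemeshow deciles-of-risk test and a bootstrap-smoothed calibration
curve) and clinical utility (decision-curve analysis, i.e. net benefit over
a grid of threshold probabilities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort_stats import LogisticFit

__all__ = [
    "NomogramSpec",
    "RocResult",
    "HosmerLemeshowResult",
    "CalibrationReport",
    "DcaCurve",
    "build_nomogram",
    "reference_equation_score",
    "roc_analysis",
    "auc_mann_whitney",
    "hosmer_lemeshow",
    "bootstrap_calibration",
    "decision_curve",
]


def _expit(eta):
    return 1.0 / (1.0 + np.exp(-np.asarray(eta, dtype=float)))


# ---------------------------------------------------------------------------
# nomogram

@dataclass
class NomogramSpec:
    """Points rendering of a logistic model.

    ``ref_values`` holds, per predictor, the end of its range at which the
    contribution to the linear predictor is smallest (the low end for a
    positive coefficient, the high end for a negative one), so points are
    always non-negative and the total-points-to-probability map is monotone
    increasing.
    """

    feature_names: list[str]
    coef: np.ndarray                 # per-predictor coefficients (no intercept)
    intercept: float
    ranges: list[tuple[float, float]]
    ref_values: np.ndarray
    scale: float                     # max_j |beta_j| * range_j, the 100-point unit

    def points(self, feature: str, value) -> np.ndarray:
        i = self.feature_names.index(feature)
        v = np.asarray(value, dtype=float)
        return 100.0 * self.coef[i] * (v - self.ref_values[i]) / self.scale

    def total_points(self, values) -> np.ndarray:
        V = np.atleast_2d(np.asarray(values, dtype=float))
        return 100.0 * (V - self.ref_values) @ self.coef / self.scale

    def probability_from_points(self, total_points) -> np.ndarray:
        eta_base = self.intercept + float(self.ref_values @ self.coef)
        return _expit(eta_base + self.scale * np.asarray(total_points, dtype=float) / 100.0)

    def predict_probability(self, values) -> np.ndarray:
        V = np.atleast_2d(np.asarray(values, dtype=float))
        return _expit(self.intercept + V @ self.coef)

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "ranges": [list(r) for r in self.ranges],
            "ref_values": self.ref_values.tolist(),
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NomogramSpec":
        return cls(
            feature_names=list(d["feature_names"]),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            ranges=[tuple(r) for r in d["ranges"]],
            ref_values=np.asarray(d["ref_values"], dtype=float),
            scale=float(d["scale"]),
        )


def build_nomogram(fit: LogisticFit, ranges: dict[str, tuple[float, float]]) -> NomogramSpec:
    """Turn a converged logistic fit into a 0-100 points nomogram.

    ``ranges`` gives each predictor's displayed value range (e.g. observed
    min/max).  The predictor with the largest ``|coefficient| * range``
    spans exactly 100 points; every other axis is scaled proportionally.
    """
    if not fit.converged:
        raise ValueError("nomogram requires a converged logistic fit")
    names = fit.feature_names
    missing = [n for n in names if n not in ranges]
    if missing:
        raise ValueError(f"no value range given for predictors {missing}")
    coef = np.asarray(fit.coef[1:], dtype=float)
    rng_list = [tuple(map(float, ranges[n])) for n in names]
    spans = np.array([hi - lo for lo, hi in rng_list])
    if (spans <= 0).any():
        bad = [n for n, s in zip(names, spans) if s <= 0]
        raise ValueError(f"zero or negative value range for predictors {bad}")
    weight = np.abs(coef) * spans
    scale = float(weight.max())
    if scale <= 0:
        raise ValueError("all coefficients are zero; nomogram undefined")
    ref = np.array([lo if b >= 0 else hi for b, (lo, hi) in zip(coef, rng_list)])
    return NomogramSpec(
        feature_names=list(names),
        coef=coef,
        intercept=float(fit.coef[0]),
        ranges=rng_list,
        ref_values=ref,
        scale=scale,
    )


def reference_equation_score(ctr, morph_irregularity, lobulation, fd3d):
    """Fixed reference linear score of the STAS nomogram.

    ``-2.1 + 0.3*CTR + 0.2*morphological_irregularity + 0.15*lobulation +
    0.4*FD3D``, with CTR on the 0-100 percent scale and the two CT signs
    coded 0/1.  The coefficients are kept verbatim as reported for the
    original clinical model; note that the positive FD 3D weight is at odds
    with STAS-positive tumors having *lower* FD 3D, and no sign
    reconciliation is attempted here (see docs/methods.md).
    """
    return (
        -2.1
        + 0.3 * np.asarray(ctr, dtype=float)
        + 0.2 * np.asarray(morph_irregularity, dtype=float)
        + 0.15 * np.asarray(lobulation, dtype=float)
        + 0.4 * np.asarray(fd3d, dtype=float)
    )


# ---------------------------------------------------------------------------
# ROC

@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    youden_cutoff: float
    sensitivity: float
    specificity: float
    n_boot: int
    seed: int


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _sens_spec(scores, labels, cutoff) -> tuple[float, float]:
    y = np.asarray(labels, dtype=int)
    pred = np.asarray(scores, dtype=float) >= cutoff
    sens = float(pred[y == 1].mean())
    spec = float((~pred[y == 0]).mean())
    return sens, spec


def roc_analysis(probabilities, labels, n_boot: int = 2000, seed: int = 0) -> RocResult:
    """Empirical ROC, trapezoid AUC, percentile-bootstrap CI, Youden cutoff.

    Classification rule at a cutoff ``t`` is ``probability >= t``.  The
    Youden cutoff maximizes sensitivity + specificity - 1 over all distinct
    scores, ties broken toward the lowest cutoff (favoring sensitivity).
    The trapezoid AUC over the full empirical curve equals the Mann-Whitney
    concordance estimator.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(y, p, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    cutoffs = np.unique(p)
    best_j, best_cut, best_ss = -np.inf, cutoffs[0], (0.0, 0.0)
    for c in cutoffs:  # ascending, so ties keep the lowest cutoff
        sens, spec = _sens_spec(p, y, c)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_cut, best_ss = j, float(c), (sens, spec)
    rng = np.random.default_rng(seed)
    n = len(y)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        guard = 0
        while len(np.unique(y[idx])) < 2:
            idx = rng.integers(0, n, n)
            guard += 1
            if guard > 1000:
                raise RuntimeError("cannot draw a two-class bootstrap resample")
        boot[b] = auc_mann_whitney(p[idx], y[idx])
    lo, hi = (np.percentile(boot, [2.5, 97.5]) if n_boot > 0 else (auc, auc))
    return RocResult(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
        ci_low=float(lo), ci_high=float(hi),
        youden_cutoff=best_cut, sensitivity=best_ss[0], specificity=best_ss[1],
        n_boot=n_boot, seed=seed,
    )


# ---------------------------------------------------------------------------
# calibration

@dataclass
class HosmerLemeshowResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame


def _risk_bins(p: np.ndarray, g: int) -> np.ndarray:
    """Quantile bin index per observation; tied probabilities share a bin."""
    codes = pd.qcut(p, q=g, labels=False, duplicates="drop")
    return np.asarray(codes, dtype=int)


def hosmer_lemeshow(probabilities, labels, g: int = 10) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow goodness-of-fit over deciles of predicted risk.

    The statistic is ``sum_b (O_b - E_b)^2 / (E_b (1 - p_bar_b))`` with
    ``p_bar_b`` the mean predicted risk in bin b, referred to chi-square on
    ``g - 2`` degrees of freedom (the convention for probabilities produced
    by a fitted logistic model).  Bins with expected counts of 0 or n are
    merged with a neighbor, with a warning.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(p) < 2 * g:
        raise ValueError(f"need at least {2 * g} observations for g={g} bins")
    codes = _risk_bins(p, g)
    bins = []
    for b in sorted(np.unique(codes)):
        m = codes == b
        bins.append([int(m.sum()), int(y[m].sum()), float(p[m].sum()), float(p[m].mean())])
    # merge degenerate bins (expected events 0 or all) into a neighbor
    i = 0
    while i < len(bins):
        nb, ob, eb, _ = bins[i]
        if (eb < 1e-9 or eb > nb - 1e-9) and len(bins) > 1:
            warnings.warn("merging degenerate risk bin with neighbor", stacklevel=2)
            j = i + 1 if i + 1 < len(bins) else i - 1
            nb2, ob2, eb2, _ = bins[j]
            merged = [nb + nb2, ob + ob2, eb + eb2, (eb + eb2) / (nb + nb2)]
            bins[min(i, j)] = merged
            del bins[max(i, j)]
            i = 0
        else:
            i += 1
    stat = 0.0
    rows = []
    for nb, ob, eb, pbar in bins:
        stat += (ob - eb) ** 2 / (eb * (1.0 - pbar)) if 0 < pbar < 1 else 0.0
        rows.append({"n": nb, "observed": ob, "expected": eb, "mean_predicted": pbar})
    df = max(len(bins) - 2, 1)
    return HosmerLemeshowResult(
        statistic=float(stat), df=df,
        p_value=float(sps.chi2.sf(stat, df)),
        table=pd.DataFrame(rows),
    )


@dataclass
class CalibrationReport:
    hosmer_lemeshow: HosmerLemeshowResult
    apparent: pd.DataFrame          # per-bin mean predicted vs observed rate
    boot_mean: pd.DataFrame         # bootstrap-smoothed curve on the apparent grid
    n_boot: int
    seed: int


def _binned_curve(p: np.ndarray, y: np.ndarray, g: int) -> pd.DataFrame:
    codes = _risk_bins(p, g)
    rows = []
    for b in sorted(np.unique(codes)):
        m = codes == b
        rows.append({"mean_predicted": float(p[m].mean()), "observed_rate": float(y[m].mean()), "n": int(m.sum())})
    return pd.DataFrame(rows)


def bootstrap_calibration(probabilities, labels, n_boot: int = 1000, seed: int = 0, g: int = 10) -> CalibrationReport:
    """Bootstrap-smoothed calibration curve plus the Hosmer-Lemeshow test.

    Each resample (with replacement) is re-binned into risk deciles and its
    observed-vs-predicted curve interpolated onto the apparent curve's
    predicted-risk grid; the report carries the pointwise mean and 2.5/97.5
    percentile band.  Deterministic for a fixed seed.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    hl = hosmer_lemeshow(p, y, g=g)
    apparent = _binned_curve(p, y, g)
    grid = apparent["mean_predicted"].to_numpy()
    rng = np.random.default_rng(seed)
    n = len(y)
    curves = np.empty((n_boot, len(grid)))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        guard = 0
        while len(np.unique(y[idx])) < 2:
            idx = rng.integers(0, n, n)
            guard += 1
            if guard > 1000:
                raise RuntimeError("cannot draw a two-class bootstrap resample")
        cb = _binned_curve(p[idx], y[idx], g)
        curves[b] = np.interp(grid, cb["mean_predicted"], cb["observed_rate"])
    boot_mean = pd.DataFrame({
        "mean_predicted": grid,
        "observed_rate_mean": curves.mean(axis=0),
        "observed_rate_lo": np.percentile(curves, 2.5, axis=0),
        "observed_rate_hi": np.percentile(curves, 97.5, axis=0),
    })
    return CalibrationReport(hosmer_lemeshow=hl, apparent=apparent, boot_mean=boot_mean, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# decision-curve analysis

@dataclass
class DcaCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray

    def useful_range(self) -> tuple[float, float] | None:
        """Threshold band where the model beats both treat-all and treat-none."""
        better = self.nb_model > np.maximum(self.nb_all, 0.0)
        if not better.any():
            return None
        t = self.thresholds[better]
        return float(t.min()), float(t.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "net_benefit_model": self.nb_model,
            "net_benefit_all": self.nb_all,
            "net_benefit_none": self.nb_none,
        })


def decision_curve(probabilities, labels, thresholds=None) -> DcaCurve:
    """Net benefit of the model vs treat-all and treat-none strategies.

    ``NB_model(t) = TP(t)/n - FP(t)/n * t/(1-t)`` with the classification
    rule ``probability >= t``; ``NB_all(t) = prevalence -
    (1 - prevalence) * t/(1-t)``; treat-none is identically zero.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if thresholds is None:
        thresholds = np.round(np.arange(1, 100) / 100.0, 2)
    t = np.asarray(thresholds, dtype=float)
    if (t >= 1.0).any() or (t <= 0.0).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prev = y.mean()
    odds = t / (1.0 - t)
    pred = p[None, :] >= t[:, None]
    tp = (pred & (y == 1)[None, :]).sum(axis=1) / n
    fp = (pred & (y == 0)[None, :]).sum(axis=1) / n
    nb_model = tp - fp * odds
    nb_all = prev - (1.0 - prev) * odds
    return DcaCurve(thresholds=t, nb_model=nb_model, nb_all=nb_all, nb_none=np.zeros_like(t))
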