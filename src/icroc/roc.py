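"""Bi-distributional (Universal) and empirical ROC curves and their AUC.

A Bi-distributional ROC model assumes a distribution family for the
negative-class scores (F0) and one for the positive-class scores (F1).
The resulting curve is the composition ``R(p) = 1 - F1(F0^{-1}(1 - p))``,
valid for any pair of continuous score distributions; the area under it is
obtained by adaptive Gauss–Kronrod quadrature.  Empirical curves are built
from score/label samples with thresholds at the unique score values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate
from sklearn.metrics import roc_curve as _sk_roc_curve

from .families import FittedDistribution, ParamVector

__all__ = [
    "BiDistributionPair",
    "ROCCurve",
    "uroc_function",
    "roc_points_at_pooled_thresholds",
    "empirical_roc",
    "auc",
]

# probabilities are kept strictly interior before quantile inversion
_P_EPS = 1e-12


def _as_fitted(dist) -> FittedDistribution:
    if isinstance(dist, FittedDistribution):
        return dist
    if isinstance(dist, ParamVector):
        return FittedDistribution(spec=dist, loglik=float("nan"), n=0)
    raise TypeError(f"expected ParamVector or FittedDistribution, got {type(dist)!r}")


@dataclass
class BiDistributionPair:
    """A fitted positive-class / negative-class distribution pair.

    ``label`` lists the positive family first, e.g. ``"Weibull-Gamma"``.
    """

    pos: FittedDistribution
    neg: FittedDistribution
    label: str = ""

    def __post_init__(self) -> None:
        self.pos = _as_fitted(self.pos)
        self.neg = _as_fitted(self.neg)
        if not self.label:
            self.label = f"{self.pos.spec.family.value}-{self.neg.spec.family.value}"

    @classmethod
    def from_params(cls, pos: ParamVector, neg: ParamVector, label: str = "") -> "BiDistributionPair":
        return cls(pos=_as_fitted(pos), neg=_as_fitted(neg), label=label)

    def swapped(self) -> "BiDistributionPair":
        """The pair with the two classes exchanged."""
        return BiDistributionPair(pos=self.neg, neg=self.pos)


@dataclass
class ROCCurve:
    """An ordered (FPR, TPR) point set from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    kind: str = "empirical"  # "parametric" | "empirical"
    source: str = ""
    thresholds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if self.fpr.shape != self.tpr.shape or self.fpr.size < 2:
            raise ValueError("fpr and tpr must be equal-length vectors of size >= 2")
        if np.any(np.diff(self.fpr) < 0):
            raise ValueError("fpr must be nondecreasing")

    def __len__(self) -> int:
        return self.fpr.size


def uroc_function(pair: BiDistributionPair) -> Callable[[np.ndarray], np.ndarray]:
    """The Bi-distributional ROC as a function R on [0, 1].

    ``R(p) = 1 - F1(F0^{-1}(1 - p))`` for interior p, with R(0)=0 and
    R(1)=1 pinned exactly; values are clipped to [0, 1].
    """
    pos = pair.pos.spec.frozen()
    neg = pair.neg.spec.frozen()

    def R(p):
        p = np.asarray(p, dtype=float)
        scalar = p.ndim == 0
        p = np.atleast_1d(p)
        q = np.clip(p, _P_EPS, 1.0 - _P_EPS)
        with np.errstate(over="ignore", invalid="ignore"):
            out = 1.0 - pos.cdf(neg.ppf(1.0 - q))
        out = np.clip(np.nan_to_num(out, nan=0.0), 0.0, 1.0)
        out[p <= 0.0] = 0.0
        out[p >= 1.0] = 1.0
        return out[0] if scalar else out

    return R


def roc_points_at_pooled_thresholds(pair: BiDistributionPair, pooled) -> ROCCurve:
    """Parametric ROC points evaluated at an observed pooled threshold set.

    Each threshold x contributes the point ``(1 - F0(x), 1 - F1(x))``;
    points are ordered by decreasing threshold so FPR is nondecreasing, and
    the endpoints (0,0) and (1,1) are appended.
    """
    x = np.sort(np.asarray(pooled, dtype=float).ravel())[::-1]
    if x.size == 0:
        raise ValueError("pooled threshold set must be nonempty")
    fpr = 1.0 - pair.neg.spec.frozen().cdf(x)
    tpr = 1.0 - pair.pos.spec.frozen().cdf(x)
    fpr = np.concatenate([[0.0], np.clip(fpr, 0.0, 1.0), [1.0]])
    tpr = np.concatenate([[0.0], np.clip(tpr, 0.0, 1.0), [1.0]])
    fpr = np.maximum.accumulate(fpr)  # guard against tiny cdf roundoff
    tpr = np.maximum.accumulate(tpr)
    thresholds = np.concatenate([[np.inf], x, [-np.inf]])
    return ROCCurve(fpr=fpr, tpr=tpr, kind="parametric", source=pair.label, thresholds=thresholds)


def roc_points_on_grid(pair: BiDistributionPair, num: int = 512) -> ROCCurve:
    """Parametric ROC points on a uniform FPR grid of ``num`` interior points."""
    p = np.linspace(0.0, 1.0, num + 2)
    R = uroc_function(pair)
    return ROCCurve(fpr=p, tpr=np.maximum.accumulate(R(p)), kind="parametric", source=pair.label)


def empirical_roc(scores, labels) -> ROCCurve:
    """Empirical ROC with thresholds at unique score values, ties grouped.

    Scores tied at a threshold move the curve in a single (diagonal) step,
    matching the trapezoidal-AUC convention of standard ROC routines.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    present = np.unique(labels)
    if not np.array_equal(present, [0, 1]):
        for cls in (0, 1):
            if cls not in present:
                raise ValueError(f"class {cls} is absent from labels")
        raise ValueError(f"labels must be 0/1, got values {present}")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:  # pragma: no cover - sklearn guarantees
        fpr = np.append(fpr, 1.0)
        tpr = np.append(tpr, 1.0)
        thr = np.append(thr, -np.inf)
    return ROCCurve(fpr=fpr, tpr=tpr, kind="empirical", source="scores", thresholds=thr)


def auc(curve_or_pair) -> float:
    """Area under the curve.

    Parametric pairs are integrated by adaptive Gauss–Kronrod quadrature of
    R(p) on [0, 1] to absolute tolerance 1e-8 (with a dense trapezoid
    fallback if the quadrature fails to converge); empirical curves use the
    trapezoidal rule on the stored point set.
    """
    if isinstance(curve_or_pair, BiDistributionPair):
        R = uroc_function(curve_or_pair)
        with warnings.catch_warnings():
            warnings.simplefilter("error", integrate.IntegrationWarning)
            try:
                value, _ = integrate.quad(R, 0.0, 1.0, epsabs=1e-8, epsrel=1e-8, limit=200)
            except integrate.IntegrationWarning:
                warnings.warn(
                    "Gauss-Kronrod quadrature did not converge; "
                    "falling back to a 10^4-point trapezoid",
                    stacklevel=2,
                )
                p = np.linspace(0.0, 1.0, 10_001)
                value = float(np.trapezoid(R(p), p))
        return float(min(max(value, 0.0), 1.0))
    if isinstance(curve_or_pair, ROCCurve):
        c = curve_or_pair
        return float(np.trapezoid(c.tpr, c.fpr))
    raise TypeError(f"expected BiDistributionPair or ROCCurve, got {type(curve_or_pair)!r}")
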