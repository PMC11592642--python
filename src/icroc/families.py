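"""Seven score-distribution families with density, cdf, quantile, sampling and ML fitting.

The families (Normal, Exponential, Weibull, Gamma, EV, GEV, GP) are the
candidate marginals for the negative- and positive-class score distributions
of a Bi-distributional ROC model.  Parameterizations are canonical:

* ``Normal(mu, sigma)`` — mean and standard deviation, ``sigma > 0``;
* ``Exponential(mu)`` — **mean** parameterized, ``mu > 0``;
* ``Weibull(alpha, beta)`` — shape ``alpha > 0``, scale ``beta > 0``;
* ``Gamma(alpha, beta)`` — shape ``alpha > 0``, **rate** ``beta > 0``
  (the reporting layer may print the scale ``1/beta``);
* ``EV(mu, sigma)`` — minimum-type Gumbel (extreme value), location/scale;
* ``GEV(k, sigma, mu)`` — generalized extreme value with shape ``k``
  (``k > 0`` heavy right tail, ``k = 0`` the Gumbel limit);
* ``GP(k, sigma, mu)`` — generalized Pareto; support ``x >= mu`` for
  ``k >= 0`` and ``mu <= x <= mu - sigma/k`` for ``k < 0``.

Weibull and Gamma maximum-likelihood estimates are obtained from their
score equations (profile shape equation for the Weibull; digamma equation
for the Gamma) solved to tight tolerance, so the returned estimates satisfy
the likelihood equations to better than 1e-8.  Normal and Exponential have
closed-form MLEs; EV/GEV/GP are fitted by numeric likelihood maximization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "Family",
    "FAMILY_ORDER",
    "PARAM_NAMES",
    "ParamVector",
    "FittedDistribution",
    "ParameterDomainError",
    "FitInfeasibleError",
    "pdf",
    "cdf",
    "icdf",
    "sample",
    "fit_mle",
    "loglik",
]


class Family(str, Enum):
    """Canonical family tags, in the fixed order used wherever pairs are enumerated."""

    NORMAL = "Normal"
    EXPONENTIAL = "Exponential"
    WEIBULL = "Weibull"
    GAMMA = "Gamma"
    EV = "EV"
    GEV = "GEV"
    GP = "GP"


FAMILY_ORDER: tuple[Family, ...] = tuple(Family)

PARAM_NAMES: dict[Family, tuple[str, ...]] = {
    Family.NORMAL: ("mu", "sigma"),
    Family.EXPONENTIAL: ("mu",),
    Family.WEIBULL: ("alpha", "beta"),
    Family.GAMMA: ("alpha", "beta"),
    Family.EV: ("mu", "sigma"),
    Family.GEV: ("k", "sigma", "mu"),
    Family.GP: ("k", "sigma", "mu"),
}

#: Families whose support is the strictly positive half line (for fitting).
POSITIVE_FAMILIES = frozenset(
    {Family.EXPONENTIAL, Family.WEIBULL, Family.GAMMA}
)


class ParameterDomainError(ValueError):
    """A distribution parameter violates its domain constraint."""


class FitInfeasibleError(ValueError):
    """The data lie outside the family's support; the fit cannot be attempted."""


@dataclass(frozen=True)
class ParamVector:
    """A family tag plus its named parameter values."""

    family: Family
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        names = PARAM_NAMES[self.family]
        got = tuple(self.params)
        if set(got) != set(names):
            raise ParameterDomainError(
                f"{self.family.value} expects parameters {names}, got {got}"
            )
        object.__setattr__(self, "params", dict(self.params))
        self._validate()

    def _validate(self) -> None:
        p = self.params
        fam = self.family
        if fam is Family.NORMAL and p["sigma"] <= 0:
            raise ParameterDomainError("Normal requires sigma > 0")
        if fam is Family.EXPONENTIAL and p["mu"] <= 0:
            raise ParameterDomainError("Exponential requires mean mu > 0")
        if fam in (Family.WEIBULL, Family.GAMMA):
            if p["alpha"] <= 0:
                raise ParameterDomainError(f"{fam.value} requires shape alpha > 0")
            if p["beta"] <= 0:
                raise ParameterDomainError(
                    f"{fam.value} requires {'scale' if fam is Family.WEIBULL else 'rate'} beta > 0"
                )
        if fam is Family.EV and p["sigma"] <= 0:
            raise ParameterDomainError("EV requires sigma > 0")
        if fam in (Family.GEV, Family.GP) and p["sigma"] <= 0:
            raise ParameterDomainError(f"{fam.value} requires sigma > 0")
        for name, value in p.items():
            if not math.isfinite(value):
                raise ParameterDomainError(f"{fam.value} parameter {name} is not finite")

    def frozen(self):
        """The equivalent scipy.stats frozen distribution."""
        p = self.params
        fam = self.family
        if fam is Family.NORMAL:
            return stats.norm(loc=p["mu"], scale=p["sigma"])
        if fam is Family.EXPONENTIAL:
            return stats.expon(scale=p["mu"])
        if fam is Family.WEIBULL:
            return stats.weibull_min(p["alpha"], scale=p["beta"])
        if fam is Family.GAMMA:
            return stats.gamma(p["alpha"], scale=1.0 / p["beta"])
        if fam is Family.EV:
            # minimum-type Gumbel: pdf (1/sigma) e^z exp(-e^z), z=(x-mu)/sigma
            return stats.gumbel_l(loc=p["mu"], scale=p["sigma"])
        if fam is Family.GEV:
            # scipy's shape c is the negative of the k convention used here
            return stats.genextreme(-p["k"], loc=p["mu"], scale=p["sigma"])
        if fam is Family.GP:
            return stats.genpareto(p["k"], loc=p["mu"], scale=p["sigma"])
        raise AssertionError(f"unhandled family {fam}")  # pragma: no cover

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(self.params[name] for name in PARAM_NAMES[self.family])

    def __repr__(self) -> str:  # e.g. Weibull(alpha=2, beta=1)
        inner = ", ".join(f"{k}={v:g}" for k, v in self.params.items())
        return f"{self.family.value}({inner})"


@dataclass
class FittedDistribution:
    """One family fitted to one class sample by maximum likelihood."""

    spec: ParamVector
    loglik: float
    n: int
    converged: bool = True
    notes: str = ""

    def to_record(self) -> dict:
        return {
            "family": self.spec.family.value,
            "params": dict(self.spec.params),
            "loglik": self.loglik,
            "n": self.n,
            "converged": self.converged,
            "notes": self.notes,
        }

    @classmethod
    def from_record(cls, rec: Mapping) -> "FittedDistribution":
        return cls(
            spec=ParamVector(Family(rec["family"]), rec["params"]),
            loglik=float(rec["loglik"]),
            n=int(rec["n"]),
            converged=bool(rec.get("converged", True)),
            notes=str(rec.get("notes", "")),
        )


# ---------------------------------------------------------------------------
# Elementary operations


def pdf(spec: ParamVector, x) -> np.ndarray:
    """Density of ``spec`` at ``x``; exactly zero outside the support."""
    return np.asarray(spec.frozen().pdf(np.asarray(x, dtype=float)))


def cdf(spec: ParamVector, x) -> np.ndarray:
    return np.asarray(spec.frozen().cdf(np.asarray(x, dtype=float)))


def icdf(spec: ParamVector, p) -> np.ndarray:
    """Quantile function; endpoints map to the support infimum/supremum."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("probabilities must lie in [0, 1]")
    return np.asarray(spec.frozen().ppf(p))


def sample(spec: ParamVector, n: int, seed: int) -> np.ndarray:
    """Inverse-transform sample of size ``n``, reproducible for a fixed seed."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    # keep u strictly interior so every family maps into its open support
    u = np.clip(u, 1e-16, 1.0 - 1e-16)
    return np.asarray(spec.frozen().ppf(u))


def loglik(spec: ParamVector, data: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        return float(np.sum(spec.frozen().logpdf(np.asarray(data, dtype=float))))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting


def _require_positive(family: Family, data: np.ndarray) -> None:
    if np.min(data) <= 0.0:
        raise FitInfeasibleError(
            f"{family.value} requires strictly positive data "
            f"(min = {np.min(data):g})"
        )


def weibull_profile_residuals(alpha: float, beta: float, data: np.ndarray) -> tuple[float, float]:
    """Residuals of the two Weibull likelihood equations at (alpha, beta).

    The first equation expresses the scale through the shape,
    ``beta = (mean(x^alpha))^(1/alpha)``; the second is the shape score
    equation.  Both residuals vanish at the MLE.
    """
    x = np.asarray(data, dtype=float)
    n = x.size
    logx = np.log(x)
    xa = np.exp(alpha * (logx - logx.max()))  # scaled to avoid overflow
    beta_hat = math.exp(logx.max() + math.log(np.mean(xa)) / alpha)
    r1 = beta - beta_hat
    z = logx - math.log(beta)
    xb = np.exp(alpha * z)  # (x/beta)^alpha
    denom = n * math.log(beta) + float(np.sum(xb * z)) * 1.0 - float(np.sum(logx))
    # shape equation written as alpha = n / (n log beta + sum (x/b)^a log(x/b) - sum log x)
    r2 = alpha - n / denom if denom != 0 else math.inf
    return r1, r2


def _fit_weibull(data: np.ndarray) -> tuple[ParamVector, bool, str]:
    x = np.asarray(data, dtype=float)
    logx = np.log(x)
    mlog = float(np.mean(logx))

    def profile(alpha: float) -> float:
        # d/dalpha of the profile log-likelihood, up to a positive factor
        w = np.exp(alpha * (logx - logx.max()))
        return 1.0 / alpha + mlog - float(np.sum(w * logx) / np.sum(w))

    # method-of-moments start via the log-variance of a Weibull
    s = float(np.std(logx))
    a0 = (math.pi / math.sqrt(6.0)) / s if s > 0 else 1.0
    lo, hi = a0, a0
    while profile(lo) < 0 and lo > 1e-8:
        lo /= 2.0
    while profile(hi) > 0 and hi < 1e8:
        hi *= 2.0
    if not (profile(lo) >= 0 >= profile(hi)):
        return (
            ParamVector(Family.WEIBULL, {"alpha": max(a0, 1e-8), "beta": float(np.mean(x))}),
            False,
            "profile equation could not be bracketed",
        )
    alpha = optimize.brentq(profile, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=500)
    w = np.exp(alpha * (logx - logx.max()))
    beta = math.exp(logx.max() + math.log(float(np.mean(w))) / alpha)
    return ParamVector(Family.WEIBULL, {"alpha": alpha, "beta": beta}), True, ""


def gamma_digamma_residual(alpha: float, data: np.ndarray) -> float:
    """Residual of the Gamma shape (digamma) equation at ``alpha``."""
    x = np.asarray(data, dtype=float)
    c = math.log(float(np.mean(x))) - float(np.mean(np.log(x)))
    return math.log(alpha) - float(special.digamma(alpha)) - c


def _fit_gamma(data: np.ndarray) -> tuple[ParamVector, bool, str]:
    x = np.asarray(data, dtype=float)
    xbar = float(np.mean(x))
    c = math.log(xbar) - float(np.mean(np.log(x)))
    if c <= 0:  # degenerate (constant data); digamma equation has no root
        return (
            ParamVector(Family.GAMMA, {"alpha": 1.0, "beta": 1.0 / xbar}),
            False,
            "log-mean inequality degenerate; constant data?",
        )
    # classical closed-form start for the digamma equation
    a0 = (3.0 - c + math.sqrt((c - 3.0) ** 2 + 24.0 * c)) / (12.0 * c)
    f = lambda a: math.log(a) - float(special.digamma(a)) - c
    lo, hi = a0, a0
    while f(lo) < 0 and lo > 1e-10:
        lo /= 2.0
    while f(hi) > 0 and hi < 1e10:
        hi *= 2.0
    alpha = optimize.brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=500)
    beta = alpha / xbar  # rate
    return ParamVector(Family.GAMMA, {"alpha": alpha, "beta": beta}), True, ""


def _fit_by_scipy(family: Family, data: np.ndarray) -> tuple[ParamVector, bool, str]:
    """Numeric MLE for the location/scale and extreme-value families."""
    x = np.asarray(data, dtype=float)
    note = ""
    try:
        if family is Family.EV:
            loc, scale = stats.gumbel_l.fit(x)
            spec = ParamVector(Family.EV, {"mu": loc, "sigma": scale})
        elif family is Family.GEV:
            c, loc, scale = stats.genextreme.fit(x)
            spec = ParamVector(Family.GEV, {"k": -c, "sigma": scale, "mu": loc})
        elif family is Family.GP:
            # location pinned at the support origin; data must be positive
            c, loc, scale = stats.genpareto.fit(x, floc=0.0)
            spec = ParamVector(Family.GP, {"k": c, "sigma": scale, "mu": 0.0})
        else:  # pragma: no cover
            raise AssertionError(family)
    except (ParameterDomainError, RuntimeError, ValueError) as exc:
        raise FitInfeasibleError(f"{family.value} fit failed: {exc}") from exc
    ll = loglik(spec, x)
    converged = math.isfinite(ll)
    if not converged:
        note = "log-likelihood not finite at the numeric optimum"
    return spec, converged, note


def fit_mle(family: Family, data) -> FittedDistribution:
    """Fit one family to one class sample by maximum likelihood.

    Raises :class:`FitInfeasibleError` when the data fall outside the
    family's support (e.g. non-positive values for Weibull/Gamma/Exponential,
    or for the GP whose location is fixed at 0).  Non-convergence is reported
    through ``converged=False`` rather than an exception.
    """
    x = np.asarray(data, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot fit an empty sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("data must be finite")
    fam = Family(family)

    if fam in POSITIVE_FAMILIES or fam is Family.GP:
        _require_positive(fam, x)

    converged, note = True, ""
    if fam is Family.NORMAL:
        mu = float(np.mean(x))
        sigma = float(np.sqrt(np.mean((x - mu) ** 2)))  # MLE, divisor n
        if sigma <= 0:
            sigma, converged, note = 1e-12, False, "constant sample; sigma floored"
        spec = ParamVector(Family.NORMAL, {"mu": mu, "sigma": sigma})
    elif fam is Family.EXPONENTIAL:
        spec = ParamVector(Family.EXPONENTIAL, {"mu": float(np.mean(x))})
    elif fam is Family.WEIBULL:
        spec, converged, note = _fit_weibull(x)
    elif fam is Family.GAMMA:
        spec, converged, note = _fit_gamma(x)
    else:
        spec, converged, note = _fit_by_scipy(fam, x)

    ll = loglik(spec, x)
    if converged and not math.isfinite(ll):
        converged, note = False, "log-likelihood not finite at the estimate"
    return FittedDistribution(spec=spec, loglik=ll, n=int(x.size), converged=converged, notes=note)
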