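"""Maximum-likelihood fitting of candidate concentration distributions and
AIC-based family selection.

Closed-form MLEs are used where they exist (normal, lognormal, inverse
Gaussian); Weibull and gamma estimates come from numerical likelihood
maximisation with the location pinned at zero. Zeros produced by the
below-detection substitution rule are excluded from positive-support fits
with a logged count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, FitError, SelectionError

logger = logging.getLogger(__name__)

#: Fixed family order, used for deterministic tie-breaking in selection.
FAMILIES = ("lognormal", "weibull", "inverse_gaussian", "gamma", "normal")

#: Families whose support excludes zero.
_POSITIVE_SUPPORT = ("lognormal", "weibull", "inverse_gaussian", "gamma")

#: Number of free parameters per family (location fixed at 0 for positive families).
_N_PARAMS = {f: 2 for f in FAMILIES}

_MIN_N = 5


@dataclass(frozen=True)
class FittedDist:
    """A fitted family with its MLE parameters and information criteria."""

    family: str
    params: tuple[float, ...]
    log_likelihood: float
    aic: float
    n: int

    @property
    def dist(self):
        """The frozen scipy distribution for the fitted parameters."""
        if self.family == "lognormal":
            sigma, scale = self.params
            return stats.lognorm(sigma, scale=scale)
        if self.family == "weibull":
            k, lam = self.params
            return stats.weibull_min(k, scale=lam)
        if self.family == "inverse_gaussian":
            mean, lam = self.params
            return stats.invgauss(mean / lam, scale=lam)
        if self.family == "gamma":
            a, scale = self.params
            return stats.gamma(a, scale=scale)
        if self.family == "normal":
            loc, scale = self.params
            return stats.norm(loc, scale)
        raise FitError(f"unknown family {self.family!r}")

    @property
    def mean(self) -> float:
        return float(self.dist.mean())

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.dist.rvs(size=n, random_state=rng)


def _prepare(values: Sequence[float], family: str) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise FitError("values must be one-dimensional")
    if np.isnan(x).any():
        raise FitError("values contain NaN")
    if family in _POSITIVE_SUPPORT:
        n_zero = int((x <= 0).sum())
        if n_zero:
            logger.info(
                "excluding %d non-positive value(s) from %s fit", n_zero, family
            )
            x = x[x > 0]
    if len(x) < _MIN_N:
        raise FitError(f"need at least {_MIN_N} usable values, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all values identical; nothing to fit")
    return x


def fit_family(values: Sequence[float], family: str) -> FittedDist:
    """Maximum-likelihood fit of one family.

    Deterministic for a given value list. Raises
    :class:`DegenerateDataError` for zero-variance data and :class:`FitError`
    for non-finite likelihoods or failed optimisation.
    """
    if family not in FAMILIES:
        raise FitError(f"unknown family {family!r}; choose from {FAMILIES}")
    x = _prepare(values, family)

    if family == "normal":
        params = (float(np.mean(x)), float(np.std(x)))
    elif family == "lognormal":
        logs = np.log(x)
        mu, sigma = float(np.mean(logs)), float(np.std(logs))
        if sigma == 0:
            raise DegenerateDataError("zero variance on the log scale")
        params = (sigma, math.exp(mu))
    elif family == "inverse_gaussian":
        # MLE: mu_hat = xbar; lambda_hat = n / sum(1/x - 1/xbar)
        xbar = float(np.mean(x))
        denom = float(np.sum(1.0 / x - 1.0 / xbar))
        if denom <= 0:
            raise FitError("inverse-Gaussian MLE undefined for these data")
        params = (xbar, len(x) / denom)
    elif family == "weibull":
        try:
            k, _, lam = stats.weibull_min.fit(x, floc=0)
        except Exception as exc:  # pragma: no cover - scipy internal failure
            raise FitError(f"Weibull fit failed: {exc}") from exc
        params = (float(k), float(lam))
    else:  # gamma
        try:
            a, _, scale = stats.gamma.fit(x, floc=0)
        except Exception as exc:  # pragma: no cover
            raise FitError(f"gamma fit failed: {exc}") from exc
        params = (float(a), float(scale))

    fitted = FittedDist(family=family, params=params, log_likelihood=0.0, aic=0.0, n=len(x))
    ll = float(np.sum(fitted.dist.logpdf(x)))
    if not np.isfinite(ll):
        raise FitError(f"{family}: non-finite log-likelihood")
    k_free = _N_PARAMS[family]
    return FittedDist(
        family=family, params=params, log_likelihood=ll, aic=2 * k_free - 2 * ll, n=len(x)
    )


def select_distribution(
    values: Sequence[float], candidates: Sequence[str] = FAMILIES
) -> FittedDist:
    """Fit each candidate family and return the one with the lowest AIC.

    Candidates that fail to fit are skipped with a logged reason; ties are
    broken by fewest free parameters, then by the fixed family order.
    """
    if not candidates:
        raise SelectionError("candidate list is empty")
    fits: list[FittedDist] = []
    for family in candidates:
        try:
            fits.append(fit_family(values, family))
        except FitError as exc:
            logger.warning("skipping %s: %s", family, exc)
    if not fits:
        raise SelectionError("every candidate family failed to fit")
    order = {f: i for i, f in enumerate(FAMILIES)}
    return min(fits, key=lambda f: (f.aic, _N_PARAMS[f.family], order[f.family]))
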