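"""Quantile- and moment-calibrated synthetic data generators.

The study population's raw records (98 concentration batches, ~29k consumption
records) are not public; these generators emulate their statistical structure
from the published summary statistics so the downstream pipeline can be
exercised and tested.

Consumption marginals are modelled as shifted (3-parameter) lognormals pinned
exactly to the published P5/P50/P95 anchors: three anchors determine the three
parameters uniquely, and the heavy right tail of annual consumption
(P95/P50 ≈ 6.3) makes a log family the natural choice. Metal concentrations
follow the per-metal families identified for the real samples — Weibull for
As, inverse Gaussian for Mn, lognormal for the others — calibrated so the
model mean matches the published mean and the survival probability at the
30 mg/kg pharmacopoeia limit matches the published exceedance ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq

from .datamodel import DETECTED, MEASURED_METALS, ConcentrationTable, ConsumptionRecords, validate_metal
from .errors import CalibrationError, ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: Pharmacopoeia maximum residual limit for heavy metals in Pheretima, mg/kg.
DEFAULT_LIMIT = 30.0

#: Published consumption anchors: (P5, P50, P95) per marginal.
CONSUMPTION_ANCHORS = {
    "annual_consumption": (60.0, 168.0, 1050.0),   # g/y
    "exposure_frequency": (7.0, 14.0, 98.0),       # d/y
    "daily_intake": (6.0, 9.0, 18.0),              # g/d
}

#: Published per-metal mean concentration (mg/kg) and fraction of samples
#: above the 30 mg/kg limit, with the distribution family found to fit each.
METAL_TARGETS = {
    "As": ("weibull", 13.51, 0.0510),
    "Cd": ("lognormal", 2.52, 0.0),
    "Cr": ("lognormal", 31.85, 0.3571),
    "Cu": ("lognormal", 17.23, 0.0612),
    "Hg": ("lognormal", 1.58, 0.0102),
    "Mn": ("inverse_gaussian", 83.45, 0.8265),
    "Ni": ("lognormal", 8.05, 0.0306),
    "Pb": ("lognormal", 9.33, 0.0306),
}

#: Default coefficient of variation used when only the mean constrains a
#: two-parameter lognormal (the Cd case: zero published exceedance).
DEFAULT_CV = 0.5

_Z95 = float(stats.norm.ppf(0.95))


@dataclass(frozen=True)
class ConsumptionModel:
    """Shifted lognormal: X = shift + exp(N(log_location, log_scale))."""

    shift: float
    log_location: float
    log_scale: float

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValidationError("shift must be non-negative")
        if self.log_scale < 0:
            raise ValidationError("log_scale must be non-negative")

    @property
    def mean(self) -> float:
        """Closed-form mean: shift + exp(mu + sigma^2 / 2)."""
        return self.shift + math.exp(self.log_location + self.log_scale**2 / 2)

    def ppf(self, q) -> np.ndarray:
        """Quantile function (strictly increasing for log_scale > 0)."""
        return self.shift + np.exp(
            self.log_location + self.log_scale * stats.norm.ppf(q)
        )

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.shift + np.exp(
            rng.normal(self.log_location, self.log_scale, size=n)
        )


def calibrate_consumption(q5: float, q50: float, q95: float) -> ConsumptionModel:
    """Fit the unique shifted lognormal through three symmetric quantile anchors.

    Because the 5% and 95% normal deviates are opposite (±z), the shifted
    median satisfies (q50−γ)² = (q5−γ)(q95−γ); solving this linear-in-γ
    identity gives the shift, then μ = ln(q50−γ) and
    σ = (ln(q95−γ) − μ) / z₀.₉₅.
    """
    if not 0 < q5 < q50 < q95:
        raise ValidationError("quantile anchors must satisfy 0 < q5 < q50 < q95")
    denom = q5 + q95 - 2 * q50
    if abs(denom) < 1e-12:
        gamma = 0.0  # symmetric-in-log anchors: q50^2 == q5*q95
    else:
        gamma = (q5 * q95 - q50**2) / denom
    if gamma >= q5:
        raise CalibrationError(
            f"shift {gamma:.4g} is not below the lowest anchor {q5}; "
            "anchors are incompatible with a shifted lognormal"
        )
    if gamma < 0:
        if gamma > -1e-9 * q50:
            gamma = 0.0  # numerical noise around the zero-shift boundary
        else:
            raise CalibrationError(
                f"anchors require a negative shift ({gamma:.4g}); they are "
                "log-convex and incompatible with a non-negative-shift lognormal"
            )
    mu = math.log(q50 - gamma)
    sigma = (math.log(q95 - gamma) - mu) / _Z95
    return ConsumptionModel(shift=gamma, log_location=mu, log_scale=sigma)


def default_consumption_models() -> dict[str, ConsumptionModel]:
    """The three marginal models calibrated to the published anchors."""
    return {
        name: calibrate_consumption(*anchors)
        for name, anchors in CONSUMPTION_ANCHORS.items()
    }


def sample_consumption(
    model: ConsumptionModel,
    n: int,
    seed: int,
    ef_model: Optional[ConsumptionModel] = None,
    di_model: Optional[ConsumptionModel] = None,
) -> ConsumptionRecords:
    """Draw n independent consumption records.

    Annual consumption comes from ``model``; exposure frequency and daily
    intake come from companion models (defaults calibrated to their own
    published anchors). The three marginals are drawn independently — their
    joint dependence in the source records is unpublished — so the
    AC ≈ EF × DI identity holds only approximately, as it does in the
    published marginals. Frequency draws are clipped at 365 d/y.
    """
    if n < 1:
        raise ValidationError("n must be at least 1")
    defaults = default_consumption_models()
    ef_model = ef_model or defaults["exposure_frequency"]
    di_model = di_model or defaults["daily_intake"]
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "annual_consumption": model.rvs(n, rng),
            "exposure_frequency": np.minimum(ef_model.rvs(n, rng), 365.0),
            "daily_intake": di_model.rvs(n, rng),
        }
    )
    return ConsumptionRecords(frame=frame)


@dataclass(frozen=True)
class MetalModel:
    """A calibrated concentration distribution for one metal.

    ``params`` are family-specific: (sigma, scale=e^mu) for lognormal,
    (shape k, scale λ) for Weibull, (mean μ, shape λ) for inverse Gaussian.
    """

    metal: str
    family: str
    params: tuple[float, ...]
    target_mean: float
    target_exceedance: float
    limit: float = DEFAULT_LIMIT

    @property
    def dist(self):
        """The frozen scipy distribution."""
        if self.family == "lognormal":
            sigma, scale = self.params
            return stats.lognorm(sigma, scale=scale)
        if self.family == "weibull":
            k, lam = self.params
            return stats.weibull_min(k, scale=lam)
        if self.family == "inverse_gaussian":
            mean, lam = self.params
            return stats.invgauss(mean / lam, scale=lam)
        raise ConfigurationError(f"unknown family {self.family!r}")

    @property
    def mean(self) -> float:
        return float(self.dist.mean())

    def exceedance(self) -> float:
        """Model probability of exceeding the concentration limit."""
        return float(self.dist.sf(self.limit))

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.dist.rvs(size=n, random_state=rng)


def calibrate_metal(
    metal: str,
    family: str,
    target_mean: float,
    target_exceedance: float,
    limit: float = DEFAULT_LIMIT,
    cv: float = DEFAULT_CV,
    on_infeasible: str = "raise",
) -> MetalModel:
    """Solve the two-constraint calibration: mean and tail probability.

    Finds family parameters with model mean equal to ``target_mean`` (to 1e-6
    relative) and survival at ``limit`` equal to ``target_exceedance`` (to 1e-6
    absolute). With ``target_exceedance == 0`` only the mean constraint applies
    and the second parameter comes from the default coefficient of variation.

    ``on_infeasible="nearest"`` returns, instead of raising, the mean-exact
    model whose exceedance is as close as the family allows (used when
    published mean/exceedance pairs are jointly unreachable).
    """
    validate_metal(metal)
    if target_mean <= 0:
        raise ValidationError("target_mean must be positive")
    if not 0 <= target_exceedance < 1:
        raise ValidationError("target_exceedance must lie in [0, 1)")
    if on_infeasible not in ("raise", "nearest"):
        raise ValidationError(f"unknown on_infeasible mode {on_infeasible!r}")

    if family == "lognormal":
        params = _calibrate_lognormal(
            metal, target_mean, target_exceedance, limit, cv, on_infeasible
        )
    elif family == "weibull":
        params = _calibrate_weibull(metal, target_mean, target_exceedance, limit, cv)
    elif family == "inverse_gaussian":
        params = _calibrate_invgauss(metal, target_mean, target_exceedance, limit, cv)
    else:
        raise ConfigurationError(f"unknown family {family!r}")
    return MetalModel(
        metal=metal,
        family=family,
        params=tuple(float(p) for p in params),
        target_mean=target_mean,
        target_exceedance=target_exceedance,
        limit=limit,
    )


def _lognormal_from_mean_cv(mean: float, cv: float) -> tuple[float, float]:
    sigma = math.sqrt(math.log(1 + cv**2))
    mu = math.log(mean) - sigma**2 / 2
    return sigma, math.exp(mu)


def _calibrate_lognormal(metal, mean, exceedance, limit, cv, on_infeasible):
    if exceedance == 0:
        return _lognormal_from_mean_cv(mean, cv)
    # sf(limit) = p  =>  (ln L - mu)/sigma = z_p;  mean  =>  mu + sigma^2/2 = ln m.
    # Eliminating mu: sigma^2/2 - z*sigma - ln(m/L) = 0.
    z = stats.norm.ppf(1 - exceedance)
    log_ratio = math.log(mean / limit)
    disc = z**2 + 2 * log_ratio
    if disc < 0:
        max_p = float(stats.norm.sf(math.sqrt(-2 * log_ratio)))
        if on_infeasible == "nearest":
            # sigma at the exceedance maximiser; the mean stays exact
            sigma = math.sqrt(-2 * log_ratio)
            mu = math.log(mean) - sigma**2 / 2
            logger.warning(
                "%s: requested exceedance %.4f unreachable for a lognormal with "
                "mean %.4g (max %.4f); using nearest-feasible sigma",
                metal, exceedance, mean, max_p,
            )
            return sigma, math.exp(mu)
        raise CalibrationError(
            f"{metal}: no lognormal with mean {mean} has P(X>{limit}) = "
            f"{exceedance}; the maximum achievable exceedance is {max_p:.4%}"
        )
    roots = sorted(r for r in (z - math.sqrt(disc), z + math.sqrt(disc)) if r > 0)
    if not roots:
        raise CalibrationError(f"{metal}: no positive sigma root")
    # Both roots satisfy both constraints when the mean is below the limit;
    # the smaller sigma (lighter tail) is the realistic choice.
    sigma = roots[0]
    mu = math.log(mean) - sigma**2 / 2
    return sigma, math.exp(mu)


def _calibrate_weibull(metal, mean, exceedance, limit, cv):
    if exceedance == 0:
        # mean + CV determine shape then scale: CV depends on k only.
        def cv_of(k):
            g1 = special.gamma(1 + 1 / k)
            g2 = special.gamma(1 + 2 / k)
            return math.sqrt(g2 / g1**2 - 1)

        k = brentq(lambda kk: cv_of(kk) - cv, 0.1, 50.0)
        return k, mean / special.gamma(1 + 1 / k)

    target = -math.log(exceedance)

    def constraint(k):
        lam = mean / special.gamma(1 + 1 / k)
        return (limit / lam) ** k - target

    roots = _scan_roots(constraint, 0.05, 100.0)
    if not roots:
        raise CalibrationError(
            f"{metal}: no Weibull shape satisfies mean {mean} and "
            f"P(X>{limit}) = {exceedance}"
        )
    # The constraint can cross zero twice; the larger shape (finite mode,
    # increasing hazard) is the physically sensible root.
    k = max(roots)
    return k, mean / special.gamma(1 + 1 / k)


def _calibrate_invgauss(metal, mean, exceedance, limit, cv):
    if exceedance == 0:
        # CV of IG(mean, lambda) is sqrt(mean/lambda).
        return mean, mean / cv**2

    def constraint(lam):
        return stats.invgauss(mean / lam, scale=lam).sf(limit) - exceedance

    lo, hi = 1e-3, 1e6
    if constraint(lo) * constraint(hi) > 0:
        raise CalibrationError(
            f"{metal}: no inverse-Gaussian shape in [{lo}, {hi}] satisfies "
            f"mean {mean} and P(X>{limit}) = {exceedance}"
        )
    lam = brentq(constraint, lo, hi, xtol=1e-12)
    return mean, lam


def _scan_roots(f, lo, hi, n_grid=400):
    grid = np.geomspace(lo, hi, n_grid)
    vals = np.array([f(g) for g in grid])
    roots = []
    for i in range(n_grid - 1):
        if np.sign(vals[i]) != np.sign(vals[i + 1]):
            roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-12))
    return roots


def default_metal_models(limit: float = DEFAULT_LIMIT) -> dict[str, MetalModel]:
    """Calibrated models for all eight measured metals.

    Hg's published mean/exceedance pair is jointly unreachable for a
    lognormal, so its model keeps the mean exact and takes the
    closest-achievable exceedance (~0.76% vs 1.02% published).
    """
    models = {}
    for metal, (family, mean, exceedance) in METAL_TARGETS.items():
        models[metal] = calibrate_metal(
            metal, family, mean, exceedance, limit=limit,
            on_infeasible="nearest" if metal == "Hg" else "raise",
        )
    return models


def sample_concentration_table(
    models: Mapping[str, MetalModel],
    n_samples: int,
    seed: int,
) -> ConcentrationTable:
    """Draw a sample × metal concentration table with independent per-metal draws.

    Metals are sampled independently within a sample (no cross-metal copula).
    All generated values are "detected": the generating families have support
    on the positive axis, mirroring the real survey in which every metal was
    quantified in every sample.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be at least 1")
    missing = [m for m in MEASURED_METALS if m not in models]
    if missing:
        raise ConfigurationError(f"missing metal models: {', '.join(missing)}")
    rng = np.random.default_rng(seed)
    index = pd.Index([f"S{i + 1:03d}" for i in range(n_samples)], name="sample_id")
    values = pd.DataFrame(
        {metal: models[metal].rvs(n_samples, rng) for metal in MEASURED_METALS},
        index=index,
    )
    status = pd.DataFrame(DETECTED, index=index, columns=list(MEASURED_METALS))
    return ConcentrationTable(values=values, censor_status=status)
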