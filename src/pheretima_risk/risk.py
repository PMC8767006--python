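"""The exposure and risk equations, the Monte Carlo driver, and summaries.

The estimated daily intake for metal *i* is

    EDI_i = C_i × AC × E_D × T / (BW × T_A × 1000)

with C_i the concentration (mg/kg), AC the annual consumption (g/y), E_D the
exposure duration (y), T the material-to-decoction transfer ratio, BW the body
weight (kg) and T_A the averaging time (d). For non-carcinogenic endpoints
T_A = E_D × 365 so the duration cancels; for carcinogenic endpoints
T_A = 70 × 365 (lifetime averaging) and intake scales with E_D. Risk metrics:
HQ = EDI/RfD, HI = ΣHQ, CRi = EDI × CSF, CRT = ΣCRi over the four oral
carcinogens. HQ/HI above 1 and CRi/CRT above 1×10⁻⁴ are conventionally
unacceptable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .datamodel import (
    CARCINOGENS,
    MEASURED_METALS,
    ConsumptionRecords,
    ExposureConfig,
    ToxTable,
    default_tox_table,
)
from .errors import ConfigurationError, ValidationError
from .fitting import FittedDist
from .synthetic import ConsumptionModel, MetalModel

#: Acceptability thresholds.
HQ_THRESHOLD = 1.0
CR_THRESHOLD = 1e-4

#: Reported percentiles (type-7 / linear interpolation convention).
PERCENTILES = (10, 25, 50, 75, 90, 95, 97.5)

USER_CLASSES = ("random", "average", "high")

ConcentrationSource = Union[MetalModel, FittedDist]
ConsumptionSource = Union[ConsumptionRecords, ConsumptionModel]


def compute_edi(ci, ac, config: ExposureConfig):
    """Estimated daily intake, mg/(kg·d). Vectorised over ``ci`` and ``ac``."""
    ci = np.asarray(ci, dtype=float)
    ac = np.asarray(ac, dtype=float)
    if (ci < 0).any():
        raise ValidationError("concentration must be non-negative")
    if (ac <= 0).any():
        raise ValidationError("annual consumption must be positive")
    return (
        ci * ac * config.exposure_duration * config.transfer_ratio
        / (config.body_weight * config.averaging_time_days * 1000.0)
    )


def compute_hq(edi, rfd: float):
    """Hazard quotient: intake relative to the reference dose."""
    if rfd <= 0:
        raise ValidationError("RfD must be positive")
    return np.asarray(edi, dtype=float) / rfd


def compute_hi(hq_by_metal: Mapping[str, float]):
    """Hazard index: the sum of hazard quotients over co-occurring metals."""
    if not hq_by_metal:
        raise ValidationError("hazard-quotient map is empty")
    return sum(hq_by_metal.values())


def compute_cri(edi, csf: float):
    """Incremental lifetime cancer risk for one metal: EDI × CSF."""
    if csf <= 0:
        raise ValidationError("CSF must be positive")
    return np.asarray(edi, dtype=float) * csf


def compute_crt(cri_by_metal: Mapping[str, float]):
    """Total cancer risk: the sum over the carcinogenic metals."""
    if not cri_by_metal:
        raise ValidationError("cancer-risk map is empty")
    return sum(cri_by_metal.values())


@dataclass
class RiskDraws:
    """Per-iteration Monte Carlo draws of every risk metric.

    ``edi`` and ``hq`` are iteration × metal frames over the eight measured
    metals; ``cri`` covers the four carcinogens; ``hi`` and ``crt`` are the
    row sums of ``hq`` and ``cri``.
    """

    edi: pd.DataFrame
    hq: pd.DataFrame
    cri: pd.DataFrame
    hi: pd.Series
    crt: pd.Series
    config: ExposureConfig

    @property
    def n_iterations(self) -> int:
        return len(self.hi)


def _resolve_annual_consumption(
    consumption: ConsumptionSource,
    user_class: str,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """AC per iteration under a user class.

    random: resampled with replacement from records (or fresh model draws);
    average: fixed at the mean; high: fixed at the 95th percentile.
    """
    if user_class not in USER_CLASSES:
        raise ValidationError(f"unknown user class {user_class!r}")
    if isinstance(consumption, ConsumptionRecords):
        ac = consumption.annual_consumption
        if user_class == "random":
            return rng.choice(ac, size=n, replace=True)
        if user_class == "average":
            return np.full(n, float(np.mean(ac)))
        return np.full(n, float(np.percentile(ac, 95)))
    if isinstance(consumption, ConsumptionModel):
        if user_class == "random":
            return consumption.rvs(n, rng)
        if user_class == "average":
            return np.full(n, consumption.mean)
        return np.full(n, float(consumption.ppf(0.95)))
    raise ConfigurationError(
        "consumption must be ConsumptionRecords or ConsumptionModel"
    )


def _draw_concentration(
    dist: ConcentrationSource, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw concentrations, redrawing any negatives (normal candidates only)."""
    draws = dist.rvs(n, rng)
    for _ in range(100):
        neg = draws < 0
        if not neg.any():
            return draws
        draws[neg] = dist.rvs(int(neg.sum()), rng)
    raise ConfigurationError(
        "concentration distribution keeps producing negative draws"
    )


def run_monte_carlo(
    metal_dists: Mapping[str, ConcentrationSource],
    consumption: ConsumptionSource,
    config: ExposureConfig,
    user_class: str = "random",
    tox: Optional[ToxTable] = None,
) -> RiskDraws:
    """Propagate concentration and consumption uncertainty through the risk
    equations for ``config.n_iterations`` iterations.

    Each iteration draws one concentration per metal from its distribution
    (truncated at zero) and one annual-consumption value per the user class;
    concentration and consumption are sampled independently. Reproducible for
    a fixed ``config.seed``.
    """
    missing = [m for m in MEASURED_METALS if m not in metal_dists]
    if missing:
        raise ConfigurationError(f"missing concentration distributions: {', '.join(missing)}")
    tox = tox or default_tox_table()
    n = config.n_iterations
    rng = np.random.default_rng(config.seed)

    ac = _resolve_annual_consumption(consumption, user_class, n, rng)
    conc = {m: _draw_concentration(metal_dists[m], n, rng) for m in MEASURED_METALS}

    edi = pd.DataFrame({m: compute_edi(conc[m], ac, config) for m in MEASURED_METALS})
    hq = pd.DataFrame({m: compute_hq(edi[m], tox.rfd_for(m)) for m in MEASURED_METALS})
    cri = pd.DataFrame({m: compute_cri(edi[m], tox.csf_for(m)) for m in CARCINOGENS})
    return RiskDraws(
        edi=edi, hq=hq, cri=cri, hi=hq.sum(axis=1), crt=cri.sum(axis=1), config=config
    )


@dataclass
class RiskSummary:
    """Order statistics and threshold-exceedance probabilities per metric.

    ``table`` is indexed by metric name (``HQ_As``, ``HI``, ``CRi_Cr``,
    ``CRT``, ``EDI_As``, ...) with columns min/mean/max, the reported
    percentiles, and the exceedance probability where a threshold applies.
    """

    table: pd.DataFrame

    def exceedance(self, metric: str) -> float:
        return float(self.table.loc[metric, "exceedance"])


def _stat_row(draws: np.ndarray, threshold: Optional[float]) -> dict:
    row = {
        "min": float(np.min(draws)),
        "mean": float(np.mean(draws)),
        "max": float(np.max(draws)),
    }
    for p in PERCENTILES:
        row[f"P{p:g}"] = float(np.percentile(draws, p))
    row["exceedance"] = (
        float(np.mean(draws > threshold)) if threshold is not None else np.nan
    )
    return row


def summarize(draws: RiskDraws) -> RiskSummary:
    """Reduce per-iteration draws to the reported summary statistics."""
    if draws.n_iterations < 1:
        raise ValidationError("no draws to summarize")
    rows = {}
    for m in draws.edi.columns:
        rows[f"EDI_{m}"] = _stat_row(draws.edi[m].to_numpy(), None)
    for m in draws.hq.columns:
        rows[f"HQ_{m}"] = _stat_row(draws.hq[m].to_numpy(), HQ_THRESHOLD)
    rows["HI"] = _stat_row(draws.hi.to_numpy(), HQ_THRESHOLD)
    for m in draws.cri.columns:
        rows[f"CRi_{m}"] = _stat_row(draws.cri[m].to_numpy(), CR_THRESHOLD)
    rows["CRT"] = _stat_row(draws.crt.to_numpy(), CR_THRESHOLD)
    return RiskSummary(table=pd.DataFrame(rows).T)


def deterministic_assessment(
    conc_mean: Mapping[str, float],
    conc_p95: Mapping[str, float],
    ac_mean: float,
    ac_p95: float,
    config: ExposureConfig,
    tox: Optional[ToxTable] = None,
) -> pd.DataFrame:
    """Single-point assessment for the average user (mean concentration, mean
    consumption) and the high user (P95 concentration, P95 consumption).

    Returns a metric × {average, high} table directly comparable to the
    probabilistic summaries.
    """
    tox = tox or default_tox_table()
    out: dict[str, dict[str, float]] = {"average": {}, "high": {}}
    for scenario, conc, ac in (
        ("average", conc_mean, ac_mean),
        ("high", conc_p95, ac_p95),
    ):
        hq = {}
        cri = {}
        for m in MEASURED_METALS:
            if m not in conc:
                raise ConfigurationError(f"missing {scenario} concentration for {m}")
            edi = float(compute_edi(conc[m], ac, config))
            out[scenario][f"EDI_{m}"] = edi
            hq[m] = float(compute_hq(edi, tox.rfd_for(m)))
            out[scenario][f"HQ_{m}"] = hq[m]
            if m in CARCINOGENS:
                cri[m] = float(compute_cri(edi, tox.csf_for(m)))
                out[scenario][f"CRi_{m}"] = cri[m]
        out[scenario]["HI"] = compute_hi(hq)
        out[scenario]["CRT"] = compute_crt(cri)
    return pd.DataFrame(out)
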