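"""Domain types for the risk assessment: metals, concentration and consumption
tables, toxicological reference values, and exposure parameters.

Concentrations are mg/kg dry weight; annual consumption is g/year; exposure
frequency is days/year; daily intake is g/day; body weight is kg. Units are
fixed — the intake equation embeds the g-to-kg factor of 1000 explicitly — and
no automatic conversion is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, ValidationError

#: The eight metals measured in dried earthworm (Pheretima) material.
MEASURED_METALS: tuple[str, ...] = ("As", "Cd", "Cr", "Cu", "Hg", "Mn", "Ni", "Pb")

#: Metals for which oral reference doses are tabulated (superset of the measured set).
EXTENDED_METALS: tuple[str, ...] = MEASURED_METALS + ("Co", "Zn", "Al")

#: Metals with an oral cancer slope factor.
CARCINOGENS: tuple[str, ...] = ("Cr", "Cd", "Pb", "As")

#: Censoring states of a single concentration measurement.
DETECTED = "detected"
BELOW_LOD = "below_LOD"
BETWEEN_LOD_LOQ = "between_LOD_LOQ"
CENSOR_STATUSES = (DETECTED, BELOW_LOD, BETWEEN_LOD_LOQ)


def validate_metal(code: str, *, measured_only: bool = True) -> str:
    """Validate a metal code, returning it unchanged.

    ``measured_only=True`` restricts to the eight measured metals; otherwise the
    extended toxicology set (adds Co, Zn, Al) is admitted.
    """
    allowed = MEASURED_METALS if measured_only else EXTENDED_METALS
    if code not in allowed:
        raise ValidationError(
            f"unknown metal code {code!r}; expected one of {', '.join(allowed)}"
        )
    return code


@dataclass(frozen=True)
class DetectionLimits:
    """Per-metal limit of detection (LOD) and limit of quantification (LOQ), mg/kg."""

    lod: Mapping[str, float]
    loq: Mapping[str, float]

    def __post_init__(self) -> None:
        for metal, lod in self.lod.items():
            validate_metal(metal)
            if metal not in self.loq:
                raise ValidationError(f"LOQ missing for metal {metal}")
            if not 0 < lod < self.loq[metal]:
                raise ValidationError(
                    f"require 0 < LOD < LOQ for {metal}, got LOD={lod}, LOQ={self.loq[metal]}"
                )


def censor_value(
    status: str,
    raw: Optional[float],
    limits: Optional[DetectionLimits],
    metal: str,
) -> float:
    """Apply the below-detection substitution rule to one measurement.

    Detected values pass through unchanged; values below the LOD are replaced
    by 0; values between the LOD and LOQ are replaced by LOQ/2. The rule is
    idempotent: its outputs are fixed points of itself.
    """
    validate_metal(metal)
    if status not in CENSOR_STATUSES:
        raise ValidationError(f"unknown censor status {status!r}")
    if status == DETECTED:
        if raw is None:
            raise ValidationError(f"detected entry for {metal} has no value")
        if raw < 0:
            raise ValidationError(f"negative concentration {raw} for {metal}")
        return float(raw)
    if limits is None or metal not in limits.loq:
        raise ConfigurationError(
            f"detection limits required to substitute a non-detected {metal} entry"
        )
    if status == BELOW_LOD:
        return 0.0
    return limits.loq[metal] / 2.0


@dataclass(frozen=True)
class ToxTable:
    """Oral reference doses (RfD, mg/(kg·d)) and cancer slope factors (CSF, (kg·d)/mg)."""

    rfd: Mapping[str, float]
    csf: Mapping[str, float]

    def __post_init__(self) -> None:
        for metal, value in self.rfd.items():
            validate_metal(metal, measured_only=False)
            if value <= 0:
                raise ValidationError(f"RfD for {metal} must be positive, got {value}")
        for metal, value in self.csf.items():
            validate_metal(metal, measured_only=False)
            if value <= 0:
                raise ValidationError(f"CSF for {metal} must be positive, got {value}")

    def rfd_for(self, metal: str) -> float:
        return self.rfd[metal]

    def csf_for(self, metal: str) -> float:
        """CSF lookup; raises KeyError for metals outside the carcinogen set."""
        return self.csf[metal]


def default_tox_table() -> ToxTable:
    """USEPA-derived oral reference doses and cancer slope factors.

    RfDs cover the eleven metals of the extended set; slope factors exist only
    for the four oral carcinogens Cr, Cd, Pb and As.
    """
    return ToxTable(
        rfd={
            "Cr": 1.5,
            "Mn": 0.14,
            "Co": 0.0003,
            "Ni": 0.02,
            "Cu": 0.04,
            "Zn": 0.3,
            "Cd": 0.001,
            "As": 0.0003,
            "Pb": 0.0085,
            "Al": 0.0004,
            "Hg": 0.0003,
        },
        csf={"Cr": 0.5, "Cd": 0.38, "Pb": 0.0085, "As": 1.5},
    )


NONCARCINOGENIC = "noncarcinogenic"
CARCINOGENIC = "carcinogenic"


@dataclass(frozen=True)
class ExposureConfig:
    """Exposure-scenario parameters for the intake equation.

    The averaging time T_A depends on the endpoint: for non-carcinogenic risk
    it equals the exposure duration (E_D × 365 d), so the E_D factor cancels
    from the intake; for carcinogenic risk the dose is averaged over a 70-year
    lifetime (70 × 365 d) and intake scales linearly with E_D.
    """

    body_weight: float = 63.0           # kg, Chinese adult average
    transfer_ratio: float = 0.10        # fraction transferred from material to decoction
    exposure_duration: float = 20.0     # years (E_D)
    averaging_mode: str = NONCARCINOGENIC
    lifetime: float = 70.0              # years, carcinogenic averaging horizon
    n_iterations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.transfer_ratio <= 1:
            raise ValidationError("transfer_ratio must lie in (0, 1]")
        if self.exposure_duration <= 0:
            raise ValidationError("exposure_duration must be positive")
        if self.body_weight <= 0:
            raise ValidationError("body_weight must be positive")
        if self.averaging_mode not in (NONCARCINOGENIC, CARCINOGENIC):
            raise ValidationError(f"unknown averaging_mode {self.averaging_mode!r}")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be at least 1")

    @property
    def averaging_time_days(self) -> float:
        """T_A in days, per the averaging convention for the chosen endpoint."""
        if self.averaging_mode == NONCARCINOGENIC:
            return self.exposure_duration * 365.0
        return self.lifetime * 365.0


@dataclass
class ConcentrationTable:
    """Sample × metal concentration matrix (mg/kg) with censoring metadata.

    ``values`` is indexed by sample id with one column per measured metal;
    ``censor_status`` mirrors its shape. After substitution, a censored cell
    holds exactly 0 (below LOD) or LOQ/2 (between LOD and LOQ).
    """

    values: pd.DataFrame
    censor_status: pd.DataFrame
    origin: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        for metal in MEASURED_METALS:
            if metal not in cols:
                raise ValidationError(f"concentration table missing metal column {metal}")
        for col in cols:
            validate_metal(col)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("concentration table contains negative values")
        if self.values.isna().any().any():
            raise ValidationError("concentration table contains missing values")
        if list(self.censor_status.columns) != cols or len(self.censor_status) != len(self.values):
            raise ValidationError("censor_status shape must match values")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def means(self) -> pd.Series:
        """Per-metal arithmetic mean concentration, mg/kg."""
        return self.values.mean()

    def percentile(self, q: float) -> pd.Series:
        """Per-metal percentile (linear interpolation of order statistics)."""
        return self.values.quantile(q / 100.0)

    def exceedance(self, limit: float = 30.0) -> pd.Series:
        """Fraction of samples above a concentration limit, per metal."""
        return (self.values > limit).mean()


#: Relative slack allowed between mean annual consumption and the product of the
#: mean exposure frequency and mean daily intake before a consistency warning is
#: issued. The three marginals are surveyed independently and are only
#: approximately consistent in real records.
_CONSISTENCY_RTOL = 0.25


@dataclass
class ConsumptionRecords:
    """Per-individual consumption records.

    Columns: ``annual_consumption`` (g/y), ``exposure_frequency`` (d/y),
    ``daily_intake`` (g/d). All strictly positive; frequency cannot exceed 365.
    """

    frame: pd.DataFrame = field(repr=False)

    COLUMNS = ("annual_consumption", "exposure_frequency", "daily_intake")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"consumption file missing columns: {', '.join(missing)}")
        if len(self.frame) < 1:
            raise ValidationError("consumption records are empty")
        data = self.frame[list(self.COLUMNS)]
        if data.isna().any().any():
            raise ValidationError("consumption records contain missing values")
        if (data.to_numpy() <= 0).any():
            raise ValidationError("consumption fields must be strictly positive")
        if (self.frame["exposure_frequency"] > 365).any():
            raise ValidationError("exposure_frequency cannot exceed 365 d/y")
        mean_ac = self.frame["annual_consumption"].mean()
        implied = self.frame["exposure_frequency"].mean() * self.frame["daily_intake"].mean()
        if abs(mean_ac - implied) > _CONSISTENCY_RTOL * mean_ac:
            warnings.warn(
                "mean annual consumption "
                f"({mean_ac:.1f} g/y) deviates from mean frequency x mean daily intake "
                f"({implied:.1f} g/y) by more than {_CONSISTENCY_RTOL:.0%}",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def annual_consumption(self) -> np.ndarray:
        return self.frame["annual_consumption"].to_numpy()

    def summarize(self) -> pd.DataFrame:
        """P5/P50/P95/mean table of the three consumption marginals."""
        data = self.frame[list(self.COLUMNS)]
        out = pd.DataFrame(
            {
                "P5": data.quantile(0.05),
                "P50": data.quantile(0.50),
                "P95": data.quantile(0.95),
                "Mean": data.mean(),
            }
        )
        return out.T
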