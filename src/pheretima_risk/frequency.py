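"""Inversion of the acceptable-cancer-risk budget into a safe dosing frequency.

Working from the driver metal with the highest cancer risk (arsenic), the
maximum tolerable intake is the acceptable lifetime risk Risk_l times the
share SF of the total dietary risk budget allocated to traditional-medicine
use, divided by the slope factor:

    EDI_max = Risk_l × SF / CSF

Feeding EDI_max back through the intake equation with annual consumption
AC = RDI × EF (maximum recommended daily intake times dosing days per year)
and solving for EF gives

    EF = EDI_max × T_A × BW × 1000 / (C_l × RDI × T × E_D)

with T_A = lifetime × 365. SF is applied exactly once, in EDI_max: applying
it again in the EF step would cancel it from the composition and the safe
frequency would no longer depend on the budget share at all. The cancelling
variant is available behind ``sf_in_frequency=True`` for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class FrequencyPolicy:
    """Constants of the risk-budget inversion.

    Defaults follow the pharmacopoeia limits for dried earthworm material
    (30 mg/kg concentration limit, 10 g/d maximum daily intake) with the
    arsenic oral slope factor as the driver.
    """

    risk_limit: float = 1e-4        # acceptable lifetime cancer risk
    safe_factor: float = 0.133      # TCM share of the dietary risk budget
    csf_driver: float = 1.5         # (kg·d)/mg, As oral slope factor
    rdi: float = 10.0               # g/d, maximum recommended daily intake
    conc_limit: float = 30.0        # mg/kg
    exposure_duration: float = 20.0  # years
    lifetime: float = 70.0          # years (averaging horizon)
    transfer_ratio: float = 0.1
    body_weight: float = 63.0       # kg
    sf_in_frequency: bool = False   # literal (SF-cancelling) composition

    def __post_init__(self) -> None:
        positive = (
            "risk_limit", "safe_factor", "csf_driver", "rdi", "conc_limit",
            "exposure_duration", "lifetime", "transfer_ratio", "body_weight",
        )
        for name in positive:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("safe_factor", "transfer_ratio"):
            if getattr(self, name) > 1:
                raise ValidationError(f"{name} must not exceed 1")
        if self.conc_limit == 0:
            raise ValidationError("conc_limit must be positive")


def compute_edi_max(policy: FrequencyPolicy) -> float:
    """Maximum tolerable daily intake, mg/(kg·d): Risk_l × SF / CSF."""
    return policy.risk_limit * policy.safe_factor / policy.csf_driver


def compute_exposure_frequency(policy: FrequencyPolicy) -> float:
    """Allowable dosing days per year keeping lifetime cancer risk in budget."""
    ta_days = policy.lifetime * 365.0
    ef = (
        compute_edi_max(policy) * ta_days * policy.body_weight * 1000.0
        / (policy.conc_limit * policy.rdi * policy.transfer_ratio * policy.exposure_duration)
    )
    if policy.sf_in_frequency:
        ef /= policy.safe_factor
    return ef


def recommended_frequency(policy: FrequencyPolicy) -> int:
    """The frequency rounded up to whole days, as quoted in recommendations."""
    return math.ceil(compute_exposure_frequency(policy))


def frequency_curve(
    policy: FrequencyPolicy, limits: Sequence[float]
) -> pd.DataFrame:
    """EF as a function of the concentration limit over a grid.

    The curve is strictly decreasing with EF × C_l constant (all other
    constants fixed).
    """
    limits = np.asarray(limits, dtype=float)
    if limits.ndim != 1 or len(limits) == 0:
        raise ValidationError("limits grid must be a non-empty 1-D sequence")
    if (limits <= 0).any() or (np.diff(limits) <= 0).any():
        raise ValidationError("limits grid must be strictly positive and increasing")
    ef = [
        compute_exposure_frequency(replace(policy, conc_limit=float(c)))
        for c in limits
    ]
    return pd.DataFrame({"conc_limit": limits, "exposure_frequency": ef})
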