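"""From ventilation physiology to bench deformation velocities.

Preterm ventilation parameters (tidal volume, functional residual capacity,
inspiration time) are converted into the deformation velocity a uniaxial
test must apply to mimic inspiration on a punched tissue sample:

1. relative lung-volume increase  ΔV/V = V_T / FRC,
2. linear (radius) strain of the lung treated as a homogeneous sphere,
   ε = (1 + ΔV/V)^{1/3} − 1,
3. deformation velocity  v = ε · L / t_insp, reported in mm·min⁻¹ for a
   sample of length L stretched over one inspiration time.

All intermediates are carried unrounded; rounding happens only in report
formatting (the printed clinical figures — e.g. a ~18 % volume increase at
4 ml·kg⁻¹ tidal volume over a 21.4 ml·kg⁻¹ FRC giving a 5.9 % radius strain
and 26 mm·min⁻¹ — only reproduce from the unrounded chain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "VentilationScenario",
    "volume_increase_fraction",
    "radius_strain",
    "deformation_velocity",
    "velocity_table",
]


@dataclass(frozen=True)
class VentilationScenario:
    """Ventilation parameters defining one deformation-velocity estimate.

    Units: volumes in ml per kg body weight, inspiration time in s, sample
    length in mm.  ``max_linear_strain`` optionally replaces the
    sphere-model strain with a cap (e.g. 0.15, the largest strain lung cells
    tolerate elastically).
    """

    tidal_volume_ml_per_kg: float
    frc_ml_per_kg: float
    inspiration_time_s: float
    sample_length_mm: float = 2.0
    max_linear_strain: float | None = None

    def __post_init__(self) -> None:
        if self.tidal_volume_ml_per_kg < 0:
            raise ValueError("tidal volume must be nonnegative")
        if self.frc_ml_per_kg <= 0:
            raise ValueError("FRC must be positive")
        if self.inspiration_time_s <= 0:
            raise ValueError("inspiration time must be positive")
        if self.sample_length_mm <= 0:
            raise ValueError("sample length must be positive")
        if self.tidal_volume_ml_per_kg >= self.frc_ml_per_kg:
            warnings.warn("tidal volume >= FRC is physiologically implausible", stacklevel=2)

    def linear_strain(self) -> float:
        strain = radius_strain(volume_increase_fraction(self))
        if self.max_linear_strain is not None:
            strain = min(strain, self.max_linear_strain)
        return strain

    def deformation_velocity_mm_per_min(self) -> float:
        return deformation_velocity(
            self.linear_strain(), self.sample_length_mm, self.inspiration_time_s
        )


def volume_increase_fraction(scenario: VentilationScenario) -> float:
    """Relative lung-volume increase per breath, V_T / FRC (unrounded)."""
    return scenario.tidal_volume_ml_per_kg / scenario.frc_ml_per_kg


def radius_strain(volume_fraction: float) -> float:
    """Linear strain of a homogeneous sphere whose volume grows by ``volume_fraction``.

    ε = (1 + ΔV/V)^{1/3} − 1 ≈ (ΔV/V)/3 for small volume changes.
    """
    if volume_fraction <= -1:
        raise ValueError("volume fraction must exceed -1")
    return (1.0 + volume_fraction) ** (1.0 / 3.0) - 1.0


def deformation_velocity(
    linear_strain: float, sample_length_mm: float, inspiration_time_s: float
) -> float:
    """Deformation (expansion) velocity in mm·min⁻¹ for one inspiration.

    v = strain × sample length / inspiration time, converted from mm/s.
    """
    if linear_strain < 0:
        raise ValueError("linear strain must be nonnegative")
    if sample_length_mm <= 0:
        raise ValueError("sample length must be positive")
    if inspiration_time_s <= 0:
        raise ValueError("inspiration time must be positive")
    return linear_strain * sample_length_mm / inspiration_time_s * 60.0


def velocity_table(scenarios: list[VentilationScenario]) -> pd.DataFrame:
    """Tabulate the derivation chain for a set of scenarios.

    Columns carry both unrounded values and the report-rounded forms
    (percentages to one decimal, velocity to the nearest integer).
    """
    rows = []
    for s in scenarios:
        frac = volume_increase_fraction(s)
        strain = s.linear_strain()
        vel = s.deformation_velocity_mm_per_min()
        rows.append(
            {
                "tidal_volume_ml_per_kg": s.tidal_volume_ml_per_kg,
                "frc_ml_per_kg": s.frc_ml_per_kg,
                "inspiration_time_s": s.inspiration_time_s,
                "sample_length_mm": s.sample_length_mm,
                "volume_increase_fraction": frac,
                "volume_increase_pct": round(frac * 100, 1),
                "linear_strain": strain,
                "linear_strain_pct": round(strain * 100, 1),
                "velocity_mm_per_min": vel,
                "velocity_mm_per_min_rounded": round(vel),
            }
        )
    return pd.DataFrame(rows)
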