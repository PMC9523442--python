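"""Kilian's van der Waals rubber-network model for soft-tissue hyperelasticity.

The model treats the tissue as a network of chains with finite extensibility
and weak global interactions, in analogy with the van der Waals equation of
state for real gases.  For uniaxial loading at stretch ``λ`` (λ = 1
undeformed, λ < 1 compression, λ > 1 tension) the nominal stress is

    f(λ) = G · D(λ) · ( 1/(1 − η) − a · Φ(λ)^{1/2} )

with the deformation function ``D(λ) = λ − λ⁻²``, the conformation measure
``Φ(λ) = ½(λ² + 2/λ − 3)``, ``η = (Φ/Φ_m)^{1/2}`` and ``Φ_m = Φ(λ_m)``.
``G`` is the shear modulus (Pa), ``a`` the dimensionless global-interaction
parameter and ``λ_m`` the limiting stretch set by maximum chain
extensibility.  The stress diverges as η → 1 (strain stiffening) and reduces
to the neo-Hookean form ``G·D(λ)`` as a → 0, λ_m → ∞.

The associated strain-energy density is

    W(λ) = −G { 2 Φ_m [ln(1 − η) + η] + ⅔ a Φ^{3/2} }

with ``dW/dλ = f(λ)`` identically, and the small-strain (infinitesimal)
Young's modulus is ``E = 2G(1 + ν)`` — ``3G`` for incompressible tissue
(ν = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VdWParameters",
    "BeyondExtensibilityError",
    "deformation_function",
    "conformation_phi",
    "nominal_stress",
    "strain_energy",
    "young_from_shear",
]


class BeyondExtensibilityError(ValueError):
    """The evaluated stretch lies at or beyond the network's extensibility limit (η ≥ 1)."""


@dataclass(frozen=True)
class VdWParameters:
    """Constitutive parameters of one fitted van der Waals network.

    Parameters
    ----------
    shear_modulus_Pa : float
        Shear modulus G > 0 in Pa.
    interaction : float
        Global chain-interaction parameter a ≥ 0 (dimensionless).
    limit_stretch : float
        Limiting stretch λ_m > 1 from finite chain extensibility.
    poisson_ratio : float
        ν in [0, 0.5]; fixed at 0.5 (incompressible) for biological tissue
        and not a fitted quantity.
    """

    shear_modulus_Pa: float
    interaction: float
    limit_stretch: float
    poisson_ratio: float = field(default=0.5)

    def __post_init__(self) -> None:
        if not self.shear_modulus_Pa > 0:
            raise ValueError(f"shear modulus must be positive, got {self.shear_modulus_Pa}")
        if self.interaction < 0:
            raise ValueError(f"interaction parameter a must be nonnegative, got {self.interaction}")
        if not self.limit_stretch > 1:
            raise ValueError(f"limit stretch λ_m must exceed 1, got {self.limit_stretch}")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError(f"Poisson ratio must lie in [0, 0.5], got {self.poisson_ratio}")

    @property
    def young_modulus_Pa(self) -> float:
        """Young's modulus E = 2G(1+ν)."""
        return young_from_shear(self)


def _as_stretch(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch λ must be positive")
    return lam


def deformation_function(lam):
    """Deformation function D(λ) = λ − λ⁻²; zero at λ=1, sign follows loading direction."""
    lam = _as_stretch(lam)
    out = lam - lam**-2
    return out if out.ndim else float(out)


def conformation_phi(lam):
    """Conformation measure Φ(λ) = ½(λ² + 2/λ − 3); nonnegative, zero only at λ=1."""
    lam = _as_stretch(lam)
    out = 0.5 * (lam**2 + 2.0 / lam - 3.0)
    # clip the tiny negative round-off at λ≈1 so sqrt(Φ) stays real
    out = np.where(out < 0, 0.0, out)
    return out if out.ndim else float(out)


def _eta(lam, params: VdWParameters):
    phi_m = conformation_phi(params.limit_stretch)
    return np.sqrt(conformation_phi(lam) / phi_m)


def nominal_stress(lam, params: VdWParameters):
    """Nominal (first Piola) uniaxial stress f(λ) in Pa.

    Raises
    ------
    BeyondExtensibilityError
        If η(λ) ≥ 1, i.e. Φ(λ) reaches Φ(λ_m): the model diverges there and
        evaluation is refused rather than clamped.
    """
    lam = _as_stretch(lam)
    eta = _eta(lam, params)
    if np.any(eta >= 1):
        raise BeyondExtensibilityError(
            f"stretch beyond network extensibility: η ≥ 1 (λ_m = {params.limit_stretch})"
        )
    out = params.shear_modulus_Pa * deformation_function(lam) * (
        1.0 / (1.0 - eta) - params.interaction * np.sqrt(conformation_phi(lam))
    )
    return out if np.ndim(out) else float(out)


def strain_energy(lam, params: VdWParameters):
    """Strain-energy density W(λ) in Pa, with W(1) = 0 and dW/dλ = f(λ).

    W(λ) = −G { 2 Φ_m [ln(1−η) + η] + ⅔ a Φ^{3/2} }.
    """
    lam = _as_stretch(lam)
    eta = _eta(lam, params)
    if np.any(eta >= 1):
        raise BeyondExtensibilityError(
            f"stretch beyond network extensibility: η ≥ 1 (λ_m = {params.limit_stretch})"
        )
    phi = conformation_phi(lam)
    phi_m = conformation_phi(params.limit_stretch)
    out = -params.shear_modulus_Pa * (
        2.0 * phi_m * (np.log1p(-eta) + eta) + (2.0 / 3.0) * params.interaction * phi**1.5
    )
    return out if np.ndim(out) else float(out)


def young_from_shear(params: VdWParameters) -> float:
    """Young's modulus from the shear modulus, E = 2G(1+ν) (= 3G at ν = 0.5)."""
    return 2.0 * params.shear_modulus_Pa * (1.0 + params.poisson_ratio)
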