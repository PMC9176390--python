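"""Per-point dose-equivalent chain: thermal fluence → total fluence → H_n.

The neutron dose equivalent at a phantom point is

    H_n = Φ · ∫ Q(E) k(E) (dφ/dE) dE,

with the total fluence recovered from the TLD-measured thermal fluence and
the thermal fraction of the (simulated or synthetic) unit spectrum,
Φ = Φ_th / p_th.  The photon contribution adds linearly; uncertainties
combine in quadrature at the standard (k = 1) level with a three-component
budget: Monte Carlo counting statistics, TLD experiment, and transport-model
systematics.

Unit bookkeeping: fluence in cm⁻²·Gy⁻¹, coefficients in pSv·cm², doses in
mSv per treatment Gy (1 pSv·cm² × 1 cm⁻² = 1e-9 mSv).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .conversion import ConversionTable, fold
from .errors import InvalidDomainError, InvalidFractionError, NormalizationError
from .spectra import GroupBoundaries, NeutronSpectrum, group_fractions
from .tld import CalibrationSet, TLDPairReading, photon_dose, thermal_fluence

__all__ = [
    "PSV_CM2_TO_MSV",
    "UncertaintyBudget",
    "PointDose",
    "total_fluence",
    "neutron_dose_equivalent",
    "total_dose",
    "combine_relative",
    "point_dose_chain",
]

#: 1 pSv·cm² folded with 1 cm⁻² of fluence is 1e-9 mSv.
PSV_CM2_TO_MSV = 1e-9


@dataclass(frozen=True)
class UncertaintyBudget:
    """Relative (k=1) uncertainty components applied to the neutron dose."""

    mc_statistical: float = 0.08
    tld_experimental: float = 0.15
    model_systematic: float = 0.20

    def __post_init__(self) -> None:
        for name in ("mc_statistical", "tld_experimental", "model_systematic"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise InvalidDomainError(f"{name} must lie in [0, 1)")


def combine_relative(budget: UncertaintyBudget) -> float:
    """Quadrature sum of the budget components (0.262 for the defaults)."""
    return math.sqrt(
        budget.mc_statistical**2
        + budget.tld_experimental**2
        + budget.model_systematic**2
    )


@dataclass(frozen=True)
class PointDose:
    """Photon, neutron and total dose equivalent at a phantom point, mSv/Gy."""

    point_id: int | str
    h_gamma: float
    u_gamma: float
    h_neutron: float
    u_neutron: float
    h_total: float
    u_total: float

    def __post_init__(self) -> None:
        if min(self.h_gamma, self.h_neutron, self.h_total) < 0.0:
            raise InvalidDomainError("dose equivalents must be non-negative")
        if abs(self.h_total - (self.h_gamma + self.h_neutron)) > 1e-9 * max(
            1.0, self.h_total
        ):
            raise InvalidDomainError("h_total must equal h_gamma + h_neutron")


def total_fluence(phi_th: float, p_th: float) -> float:
    """Total fluence Φ = Φ_th / p_th from the thermal fluence and fraction."""
    if phi_th < 0.0:
        raise InvalidDomainError("thermal fluence must be non-negative")
    if not (0.0 < p_th <= 1.0):
        raise InvalidFractionError(f"thermal fraction must lie in (0, 1], got {p_th!r}")
    return phi_th / p_th


def neutron_dose_equivalent(
    phi: float,
    unit_spec: NeutronSpectrum,
    qk: ConversionTable,
    budget: UncertaintyBudget | None = None,
) -> tuple[float, float]:
    """Neutron dose equivalent (mSv per treatment Gy) and its uncertainty.

    ``phi`` is the total fluence in cm⁻²·Gy⁻¹; ``unit_spec`` must be
    unit-normalized so that the fold gives the fluence-averaged Q·k.
    """
    if phi < 0.0:
        raise InvalidDomainError("total fluence must be non-negative")
    if unit_spec.normalization != "unit":
        raise NormalizationError("neutron_dose_equivalent requires a unit spectrum")
    budget = budget or UncertaintyBudget()
    h_n = phi * fold(unit_spec, qk) * PSV_CM2_TO_MSV
    return h_n, h_n * combine_relative(budget)


def total_dose(
    point_id: int | str,
    h_gamma: tuple[float, float],
    h_neutron: tuple[float, float],
) -> PointDose:
    """Sum the photon and neutron dose equivalents; uncertainties in quadrature."""
    hg, ug = h_gamma
    hn, un = h_neutron
    if hg < 0.0 or hn < 0.0:
        raise InvalidDomainError("dose equivalents must be non-negative")
    return PointDose(point_id, hg, ug, hn, un, hg + hn, math.hypot(ug, un))


def point_dose_chain(
    reading: TLDPairReading,
    unit_spec: NeutronSpectrum,
    qk: ConversionTable,
    calib: CalibrationSet | None = None,
    budget: UncertaintyBudget | None = None,
    bounds: GroupBoundaries | None = None,
) -> PointDose:
    """Full chain at one point: pair readout → Φ_th → Φ → H_n; plus H_γ.

    The thermal fraction p_th is the thermal group fraction of the supplied
    unit spectrum, using the same group definition as ``group_fractions``.
    """
    calib = calib or CalibrationSet()
    phi_th, _, _ = thermal_fluence(reading, calib)
    p_th = group_fractions(unit_spec, bounds).thermal
    phi = total_fluence(phi_th, p_th)
    h_n = neutron_dose_equivalent(phi, unit_spec, qk, budget)
    h_g = photon_dose(reading, calib)
    return total_dose(reading.point_id, tuple(h_g), h_n)
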