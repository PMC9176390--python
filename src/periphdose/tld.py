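"""TLD-600/TLD-700 pair dosimetry.

The ⁶LiF chip (TLD-600) responds to both photons and thermal neutrons, the
⁷LiF chip (TLD-700) essentially to photons only, so the pair difference
isolates the thermal-neutron signal:

    Φ_th = f_n · [ R600 − (f700γ / f600γ) · R700 ]

while the photon dose equivalent comes straight from the TLD-700 absorbed
dose with radiation weighting factor w_R = 1.  Readouts are assumed already
normalized per treatment Gy; all outputs are per treatment Gy.

Default calibration factors: f_n = 488 n·cm⁻² per au (6 %),
f700γ = 1.86e-4 mGy/au (4 %), f600γ = 1.99e-4 mGy/au (5 %).  Uncertainties
propagate to first order in quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import math

from .errors import InconsistentPairError, InvalidDomainError

__all__ = [
    "TLDPairReading",
    "CalibrationSet",
    "DoseValue",
    "ThermalFluenceResult",
    "thermal_fluence",
    "photon_dose",
    "invert_pair",
]


@dataclass(frozen=True)
class TLDPairReading:
    """Raw pair readouts in arbitrary units (au), per treatment Gy."""

    point_id: int | str
    r600: float
    r700: float
    u_r600: float = 0.0
    u_r700: float = 0.0

    def __post_init__(self) -> None:
        if self.r600 < 0.0 or self.r700 < 0.0:
            raise InvalidDomainError("TLD readouts must be non-negative")
        if self.u_r600 < 0.0 or self.u_r700 < 0.0:
            raise InvalidDomainError("readout uncertainties must be non-negative")


@dataclass(frozen=True)
class CalibrationSet:
    """Calibration factors and their relative standard uncertainties."""

    f_n: float = 488.0  # n cm^-2 per au
    u_f_n_rel: float = 0.06
    f700_gamma: float = 1.86e-4  # mGy per au
    u_f700_rel: float = 0.04
    f600_gamma: float = 1.99e-4  # mGy per au
    u_f600_rel: float = 0.05

    def __post_init__(self) -> None:
        if min(self.f_n, self.f700_gamma, self.f600_gamma) <= 0.0:
            raise InvalidDomainError("calibration factors must be positive")
        for u in (self.u_f_n_rel, self.u_f700_rel, self.u_f600_rel):
            if not (0.0 <= u < 1.0):
                raise InvalidDomainError("relative uncertainties must lie in [0, 1)")

    @property
    def gamma_ratio(self) -> float:
        """f700γ / f600γ — the photon-subtraction weight in the pair difference."""
        return self.f700_gamma / self.f600_gamma

    @property
    def u_gamma_ratio_rel(self) -> float:
        return math.hypot(self.u_f700_rel, self.u_f600_rel)


class ThermalFluenceResult(NamedTuple):
    value: float  # cm^-2 per treatment Gy
    uncertainty: float
    clipped: bool


class DoseValue(NamedTuple):
    value: float  # mSv per treatment Gy
    uncertainty: float


def thermal_fluence(
    reading: TLDPairReading, calib: CalibrationSet | None = None
) -> ThermalFluenceResult:
    """Thermal neutron fluence from a TLD pair, cm⁻² per treatment Gy.

    Negative net signals within two combined standard uncertainties of zero
    are clipped to zero (flagged); a more negative net signal raises
    :class:`InconsistentPairError`.
    """
    calib = calib or CalibrationSet()
    ratio = calib.gamma_ratio
    net = reading.r600 - ratio * reading.r700
    # first-order propagation: readouts, gamma-ratio, neutron factor
    u_net_sq = (
        reading.u_r600**2
        + (ratio * reading.u_r700) ** 2
        + (ratio * reading.r700 * calib.u_gamma_ratio_rel) ** 2
    )
    phi = calib.f_n * net
    u_phi = math.sqrt(
        (phi * calib.u_f_n_rel) ** 2 + (calib.f_n**2) * u_net_sq
    )
    clipped = False
    if phi < 0.0:
        if phi < -2.0 * u_phi:
            raise InconsistentPairError(
                f"point {reading.point_id}: net TLD signal {net:g} au is more than "
                "2 sigma below zero — pair inconsistent"
            )
        warnings.warn(
            f"point {reading.point_id}: negative net TLD signal clipped to zero",
            stacklevel=2,
        )
        phi, clipped = 0.0, True
    return ThermalFluenceResult(phi, u_phi, clipped)


def photon_dose(
    reading: TLDPairReading, calib: CalibrationSet | None = None
) -> DoseValue:
    """Photon dose equivalent from the TLD-700 readout, mSv per treatment Gy.

    Absorbed dose in mGy maps one-to-one to mSv (w_R = 1).
    """
    calib = calib or CalibrationSet()
    h = calib.f700_gamma * reading.r700
    u = math.sqrt(
        (h * calib.u_f700_rel) ** 2 + (calib.f700_gamma * reading.u_r700) ** 2
    )
    return DoseValue(h, u)


def invert_pair(
    phi_th: float,
    h_gamma: float,
    calib: CalibrationSet | None = None,
    point_id: int | str = 0,
) -> TLDPairReading:
    """Exact algebraic inverse: readouts that reproduce (Φ_th, H_γ).

    Fixture generator for synthetic campaigns; round-trips through
    :func:`thermal_fluence` and :func:`photon_dose` to relative 1e-9.
    """
    if phi_th < 0.0 or h_gamma < 0.0:
        raise InvalidDomainError("target fluence and photon dose must be non-negative")
    calib = calib or CalibrationSet()
    r700 = h_gamma / calib.f700_gamma
    r600 = phi_th / calib.f_n + calib.gamma_ratio * r700
    return TLDPairReading(point_id, r600, r700)
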