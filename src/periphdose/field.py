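"""Reduce an absolute in-room neutron spectrum to its dosimetric summary.

The summary carries the quantities used to characterize a treatment-room
neutron field per treatment Gy: total fluence Φ (cm⁻²·Gy⁻¹), ambient dose
equivalent H*(10) (µSv·Gy⁻¹), the fluence- and dose-averaged energies
(MeV), the spectrum-averaged conversion coefficient h*(10) = H*(10)/Φ
(pSv·cm²), and the four-group shares of both fluence and H*(10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conversion import ConversionTable, dose_avg_energy, fold
from .errors import DegenerateSpectrumError, InvalidDomainError
from .spectra import (
    GROUP_NAMES,
    GroupBoundaries,
    GroupFractions,
    NeutronSpectrum,
    fluence_avg_energy,
    group_fractions,
    masked_to_group,
)

__all__ = ["FieldSummary", "summarize_field", "hstar_coefficient"]

#: pSv -> µSv
_PSV_TO_USV = 1e-6


@dataclass(frozen=True)
class FieldSummary:
    total_fluence: float  # cm^-2 Gy^-1
    h_star_10: float  # µSv Gy^-1
    e_phi: float  # MeV
    e_hstar: float  # MeV
    h_star_coeff: float  # pSv cm^2
    fluence_fractions: GroupFractions
    hstar_fractions: GroupFractions

    def __post_init__(self) -> None:
        recon = self.h_star_coeff * self.total_fluence * _PSV_TO_USV
        if abs(recon - self.h_star_10) > 1e-6 * max(self.h_star_10, 1e-300):
            raise InvalidDomainError(
                "inconsistent summary: h*(10) coefficient × fluence != H*(10)"
            )

    def to_frame(self) -> pd.DataFrame:
        """One-row table in the standard reporting units."""
        row = {
            "phi_cm2_gy": self.total_fluence,
            "hstar10_usv_gy": self.h_star_10,
            "e_phi_mev": self.e_phi,
            "e_hstar_mev": self.e_hstar,
            "hstar_coeff_psv_cm2": self.h_star_coeff,
        }
        for name, f in zip(GROUP_NAMES, self.fluence_fractions.as_array()):
            row[f"fluence_frac_{name}"] = f
        for name, f in zip(GROUP_NAMES, self.hstar_fractions.as_array()):
            row[f"hstar_frac_{name}"] = f
        return pd.DataFrame([row])


def summarize_field(
    spec: NeutronSpectrum,
    hstar_table: ConversionTable,
    bounds: GroupBoundaries | None = None,
) -> FieldSummary:
    """Summarize an *absolute* spectrum (cm⁻²·Gy⁻¹) into the standard quantity set.

    Group H*(10) shares fold each group's masked sub-spectrum, with straddling
    bins split by log-energy overlap exactly as in ``group_fractions``.
    """
    total = spec.total()
    if total <= 0.0:
        raise DegenerateSpectrumError("cannot summarize a zero-fluence spectrum")
    bounds = bounds or GroupBoundaries()
    h_psv = fold(spec, hstar_table)
    group_h = np.array(
        [fold(masked_to_group(spec, g, bounds), hstar_table) for g in range(4)]
    )
    return FieldSummary(
        total_fluence=total,
        h_star_10=h_psv * _PSV_TO_USV,
        e_phi=fluence_avg_energy(spec),
        e_hstar=dose_avg_energy(spec, hstar_table),
        h_star_coeff=h_psv / total,
        fluence_fractions=group_fractions(spec, bounds),
        hstar_fractions=GroupFractions.from_array(group_h / group_h.sum()),
    )


def hstar_coefficient(total_fluence: float, h_star_10: float) -> float:
    """Spectrum-averaged h*(10) = H*(10)/Φ in pSv·cm².

    ``total_fluence`` in cm⁻²·Gy⁻¹, ``h_star_10`` in µSv·Gy⁻¹.
    """
    if total_fluence <= 0.0 or h_star_10 <= 0.0:
        raise InvalidDomainError("fluence and H*(10) must be positive")
    return h_star_10 / _PSV_TO_USV / total_fluence
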