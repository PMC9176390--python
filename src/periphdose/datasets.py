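"""Bundled reference campaign: a head irradiation in a passive 200 MeV proton beam.

Per-point inputs measured/simulated inside the anthropomorphic phantom during
a brain-treatment irradiation: four-group neutron fluence fractions of the
simulated unit spectra (printed as integer percent), and the TLD-pair results
— thermal neutron fluence and photon dose equivalent per treatment Gy.  The
isocenter point (2) carried no TLD pair and has fractions only.

These numbers are campaign *inputs* for the dose pipeline; spectra themselves
are regenerated synthetically at the group-fraction level.
"""

from __future__ import annotations

import math

import pandas as pd

from .spectra import GroupFractions

__all__ = [
    "head_campaign",
    "campaign_fractions",
    "instrumented_points",
    "ROOM_POINT_A_EXPERIMENTAL",
    "ROOM_POINT_B_EXPERIMENTAL",
    "ROOM_POINT_B_SIMULATION",
]

# point, thermal%, epithermal%, fast%, high%, phi_th (1e6 cm^-2/Gy), u,
# photon dose (1e-2 mSv/Gy), u.  NaN marks the uninstrumented isocenter.
_NAN = float("nan")
_CAMPAIGN_ROWS = [
    (1, 54, 14, 18, 14, 6.29, 0.38, 9.23, 0.37),
    (2, 48, 12, 22, 19, _NAN, _NAN, _NAN, _NAN),
    (3, 57, 14, 17, 12, 8.27, 0.50, 12.09, 0.48),
    (4, 56, 15, 18, 11, 9.47, 0.57, 9.23, 0.37),
    (5, 61, 16, 14, 9, 5.34, 0.32, 7.19, 0.29),
    (6, 58, 16, 16, 9, 6.05, 0.36, 7.40, 0.30),
    (7, 47, 17, 23, 13, 5.53, 0.33, 11.64, 0.47),
    (8, 47, 18, 22, 14, 5.61, 0.34, 10.52, 0.42),
    (9, 58, 15, 12, 15, 4.67, 0.28, 5.12, 0.20),
    (10, 59, 9, 12, 20, 2.82, 0.17, 3.73, 0.15),
    (11, 54, 7, 14, 25, 1.320, 0.079, 3.71, 0.15),
    (12, 58, 9, 12, 21, 2.32, 0.14, 4.21, 0.17),
    (13, 61, 10, 13, 15, 2.86, 0.17, 3.42, 0.14),
    (14, 60, 10, 14, 16, 3.19, 0.19, 4.30, 0.17),
    (15, 55, 18, 14, 13, 3.71, 0.22, 3.46, 0.14),
    (16, 57, 13, 17, 13, 7.30, 0.44, 10.22, 0.41),
]

# In-room field characterization at the two spectrometry positions
# (fluence fractions as decimal shares; used as generator targets).
ROOM_POINT_A_EXPERIMENTAL = {
    "fluence_fractions": (0.309, 0.371, 0.291, 0.029),
    "hstar_fractions": (0.030, 0.041, 0.853, 0.076),
    "phi_cm2_gy": 1.489e6,
    "u_phi": 0.055e6,
    "hstar10_usv_gy": 184.0,
    "u_hstar10": 12.0,
    "e_phi_mev": 3.90,
    "e_hstar_mev": 9.66,
    "hstar_coeff_psv_cm2": 123.7,
}
ROOM_POINT_B_EXPERIMENTAL = {
    "fluence_fractions": (0.318, 0.355, 0.306, 0.020),
    "hstar_fractions": (0.029, 0.038, 0.884, 0.049),
    "phi_cm2_gy": 1.577e6,
    "u_phi": 0.063e6,
    "hstar10_usv_gy": 203.0,
    "u_hstar10": 13.0,
    "e_phi_mev": 3.10,
    "e_hstar_mev": 7.70,
    "hstar_coeff_psv_cm2": 129.8,
}
ROOM_POINT_B_SIMULATION = {
    "fluence_fractions": (0.361, 0.242, 0.355, 0.042),
    "hstar_fractions": (0.028, 0.026, 0.839, 0.107),
}


def head_campaign() -> pd.DataFrame:
    """The per-point campaign table.

    Columns: ``point_id``, integer-percent fluence fractions
    (``thermal_pct`` .. ``high_pct``), ``phi_th`` / ``u_phi_th``
    (cm⁻²·Gy⁻¹) and ``h_gamma`` / ``u_h_gamma`` (mSv·Gy⁻¹); the
    uninstrumented isocenter row has NaN TLD columns.
    """
    df = pd.DataFrame(
        _CAMPAIGN_ROWS,
        columns=[
            "point_id",
            "thermal_pct",
            "epithermal_pct",
            "fast_pct",
            "high_pct",
            "phi_th",
            "u_phi_th",
            "h_gamma",
            "u_h_gamma",
        ],
    )
    for col in ("phi_th", "u_phi_th"):
        df[col] = df[col] * 1e6
    for col in ("h_gamma", "u_h_gamma"):
        df[col] = df[col] * 1e-2
    return df


def campaign_fractions(point_id: int) -> GroupFractions:
    """Normalized four-group fluence fractions for one campaign point."""
    for row in _CAMPAIGN_ROWS:
        if row[0] == point_id:
            return GroupFractions.from_percent(*row[1:5])
    raise KeyError(f"no campaign point {point_id}")


def instrumented_points() -> list[int]:
    """Ids of the 15 points that carried a TLD pair (isocenter excluded)."""
    return [row[0] for row in _CAMPAIGN_ROWS if not math.isnan(row[5])]
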