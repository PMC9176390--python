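"""Energy grids, neutron spectra, group decomposition and parametric shapes.

Conventions
-----------
Spectra are stored as per-bin *integrated* fluence — cm⁻²·Gy⁻¹ when absolute,
dimensionless summing to one when unit-normalized — never as densities.  With
that choice group sums and coefficient folding are exact bin sums.  For
plotting, the conventional per-lethargy density is
``bin_fluence / ln(E_hi / E_lo)``.

Energies are in MeV throughout.  The default grid spans 1e-9 MeV (1 meV) to
200 MeV at 10 bins per decade, the eleven energy decades a Bonner sphere
spectrometer covers.

The four-group decomposition uses the standard boundaries: thermal
E ≤ 0.4 eV, epithermal 0.4 eV – 0.1 MeV, fast 0.1 – 20 MeV and high energy
above 20 MeV.  A bin straddling a boundary is split between the two groups in
proportion to log-energy overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import DegenerateSpectrumError, GridMismatchError, InvalidDomainError

__all__ = [
    "DEFAULT_EMIN",
    "DEFAULT_EMAX",
    "THERMAL_TEMPERATURE_MEV",
    "HIGH_PEAK_LOG10_WIDTH",
    "EnergyGrid",
    "GroupBoundaries",
    "GroupFractions",
    "NeutronSpectrum",
    "ParametricSpectrum",
    "make_log_grid",
    "normalize",
    "group_overlap_matrix",
    "group_fluences",
    "group_fractions",
    "masked_to_group",
    "fluence_avg_energy",
    "component_shapes",
    "make_parametric",
    "rebin",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

DEFAULT_EMIN = 1e-9  # MeV
DEFAULT_EMAX = 200.0  # MeV

#: Temperature of the thermal Maxwellian component (kT at 293 K), MeV.
THERMAL_TEMPERATURE_MEV = 2.53e-8

#: Fixed relative width (in log10 E) of the high-energy peak component.
HIGH_PEAK_LOG10_WIDTH = 0.25

GROUP_NAMES = ("thermal", "epithermal", "fast", "high_energy")


@dataclass
class EnergyGrid:
    """A strictly increasing set of positive bin edges, length n+1 for n bins."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.ndim != 1 or self.edges.size < 2:
            raise InvalidDomainError("grid needs at least two edges (one bin)")
        if np.any(self.edges <= 0.0):
            raise InvalidDomainError("all grid edges must be positive")
        if np.any(np.diff(self.edges) <= 0.0):
            raise InvalidDomainError("grid edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def midpoints(self) -> np.ndarray:
        """Geometric bin midpoints — the representative energies on a log grid."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def log_widths(self) -> np.ndarray:
        """Natural-log bin widths (lethargy widths)."""
        return np.diff(np.log(self.edges))

    def refine(self, factor: int = 2) -> "EnergyGrid":
        """A grid with every bin split into ``factor`` log-equal sub-bins."""
        if factor < 1:
            raise InvalidDomainError("refinement factor must be >= 1")
        loge = np.log(self.edges)
        parts = [
            np.linspace(loge[i], loge[i + 1], factor + 1)[:-1]
            for i in range(self.n_bins)
        ]
        new = np.exp(np.concatenate(parts + [loge[-1:]]))
        new[0] = self.edges[0]
        new[-1] = self.edges[-1]
        return EnergyGrid(new)

    def compatible_with(self, other: "EnergyGrid") -> bool:
        return self.edges.size == other.edges.size and np.allclose(
            self.edges, other.edges, rtol=1e-12, atol=0.0
        )


def make_log_grid(
    emin: float = DEFAULT_EMIN,
    emax: float = DEFAULT_EMAX,
    bins_per_decade: int = 10,
) -> EnergyGrid:
    """Logarithmically spaced grid from ``emin`` up to (at least) ``emax``.

    The bin count is ``ceil(bins_per_decade * log10(emax/emin))``; the last
    edge may therefore overshoot ``emax`` by less than one bin width.
    """
    if not (0.0 < emin < emax):
        raise InvalidDomainError(
            f"need 0 < emin < emax, got emin={emin!r}, emax={emax!r}"
        )
    if bins_per_decade < 1:
        raise InvalidDomainError("bins_per_decade must be >= 1")
    n = math.ceil(bins_per_decade * math.log10(emax / emin) - 1e-12)
    edges = emin * 10.0 ** (np.arange(n + 1) / bins_per_decade)
    edges[0] = emin
    return EnergyGrid(edges)


@dataclass(frozen=True)
class GroupBoundaries:
    """Energy-group boundaries in MeV (thermal ≤ 0.4 eV, ..., high > 20 MeV)."""

    thermal_upper: float = 4.0e-7
    epithermal_upper: float = 0.1
    fast_upper: float = 20.0
    maximum: float = 200.0

    def __post_init__(self) -> None:
        seq = (self.thermal_upper, self.epithermal_upper, self.fast_upper, self.maximum)
        if any(b <= a for a, b in zip(seq, seq[1:])) or seq[0] <= 0:
            raise InvalidDomainError("group boundaries must be positive and increasing")


@dataclass(frozen=True)
class GroupFractions:
    """Four-group fluence (or dose) shares, each in [0,1], summing to one."""

    thermal: float
    epithermal: float
    fast: float
    high_energy: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-9) or np.any(arr > 1.0 + 1e-9):
            raise InvalidDomainError(f"fractions must lie in [0,1], got {arr}")
        if abs(arr.sum() - 1.0) > 1e-6:
            raise InvalidDomainError(f"fractions must sum to 1, got {arr.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.thermal, self.epithermal, self.fast, self.high_energy], dtype=float
        )

    @classmethod
    def from_array(cls, arr) -> "GroupFractions":
        a = np.asarray(arr, dtype=float)
        return cls(*a.tolist())

    @classmethod
    def from_percent(cls, thermal, epithermal, fast, high_energy) -> "GroupFractions":
        """Build from printed percentages, renormalizing rounding residue."""
        a = np.array([thermal, epithermal, fast, high_energy], dtype=float)
        if np.any(a < 0):
            raise InvalidDomainError("percentages must be non-negative")
        total = a.sum()
        if total <= 0:
            raise InvalidDomainError("percentages must not all be zero")
        return cls.from_array(a / total)


@dataclass
class NeutronSpectrum:
    """Per-bin integrated fluence on an :class:`EnergyGrid`.

    ``normalization`` is ``"absolute"`` (cm⁻²·Gy⁻¹) or ``"unit"``
    (dimensionless, summing to one).
    """

    grid: EnergyGrid
    bin_fluence: np.ndarray
    bin_uncertainty: np.ndarray | None = None
    normalization: str = "absolute"

    def __post_init__(self) -> None:
        self.bin_fluence = np.asarray(self.bin_fluence, dtype=float)
        if self.bin_fluence.shape != (self.grid.n_bins,):
            raise GridMismatchError(
                f"fluence length {self.bin_fluence.size} != {self.grid.n_bins} bins"
            )
        if np.any(self.bin_fluence < 0.0):
            raise InvalidDomainError("bin fluence must be non-negative")
        if self.bin_uncertainty is not None:
            self.bin_uncertainty = np.asarray(self.bin_uncertainty, dtype=float)
            if self.bin_uncertainty.shape != self.bin_fluence.shape:
                raise GridMismatchError("uncertainty length differs from fluence")
            if np.any(self.bin_uncertainty < 0.0):
                raise InvalidDomainError("bin uncertainties must be non-negative")
        if self.normalization not in ("absolute", "unit"):
            raise InvalidDomainError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "unit" and abs(self.total() - 1.0) > 1e-9:
            raise InvalidDomainError("unit spectrum must sum to 1 within 1e-9")

    def total(self) -> float:
        return float(self.bin_fluence.sum())

    def per_lethargy(self) -> np.ndarray:
        """Fluence per unit lethargy, the usual plotting convention."""
        return self.bin_fluence / self.grid.log_widths


def normalize(spec: NeutronSpectrum) -> NeutronSpectrum:
    """Scale a spectrum to unit total fluence (shape preserving)."""
    total = spec.total()
    if total <= 0.0:
        raise DegenerateSpectrumError("cannot normalize a zero-fluence spectrum")
    u = None if spec.bin_uncertainty is None else spec.bin_uncertainty / total
    phi = spec.bin_fluence / total
    # force exact unit sum against fp rounding
    phi = phi / phi.sum()
    return NeutronSpectrum(spec.grid, phi, u, "unit")


def group_overlap_matrix(grid: EnergyGrid, bounds: GroupBoundaries | None = None) -> np.ndarray:
    """(n_bins, 4) matrix of log-overlap shares of each bin with each group.

    Rows sum to one; a bin fully inside a group has a single unit entry.  The
    outermost groups are unbounded so that grids extending slightly past the
    nominal maximum are still fully assigned.
    """
    bounds = bounds or GroupBoundaries()
    lo = np.log(grid.edges[:-1])
    hi = np.log(grid.edges[1:])
    cuts = np.log(
        [bounds.thermal_upper, bounds.epithermal_upper, bounds.fast_upper]
    )
    gl = np.concatenate(([-np.inf], cuts))
    gu = np.concatenate((cuts, [np.inf]))
    ov = np.clip(
        np.minimum(hi[:, None], gu[None, :]) - np.maximum(lo[:, None], gl[None, :]),
        0.0,
        None,
    )
    return ov / (hi - lo)[:, None]


def group_fluences(
    spec: NeutronSpectrum, bounds: GroupBoundaries | None = None
) -> np.ndarray:
    """Absolute fluence in each of the four groups (sums to the total)."""
    w = group_overlap_matrix(spec.grid, bounds)
    return w.T @ spec.bin_fluence


def group_fractions(
    spec: NeutronSpectrum, bounds: GroupBoundaries | None = None
) -> GroupFractions:
    """Four-group fluence fractions of a spectrum."""
    total = spec.total()
    if total <= 0.0:
        raise DegenerateSpectrumError("group fractions of a zero-fluence spectrum")
    g = group_fluences(spec, bounds) / total
    return GroupFractions.from_array(g / g.sum())


def masked_to_group(
    spec: NeutronSpectrum, group: int | str, bounds: GroupBoundaries | None = None
) -> NeutronSpectrum:
    """The sub-spectrum belonging to one group (straddling bins split by log overlap)."""
    if isinstance(group, str):
        group = GROUP_NAMES.index(group)
    w = group_overlap_matrix(spec.grid, bounds)[:, group]
    return NeutronSpectrum(spec.grid, spec.bin_fluence * w, None, "absolute")


def fluence_avg_energy(spec: NeutronSpectrum) -> float:
    """Fluence-weighted mean of the geometric bin-midpoint energies, MeV."""
    total = spec.total()
    if total <= 0.0:
        raise DegenerateSpectrumError("average energy of a zero-fluence spectrum")
    return float(np.dot(spec.bin_fluence, spec.grid.midpoints) / total)


@dataclass(frozen=True)
class ParametricSpectrum:
    """Reduced parametric model of a workplace neutron spectrum.

    Four physically motivated components — thermal Maxwellian, epithermal
    power law, evaporation peak, high-energy peak — with at most seven free
    parameters.  Each amplitude is the *total fluence* of its component, so
    the model is linear in the amplitudes.
    """

    amp_thermal: float = 0.0
    amp_epithermal: float = 0.0
    amp_evaporation: float = 0.0
    amp_high: float = 0.0
    slope_b: float = 1.0
    temp_evap: float = 1.0  # MeV
    peak_high: float = 100.0  # MeV

    def __post_init__(self) -> None:
        for name in ("amp_thermal", "amp_epithermal", "amp_evaporation", "amp_high"):
            if getattr(self, name) < 0.0:
                raise InvalidDomainError(f"{name} must be non-negative")
        if not (0.5 <= self.slope_b <= 1.5):
            raise InvalidDomainError("slope_b must lie in [0.5, 1.5]")
        if not (0.3 <= self.temp_evap <= 3.0):
            raise InvalidDomainError("temp_evap must lie in [0.3, 3] MeV")
        if not (30.0 <= self.peak_high <= 180.0):
            raise InvalidDomainError("peak_high must lie in [30, 180] MeV")

    def amplitudes(self) -> np.ndarray:
        return np.array(
            [self.amp_thermal, self.amp_epithermal, self.amp_evaporation, self.amp_high]
        )


def _maxwellian_bins(edges: np.ndarray, temperature: float) -> np.ndarray:
    # flux density ~ E exp(-E/T); antiderivative -(E T + T^2) exp(-E/T)
    with np.errstate(under="ignore"):
        antider = -(edges * temperature + temperature**2) * np.exp(-edges / temperature)
    return np.diff(antider)


def _powerlaw_bins(
    edges: np.ndarray, slope_b: float, lo: float, hi: float
) -> np.ndarray:
    # density ~ E^-b confined to (lo, hi)
    a = np.clip(edges[:-1], lo, hi)
    b = np.clip(edges[1:], lo, hi)
    out = np.zeros(edges.size - 1)
    mask = b > a
    if abs(slope_b - 1.0) < 1e-12:
        out[mask] = np.log(b[mask] / a[mask])
    else:
        p = 1.0 - slope_b
        out[mask] = (b[mask] ** p - a[mask] ** p) / p
    return out


def _evaporation_bins(edges: np.ndarray, temperature: float) -> np.ndarray:
    # density ~ (E/T^2) exp(-E/T); antiderivative -(E + T) exp(-E/T) / T
    with np.errstate(under="ignore"):
        antider = -(edges + temperature) * np.exp(-edges / temperature) / temperature
    return np.diff(antider)


def _highpeak_bins(
    edges: np.ndarray, peak: float, width: float = HIGH_PEAK_LOG10_WIDTH
) -> np.ndarray:
    # Gaussian in log10 E, fixed relative width
    z = (np.log10(edges) - math.log10(peak)) / width
    return np.diff(ndtr(z))


def component_shapes(params: ParametricSpectrum, grid: EnergyGrid) -> np.ndarray:
    """(n_bins, 4) matrix of unit-normalized component shapes on ``grid``.

    Columns follow the group order thermal, epithermal, evaporation, high.
    A column with no support on the grid is left all-zero.
    """
    bounds = GroupBoundaries()
    cols = [
        _maxwellian_bins(grid.edges, THERMAL_TEMPERATURE_MEV),
        _powerlaw_bins(grid.edges, params.slope_b, bounds.thermal_upper, bounds.epithermal_upper),
        _evaporation_bins(grid.edges, params.temp_evap),
        _highpeak_bins(grid.edges, params.peak_high),
    ]
    out = np.zeros((grid.n_bins, 4))
    for j, c in enumerate(cols):
        c = np.clip(c, 0.0, None)  # guard fp round-off at antiderivative diffs
        s = c.sum()
        if s > 0.0:
            out[:, j] = c / s
    return out


def make_parametric(params: ParametricSpectrum, grid: EnergyGrid) -> NeutronSpectrum:
    """Evaluate the four-component parametric model on a grid.

    Returns an absolute spectrum whose total fluence equals the sum of the
    component amplitudes; normalize it for use as a unit spectrum.
    """
    shapes = component_shapes(params, grid)
    phi = shapes @ params.amplitudes()
    if phi.sum() <= 0.0:
        raise DegenerateSpectrumError(
            "parametric spectrum has zero fluence (all amplitudes zero or no support)"
        )
    return NeutronSpectrum(grid, phi, None, "absolute")


def rebin(spec: NeutronSpectrum, new_grid: EnergyGrid) -> NeutronSpectrum:
    """Redistribute per-bin fluence onto a new grid by log-energy overlap.

    The new grid must cover the old one; total fluence is conserved exactly.
    """
    lo_o, hi_o = np.log(spec.grid.edges[:-1]), np.log(spec.grid.edges[1:])
    lo_n, hi_n = np.log(new_grid.edges[:-1]), np.log(new_grid.edges[1:])
    if lo_n[0] > lo_o[0] + 1e-12 or hi_n[-1] < hi_o[-1] - 1e-12:
        raise GridMismatchError("new grid does not cover the old grid span")
    ov = np.clip(
        np.minimum(hi_o[:, None], hi_n[None, :]) - np.maximum(lo_o[:, None], lo_n[None, :]),
        0.0,
        None,
    ) / (hi_o - lo_o)[:, None]
    phi = ov.T @ spec.bin_fluence
    u = None
    if spec.bin_uncertainty is not None:
        u = np.sqrt(ov.T**2 @ spec.bin_uncertainty**2)
    return NeutronSpectrum(new_grid, phi, u, "absolute")


# ---------------------------------------------------------------------------
# CSV interface: e_low,e_high,fluence[,u_fluence]; edges contiguous, increasing.

def write_spectrum_csv(spec: NeutronSpectrum, path) -> None:
    unit = "cm^-2 Gy^-1" if spec.normalization == "absolute" else "unit"
    df = pd.DataFrame(
        {
            "e_low": spec.grid.edges[:-1],
            "e_high": spec.grid.edges[1:],
            "fluence": spec.bin_fluence,
        }
    )
    if spec.bin_uncertainty is not None:
        df["u_fluence"] = spec.bin_uncertainty
    with open(path, "w") as fh:
        fh.write(f"# units: MeV, per-bin fluence [{unit}]\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_spectrum_csv(path) -> NeutronSpectrum:
    path = Path(path)
    normalization = "absolute"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "[unit]" in first:
        normalization = "unit"
    df = pd.read_csv(path, comment="#")
    required = {"e_low", "e_high", "fluence"}
    if not required.issubset(df.columns):
        raise InvalidDomainError(f"{path}: expected columns {sorted(required)}")
    e_low = df["e_low"].to_numpy(float)
    e_high = df["e_high"].to_numpy(float)
    if not np.allclose(e_low[1:], e_high[:-1], rtol=1e-9, atol=0.0):
        raise InvalidDomainError(f"{path}: bin edges are not contiguous")
    grid = EnergyGrid(np.concatenate((e_low, e_high[-1:])))
    u = df["u_fluence"].to_numpy(float) if "u_fluence" in df.columns else None
    return NeutronSpectrum(grid, df["fluence"].to_numpy(float), u, normalization)
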