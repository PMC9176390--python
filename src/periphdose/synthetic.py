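"""Synthetic test inputs: spectra with prescribed group fractions, TLD
readings, sphere counts and an analytic response matrix.

Everything here is generator code — no radiation transport.  The response
matrix in particular is explicitly synthetic: smooth log-Gaussian
sensitivities that make the few-channel inverse problem well posed, not a
model of any physical sphere set.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidDomainError
from .spectra import (
    EnergyGrid,
    GroupBoundaries,
    GroupFractions,
    NeutronSpectrum,
    ParametricSpectrum,
    component_shapes,
    group_overlap_matrix,
    write_spectrum_csv,
)
from .tld import CalibrationSet, invert_pair
from .unfolding import ResponseMatrix, SphereCountSet, forward_counts

__all__ = [
    "PointSpec",
    "spectrum_with_fractions",
    "random_shape_params",
    "analytic_response_matrix",
    "noisy_counts",
    "phantom_fixture",
]


@dataclass(frozen=True)
class PointSpec:
    """Recipe for one synthetic phantom point."""

    point_id: int
    fractions: GroupFractions
    phi_th: float  # cm^-2 Gy^-1
    h_gamma: float  # mSv Gy^-1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phi_th < 0.0 or self.h_gamma < 0.0:
            raise InvalidDomainError("fluence and photon dose must be non-negative")


def random_shape_params(rng: np.random.Generator) -> ParametricSpectrum:
    """Shape parameters drawn log/linearly-uniform inside their valid ranges.

    Amplitudes are left at zero; only the three shape parameters matter here.
    """
    return ParametricSpectrum(
        slope_b=float(rng.uniform(0.6, 1.4)),
        temp_evap=float(np.exp(rng.uniform(np.log(0.3), np.log(3.0)))),
        peak_high=float(np.exp(rng.uniform(np.log(30.0), np.log(180.0)))),
    )


def spectrum_with_fractions(
    target: GroupFractions,
    grid: EnergyGrid | None = None,
    seed: int = 0,
    bounds: GroupBoundaries | None = None,
) -> NeutronSpectrum:
    """Unit spectrum whose four-group fluence fractions equal ``target`` exactly.

    A four-component parametric spectrum with seeded random in-range shape
    parameters is built, each component is truncated to the bins lying fully
    inside its own group (so the amplitude solve is diagonal under the
    log-overlap splitting rule), and the amplitudes are set to the target
    fractions.
    """
    from .spectra import make_log_grid  # local import avoids cycle at module load

    grid = grid or make_log_grid()
    bounds = bounds or GroupBoundaries()
    rng = np.random.default_rng(seed)
    params = random_shape_params(rng)
    shapes = component_shapes(params, grid)
    w = group_overlap_matrix(grid, bounds)
    targets = target.as_array()
    phi = np.zeros(grid.n_bins)
    for g in range(4):
        inside = w[:, g] >= 1.0 - 1e-12
        comp = np.where(inside, shapes[:, g], 0.0)
        s = comp.sum()
        if s <= 0.0:
            if targets[g] > 0.0:
                raise InvalidDomainError(
                    f"grid cannot represent group {g} but its target fraction is "
                    f"{targets[g]:g}"
                )
            continue
        phi += targets[g] * comp / s
    phi = phi / phi.sum()
    return NeutronSpectrum(grid, phi, None, "unit")


def analytic_response_matrix(
    grid: EnergyGrid, n_spheres: int = 9, seed: int = 0
) -> ResponseMatrix:
    """Smooth synthetic sphere responses: ``n_spheres`` plain moderating
    spheres whose sensitivity peak climbs monotonically from thermal to
    ~10 MeV, plus two modified spheres with an added response shoulder above
    20 MeV.
    """
    if n_spheres < 4:
        raise InvalidDomainError("need at least 4 plain spheres")
    rng = np.random.default_rng(seed)
    logm = np.log10(grid.midpoints)
    centers = np.linspace(-8.0, 1.0, n_spheres)
    centers = centers + rng.uniform(-0.05, 0.05, n_spheres)
    centers.sort()
    widths = rng.uniform(0.9, 1.3, n_spheres)
    amps = 1.0 + 0.15 * np.arange(n_spheres) + rng.uniform(0.0, 0.1, n_spheres)
    rows = [
        a * np.exp(-0.5 * ((logm - c) / w) ** 2)
        for a, c, w in zip(amps, centers, widths)
    ]
    # modified spheres: attenuated copy of the largest plain sphere plus a
    # high-energy shoulder guaranteed to dominate every plain response there
    plain = np.array(rows)
    at_100 = plain[:, np.argmin(np.abs(grid.midpoints - 100.0))].max()
    shoulder_amp = 3.0 * max(at_100, 0.1)
    for c_hi in (np.log10(80.0), np.log10(120.0)):
        rows.append(
            0.7 * plain[-1] + shoulder_amp * np.exp(-0.5 * ((logm - c_hi) / 0.35) ** 2)
        )
    diam = np.linspace(2.5, 12.0, n_spheres)
    ids = [f"{d:.1f}in" for d in diam] + ["mod-Cu", "mod-Pb"]
    return ResponseMatrix(ids, grid, np.array(rows))


def noisy_counts(
    spec: NeutronSpectrum,
    rm: ResponseMatrix,
    rel_noise: float = 0.01,
    seed: int = 0,
) -> SphereCountSet:
    """Forward counts perturbed by multiplicative Gaussian noise.

    ``rel_noise`` is the relative counting-statistics level (default 1 %);
    the per-sphere uncertainties are set to ``rel_noise`` × counts.
    """
    if rel_noise < 0.0:
        raise InvalidDomainError("rel_noise must be non-negative")
    exact = forward_counts(spec, rm)
    rng = np.random.default_rng(seed)
    factors = np.clip(1.0 + rel_noise * rng.standard_normal(exact.counts.size), 0.05, None)
    counts = exact.counts * factors
    return SphereCountSet(rm.sphere_ids, counts, rel_noise * counts)


def phantom_fixture(
    specs: list[PointSpec],
    calib: CalibrationSet | None = None,
    outdir: str | Path = ".",
    grid: EnergyGrid | None = None,
) -> dict[str, Path]:
    """Write a complete per-point fixture: TLD CSV, unit-spectrum CSVs and an
    expected-output CSV (thermal fluence, thermal fraction, total fluence,
    photon dose) for regression tests.
    """
    from .spectra import group_fractions, make_log_grid

    calib = calib or CalibrationSet()
    grid = grid or make_log_grid()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "spectra").mkdir(exist_ok=True)

    tld_rows, expected_rows = [], []
    for ps in specs:
        reading = invert_pair(ps.phi_th, ps.h_gamma, calib, point_id=ps.point_id)
        tld_rows.append(
            {"point_id": ps.point_id, "r600_au": reading.r600, "r700_au": reading.r700}
        )
        spec = spectrum_with_fractions(ps.fractions, grid, seed=ps.seed)
        write_spectrum_csv(spec, outdir / "spectra" / f"point_{ps.point_id}.csv")
        p_th = group_fractions(spec).thermal
        expected_rows.append(
            {
                "point_id": ps.point_id,
                "phi_th": ps.phi_th,
                "p_th": p_th,
                "phi_total": ps.phi_th / p_th if p_th > 0 else float("nan"),
                "h_gamma": ps.h_gamma,
            }
        )
    tld_path = outdir / "tld.csv"
    expected_path = outdir / "expected.csv"
    pd.DataFrame(tld_rows, columns=["point_id", "r600_au", "r700_au"]).to_csv(
        tld_path, index=False, lineterminator="\n"
    )
    pd.DataFrame(
        expected_rows, columns=["point_id", "phi_th", "p_th", "phi_total", "h_gamma"]
    ).to_csv(expected_path, index=False, lineterminator="\n")
    return {"tld": tld_path, "spectra_dir": outdir / "spectra", "expected": expected_path}
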