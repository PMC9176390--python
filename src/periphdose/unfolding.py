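"""Two-stage few-channel spectrum unfolding for Bonner sphere data.

Stage 1 (*parametric*): the spectrum is constrained to the four-component
parametric model (≤ 7 free parameters).  For fixed shape parameters the
sphere counts are linear in the four component amplitudes, so the fit is
separable: a bounded nonlinear search over the three shape parameters with a
non-negative linear least-squares (NNLS) solve for the amplitudes inside.
Multiple seeded restarts guard against local minima.

Stage 2 (*numeric*): a SAND-II-style log-multiplicative adjustment — our
documented stand-in for a special-gradient-method refinement
(``method="sgm_like"``) — perturbs the stage-1 solution bin by bin:

    φ_j ← φ_j · exp( Σ_i ŵ_ij ln(C_i^meas / C_i^calc) ),

with response-share weights ŵ normalized over spheres.  Steps that would
increase chi-square are damped (halved) and the iteration stops when no
damped step improves, so the chi-square sequence is non-increasing and bins
stay non-negative by construction.

Reduced chi-square is reported as χ²/n_spheres for both stages (one
convention, so the two stages are directly comparable).

Per-bin uncertainties come from a variability analysis: the measured counts
are resampled within their uncertainties, each replicate is re-unfolded
(parametric restarts seeded near the fitted parameters, then numeric
refinement), and the bin-wise standard deviation over accepted replicates is
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

from .errors import (
    DegenerateSpectrumError,
    GridMismatchError,
    InsufficientVariabilityError,
    InvalidDomainError,
    PeriphdoseError,
)
from .spectra import (
    EnergyGrid,
    NeutronSpectrum,
    ParametricSpectrum,
    component_shapes,
)

__all__ = [
    "ResponseMatrix",
    "SphereCountSet",
    "UnfoldResult",
    "forward_counts",
    "unfold_parametric",
    "unfold_numeric",
    "unfold_two_stage",
    "bin_uncertainties",
]

_SHAPE_LO = np.array([0.5, 0.3, 30.0])
_SHAPE_HI = np.array([1.5, 3.0, 180.0])
_N_FREE_PARAMS = 7


@dataclass
class ResponseMatrix:
    """Per-(sphere, bin) response in cm² (counts per unit fluence)."""

    sphere_ids: list[str]
    grid: EnergyGrid
    response: np.ndarray

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        if len(self.sphere_ids) < 4:
            raise InvalidDomainError("a response matrix needs at least 4 spheres")
        if self.response.shape != (len(self.sphere_ids), self.grid.n_bins):
            raise GridMismatchError(
                f"response shape {self.response.shape} != "
                f"({len(self.sphere_ids)}, {self.grid.n_bins})"
            )
        if np.any(self.response < 0.0):
            raise InvalidDomainError("responses must be non-negative")

    @property
    def n_spheres(self) -> int:
        return len(self.sphere_ids)

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.response))


@dataclass
class SphereCountSet:
    """Normalized per-sphere count rates (counts per treatment Gy)."""

    sphere_ids: list[str]
    counts: np.ndarray
    uncertainties: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.uncertainties = np.asarray(self.uncertainties, dtype=float)
        if self.counts.shape != (len(self.sphere_ids),) or (
            self.uncertainties.shape != self.counts.shape
        ):
            raise GridMismatchError("counts/uncertainties length != number of spheres")
        if np.any(self.counts < 0.0) or np.any(self.uncertainties < 0.0):
            raise InvalidDomainError("counts and uncertainties must be non-negative")


@dataclass
class UnfoldResult:
    spectrum: NeutronSpectrum
    params: ParametricSpectrum | None
    chi2_parametric: float
    chi2_numeric: float | None = None
    iterations: int = 0
    accepted_steps: int = 0
    rejected_steps: int = 0
    converged: bool = False
    method: str = "parametric"

    @property
    def chi2_final(self) -> float:
        return self.chi2_parametric if self.chi2_numeric is None else self.chi2_numeric


def forward_counts(spec: NeutronSpectrum, rm: ResponseMatrix) -> SphereCountSet:
    """Linear forward model: count_i = Σ_j response_ij · φ_j."""
    if not spec.grid.compatible_with(rm.grid):
        raise GridMismatchError("spectrum and response matrix grids differ")
    c = rm.response @ spec.bin_fluence
    return SphereCountSet(list(rm.sphere_ids), c, np.zeros_like(c))


def _effective_sigma(counts: SphereCountSet) -> np.ndarray:
    """Per-sphere weights; zero uncertainties fall back to 0.1 % of the count scale."""
    sigma = counts.uncertainties.copy()
    scale = counts.counts.max() if counts.counts.size else 1.0
    floor = max(1e-3 * scale, 1e-300)
    sigma[sigma <= 0.0] = floor
    return sigma


def _amps_for_theta(
    theta: np.ndarray, counts: np.ndarray, sigma: np.ndarray, rm: ResponseMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inner linear solve: NNLS amplitudes for fixed shape parameters."""
    params = ParametricSpectrum(
        slope_b=float(theta[0]), temp_evap=float(theta[1]), peak_high=float(theta[2])
    )
    shapes = component_shapes(params, rm.grid)
    design = (rm.response @ shapes) / sigma[:, None]
    amps, _ = nnls(design, counts / sigma)
    resid = design @ amps - counts / sigma
    return amps, resid, shapes


def unfold_parametric(
    counts: SphereCountSet,
    rm: ResponseMatrix,
    seed: int = 0,
    n_restarts: int = 16,
    chi2_accept: float = 1.2,
    theta_center: np.ndarray | None = None,
) -> UnfoldResult:
    """Stage-1 bounded least-squares fit of the parametric spectrum model.

    Returns the best solution over all restarts regardless of the acceptance
    criterion; ``converged`` records whether reduced χ² ≤ ``chi2_accept``.
    ``theta_center``, when given, biases restarts around those shape
    parameters (used by the variability analysis).
    """
    if np.all(counts.counts <= 0.0):
        raise DegenerateSpectrumError("all-zero count set cannot be unfolded")
    if rm.n_spheres < _N_FREE_PARAMS:
        warnings.warn(
            f"only {rm.n_spheres} spheres for {_N_FREE_PARAMS} free parameters; "
            "fit is under-determined",
            stacklevel=2,
        )
    sigma = _effective_sigma(counts)
    rng = np.random.default_rng(seed)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _amps_for_theta(theta, counts.counts, sigma, rm)[1]

    log_lo, log_hi = np.log(_SHAPE_LO), np.log(_SHAPE_HI)
    best = None
    for _ in range(max(1, n_restarts)):
        if theta_center is None:
            x0 = np.exp(rng.uniform(log_lo, log_hi))
        else:
            x0 = np.clip(
                theta_center * np.exp(rng.normal(0.0, 0.1, 3)), _SHAPE_LO, _SHAPE_HI
            )
        try:
            sol = least_squares(
                residuals, x0, bounds=(_SHAPE_LO, _SHAPE_HI), xtol=1e-10, ftol=1e-10
            )
        except PeriphdoseError:  # pragma: no cover - defensive
            continue
        chi2 = float(np.sum(sol.fun**2))
        if best is None or chi2 < best[0]:
            best = (chi2, sol.x.copy())
    chi2, theta = best
    amps, _, shapes = _amps_for_theta(theta, counts.counts, sigma, rm)
    params = ParametricSpectrum(
        amp_thermal=float(amps[0]),
        amp_epithermal=float(amps[1]),
        amp_evaporation=float(amps[2]),
        amp_high=float(amps[3]),
        slope_b=float(theta[0]),
        temp_evap=float(theta[1]),
        peak_high=float(theta[2]),
    )
    phi = shapes @ amps
    chi2_red = chi2 / rm.n_spheres
    return UnfoldResult(
        spectrum=NeutronSpectrum(rm.grid, phi, None, "absolute"),
        params=params,
        chi2_parametric=chi2_red,
        converged=chi2_red <= chi2_accept,
        method="parametric",
    )


def unfold_numeric(
    counts: SphereCountSet,
    rm: ResponseMatrix,
    guess: NeutronSpectrum,
    chi2_target: float = 1.0,
    max_iter: int = 2000,
) -> UnfoldResult:
    """Stage-2 log-multiplicative refinement (``sgm_like``) of a guess spectrum.

    Chi-square is non-increasing over accepted iterations and the spectrum
    stays non-negative by construction.
    """
    if not guess.grid.compatible_with(rm.grid):
        raise GridMismatchError("guess spectrum grid incompatible with response matrix")
    phi = guess.bin_fluence.astype(float).copy()
    if phi.sum() <= 0.0:
        raise DegenerateSpectrumError("guess spectrum has zero fluence")
    sigma = _effective_sigma(counts)
    meas = counts.counts
    fitted = meas > 0.0

    def chi2_of(p: np.ndarray) -> tuple[float, np.ndarray]:
        calc = rm.response @ p
        return float(np.sum(((meas - calc) / sigma) ** 2)) / rm.n_spheres, calc

    chi2, calc = chi2_of(phi)
    accepted = rejected = iterations = 0
    converged = chi2 <= chi2_target
    while not converged and iterations < max_iter:
        if np.any(calc[fitted] <= 0.0):
            raise PeriphdoseError(
                "calculated counts vanished for a measured sphere; guess spectrum "
                "has no support in its sensitive range"
            )
        log_ratio = np.zeros_like(meas)
        log_ratio[fitted] = np.log(meas[fitted] / calc[fitted])
        w = rm.response * phi[None, :] / np.where(calc > 0, calc, 1.0)[:, None]
        w[~fitted, :] = 0.0
        col = w.sum(axis=0)
        w_hat = np.divide(w, col[None, :], out=np.zeros_like(w), where=col[None, :] > 0)
        exponent = w_hat.T @ log_ratio
        lam, improved = 1.0, False
        while lam > 1e-4:
            trial = phi * np.exp(lam * exponent)
            chi2_trial, calc_trial = chi2_of(trial)
            if chi2_trial < chi2 * (1.0 - 1e-12):
                phi, chi2, calc = trial, chi2_trial, calc_trial
                improved = True
                accepted += 1
                break
            rejected += 1
            lam *= 0.5
        iterations += 1
        if not improved:
            break
        converged = chi2 <= chi2_target
    return UnfoldResult(
        spectrum=NeutronSpectrum(rm.grid, phi, None, "absolute"),
        params=None,
        chi2_parametric=float("nan"),
        chi2_numeric=chi2,
        iterations=iterations,
        accepted_steps=accepted,
        rejected_steps=rejected,
        converged=converged,
        method="sgm_like",
    )


def unfold_two_stage(
    counts: SphereCountSet,
    rm: ResponseMatrix,
    seed: int = 0,
    n_restarts: int = 16,
    chi2_accept: float = 1.2,
    chi2_target: float = 1.0,
    max_iter: int = 2000,
    theta_center: np.ndarray | None = None,
) -> UnfoldResult:
    """Parametric fit followed by numeric refinement of its solution."""
    stage1 = unfold_parametric(
        counts, rm, seed=seed, n_restarts=n_restarts, chi2_accept=chi2_accept,
        theta_center=theta_center,
    )
    stage2 = unfold_numeric(
        counts, rm, stage1.spectrum, chi2_target=chi2_target, max_iter=max_iter
    )
    return UnfoldResult(
        spectrum=stage2.spectrum,
        params=stage1.params,
        chi2_parametric=stage1.chi2_parametric,
        chi2_numeric=stage2.chi2_numeric,
        iterations=stage2.iterations,
        accepted_steps=stage2.accepted_steps,
        rejected_steps=stage2.rejected_steps,
        converged=stage2.converged or stage1.converged,
        method="two_stage",
    )


def bin_uncertainties(
    counts: SphereCountSet,
    rm: ResponseMatrix,
    result: UnfoldResult,
    n_reps: int = 50,
    seed: int = 0,
    chi2_accept: float = 2.0,
    n_restarts: int = 4,
) -> np.ndarray:
    """Per-bin standard uncertainties from a count-resampling variability analysis.

    Replicate count sets are drawn from the measured counts' uncertainties,
    re-unfolded (two-stage, restarts seeded near the fitted shape parameters)
    and the per-bin standard deviation over the accepted replicates returned.
    """
    if n_reps < 10:
        raise InvalidDomainError("need n_reps >= 10 for a variability analysis")
    if np.all(counts.uncertainties == 0.0):
        # resampling is a no-op: the solution carries no count-driven variability
        return np.zeros(rm.grid.n_bins)
    rng = np.random.default_rng(seed)
    theta_center = None
    if result.params is not None:
        theta_center = np.array(
            [result.params.slope_b, result.params.temp_evap, result.params.peak_high]
        )
    accepted = []
    for rep in range(n_reps):
        c = np.clip(
            counts.counts + counts.uncertainties * rng.standard_normal(counts.counts.size),
            0.0,
            None,
        )
        rep_counts = SphereCountSet(list(counts.sphere_ids), c, counts.uncertainties)
        try:
            res = unfold_two_stage(
                rep_counts,
                rm,
                seed=int(rng.integers(0, 2**31 - 1)),
                n_restarts=n_restarts,
                theta_center=theta_center,
            )
        except PeriphdoseError:
            continue
        if res.chi2_final <= chi2_accept:
            accepted.append(res.spectrum.bin_fluence)
    if len(accepted) < 3:
        raise InsufficientVariabilityError(
            f"only {len(accepted)} accepted replicates out of {n_reps}"
        )
    return np.std(np.array(accepted), axis=0, ddof=1)
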