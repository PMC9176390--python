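# Methods

This note documents the models, numerical choices and limitations behind
`periphdose`. It states no empirical result that the test suite or
`scripts/acceptance.py` do not themselves compute.

## Spectra and energy grid

Spectra are stored as per-bin *integrated* fluence on a strictly increasing
log-energy grid, not as densities. This makes group sums and
coefficient folding exact bin sums; the per-lethargy density used for
plotting is `bin_fluence / ln(E_hi/E_lo)`. The default grid spans
1e-9–200 MeV at 10 bins per decade (114 bins; the last edge overshoots to
251 MeV because the bin count is rounded up), covering the eleven decades a
Bonner sphere spectrometer resolves. The geometric bin midpoint is the
representative energy — the natural choice on a log grid.

The four-group decomposition is thermal E ≤ 0.4 eV, epithermal
0.4 eV–0.1 MeV, fast 0.1–20 MeV, high energy > 20 MeV. A bin straddling a
boundary is split between groups in proportion to log-energy overlap; this
rule is exactly linear under grid refinement, so refining a grid changes no
group fraction.

### Parametric spectrum model

Workplace neutron spectra are modelled with four components and at most
seven free parameters:

| component   | shape (flux density)                | free parameters |
|-------------|-------------------------------------|-----------------|
| thermal     | Maxwellian `E·exp(−E/kT)`, kT fixed at 2.53e-8 MeV | amplitude |
| epithermal  | power law `E^(−b)` confined to (0.4 eV, 0.1 MeV)   | amplitude, b ∈ [0.5, 1.5] |
| evaporation | `(E/T²)·exp(−E/T)`                  | amplitude, T ∈ [0.3, 3] MeV |
| high energy | Gaussian in log10 E, width fixed at 0.25 decades   | amplitude, peak ∈ [30, 180] MeV |

Each amplitude is the total fluence of its component (the model is linear in
the amplitudes), and per-bin values are computed from analytic
antiderivatives, so there is no quadrature error in the component shapes.
These functional forms are this package's own design: the widely used
parametric unfolding codes do not publish theirs, so the components here are
a documented stand-in chosen to reproduce the standard qualitative features
(thermal peak, 1/E-like epithermal bridge, evaporation peak, high-energy
peak), not a reconstruction of any code's internals.

## Conversion coefficients

Two node tables ship as CSV data:

* `hstar_ambient.csv` — fluence-to-ambient-dose-equivalent coefficients
  h\*(10)(E) in pSv·cm², standard reference values with a high-energy
  extension above 20 MeV.
* `qk_soft_tissue.csv` — the product Q(E)·k(E) of the neutron quality
  factor and the ICRU soft-tissue kerma factor, i.e. the point dose
  equivalent per unit fluence under the kerma approximation. Built from
  1/v nitrogen-capture kerma at low energy, hydrogen elastic-scattering
  kerma in the keV–MeV range and nuclear-reaction kerma above 20 MeV, with
  mean quality factors peaking near 0.5 MeV (Q̄ ≈ 11) and declining at high
  energy where the secondaries are fast, low-LET protons.

Interpolation is log-log between nodes (the coefficients span orders of
magnitude over eleven decades), linear in value across any zero node, exact
at nodes, and constant above the last node. The constant extension has no
hard cap: the default grid's last bin reaches 251 MeV, slightly past the
nominal 200 MeV maximum, and folding it must remain legal. Energies below
the first node are an error.

Folding is midpoint evaluation — per-bin fluence times the coefficient at
the geometric midpoint — which at 10 bins/decade agrees with a
1000-subpoint log-uniform quadrature to ≲ 0.3 % (tested at 0.5 %). The
oracle quadrature is reserved for tests; the midpoint rule is the
production path because it is deterministic and controlled purely by grid
resolution.

Because the coefficient curves genuinely decline above 20 MeV, the
dose-averaged energy E_H\* exceeds the fluence-averaged energy E_Φ only
where the weighting grows with energy: the property is asserted for
evaporation-dominated spectra (support ~1 keV–20 MeV) and for realistic
thermal-heavy field spectra, not for arbitrary high-energy-peaked ones.

## TLD pair dosimetry

Thermal fluence: `Φ_th = f_n·(R600 − (f700γ/f600γ)·R700)` with defaults
f_n = 488 n·cm⁻²/au (6 %), f700γ = 1.86e-4 mGy/au (4 %),
f600γ = 1.99e-4 mGy/au (5 %). Photon dose equivalent: `H_γ = f700γ·R700`,
mGy mapped 1:1 to mSv (w_R = 1). Readings are assumed pre-normalized per
treatment Gy; no monitor-unit bookkeeping. Uncertainties propagate to first
order in quadrature (the calibration factors are independent, so the ratio
f700γ/f600γ carries √(4² + 5²) % ≈ 6.4 %).

Sub-background pairs: a negative net signal within 2 combined standard
uncertainties of zero is clipped to zero with a warning flag; anything more
negative raises an error. The clipping threshold is this package's choice —
measured data can dip below background, but a > 2σ negative pair indicates a
readout problem rather than noise.

`invert_pair` is the exact algebraic inverse and is used to generate
readouts for synthetic campaigns; the round trip is identity to 1e-9
relative.

## The dose chain and its uncertainty budget

`H_n = Φ · fold(unit spectrum, Q·k) · 1e-9` (pSv·cm² × cm⁻² → mSv), with
Φ = Φ_th/p_th and p_th the thermal group fraction of the same unit spectrum
used in the fold. The relative uncertainty on H_n combines three budget
components in plain quadrature — Monte Carlo counting statistics (default
8 %), TLD experiment (15 %, overridable per point), transport-model
systematics (20 %) — giving 26.2 % for the defaults. Quadrature of
independent k = 1 components is the only defensible combination rule absent
further information; field reports sometimes quote larger per-point numbers
that plain quadrature of these three terms cannot reproduce.

Organ equivalent doses are equal-weight arithmetic means over the organ's
contributing points (no volume weighting), with uncertainty of the mean
√(Σuᵢ²)/n assuming independent points. Because the 20 % model component is
arguably common to all points, a `correlated_model` toggle removes it per
point in quadrature, propagates the rest, and re-applies it to the averaged
neutron dose; independent propagation is the default. Organs represented by
a single point are reported with `n_points = 1` rather than suppressed.
The isocenter point carries no TLD pair and is excluded from point-dose
output.

## Bonner-sphere unfolding

Stage 1 (parametric): for fixed shape parameters θ = (b, T, peak) the
forward counts are linear in the four amplitudes, so the fit is separable —
`scipy.optimize.least_squares` over θ within its bounds with a non-negative
least-squares (NNLS) amplitude solve inside. 16 seeded restarts (log-uniform
θ starts) guard against local minima; the best solution is returned
regardless, flagged `converged` when reduced χ² ≤ 1.2.

Stage 2 (numeric, `method="sgm_like"`): a SAND-II-style log-multiplicative
update `φ_j ← φ_j·exp(Σ_i ŵ_ij ln(C_meas/C_calc))` with response-share
weights normalized over spheres, starting from the stage-1 solution. Steps
that would increase χ² are halved up to ~13 times, and the iteration stops
when no damped step improves or reduced χ² ≤ 1.0 (cap 2000 iterations), so
χ² is non-increasing and bins stay non-negative by construction. Reduced χ²
uses the single convention χ²/n_spheres for both stages so they are
directly comparable. The update rule is a documented functional analogue of
the special gradient method, whose exact form is unpublished.

Spheres with zero reported count uncertainty get a weighting floor of 0.1 %
of the largest count, purely to keep the weighted residuals finite.

Per-bin uncertainties: the measured counts are resampled within their
uncertainties, each replicate re-unfolded two-stage (4 restarts jittered
±10 % around the fitted θ, mirroring a parameter-variability analysis) and
the bin-wise standard deviation over accepted replicates (reduced χ² ≤ 2)
reported. With the synthetic response matrix this reproduces the expected
ordering — relative bin uncertainties far larger in the high-energy group,
which only the two modified spheres constrain, than in the fast group.
All-zero count uncertainties short-circuit to exactly zero bin
uncertainties.

## Synthetic generators — what they emulate and what they do not

`spectrum_with_fractions` matches *group fractions exactly* (each component
is truncated to the bins fully interior to its group, making the amplitude
solve diagonal under the log-overlap rule) while the within-group shapes
vary with the seed across their full parameter ranges. This emulates a
campaign where per-point group fractions are known but fine spectral
structure is not. Consequently any quantity that depends on within-group
shape — chiefly the folded Q·k and hence H_n — carries an irreducible
spread of roughly ±20–30 % across seeds; pipeline-level checks therefore
average over ~10 seeds and use ±30 % bands. Passing tests show the chain's
arithmetic and unit handling are right under realistic fractions; they do
not validate any transport code's spectral shapes, resonance structure, or
spatial fluence maps.

The analytic response matrix (log-Gaussian sensitivity peaks rising
monotonically from thermal to ~10 MeV, two modified spheres with a > 20 MeV
shoulder) makes the inverse problem well posed (condition number ~1e2 on
the default grid) and is *not* a model of physical sphere responses.
Count noise is multiplicative Gaussian at a configurable level, 1 % by
default — at that level indistinguishable from Poisson statistics.

The bundled campaign table stores the printed per-point values verbatim;
four of the printed integer-percent fraction rows sum to 99–101 % and are
renormalized when converted to `GroupFractions` (aggregate statistics are
computed on the printed integers).

## Determinism and problem sizes

Every stochastic component takes an explicit seed (`numpy` `default_rng`);
repeated runs are bit-identical, and the pipeline writes no timestamps into
its CSV outputs. Default problem sizes keep the full suite and the
acceptance script in the seconds-to-a-minute range: 114-bin grid, 10
generator seeds per averaged dose quantity, 11 noise replicates for the
unfolding-accuracy check, 30–60 replicates for variability analyses.

## Known limitations

* Q·k and h\*(10) tables are assembled from standard physics, not from a
  specific evaluated data release; absolute folded doses inherit their
  accuracy. No organ-specific or angular-dependent coefficient sets.
* The kerma approximation ignores charged-particle disequilibrium near
  interfaces; no RBE model beyond Q(E).
* Organs are represented by 1–4 phantom points; no computational-phantom
  delineation, no volume weighting, no risk coefficients.
* The unfolding stages are functional analogues of the established
  parametric + gradient-refinement workflow, not reconstructions of any
  specific code; measured sphere counts for real campaigns are not bundled.
* No spatial or angular field maps, no time structure, no charged-particle
  spectra, no glow-curve/fading modelling of the TLD readout.
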