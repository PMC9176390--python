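"""Energy grid, spectrum normalization, group decomposition, parametric model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from periphdose.errors import (
    DegenerateSpectrumError,
    GridMismatchError,
    InvalidDomainError,
)
from periphdose.spectra import (
    EnergyGrid,
    GroupBoundaries,
    GroupFractions,
    NeutronSpectrum,
    ParametricSpectrum,
    fluence_avg_energy,
    group_fluences,
    group_fractions,
    make_log_grid,
    make_parametric,
    normalize,
    read_spectrum_csv,
    rebin,
    write_spectrum_csv,
)
from periphdose.synthetic import spectrum_with_fractions


def _one_bin_spectrum(e_low, e_high, value=1.0):
    return NeutronSpectrum(EnergyGrid(np.array([e_low, e_high])), np.array([value]))


class TestMakeLogGrid:
    def test_one_decade_one_bin(self):
        g = make_log_grid(1.0, 10.0, 1)
        assert g.n_bins == 1
        np.testing.assert_allclose(g.edges, [1.0, 10.0])

    def test_default_span_bin_count(self):
        # ceil(10 * log10(2e11)) = 114 bins over eleven-plus decades
        g = make_log_grid(1e-9, 200.0, 10)
        assert g.n_bins == 114
        assert g.edges[0] == 1e-9
        assert g.edges[-1] >= 200.0

    @pytest.mark.parametrize(
        "emin,emax,bpd", [(10.0, 1.0, 5), (-1.0, 10.0, 5), (0.0, 10.0, 5), (1.0, 10.0, 0)]
    )
    def test_invalid_bounds(self, emin, emax, bpd):
        with pytest.raises(InvalidDomainError):
            make_log_grid(emin, emax, bpd)

    def test_log_spacing(self):
        g = make_log_grid(1e-3, 1.0, 4)
        np.testing.assert_allclose(np.diff(np.log10(g.edges)), 0.25)


class TestNormalize:
    def test_single_bin(self):
        s = normalize(_one_bin_spectrum(1.0, 2.0, 5.0))
        np.testing.assert_allclose(s.bin_fluence, [1.0])
        assert s.normalization == "unit"

    def test_proportions_preserved(self):
        g = EnergyGrid(np.array([1.0, 2.0, 4.0]))
        s = normalize(NeutronSpectrum(g, np.array([3.0, 1.0])))
        np.testing.assert_allclose(s.bin_fluence, [0.75, 0.25])

    def test_idempotent(self, grid, rng):
        s = NeutronSpectrum(grid, rng.uniform(0.0, 5.0, grid.n_bins))
        once = normalize(s)
        twice = normalize(once)
        np.testing.assert_array_equal(once.bin_fluence, twice.bin_fluence)

    def test_zero_total_raises(self, grid):
        with pytest.raises(DegenerateSpectrumError):
            normalize(NeutronSpectrum(grid, np.zeros(grid.n_bins)))


class TestGroupFractions:
    def test_all_thermal(self):
        s = _one_bin_spectrum(1e-9, 1e-8)
        f = group_fractions(s)
        np.testing.assert_allclose(f.as_array(), [1.0, 0.0, 0.0, 0.0])

    def test_symmetric_split_at_fast_boundary(self):
        # equal fluence in one bin per side of 20 MeV
        g = EnergyGrid(np.array([10.0, 20.0, 40.0]))
        f = group_fractions(NeutronSpectrum(g, np.array([1.0, 1.0])))
        assert f.fast == pytest.approx(0.5)
        assert f.high_energy == pytest.approx(0.5)

    def test_generator_round_trip_simulated_room_fractions(self, grid):
        target = GroupFractions(0.361, 0.242, 0.355, 0.042)
        spec = spectrum_with_fractions(target, grid, seed=5)
        np.testing.assert_allclose(
            group_fractions(spec).as_array(), target.as_array(), atol=1e-6
        )

    def test_straddling_bin_split_by_log_overlap(self):
        # single bin 10-40 MeV: log overlap puts log(2)/log(4) in fast
        s = _one_bin_spectrum(10.0, 40.0)
        f = group_fractions(s)
        assert f.fast == pytest.approx(np.log(2.0) / np.log(4.0))

    @given(st.integers(0, 2**31 - 1))
    def test_fractions_sum_to_one(self, seed):
        g = make_log_grid(1e-9, 200.0, 3)
        phi = np.random.default_rng(seed).uniform(0.0, 1.0, g.n_bins) + 1e-12
        f = group_fractions(NeutronSpectrum(g, phi))
        assert abs(f.as_array().sum() - 1.0) < 1e-6

    def test_zero_total_raises(self, grid):
        with pytest.raises(DegenerateSpectrumError):
            group_fractions(NeutronSpectrum(grid, np.zeros(grid.n_bins)))

    def test_from_percent_normalizes_printed_rounding(self):
        f = GroupFractions.from_percent(48, 12, 22, 19)  # sums to 101
        assert f.as_array().sum() == pytest.approx(1.0)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(InvalidDomainError):
            GroupFractions(0.5, 0.5, 0.5, 0.5)


class TestFluenceAvgEnergy:
    def test_single_bin_geometric_midpoint(self):
        s = _one_bin_spectrum(1.0, 4.0)
        assert fluence_avg_energy(s) == pytest.approx(2.0)

    def test_two_equal_bins_arithmetic_mean(self):
        g = EnergyGrid(np.array([0.5, 2.0, 4.5]))  # midpoints 1 and 3
        s = NeutronSpectrum(g, np.array([1.0, 1.0]))
        assert fluence_avg_energy(s) == pytest.approx(2.0)

    def test_three_bin_brute_force(self):
        g = EnergyGrid(np.array([1.0, 2.0, 5.0, 9.0]))
        phi = np.array([0.3, 1.2, 0.7])
        mids = np.sqrt(g.edges[:-1] * g.edges[1:])
        expected = float(np.sum(phi * mids) / phi.sum())
        assert fluence_avg_energy(NeutronSpectrum(g, phi)) == pytest.approx(expected)

    @given(st.integers(0, 2**31 - 1))
    def test_within_grid_span(self, seed):
        g = make_log_grid(1e-6, 10.0, 2)
        phi = np.random.default_rng(seed).uniform(0.0, 1.0, g.n_bins) + 1e-12
        e = fluence_avg_energy(NeutronSpectrum(g, phi))
        assert g.edges[0] <= e <= g.edges[-1]


class TestMakeParametric:
    def test_thermal_only(self, grid):
        s = make_parametric(ParametricSpectrum(amp_thermal=2.0), grid)
        f = group_fractions(s)
        assert f.thermal > 0.999
        assert s.total() == pytest.approx(2.0)

    def test_evaporation_mean_energy_is_twice_temperature(self):
        # mean of (E/T^2) exp(-E/T) is 2T; fine grid so discretization is small
        fine = make_log_grid(1e-9, 200.0, 40)
        s = make_parametric(
            ParametricSpectrum(amp_evaporation=1.0, temp_evap=1.0), fine
        )
        assert fluence_avg_energy(s) == pytest.approx(2.0, rel=0.10)

    def test_all_components_populate_all_groups(self, grid):
        s = make_parametric(
            ParametricSpectrum(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 100.0), grid
        )
        assert np.all(group_fluences(s) > 0.0)

    def test_linear_in_each_amplitude(self, grid):
        base = ParametricSpectrum(1.0, 0.5, 0.25, 0.1, 1.1, 0.9, 70.0)
        doubled = ParametricSpectrum(2.0, 0.5, 0.25, 0.1, 1.1, 0.9, 70.0)
        diff = make_parametric(doubled, grid).bin_fluence - make_parametric(
            base, grid
        ).bin_fluence
        thermal_only = make_parametric(
            ParametricSpectrum(amp_thermal=1.0, slope_b=1.1, temp_evap=0.9, peak_high=70.0),
            grid,
        ).bin_fluence
        np.testing.assert_allclose(diff, thermal_only, atol=1e-15)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"amp_thermal": -1.0},
            {"slope_b": 2.0},
            {"temp_evap": 0.1},
            {"peak_high": 10.0},
        ],
    )
    def test_out_of_range_parameters(self, kwargs):
        with pytest.raises(InvalidDomainError):
            ParametricSpectrum(**kwargs)

    def test_all_zero_amplitudes(self, grid):
        with pytest.raises(DegenerateSpectrumError):
            make_parametric(ParametricSpectrum(), grid)


class TestRebin:
    def test_refinement_conserves_fluence_and_fractions(self, grid, rng):
        phi = rng.uniform(0.0, 3.0, grid.n_bins)
        s = NeutronSpectrum(grid, phi)
        fine = rebin(s, grid.refine(2))
        assert fine.total() == pytest.approx(s.total(), rel=1e-6)
        np.testing.assert_allclose(
            group_fractions(fine).as_array(),
            group_fractions(s).as_array(),
            atol=1e-3,
        )

    def test_non_covering_grid_rejected(self, grid):
        s = NeutronSpectrum(grid, np.ones(grid.n_bins))
        with pytest.raises(GridMismatchError):
            rebin(s, make_log_grid(1e-3, 1.0, 10))


class TestSpectrumCsv:
    def test_round_trip(self, tmp_path, grid, rng):
        s = NeutronSpectrum(
            grid, rng.uniform(0.0, 2.0, grid.n_bins), rng.uniform(0.0, 0.1, grid.n_bins)
        )
        path = tmp_path / "spec.csv"
        write_spectrum_csv(s, path)
        back = read_spectrum_csv(path)
        np.testing.assert_allclose(back.grid.edges, grid.edges)
        np.testing.assert_allclose(back.bin_fluence, s.bin_fluence)
        np.testing.assert_allclose(back.bin_uncertainty, s.bin_uncertainty)
        assert back.normalization == "absolute"

    def test_unit_flag_round_trip(self, tmp_path, grid, rng):
        s = normalize(NeutronSpectrum(grid, rng.uniform(0.1, 2.0, grid.n_bins)))
        path = tmp_path / "unit.csv"
        write_spectrum_csv(s, path)
        assert read_spectrum_csv(path).normalization == "unit"

    def test_non_contiguous_edges_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("e_low,e_high,fluence\n1.0,2.0,1.0\n3.0,4.0,1.0\n")
        with pytest.raises(InvalidDomainError):
            read_spectrum_csv(path)


class TestGroupBoundaries:
    def test_defaults_match_standard_groups(self):
        b = GroupBoundaries()
        assert b.thermal_upper == pytest.approx(4e-7)
        assert b.epithermal_upper == pytest.approx(0.1)
        assert b.fast_upper == pytest.approx(20.0)

    def test_non_increasing_rejected(self):
        with pytest.raises(InvalidDomainError):
            GroupBoundaries(thermal_upper=1.0, epithermal_upper=0.5)
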