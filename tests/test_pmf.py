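"""WHAM solver, bootstrap errors, zeroing and binding-energy arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statescan.errors import InvalidParameterError
from statescan.pmf import (
    BindingFreeEnergy,
    PMFProfile,
    UmbrellaDataset,
    UmbrellaWindow,
    bayesian_bootstrap,
    binding_free_energy,
    build_histograms,
    ddg,
    occupancy_ratio,
    pmf_rmse,
    wham_solve,
    zero_to_bulk,
)
from statescan.synthetic import analytic_pmf, generate_umbrella_dataset
from statescan.units import R_KCAL, rt_kcal

from oracles import mbar_window_free_energies


class TestHistograms:
    def test_counts_conserved(self, small_harmonic_dataset):
        ds, _ = small_harmonic_dataset
        hist = build_histograms(ds, n_bins=50)
        assert hist.counts.sum() == sum(len(w.samples) for w in ds.windows)

    def test_single_window_single_bin(self):
        w = UmbrellaWindow(center=1.0, force_const=1000.0, samples=np.full(40, 1.0))
        hist = build_histograms(UmbrellaDataset([w]), n_bins=1, range=(0.5, 1.5))
        assert hist.counts[0, 0] == 40

    def test_disjoint_windows_flagged(self):
        a = UmbrellaWindow(center=0.0, force_const=100.0, samples=np.zeros(10))
        b = UmbrellaWindow(center=5.0, force_const=100.0, samples=np.full(10, 5.0))
        hist = build_histograms(UmbrellaDataset([a, b]), n_bins=50, range=(-1, 6))
        assert hist.overlaps[0]["shared_bins"] == 0

    def test_out_of_range_without_clip_rejected(self):
        w = UmbrellaWindow(center=1.0, force_const=100.0, samples=np.array([0.5, 2.5]))
        with pytest.raises(InvalidParameterError):
            build_histograms(UmbrellaDataset([w]), n_bins=10, range=(0.0, 2.0))
        hist = build_histograms(
            UmbrellaDataset([w]), n_bins=10, range=(0.0, 2.0), clip=True
        )
        assert hist.counts.sum() == 1


class TestWham:
    def test_single_unbiased_window_is_log_histogram(self):
        rng = np.random.default_rng(0)
        w = UmbrellaWindow(
            center=0.0, force_const=0.0, samples=rng.normal(0.0, 0.3, size=20000)
        )
        hist = build_histograms(
            UmbrellaDataset([w]), n_bins=40, range=(-1.2, 1.2), clip=True
        )
        prof = wham_solve(hist)
        rt = rt_kcal(w.temperature)
        occ = prof.occupied
        expected = -rt * np.log(hist.counts[0][occ])
        got = prof.free_energy[occ]
        np.testing.assert_allclose(
            got - got.mean(), expected - expected.mean(), atol=1e-9
        )

    def test_harmonic_recovery(self, small_harmonic_dataset):
        ds, pot = small_harmonic_dataset
        hist = build_histograms(ds, n_bins=80, range=pot.domain)
        prof = wham_solve(hist)
        ana = analytic_pmf(pot, hist.bin_centers)
        assert pmf_rmse(prof, ana) < 0.1

    def test_double_well_recovery(self, small_double_well_dataset):
        ds, pot = small_double_well_dataset
        hist = build_histograms(ds, n_bins=100, range=pot.domain)
        prof = wham_solve(hist)
        ana = analytic_pmf(pot, hist.bin_centers)
        assert pmf_rmse(prof, ana) < 0.12
        g = prof.free_energy[prof.occupied]
        assert abs((g.max() - g.min()) - 2.0) < 0.2

    def test_window_free_energies_match_mbar_oracle(self, small_harmonic_dataset):
        """WHAM and the sample-based MBAR-style estimator agree on F_i."""
        ds, pot = small_harmonic_dataset
        hist = build_histograms(ds, n_bins=100, range=pot.domain)
        _, f_wham, _, _ = wham_solve(hist, full_output=True)
        f_mbar = mbar_window_free_energies(ds)
        assert np.max(np.abs(f_wham - f_mbar)) < 0.05

    def test_gauge_invariance_against_constant_offset(self):
        """Adding a constant to the true potential leaves the zeroed PMF
        unchanged (same seed → identical Metropolis paths)."""
        from statescan.synthetic import double_well_potential

        base = double_well_potential(2.0, (0.0, 2.0))
        lifted = double_well_potential(2.0, (0.0, 2.0), offset=7.5)
        kw = dict(n_windows=10, spacing=0.2, force_const=500.0, n_samples=400, seed=12)
        ds_a = generate_umbrella_dataset(base, **kw)
        ds_b = generate_umbrella_dataset(lifted, **kw)
        ha = build_histograms(ds_a, n_bins=40, range=(0, 2))
        hb = build_histograms(ds_b, n_bins=40, range=(0, 2))
        pa = zero_to_bulk(wham_solve(ha), (1.7, 2.0))
        pb = zero_to_bulk(wham_solve(hb), (1.7, 2.0))
        np.testing.assert_allclose(pa.free_energy, pb.free_energy, atol=1e-9)


class TestBootstrap:
    def test_single_replicate_has_zero_stderr(self, small_harmonic_dataset):
        ds, pot = small_harmonic_dataset
        prof = bayesian_bootstrap(ds, n_boot=1, seed=1, n_bins=60, range=pot.domain)
        assert np.all(prof.stderr == 0.0)

    def test_stderr_positive_on_interior_bins(self, small_harmonic_dataset):
        ds, pot = small_harmonic_dataset
        prof = bayesian_bootstrap(ds, n_boot=25, seed=1, n_bins=60, range=pot.domain)
        interior = prof.occupied.copy()
        # ignore the outermost occupied bins where single windows dominate
        occ_idx = np.flatnonzero(interior)
        assert np.all(prof.stderr[occ_idx[5:-5]] > 0.0)

    def test_deterministic_for_fixed_seed(self, small_harmonic_dataset):
        ds, pot = small_harmonic_dataset
        a = bayesian_bootstrap(ds, n_boot=5, seed=2, n_bins=40, range=pot.domain)
        b = bayesian_bootstrap(ds, n_boot=5, seed=2, n_bins=40, range=pot.domain)
        np.testing.assert_array_equal(a.stderr, b.stderr)

    def test_more_samples_reduce_stderr(self):
        from statescan.synthetic import harmonic_potential

        pot = harmonic_potential(2.0, 0.0, (-0.5, 0.5))
        kw = dict(n_windows=6, spacing=0.15, force_const=500.0, seed=3)
        small = generate_umbrella_dataset(pot, n_samples=200, **kw)
        large = generate_umbrella_dataset(pot, n_samples=1600, **kw)
        ps = bayesian_bootstrap(small, n_boot=20, seed=4, n_bins=30, range=pot.domain)
        pl = bayesian_bootstrap(large, n_boot=20, seed=4, n_bins=30, range=pot.domain)
        assert np.median(pl.stderr[pl.occupied]) < np.median(ps.stderr[ps.occupied])


class TestZeroAndBinding:
    @pytest.fixture
    def well_profile(self):
        x = np.linspace(0, 4, 81)
        g = np.where(x < 2.0, -12.19 * np.exp(-((x - 0.5) ** 2) / 0.18), 0.0)
        return PMFProfile(x, g, np.full_like(g, 0.4))

    def test_zeroing_is_idempotent(self, well_profile):
        once = zero_to_bulk(well_profile, (3.0, 4.0))
        twice = zero_to_bulk(once, (3.0, 4.0))
        np.testing.assert_allclose(once.free_energy, twice.free_energy, atol=1e-12)

    def test_constant_profile_zeroes_to_zero(self):
        x = np.linspace(0, 1, 11)
        prof = PMFProfile(x, np.full_like(x, 4.2), np.zeros_like(x))
        out = zero_to_bulk(prof, (0.0, 1.0))
        np.testing.assert_allclose(out.free_energy, 0.0, atol=1e-12)

    def test_gauge_shift_invariance(self, well_profile):
        shifted = PMFProfile(
            well_profile.bin_centers,
            well_profile.free_energy + 3.7,
            well_profile.stderr,
        )
        a = zero_to_bulk(well_profile, (3.0, 4.0))
        b = zero_to_bulk(shifted, (3.0, 4.0))
        np.testing.assert_allclose(a.free_energy, b.free_energy, atol=1e-12)

    def test_empty_bulk_region_rejected(self, well_profile):
        with pytest.raises(InvalidParameterError):
            zero_to_bulk(well_profile, (10.0, 11.0))

    def test_well_depth_read_off(self, well_profile):
        prof = zero_to_bulk(well_profile, (3.0, 4.0))
        bfe = binding_free_energy(prof, (0.0, 2.0), site_label="OBP")
        assert bfe.dg == pytest.approx(-12.19, abs=1e-6)
        assert bfe.sd == pytest.approx(0.4)

    def test_flat_profile_gives_zero_dg(self):
        x = np.linspace(0, 1, 11)
        prof = PMFProfile(x, np.zeros_like(x), np.zeros_like(x), zero_region=(0, 1))
        assert binding_free_energy(prof, (0.0, 1.0)).dg == 0.0

    def test_deepening_well_lowers_dg_linearly(self, well_profile):
        prof = zero_to_bulk(well_profile, (3.0, 4.0))
        deeper = PMFProfile(
            prof.bin_centers,
            np.where(prof.free_energy < -1, prof.free_energy - 2.5, prof.free_energy),
            prof.stderr,
            zero_region=prof.zero_region,
        )
        d0 = binding_free_energy(prof, (0.0, 2.0)).dg
        d1 = binding_free_energy(deeper, (0.0, 2.0)).dg
        assert d1 == pytest.approx(d0 - 2.5)


class TestDdgAndOccupancy:
    @pytest.mark.parametrize(
        "obp,ebp,expected",
        [
            (-12.19, -7.05, 5.14),
            (-12.21, -5.58, 6.63),
            (-11.91, -7.82, 4.09),
            (-13.12, -6.46, 6.66),
        ],
    )
    def test_subpocket_difference(self, obp, ebp, expected):
        a = BindingFreeEnergy(dg=ebp, sd=0.5, site_label="EBP")
        b = BindingFreeEnergy(dg=obp, sd=0.7, site_label="OBP")
        value, sd = ddg(a, b)
        assert value == pytest.approx(expected, abs=1e-9)
        assert sd == pytest.approx(np.hypot(0.5, 0.7))

    def test_error_modes(self):
        a = BindingFreeEnergy(dg=-7.05, sd=0.64, site_label="EBP")
        b = BindingFreeEnergy(dg=-12.19, sd=0.74, site_label="OBP")
        _, quad = ddg(a, b, error_mode="quadrature")
        _, lin = ddg(a, b, error_mode="linear_sum")
        assert quad == pytest.approx(np.hypot(0.64, 0.74))
        assert lin == pytest.approx(1.38)

    def test_mixed_states_rejected(self):
        a = BindingFreeEnergy(dg=-7.0, sd=0.1, site_label="EBP", state_label="open")
        b = BindingFreeEnergy(dg=-12.0, sd=0.1, site_label="OBP", state_label="closed")
        with pytest.raises(InvalidParameterError):
            ddg(a, b)

    def test_equal_wells_give_zero(self):
        a = BindingFreeEnergy(dg=-5.0, sd=0.0, site_label="EBP")
        b = BindingFreeEnergy(dg=-5.0, sd=0.0, site_label="OBP")
        assert ddg(a, b)[0] == 0.0

    def test_zero_ddg_gives_unit_ratio(self):
        r = occupancy_ratio(0.0, 310.0)
        assert r.ratio == pytest.approx(1.0)
        assert r.orders_of_magnitude == 0

    @pytest.mark.parametrize("value,orders", [(5.14, 3), (6.63, 4), (6.66, 4)])
    def test_orders_of_magnitude_at_310K(self, value, orders):
        assert occupancy_ratio(value, 310.0).orders_of_magnitude == orders

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.floats(-10, 10, allow_nan=False),
        st.floats(0.01, 10, allow_nan=False),
    )
    def test_log_ratio_linear_in_ddg(self, value, bump):
        t = 310.0
        r0 = occupancy_ratio(value, t)
        r1 = occupancy_ratio(value + bump, t)
        assert r1.ratio > r0.ratio
        slope = (np.log10(r1.ratio) - np.log10(r0.ratio)) / bump
        assert slope == pytest.approx(1.0 / (R_KCAL * t * np.log(10)), rel=1e-9)

    def test_invalid_temperature_rejected(self):
        with pytest.raises(InvalidParameterError):
            occupancy_ratio(1.0, 0.0)
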