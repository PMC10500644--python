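"""Shift distributions, propensity windows, bimodality, line shapes."""

import numpy as np
import pytest

from dnpmas.ensembleshift import (
    Histogram,
    PropensityWindows,
    ShiftEnsemble,
    Spectrum1D,
    broadening_ratio,
    compare_distribution_to_lineshape,
    detect_bimodality,
    linewidth_measures,
    overlap_coefficient,
    propensity_fractions,
    rereference,
    shift_histogram,
)
from dnpmas.errors import DataError
from dnpmas.synthetic import (
    EnsembleSpec,
    SpectrumSpec,
    lorentzian_spectrum_from_t2,
    make_ensemble,
    make_spectrum,
)


def delta_ensemble(value, n=100, site="CA"):
    return ShiftEnsemble(shifts={site: np.full(n, value)})


class TestShiftHistogram:
    def test_delta_occupies_single_bin_with_unit_area(self):
        hist = shift_histogram(delta_ensemble(58.0), "CA", bin_width=0.2)
        assert (hist.counts > 0).sum() == 1
        occupied = int(np.argmax(hist.counts))
        assert hist.edges[occupied] <= 58.0 <= hist.edges[occupied + 1]
        assert np.sum(hist.density * hist.bin_width) == pytest.approx(1.0, abs=1e-9)

    def test_total_counts_equal_frame_count(self):
        ens = make_ensemble(EnsembleSpec([(0.5, 176.6, 0.2), (0.5, 177.6, 0.2)],
                                         n_frames=25000, seed=1, site="CO"))
        hist = shift_histogram(ens, "CO")
        assert hist.counts.sum() == 25000

    def test_histogram_mean_tracks_generative_mean(self):
        mu, sd, n = 57.0, 0.3, 20000
        ens = make_ensemble(EnsembleSpec([(1.0, mu, sd)], n_frames=n, seed=2))
        hist = shift_histogram(ens, "site", bin_width=0.05)
        assert hist.mean() == pytest.approx(mu, abs=4 * sd / np.sqrt(n) + 0.05)

    def test_edges_snap_to_bin_grid(self):
        hist = shift_histogram(delta_ensemble(58.07), "CA", bin_width=0.2)
        assert np.allclose(np.mod(hist.edges / 0.2, 1.0), 0.0, atol=1e-9)

    def test_unknown_site_rejected(self):
        with pytest.raises(DataError, match="unknown site"):
            shift_histogram(delta_ensemble(58.0), "CO")


class TestPropensityFractions:
    def test_delta_inside_helical_window_only(self):
        hist = shift_histogram(delta_ensemble(58.5), "CA", bin_width=0.2)
        hel, non = propensity_fractions(hist, "CA")
        assert (hel, non) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_overlap_region_counts_for_both(self):
        # Calpha 56-57.5 ppm belongs to both windows; fractions may sum > 1
        hist = shift_histogram(delta_ensemble(57.0), "CA", bin_width=0.2)
        hel, non = propensity_fractions(hist, "CA")
        assert hel == pytest.approx(1.0)
        assert non == pytest.approx(1.0)

    def test_uniform_density_gives_interval_length_arithmetic(self):
        # uniform on [53, 60]: helical 4/7 of the area, non-helical 4.5/7
        spec = Spectrum1D(ppm=np.linspace(53.0, 60.0, 1401),
                          intensity=np.ones(1401))
        hel, non = propensity_fractions(spec, "CA")
        assert hel == pytest.approx(4.0 / 7.0, abs=1e-6)
        assert non == pytest.approx(4.5 / 7.0, abs=1e-6)

    def test_invariant_under_intensity_rescaling(self):
        spec = make_spectrum(SpectrumSpec([(58.0, 1.5, 1.0, "gaussian")],
                                          (50.0, 65.0, 1501)))
        scaled = Spectrum1D(ppm=spec.ppm, intensity=spec.intensity * 37.0)
        assert propensity_fractions(spec, "CA") == pytest.approx(
            propensity_fractions(scaled, "CA")
        )

    def test_co_windows_active_by_default(self):
        hist = shift_histogram(delta_ensemble(178.0, site="CO"), "CO", bin_width=0.2)
        hel, non = propensity_fractions(hist, "CO")
        assert (hel, non) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_zero_area_rejected(self):
        spec = Spectrum1D(ppm=np.linspace(50, 60, 11), intensity=np.zeros(11))
        with pytest.raises(DataError):
            propensity_fractions(spec, "CA")

    def test_unknown_atom_rejected(self):
        hist = shift_histogram(delta_ensemble(58.0), "CA")
        with pytest.raises(DataError):
            propensity_fractions(hist, "CB")

    def test_windows_dataclass_defaults(self):
        w = PropensityWindows()
        assert w.interval("CA", "helical") == (56.0, 60.0)
        assert w.interval("CO", "non_helical") == (173.0, 177.0)


class TestBimodality:
    def test_two_separated_components_detected_with_means(self):
        ens = make_ensemble(EnsembleSpec([(0.5, 176.6, 0.2), (0.5, 177.6, 0.2)],
                                         n_frames=25000, seed=3, site="CO"))
        res = detect_bimodality(ens.shifts["CO"])
        assert res.n_modes == 2
        assert res.means[0] == pytest.approx(176.6, abs=0.05)
        assert res.means[1] == pytest.approx(177.6, abs=0.05)

    def test_single_gaussian_is_unimodal(self):
        ens = make_ensemble(EnsembleSpec([(1.0, 57.0, 0.3)], n_frames=25000, seed=4))
        assert detect_bimodality(ens.shifts["site"]).n_modes == 1

    def test_constant_vector_degenerates_to_one_mode(self):
        res = detect_bimodality(np.full(100, 58.0))
        assert res.n_modes == 1
        assert res.sds[0] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(DataError):
            detect_bimodality(np.ones(10) + np.arange(10) * 0.01)

    def test_close_modes_suppressed_by_separation_guard(self):
        # modes 0.5 sd apart: the mixture may fit better, but the guard
        # keeps the call conservative
        ens = make_ensemble(EnsembleSpec([(0.5, 177.0, 0.4), (0.5, 177.2, 0.4)],
                                         n_frames=10000, seed=5, site="CO"))
        assert detect_bimodality(ens.shifts["CO"]).n_modes == 1


class TestLinewidthMeasures:
    @pytest.mark.parametrize("shape", ["gaussian", "lorentzian"])
    def test_fwhm_recovered_within_grid_step(self, shape):
        spec = make_spectrum(SpectrumSpec([(177.0, 2.0, 1.0, shape)],
                                          (165.0, 189.0, 4801)))
        fwhm, _, centroid = linewidth_measures(spec)
        assert fwhm == pytest.approx(2.0, abs=spec.step * 2)
        assert centroid == pytest.approx(177.0, abs=0.05)

    def test_overlapping_doublet_at_least_component_width(self):
        spec = make_spectrum(SpectrumSpec(
            [(176.8, 0.8, 1.0, "gaussian"), (177.6, 0.8, 1.0, "gaussian")],
            (170.0, 184.0, 4001)))
        fwhm, _, _ = linewidth_measures(spec)
        assert fwhm >= 0.8

    def test_window_restricts_analysis(self):
        spec = make_spectrum(SpectrumSpec(
            [(60.0, 1.0, 1.0, "gaussian"), (100.0, 1.0, 5.0, "gaussian")],
            (50.0, 110.0, 6001)))
        _, _, centroid = linewidth_measures(spec, window=(55.0, 65.0))
        assert centroid == pytest.approx(60.0, abs=0.1)

    def test_flat_spectrum_rejected(self):
        spec = Spectrum1D(ppm=np.linspace(0, 10, 11), intensity=np.ones(11))
        with pytest.raises(DataError):
            linewidth_measures(spec)


class TestBroadeningRatio:
    def test_pure_lorentzian_from_its_own_t2_is_homogeneous(self):
        spec = lorentzian_spectrum_from_t2(
            T2_s=0.015, nucleus_frequency_mhz=100.6, center_ppm=177.0,
            ppm_axis=(172.0, 182.0, 20001))
        ratio, flag = broadening_ratio(spec, 0.015, 100.6)
        assert ratio == pytest.approx(1.0, rel=0.05)
        assert not flag

    def test_frozen_ensemble_line_is_flagged_inhomogeneous(self):
        # a 4 ppm line at 100.6 MHz with a 15 ms echo T2: ~402 Hz observed
        # vs ~21 Hz homogeneous -> ratio ~ 19
        spec = make_spectrum(SpectrumSpec([(177.0, 4.0, 1.0, "gaussian")],
                                          (165.0, 189.0, 4801)))
        ratio, flag = broadening_ratio(spec, 0.015, 100.6)
        assert ratio == pytest.approx(19.0, rel=0.05)
        assert flag

    def test_doubling_t2_doubles_ratio(self):
        spec = make_spectrum(SpectrumSpec([(177.0, 4.0, 1.0, "gaussian")],
                                          (165.0, 189.0, 4801)))
        r1, _ = broadening_ratio(spec, 0.01, 100.6)
        r2, _ = broadening_ratio(spec, 0.02, 100.6)
        assert r2 == pytest.approx(2 * r1, rel=1e-6)

    def test_frequency_must_be_explicit(self):
        spec = make_spectrum(SpectrumSpec([(177.0, 4.0, 1.0, "gaussian")],
                                          (165.0, 189.0, 481)))
        with pytest.raises(DataError):
            broadening_ratio(spec, 0.015, 0.0)


class TestOverlapAndComparison:
    def test_overlap_identity_and_symmetry(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        q = rng.random(200)
        dx = 0.01
        assert overlap_coefficient(p, p, dx) == pytest.approx(1.0, abs=1e-12)
        assert overlap_coefficient(p, q, dx) == pytest.approx(
            overlap_coefficient(q, p, dx), abs=1e-12
        )
        assert overlap_coefficient(p, q, dx) < 1.0

    def test_matched_gaussian_distribution_overlaps_near_one(self):
        ens = make_ensemble(EnsembleSpec([(1.0, 177.0, 0.5)], n_frames=50000,
                                         seed=6, site="CO"))
        hist = shift_histogram(ens, "CO", bin_width=0.1)
        spec = make_spectrum(SpectrumSpec(
            [(177.0, 0.5 * 2.3548, 1.0, "gaussian")], (173.0, 181.0, 4001)))
        overlap, width_ratio = compare_distribution_to_lineshape(hist, spec)
        assert overlap > 0.95
        assert width_ratio == pytest.approx(1.0, abs=0.1)

    def test_disjoint_supports_overlap_zero_with_warning(self):
        hist = shift_histogram(delta_ensemble(58.0), "CA")
        spec = make_spectrum(SpectrumSpec([(177.0, 1.0, 1.0, "gaussian")],
                                          (172.0, 182.0, 1001)))
        with pytest.warns(UserWarning, match="disjoint"):
            overlap, _ = compare_distribution_to_lineshape(hist, spec)
        assert overlap == 0.0

    def test_broadened_spectrum_reports_width_ratio_above_one(self):
        """An experimental line broader than the predicted ensemble: the
        frozen sample contains motion slower than the trajectory."""
        ens = make_ensemble(EnsembleSpec([(1.0, 177.0, 0.3)], n_frames=30000,
                                         seed=7, site="CO"))
        hist = shift_histogram(ens, "CO", bin_width=0.1)
        broad = make_spectrum(SpectrumSpec(
            [(177.0, 3.0, 1.0, "gaussian")], (167.0, 187.0, 4001)))
        overlap, width_ratio = compare_distribution_to_lineshape(hist, broad)
        assert width_ratio > 1.5
        assert overlap < 0.7


class TestRereferencing:
    def test_nearest_peak_lands_on_reference(self):
        # detergent sugar carbon anchor, axis off by +0.4 ppm
        spec = make_spectrum(SpectrumSpec(
            [(105.6, 0.8, 1.0, "gaussian")], (100.0, 110.0, 2001),
            reference_peak=("facade-sugar", 105.2)))
        fixed = rereference(spec)
        _, _, centroid = linewidth_measures(fixed)
        assert centroid == pytest.approx(105.2, abs=0.02)
        assert fixed.original_ppm is not None

    def test_missing_reference_rejected(self):
        spec = make_spectrum(SpectrumSpec([(105.6, 0.8, 1.0, "gaussian")],
                                          (100.0, 110.0, 2001)))
        with pytest.raises(DataError):
            rereference(spec)


class TestSpectrumContainer:
    def test_descending_axis_normalized_to_ascending(self):
        spec = Spectrum1D(ppm=np.array([3.0, 2.0, 1.0]),
                          intensity=np.array([30.0, 20.0, 10.0]))
        assert list(spec.ppm) == [1.0, 2.0, 3.0]
        assert list(spec.intensity) == [10.0, 20.0, 30.0]

    def test_non_monotone_axis_rejected(self):
        with pytest.raises(DataError):
            Spectrum1D(ppm=np.array([1.0, 3.0, 2.0]),
                       intensity=np.array([1.0, 2.0, 3.0]))

    def test_ensembles_validate_frame_counts(self):
        with pytest.raises(DataError):
            ShiftEnsemble(shifts={"a": np.ones(5), "b": np.ones(6)})
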