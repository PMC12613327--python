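"""Spectrum convolution, peak assignment, benchmark statistics, solvents."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from solvtune import (
    BenchmarkRecord,
    ExcitationSet,
    SolventSpec,
    convolve_spectrum,
    first_visible_peak,
    generate_synthetic_benchmark,
    mae_msd,
    solvent_lookup,
    wavelength_energy,
)


def single_state(energy=3.0, f=1.0):
    return ExcitationSet((energy,), (f,), ((0.0, 0.0, 0.0),))


def states(pairs):
    return ExcitationSet(tuple(e for e, _ in pairs),
                         tuple(f for _, f in pairs),
                         tuple((0.0, 0.0, 0.0) for _ in pairs))


class TestConvolution:
    def test_single_gaussian_height_and_fwhm(self):
        spec = convolve_spectrum(single_state(3.0, 1.0), fwhm=0.20)
        imax = int(np.argmax(spec.intensities))
        assert spec.energies[imax] == pytest.approx(3.0, abs=0.002)
        assert spec.intensities[imax] == pytest.approx(1.0, abs=1e-6)
        # half maximum at E0 +/- fwhm/2
        for e_half in (2.9, 3.1):
            idx = int(np.argmin(np.abs(spec.energies - e_half)))
            assert spec.intensities[idx] == pytest.approx(0.5, abs=0.01)

    def test_two_equal_far_states_equal_maxima(self):
        spec = convolve_spectrum(states([(2.0, 0.7), (4.0, 0.7)]))
        i1 = int(np.argmin(np.abs(spec.energies - 2.0)))
        i2 = int(np.argmin(np.abs(spec.energies - 4.0)))
        assert spec.intensities[i1] == pytest.approx(spec.intensities[i2],
                                                     rel=1e-9)

    def test_linearity_in_oscillator_strengths(self):
        s1 = convolve_spectrum(states([(2.5, 0.3), (3.1, 0.6)]))
        s2 = convolve_spectrum(states([(2.5, 0.6), (3.1, 1.2)]))
        assert np.allclose(s2.intensities, 2.0 * s1.intensities, atol=1e-12)

    def test_all_dark_yields_zero_spectrum(self):
        spec = convolve_spectrum(states([(2.0, 0.0), (3.0, 0.0)]))
        assert np.all(spec.intensities == 0.0)

    def test_grid_spans_three_fwhm(self):
        spec = convolve_spectrum(single_state(3.0), fwhm=0.2)
        assert spec.energies[0] <= 3.0 - 0.6 + 1e-9
        assert spec.energies[-1] >= 3.0 + 0.6 - 1e-9


class TestFirstVisiblePeak:
    def test_single_bright_state(self):
        spec = convolve_spectrum(single_state(3.2))
        peak = first_visible_peak(spec)
        assert peak.peak_energy == pytest.approx(3.2, abs=0.002)
        assert peak.dominant_state == 1

    def test_dark_s1_does_not_affect_spectrum(self):
        """A dark S1 leaves the first visible peak on S2."""
        spec = convolve_spectrum(states([(2.2, 0.0), (3.0, 0.8)]))
        peak = first_visible_peak(spec)
        assert peak.peak_energy == pytest.approx(3.0, abs=0.002)
        assert peak.dominant_state == 2

    def test_overlapping_states_dominant_by_contribution(self):
        """Two states 0.05 eV apart merge; the stronger one dominates and
        the maximum sits between them, nearer the stronger."""
        e1, e2, f1, f2 = 3.00, 3.05, 1.0, 0.2
        spec = convolve_spectrum(states([(e1, f1), (e2, f2)]))
        peak = first_visible_peak(spec)
        # independent dense-grid numerical maximization of the 2-Gaussian sum
        fine = np.linspace(2.8, 3.3, 200001)
        total = (f1 * np.exp(-4 * math.log(2) * (fine - e1) ** 2 / 0.04)
                 + f2 * np.exp(-4 * math.log(2) * (fine - e2) ** 2 / 0.04))
        e_ref = fine[int(np.argmax(total))]
        assert peak.peak_energy == pytest.approx(e_ref, abs=0.002)
        assert e1 < peak.peak_energy < e2
        assert peak.peak_energy - e1 < e2 - peak.peak_energy
        assert peak.dominant_state == 1

    def test_scaling_strengths_leaves_peak_unchanged(self):
        st = states([(2.4, 0.2), (3.1, 0.9)])
        scaled = states([(2.4, 0.2 * 7), (3.1, 0.9 * 7)])
        p1 = first_visible_peak(convolve_spectrum(st))
        p2 = first_visible_peak(convolve_spectrum(scaled))
        assert p1.peak_energy == p2.peak_energy
        assert p1.dominant_state == p2.dominant_state

    def test_weak_low_peak_below_visibility_skipped(self):
        spec = convolve_spectrum(states([(2.0, 0.0001), (3.0, 1.0)]))
        peak = first_visible_peak(spec, visibility_fraction=0.01)
        assert peak.peak_energy == pytest.approx(3.0, abs=0.002)

    def test_zero_spectrum_rejected(self):
        spec = convolve_spectrum(states([(2.0, 0.0)]))
        with pytest.raises(ValueError):
            first_visible_peak(spec)


class TestErrorStatistics:
    @staticmethod
    def records(errors):
        sol = solvent_lookup("DCM")
        return [BenchmarkRecord(f"m{i}", sol, 3.0 + e, 3.0)
                for i, e in enumerate(errors)]

    def test_symmetric_errors(self):
        s = mae_msd(self.records([0.1, -0.1]))
        assert s.mae == pytest.approx(0.1, abs=1e-12)
        assert s.msd == pytest.approx(0.0, abs=1e-12)

    def test_single_record(self):
        s = mae_msd(self.records([0.3]))
        assert s.mae == s.msd == pytest.approx(0.3, abs=1e-12)

    def test_hand_arithmetic(self):
        s = mae_msd(self.records([0.2, -0.4, 0.5]))
        assert s.mae == pytest.approx(1.1 / 3, abs=1e-10)
        assert s.msd == pytest.approx(0.1, abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mae_msd([])

    @given(hst.lists(hst.floats(-1, 1, allow_nan=False), min_size=1,
                     max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_mae_bounds_msd(self, errors):
        s = mae_msd(self.records(errors))
        assert s.mae >= abs(s.msd) - 1e-12
        assert s.mae >= 0

    def test_per_solvent_breakdown(self):
        sols = [solvent_lookup("DCM"), solvent_lookup("DMF")]
        recs = [BenchmarkRecord("a", sols[0], 3.2, 3.0),
                BenchmarkRecord("b", sols[1], 2.9, 3.0)]
        s = mae_msd(recs, per_solvent=True)
        assert s.per_solvent["DCM"] == (1, pytest.approx(0.2), pytest.approx(0.2))
        assert s.per_solvent["DMF"] == (1, pytest.approx(0.1), pytest.approx(-0.1))


class TestSolventTable:
    @pytest.mark.parametrize("name,eps,eps_inf", [
        ("DCM", 8.93, 2.03),
        ("DMF", 36.7, 2.04),
        ("methanol", 32.7, 1.77),
        ("toluene", 2.38, 2.24),
    ])
    def test_curated_dielectrics(self, name, eps, eps_inf):
        s = solvent_lookup(name)
        assert s.eps == eps
        assert s.eps_inf == eps_inf

    def test_case_insensitive_and_aliases(self):
        assert solvent_lookup("dcm") == solvent_lookup("Dichloromethane")
        assert solvent_lookup("THF").eps == 7.58

    def test_table_has_nine_solvents(self):
        from solvtune import SOLVENT_TABLE
        assert len(SOLVENT_TABLE) == 9
        for s in SOLVENT_TABLE.values():
            assert 1.0 <= s.eps_inf <= s.eps

    def test_unknown_solvent_lists_known(self):
        with pytest.raises(KeyError, match="DMSO"):
            solvent_lookup("water")


class TestSyntheticBenchmark:
    def test_degenerate_noise_exact_bias(self):
        recs = generate_synthetic_benchmark(50, bias=0.56, sd=0.0, seed=3)
        s = mae_msd(recs)
        assert s.mae == pytest.approx(0.56, abs=1e-12)
        assert s.msd == pytest.approx(0.56, abs=1e-12)

    def test_seed_reproducibility(self):
        a = generate_synthetic_benchmark(20, 0.1, 0.2, seed=11)
        b = generate_synthetic_benchmark(20, 0.1, 0.2, seed=11)
        assert all(x == y for x, y in zip(a, b))

    def test_estimator_recovery_half_normal(self):
        """At zero bias the MAE estimates sd*sqrt(2/pi) and the MSD zero."""
        n, sd = 10_000, 0.3
        recs = generate_synthetic_benchmark(n, bias=0.0, sd=sd, seed=42)
        s = mae_msd(recs)
        se_msd = sd / math.sqrt(n)
        se_mae = sd * math.sqrt(1 - 2 / math.pi) / math.sqrt(n)
        assert abs(s.msd) < 3 * se_msd
        assert abs(s.mae - sd * math.sqrt(2 / math.pi)) < 3 * se_mae

    def test_peaks_within_dataset_span(self):
        recs = generate_synthetic_benchmark(200, 0.0, 0.0, seed=5)
        exp = np.array([r.experimental for r in recs])
        assert exp.min() >= 1.4 and exp.max() <= 5.1


class TestWavelengthEnergy:
    def test_known_conversion(self):
        # a 300 nm absorption peak is 4.13 eV
        assert wavelength_energy(300.0) == pytest.approx(4.1328, abs=1e-4)

    def test_unit_point(self):
        assert wavelength_energy(1239.842) == pytest.approx(1.0, abs=1e-12)

    def test_involution(self):
        assert wavelength_energy(wavelength_energy(432.1), "ev_to_nm") \
            == pytest.approx(432.1, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            wavelength_energy(0.0)
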