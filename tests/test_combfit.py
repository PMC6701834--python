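import numpy as np
import pytest

from lasercomb import (
    ArtifactModel,
    CombFilterSpec,
    CombFitError,
    FitConfig,
    Recording,
    SyntheticConfig,
    apply_comb_filter,
    bandpass_300_3000,
    build_filter_module,
    compute_spectrum,
    estimate_comb_spacing,
    fit_comb_filter,
    generate_recording,
    measure_periodic_amplitude,
)
from lasercomb.combfit import (
    SpectrumEstimate,
    comb_sos,
    load_comb_specs,
    save_comb_specs,
)
from lasercomb.filters import zero_phase_apply

FS = 20_000.0


class TestComputeSpectrum:
    def test_tone_peak_at_its_frequency(self):
        t = np.arange(int(4 * FS)) / FS
        x = 10 * np.sin(2 * np.pi * 1000.0 * t)
        spec = compute_spectrum(x, FS)
        assert spec.freqs[np.argmax(spec.magnitude)] == pytest.approx(
            1000.0, abs=spec.resolution)
        assert np.max(spec.magnitude) == pytest.approx(10.0, rel=0.01)

    def test_zero_signal_all_zero(self):
        spec = compute_spectrum(np.zeros(int(2 * FS)), FS)
        assert np.all(spec.magnitude == 0)

    def test_parseval(self):
        """Sum |X|^2 / N equals sum x^2 within 1e-6 relative (direct
        time-domain oracle); spectrum magnitudes are rescaled back to raw
        FFT convention first."""
        rng = np.random.default_rng(2)
        x = rng.normal(0, 5.0, int(2 * FS))
        spec = compute_spectrum(x, FS)
        n = x.size
        raw = spec.magnitude * n / 2.0  # undo amplitude normalisation
        w = np.full(raw.size, 2.0)
        w[0] = 1.0
        if n % 2 == 0:
            w[-1] = 1.0
        energy_freq = np.sum(w * raw**2) / n
        energy_time = np.sum(x**2)
        assert energy_freq == pytest.approx(energy_time, rel=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            compute_spectrum(np.zeros(1000), FS)


def contaminated_spectrum(frame_rate, seed=0, duration=8.0):
    cfg = SyntheticConfig(
        duration=duration, n_channels=1, seed=seed,
        laser_on_interval=(0.0, duration),
        artifact=ArtifactModel(frame_rate=frame_rate),
    )
    rec, _ = generate_recording(cfg)
    bp = bandpass_300_3000(rec)
    return compute_spectrum(bp.samples[0], FS, window="hann")


class TestEstimateCombSpacing:
    def test_recovers_default_frame_rate(self):
        spec = contaminated_spectrum(15.5)
        assert estimate_comb_spacing(spec) == pytest.approx(
            15.5, abs=spec.resolution)

    def test_recovers_10_hz_frame_rate(self):
        spec = contaminated_spectrum(10.0)
        assert estimate_comb_spacing(spec) == pytest.approx(
            10.0, abs=spec.resolution)

    def test_single_peak_is_an_error(self):
        t = np.arange(int(4 * FS)) / FS
        x = 100 * np.sin(2 * np.pi * 1000.0 * t)
        spec = compute_spectrum(x, FS)
        with pytest.raises(ValueError, match="no periodic artifact"):
            estimate_comb_spacing(spec)


def toy_spectrum(center=1000.0, spacing=15.5, heights=(100, 40, 20, 10),
                 resolution=0.25, noise=1.0):
    """Symmetric constructed comb spectrum: centre + mirrored neighbours."""
    freqs = np.arange(300.0, 3000.0, resolution)
    mag = np.full(freqs.size, noise)
    def put(f, h):
        mag[np.argmin(np.abs(freqs - f))] = h
    put(center, heights[0])
    for n, h in enumerate(heights[1:], start=1):
        put(center - n * spacing, h)
        put(center + n * spacing, h)
    return SpectrumEstimate(freqs=freqs, magnitude=mag, resolution=resolution)


class TestBuildFilterModule:
    def test_hand_evaluated_neighbor_rule(self):
        """Heights 100 at centre, 40/20/10 at +-1/2/3 spacings: the 10s fall
        below the 15% cutoff, so 5 elements cover centre + two per side."""
        spec = toy_spectrum()
        mod = build_filter_module(spec, 15.5, FitConfig())
        assert mod.n_elements == 5
        assert mod.f_peak == pytest.approx(1000.0, abs=spec.resolution)

    def test_all_neighbors_below_cutoff_single_element(self):
        spec = toy_spectrum(heights=(100, 10, 5))
        mod = build_filter_module(spec, 15.5, FitConfig())
        assert mod.n_elements == 1

    def test_element_cutoffs_3_hz_around_peak(self):
        spec = toy_spectrum(center=465.0, heights=(100,))
        mod = build_filter_module(spec, 15.5, FitConfig())
        el = mod.elements[0]
        assert (el.f_low, el.f_high) == (462.0, 468.0)

    def test_scan_stops_at_band_edge(self):
        """A centre near the band edge cannot scan past it (no error)."""
        spec = toy_spectrum(center=310.0, heights=(100, 50, 50))
        mod = build_filter_module(spec, 15.5, FitConfig())
        covered = [e.center for e in mod.elements]
        assert min(covered) >= 300.0
        assert pytest.approx(310.0, abs=0.3) == mod.f_peak


class TestMeasurePeriodicAmplitude:
    def test_zero_signal(self):
        assert measure_periodic_amplitude(np.zeros(int(3 * FS)), 15.5, FS) == 0.0

    def test_noiseless_periodic_signal_preserved(self):
        """Folding a pure periodic sawtooth returns its amplitude within 5%,
        including a non-integer samples-per-period ratio."""
        from scipy.signal import sawtooth
        t = np.arange(int(3 * FS)) / FS
        x = 80.0 * sawtooth(2 * np.pi * 15.5 * t)
        assert measure_periodic_amplitude(x, 15.5, FS) == pytest.approx(
            80.0, rel=0.05)

    def test_incoherent_noise_suppressed_as_sqrt_n(self):
        """White noise folds down ~ sigma/sqrt(n_periods); quadrupling the
        period count halves the residual (extreme-value factor over the
        ~1300 phase bins included via a generous constant)."""
        rng = np.random.default_rng(4)
        sigma, spacing = 30.0, 15.5
        period = FS / spacing
        x100 = rng.normal(0, sigma, int(100 * period))
        x400 = rng.normal(0, sigma, int(400 * period))
        a100 = measure_periodic_amplitude(x100, spacing, FS)
        a400 = measure_periodic_amplitude(x400, spacing, FS)
        assert a100 < 6 * sigma / np.sqrt(100)
        assert a400 < 6 * sigma / np.sqrt(400)
        assert a400 < a100

    def test_too_few_periods_rejected(self):
        with pytest.raises(ValueError, match="20"):
            measure_periodic_amplitude(np.zeros(int(FS)), 15.5, FS)


@pytest.fixture(scope="module")
def contaminated_segment():
    """Band-passed laser-on single-channel segment (default artifact)."""
    cfg = SyntheticConfig(duration=10.0, n_channels=1, seed=12,
                          laser_on_interval=(0.0, 10.0))
    rec, gt = generate_recording(cfg)
    return cfg, bandpass_300_3000(rec).samples[0], gt


class TestFitCombFilter:
    def test_clean_signal_yields_empty_comb(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 5.0, int(4 * FS))
        spec = fit_comb_filter(x, FS)
        assert spec.n_modules == 0

    def test_converges_below_threshold(self, contaminated_segment):
        cfg, x, _ = contaminated_segment
        spec = fit_comb_filter(x, FS)
        assert spec.n_modules >= 1
        residual = zero_phase_apply(comb_sos(spec, FS), x)
        assert measure_periodic_amplitude(residual, spec.spacing, FS) < 40.0

    def test_fitted_peaks_sit_on_harmonics(self, contaminated_segment):
        """Every element centre lies within 3 Hz of k * true frame rate."""
        cfg, x, _ = contaminated_segment
        spec = fit_comb_filter(x, FS)
        fr = cfg.artifact.frame_rate
        for el in spec.all_elements():
            k = round(el.center / fr)
            assert abs(el.center - k * fr) < 3.0

    def test_unremovable_out_of_band_line_aborts(self):
        """A strong artifact line below 300 Hz cannot be notched by a comb
        restricted to 300-3000 Hz: the loop must stop with a diagnostic
        rather than spin."""
        t = np.arange(int(6 * FS)) / FS
        x = 500.0 * np.sin(2 * np.pi * 15.5 * 18 * t)  # 279 Hz, in fold not band
        x += 100.0 * np.sum(
            [np.sin(2 * np.pi * 15.5 * k * t) / (k / 25) for k in range(25, 30)],
            axis=0)
        with pytest.raises(CombFitError) as exc:
            fit_comb_filter(x, FS, spacing=15.5)
        assert exc.value.partial_spec is not None
        assert exc.value.residual_amplitude > 40.0


@pytest.fixture(scope="module")
def fitted(contaminated_segment):
    _, x, _ = contaminated_segment
    return fit_comb_filter(x, FS)


@pytest.fixture(scope="module")
def sparse_fitted():
    """Comb fitted to an artifact with only a dozen harmonics, leaving most
    of the band unrejected."""
    cfg = SyntheticConfig(
        duration=8.0, n_channels=1, seed=3, laser_on_interval=(0.0, 8.0),
        artifact=ArtifactModel(n_harmonics=12), artifact_to_sua_ratio=50.0,
    )
    rec, _ = generate_recording(cfg)
    return fit_comb_filter(bandpass_300_3000(rec).samples[0], FS)


class TestApplyCombFilter:
    def make_rec(self, x):
        return Recording(x[None, :], FS)

    def test_empty_spec_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 10, 30_000)
        spec = CombFilterSpec(channel_id="ch0", spacing=15.5)
        out = apply_comb_filter(self.make_rec(x), {"ch0": spec})
        assert np.array_equal(out.samples[0], x)

    def test_missing_channel_spec_rejected(self):
        spec = CombFilterSpec(channel_id="chX", spacing=15.5)
        with pytest.raises(KeyError, match="ch0"):
            apply_comb_filter(self.make_rec(np.zeros(1000)), {"chX": spec})

    def test_non_rejected_tone_nearly_unchanged(self, sparse_fitted):
        """Composite response oracle: a tone >= 20 Hz from every stopband
        changes by < 10% through the whole comb cascade."""
        centers = np.array([el.center for el in sparse_fitted.all_elements()])
        assert len(centers) >= 5
        freq = next(f for f in np.arange(350.0, 2900.0, 1.0)
                    if np.min(np.abs(centers - f)) >= 20.0)
        t = np.arange(int(3 * FS)) / FS
        x = np.sin(2 * np.pi * freq * t)
        out = apply_comb_filter(self.make_rec(x), sparse_fitted).samples[0]
        n = int(0.5 * FS)
        assert np.max(np.abs(out[n:-n])) == pytest.approx(1.0, abs=0.10)

    def test_tone_between_notches_of_dense_comb_survives(self, fitted):
        """Even when every harmonic in the band is notched, a tone midway
        between two notch centres keeps > 90% of its amplitude (the narrow
        elements are transparent between their stopbands)."""
        centers = np.sort([el.center for el in fitted.all_elements()])
        mid = 0.5 * (centers[50] + centers[51])
        t = np.arange(int(3 * FS)) / FS
        x = np.sin(2 * np.pi * mid * t)
        out = apply_comb_filter(self.make_rec(x), fitted).samples[0]
        n = int(0.5 * FS)
        assert np.max(np.abs(out[n:-n])) > 0.90

    def test_stopband_center_tone_attenuated_20_db(self, fitted):
        f = fitted.all_elements()[0].center
        t = np.arange(int(3 * FS)) / FS
        x = np.sin(2 * np.pi * f * t)
        out = apply_comb_filter(self.make_rec(x), fitted).samples[0]
        n = int(1.0 * FS)
        assert np.max(np.abs(out[n:-n])) < 10 ** (-20 / 20)

    def test_spec_json_round_trip(self, fitted, tmp_path):
        save_comb_specs({"ch0": fitted}, tmp_path / "comb.json")
        back = load_comb_specs(tmp_path / "comb.json")["ch0"]
        assert back.spacing == fitted.spacing
        assert back.n_modules == fitted.n_modules
        assert [e.to_dict() for e in back.all_elements()] == \
            [e.to_dict() for e in fitted.all_elements()]


class TestResidualMonotone:
    def test_residual_non_increasing_over_cycles(self, contaminated_segment):
        """Re-running the loop cycle by cycle: the folded residual amplitude
        never increases as modules are appended."""
        cfg, x, _ = contaminated_segment
        spec = fit_comb_filter(x, FS)
        residual = x
        amps = [measure_periodic_amplitude(residual, spec.spacing, FS)]
        for mod in spec.modules:
            sos = np.vstack([comb_sos(CombFilterSpec("c", spec.spacing, [mod]), FS)])
            residual = zero_phase_apply(sos, residual)
            amps.append(measure_periodic_amplitude(residual, spec.spacing, FS))
        assert all(b <= a * 1.001 for a, b in zip(amps, amps[1:]))
        assert amps[-1] < 40.0
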