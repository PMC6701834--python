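"""Synthetic extracellular recordings with a parametric laser-artifact model.

Emulates simultaneous two-photon imaging / microelectrode recordings: Gaussian
background noise, ground-truth spike trains built from biphasic templates, and
a periodic photoelectric artifact locked to the imaging frame rate. The
artifact has three ingredients:

* a sawtooth-like harmonic series at multiples of the frame rate (default
  15.5 Hz) with 1/k amplitude decay, restricted by default to the 300-3000 Hz
  single-unit band -- photoelectric coupling to the electrode is capacitive,
  so the slow (low-harmonic) part of the frame ramp is strongly suppressed
  while the sharp flyback excites the band densely;
* one brief spike-like transient per imaging frame (a Gaussian-windowed tone
  burst), emulating the residual artifact spikes that survive filtering;
* per-channel amplitude scaling, since laser coupling differs across sites.

The sawtooth component is normalised so its peak equals ``sawtooth_amplitude``;
with the default amplitude ratio of 50 the artifact peak is 50x the largest
spike template, as observed for electrodes inside the imaging window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Recording

__all__ = [
    "SpikeTemplate",
    "ArtifactModel",
    "SyntheticConfig",
    "GroundTruth",
    "artifact_trace",
    "generate_recording",
    "biphasic_template",
    "default_config",
]


@dataclass
class SpikeTemplate:
    """Single-unit waveform in microvolts at the recording sampling rate."""

    waveform: np.ndarray
    name: str = "unit"

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.size < 11:
            raise ValueError(
                f"waveform must span >= 11 samples (+-5-sample feature offsets), "
                f"got {self.waveform.size}"
            )
        trough = np.argmin(self.waveform)
        if abs(self.waveform[trough]) < np.max(np.abs(self.waveform)):
            raise ValueError("template trough must be the global extremum")

    @property
    def peak_amplitude(self) -> float:
        """Absolute value of the trough, in microvolts."""
        return float(abs(self.waveform.min()))

    @property
    def trough_offset(self) -> int:
        """Sample index of the trough within the waveform."""
        return int(np.argmin(self.waveform))


def biphasic_template(
    peak_amplitude: float,
    sampling_rate: float = 20_000.0,
    trough_width: float = 0.25e-3,
    rebound_width: float = 0.45e-3,
    rebound_fraction: float = 0.35,
    duration: float = 2.0e-3,
    name: str = "unit",
) -> SpikeTemplate:
    """Standard negative-going extracellular spike: Gaussian trough + slower rebound.

    ``peak_amplitude`` is the trough depth in microvolts (positive number).
    """
    n = max(int(round(duration * sampling_rate)), 11)
    t = (np.arange(n) - n // 3) / sampling_rate
    trough = -np.exp(-0.5 * (t / trough_width) ** 2)
    rebound = rebound_fraction * np.exp(-0.5 * ((t - 2.2 * trough_width) / rebound_width) ** 2)
    w = trough + rebound
    w *= peak_amplitude / abs(w.min())
    return SpikeTemplate(waveform=w, name=name)


@dataclass
class ArtifactModel:
    """Periodic photoelectric artifact locked to the imaging frame rate.

    Parameters
    ----------
    frame_rate : float
        Imaging frame rate in Hz; the fundamental spacing of the harmonic
        series (default 15.5).
    sawtooth_amplitude : float
        Peak of the harmonic (sawtooth-like) component, microvolts.
    n_harmonics : int
        Number of consecutive harmonics generated, counted upward from the
        first harmonic inside ``harmonic_band``.
    harmonic_decay : float
        Amplitude exponent: harmonic k carries relative amplitude
        ``1 / k**harmonic_decay`` (1 -> ideal sawtooth decay).
    harmonic_band : (float, float)
        Frequency range the harmonic series occupies, Hz.
    transient_width : float
        Total width in seconds of the per-frame spike-like transient; default
        5.5 ms, i.e. frame_rate * width ~= 8.5% of the signal affected.
    transient_amplitude : float
        Peak of the per-frame transient, microvolts.
    transient_freq : float
        Carrier frequency of the transient tone burst, Hz (in-band so the
        burst survives band-pass filtering and looks spike-like).
    transient_phase : float
        Position of the transient within the frame period, as a fraction of
        the period (default mid-frame, away from the sawtooth peak).
    channel_scale : sequence of float
        Per-channel multiplier applied to the whole artifact.
    """

    frame_rate: float = 15.5
    sawtooth_amplitude: float = 7500.0
    n_harmonics: int = 174
    harmonic_decay: float = 1.0
    harmonic_band: tuple[float, float] = (300.0, 3000.0)
    transient_width: float = 5.5e-3
    transient_amplitude: float = 300.0
    transient_freq: float = 1200.0
    transient_phase: float = 0.5
    channel_scale: tuple[float, ...] = (1.0, 0.8, 0.65, 0.5)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.transient_width >= 1.0 / self.frame_rate:
            raise ValueError(
                f"transient_width {self.transient_width} s must be shorter than one "
                f"frame period ({1.0 / self.frame_rate:.4f} s)"
            )
        for name in ("sawtooth_amplitude", "transient_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s < 0 for s in self.channel_scale):
            raise ValueError("channel_scale entries must be >= 0")

    def harmonic_indices(self) -> np.ndarray:
        """Harmonic numbers k of the generated series (frequencies k*frame_rate)."""
        k0 = int(np.ceil(self.harmonic_band[0] / self.frame_rate))
        k0 = max(k0, 1)
        k = np.arange(k0, k0 + self.n_harmonics)
        return k[k * self.frame_rate <= self.harmonic_band[1]]


def artifact_trace(
    model: ArtifactModel, duration: float, sampling_rate: float
) -> np.ndarray:
    """One channel of the artifact (channel_scale = 1), microvolts.

    Strictly periodic with period 1/frame_rate; the harmonic sum is
    phase-aligned (sine series) so the teeth are sharp, then rescaled so its
    peak equals ``sawtooth_amplitude``; one transient per frame is added at
    ``transient_phase`` of each period.
    """
    if model.frame_rate >= sampling_rate / 2:
        raise ValueError(
            f"frame_rate {model.frame_rate} Hz is not resolvable at "
            f"sampling_rate {sampling_rate} Hz"
        )
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    out = np.zeros(n)

    k = model.harmonic_indices()
    if model.sawtooth_amplitude > 0 and k.size:
        amps = 1.0 / k.astype(float) ** model.harmonic_decay
        # coherent sine series, one tooth per frame period
        phases = 2 * np.pi * model.frame_rate * np.outer(k, t)
        saw = amps @ np.sin(phases)
        peak = np.max(np.abs(saw))
        if peak > 0:
            out += saw * (model.sawtooth_amplitude / peak)

    if model.transient_amplitude > 0:
        period = 1.0 / model.frame_rate
        sigma = model.transient_width / 6.0  # +-3 sigma spans the stated width
        # phase of each sample within its frame, centred on the transient
        dt = (t + (0.5 - model.transient_phase) * period) % period - 0.5 * period
        burst = np.exp(-0.5 * (dt / sigma) ** 2) * np.cos(
            2 * np.pi * model.transient_freq * dt
        )
        out += model.transient_amplitude * burst
    return out


@dataclass
class SyntheticConfig:
    """Full parameterisation of the ground-truth generator."""

    duration: float = 60.0
    sampling_rate: float = 20_000.0
    n_channels: int = 4
    templates: list[SpikeTemplate] = field(default_factory=list)
    firing_rates: list[float] = field(default_factory=lambda: [5.0, 8.0])
    noise_sd: float = 6.0
    artifact: ArtifactModel = field(default_factory=ArtifactModel)
    laser_on_interval: tuple[float, float] | None = None
    artifact_to_sua_ratio: float | None = 50.0
    dead_time: float = 2.0e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not self.templates and self.firing_rates:
            self.templates = [
                biphasic_template(150.0, self.sampling_rate, name="unit_large"),
                biphasic_template(60.0, self.sampling_rate, name="unit_small"),
            ][: len(self.firing_rates)]
        if len(self.templates) != len(self.firing_rates):
            raise ValueError(
                f"{len(self.templates)} templates but {len(self.firing_rates)} firing_rates"
            )
        if any(r <= 0 for r in self.firing_rates):
            raise ValueError(f"firing_rates must be positive, got {self.firing_rates}")
        if self.laser_on_interval is None:
            self.laser_on_interval = (self.duration / 3.0, 2.0 * self.duration / 3.0)
        start, end = self.laser_on_interval
        if not (0 <= start < end <= self.duration):
            raise ValueError(
                f"laser_on_interval must satisfy 0 <= start < end <= duration, "
                f"got {self.laser_on_interval} with duration {self.duration}"
            )
        if self.artifact_to_sua_ratio is not None:
            if self.templates:
                biggest = max(tpl.peak_amplitude for tpl in self.templates)
                self.artifact.sawtooth_amplitude = self.artifact_to_sua_ratio * biggest

    @property
    def max_template_amplitude(self) -> float:
        return max((tpl.peak_amplitude for tpl in self.templates), default=0.0)


@dataclass
class GroundTruth:
    """Everything the generator inserted, for parameter-recovery tests."""

    spike_times: list[np.ndarray]  # per-unit sample indices of template troughs
    frame_start_times: np.ndarray  # sample indices of artifact period onsets
    unit_names: list[str] = field(default_factory=list)

    def all_spike_samples(self) -> np.ndarray:
        if not self.spike_times:
            return np.array([], dtype=int)
        return np.sort(np.concatenate(self.spike_times)).astype(int)


def _poisson_train(
    rate: float, duration: float, sampling_rate: float, dead_time: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Homogeneous Poisson event times (sample indices) with an enforced dead time."""
    # over-generate exponential gaps, then enforce the refractory floor
    n_expect = int(rate * duration * 2) + 50
    gaps = rng.exponential(1.0 / rate, size=n_expect) + dead_time
    times = np.cumsum(gaps)
    times = times[times < duration]
    return np.round(times * sampling_rate).astype(int)


def generate_recording(config: SyntheticConfig) -> tuple[Recording, GroundTruth]:
    """Build noise + spikes + laser artifact, with full ground truth.

    The three components are additive: zeroing the other amplitudes in the
    config isolates each one. The artifact is added only inside
    ``laser_on_interval``. Identical config (incl. seed) gives identical output.
    """
    # independent streams so zeroing one component leaves the others intact
    noise_ss, spike_ss = np.random.SeedSequence(config.seed).spawn(2)
    noise_rng = np.random.default_rng(noise_ss)
    spike_rng = np.random.default_rng(spike_ss)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    data = np.zeros((config.n_channels, n))

    if config.noise_sd > 0:
        data += noise_rng.normal(0.0, config.noise_sd, size=data.shape)

    spike_times: list[np.ndarray] = []
    for tpl, rate in zip(config.templates, config.firing_rates):
        trough = tpl.trough_offset
        wlen = tpl.waveform.size
        events = _poisson_train(rate, config.duration, fs, config.dead_time, spike_rng)
        # keep events whose full waveform fits
        events = events[(events >= trough) & (events + wlen - trough <= n)]
        for ev in events:
            data[:, ev - trough : ev - trough + wlen] += tpl.waveform
        spike_times.append(events)

    start, end = config.laser_on_interval
    i0, i1 = int(round(start * fs)), int(round(end * fs))
    period_samples = fs / config.artifact.frame_rate
    frame_starts = np.round(
        i0 + np.arange(int(np.ceil((i1 - i0) / period_samples))) * period_samples
    ).astype(int)
    frame_starts = frame_starts[frame_starts < i1]
    if i1 > i0:
        trace = artifact_trace(config.artifact, (i1 - i0) / fs, fs)
        scales = np.resize(np.asarray(config.artifact.channel_scale, dtype=float),
                           config.n_channels)
        data[:, i0:i1] += scales[:, None] * trace[None, :]

    rec = Recording(samples=data, sampling_rate=fs)
    gt = GroundTruth(
        spike_times=spike_times,
        frame_start_times=frame_starts,
        unit_names=[tpl.name for tpl in config.templates],
    )
    return rec, gt


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default study conditions: 60 s, 4 channels, 20 kHz, ratio-50 artifact."""
    return SyntheticConfig(seed=seed, **overrides)
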