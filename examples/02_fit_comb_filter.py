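"""Fit the custom-set comb filter to a contaminated channel and inspect it.

The parameter-setting loop alternates time-domain and frequency-domain
analysis: fold the signal over the artifact period to measure the residual
periodic amplitude; while it exceeds 40 uV, FFT the residual, centre a new
filter module on the highest spectral peak, cover its neighbours spaced
D_F = 15.5 Hz apart that exceed 15% of the centre, and notch each with a
6 Hz wide band-stop.
"""

from lasercomb import (
    bandpass_300_3000,
    compute_spectrum,
    default_config,
    estimate_comb_spacing,
    fit_comb_filter,
    generate_recording,
    measure_periodic_amplitude,
)
from lasercomb.combfit import comb_sos
from lasercomb.filters import zero_phase_apply

cfg = default_config(seed=1, duration=12.0, n_channels=1,
                     laser_on_interval=(0.0, 12.0))
rec, _ = generate_recording(cfg)
fs = rec.sampling_rate
x = bandpass_300_3000(rec).samples[0]

spacing = estimate_comb_spacing(compute_spectrum(x, fs, window="hann"))
print(f"estimated artifact spacing D_F = {spacing:.4f} Hz "
      f"(imaging frame rate; generator used {cfg.artifact.frame_rate})")
print(f"periodic amplitude before filtering: "
      f"{measure_periodic_amplitude(x, spacing, fs):8.1f} uV")

comb = fit_comb_filter(x, fs, channel_id="ch0")
print(f"fitted comb: {comb.n_modules} modules, "
      f"{len(comb.all_elements())} band-stop elements")
for m in comb.modules:
    lo = min(e.f_low for e in m.elements)
    hi = max(e.f_high for e in m.elements)
    print(f"  module at f_peak = {m.f_peak:7.1f} Hz: {m.n_elements:3d} elements "
          f"covering {lo:.0f}-{hi:.0f} Hz")

residual = zero_phase_apply(comb_sos(comb, fs), x)
print(f"periodic amplitude after filtering:  "
      f"{measure_periodic_amplitude(residual, comb.spacing, fs):8.1f} uV "
      f"(termination threshold 40 uV)")
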