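"""Generate a synthetic laser-contaminated extracellular recording.

The generator emulates a slice experiment under a resonant two-photon
microscope: Gaussian background noise, two single units firing as Poisson
processes, and — during the middle third of the recording — a periodic
photoelectric artifact locked to the 15.5 Hz imaging frame rate whose peak
is 50x the largest spike.
"""

import numpy as np

from lasercomb import default_config, generate_recording

cfg = default_config(seed=1, duration=30.0, n_channels=2)
rec, truth = generate_recording(cfg)

fs = rec.sampling_rate
on = cfg.laser_on_interval
off_part = rec.samples[0, : int(on[0] * fs)]
on_part = rec.samples[0, int(on[0] * fs) : int(on[1] * fs)]

print(f"recording: {rec.n_channels} channels x {rec.duration:.0f} s at {fs:.0f} Hz")
print(f"laser on during {on[0]:.0f}-{on[1]:.0f} s")
print(f"peak |signal| laser-off: {np.max(np.abs(off_part)):8.1f} uV  (spikes + noise)")
print(f"peak |signal| laser-on:  {np.max(np.abs(on_part)):8.1f} uV  (artifact dominates)")
for name, times in zip(truth.unit_names, truth.spike_times):
    print(f"unit {name}: {times.size} ground-truth spikes "
          f"({times.size / rec.duration:.1f} Hz)")
print(f"{truth.frame_start_times.size} imaging frames "
      f"({truth.frame_start_times.size / (on[1] - on[0]):.1f} frames/s)")

# The laser-on peak is ~50x the largest template trough (150 uV): the artifact
# buries the spikes until it is filtered out.
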