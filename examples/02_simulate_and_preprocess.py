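"""From a noisy unshielded recording to a clean averaged beat.

Simulates two minutes of a beating dipole source with realistic
interference (sensor white noise, baseline drift, 50 Hz powerline), then
runs the preprocessing chain: baseline correction, virtual gradiometry,
band-pass + notch filtering, R-peak detection and ensemble averaging.
Averaging N beats raises the signal-to-noise ratio by sqrt(N).
"""

import numpy as np

import mcgkit as m

geometry = m.planar_grid()
source = m.DipoleSource(position=[0.0, 0.0, -0.08], moment_direction=[1.0, 0.0, 0.0])
beat = m.synthesize_beat(m.BeatTemplate(), source, geometry)

recording = m.simulate_recording(
    beat, heart_rate_bpm=60, duration_s=120, noise=m.NoiseModel(), seed=0
)
raw_rms = np.sqrt(np.mean(recording.channels[0] ** 2))
print(f"raw recording: {recording.duration_s:.0f} s x {recording.n_channels} channels, "
      f"channel-0 RMS {raw_rms:.1f} pT (dominated by drift + powerline)")

averaged = m.preprocess_recording(recording)
qc = m.qc_snr(averaged)
print(f"averaged {averaged.n_beats_averaged} beats; SNR {averaged.snr:.0f} "
      f"(QC threshold {qc.threshold:g} -> {'pass' if qc.passed else 'fail'})")
print("per-beat white noise was 2 pT; after averaging the residual baseline SD is "
      f"{np.std(averaged.channels[0][averaged.time_ms < -100]):.3f} pT")
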