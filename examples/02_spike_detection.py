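"""Detect spikes in a synthetic single-electrode trace with known truth.

Injects 120 uV biphasic templates at 2 Hz into 10 uV Gaussian noise,
high-pass filters (2nd-order Butterworth, 200 Hz), detects threshold
crossings at 5 sigma with the 5 ms suppression window, and scores the
detections against the true spike times.
"""

import numpy as np

import meamask as mm
from meamask.synthetic import biphasic_template

FS = 20000.0

trace, true_times = mm.simulate_spike_trace(
    duration_s=60.0, fs=FS, rate_hz=2.0,
    template=biphasic_template(FS, amplitude_uv=120.0),
    noise_sd_uv=10.0, seed=0)

filtered = mm.highpass(trace, mm.FilterSpec())
sigma = mm.estimate_sigma(filtered)
events = mm.detect_spikes(filtered, fs=FS)

det = np.sort([e.time_s for e in events])
used = np.zeros(det.size, dtype=bool)
hits = 0
for t in np.sort(true_times):
    cand = np.flatnonzero(~used & (np.abs(det - t) <= 0.25e-3))
    if cand.size:
        used[cand[0]] = True
        hits += 1

sta = mm.spike_triggered_average(filtered[None, :], np.array([0]), events)

print(f"noise level sigma:   {sigma:.2f} uV  (threshold {5 * sigma:.1f} uV)")
print(f"true spikes:         {len(true_times)}   detected: {len(events)}")
print(f"recall:              {hits / len(true_times):.3f}")
print(f"precision:           {hits / det.size:.3f}")
print(f"STA trough:          {sta.waveform_of(0).min():.1f} uV over "
      f"{int(sta.counts[0])} aligned spikes")
# Recall/precision near 1 at +/-0.25 ms shows the 5-sigma rule with the
# 100-sample suppression window finds each template exactly once.
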