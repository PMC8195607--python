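"""Spike-train statistics for a simulated adult Purkinje cell.

Generates a 120-s labeled SS/CS train (gamma-renewal simple spikes at
60 Hz with CV 0.5, Poisson complex spikes at 1 Hz, 20 ms climbing-fiber
pause) and computes the full per-cell statistics table.
"""

from cerebquant import spikestats, synth

params = synth.SpikeSimParams(
    ss_rate=60.0, ss_shape=4.0, cs_rate=1.0, cf_pause=0.020, duration=120.0, seed=1
)
train = synth.simulate_spike_train(params)
cell = spikestats.summarize(train)

print(f"recording duration : {train.duration:.0f} s (included: {cell.included})")
print(f"SS rate            : {cell.ss.rate:.1f} Hz   (simulated 60 Hz minus pause deletions)")
print(f"SS CV              : {cell.ss.cv:.3f}       (gamma shape 4 -> 1/sqrt(4) = 0.5)")
print(f"SS mean CV2        : {cell.ss.cv2_mean:.3f}")
print(f"SS regularity index: {cell.ss.regularity_index:.3f}  (fraction of spikes in CV2<0.2 patterns)")
print(f"CS rate            : {cell.cs.rate:.2f} Hz")
print(f"CF pause           : {cell.cf_pause.mean_pause:.1f} ms  (enforced 20 ms + waiting time to next SS)")
print(f"single unit        : {cell.validation.is_single_unit}  "
      f"(CS->SS gap {1e3 * cell.validation.mean_cs_to_ss:.1f} ms vs SS ISI "
      f"{1e3 * cell.validation.mean_ss_isi:.1f} ms)")
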