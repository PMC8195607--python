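"""VOR gain/phase estimation and overnight consolidation.

Simulates sinusoidal vestibular stimulation (5 deg at 0.6 Hz) with
measurement noise and quick phases, recovers gain and phase, and
computes consolidation for a prescribed phase-reversal learning curve.
"""

from cerebquant import eyemov, synth

trace = synth.simulate_eye_session(
    synth.EyeSimParams(
        true_gain=0.8, true_phase=5.0, noise_sd=0.3, saccade_rate=0.5,
        duration=40.0, condition="VOR", seed=11,
    )
)
gp = eyemov.gain_phase(trace)
print(f"VOR gain  : {gp.gain:.3f}  (simulated 0.800)")
print(f"VOR phase : {gp.phase:.2f} deg  (simulated 5.00; 0 = perfectly compensatory)")
print(f"fit R^2   : {gp.fit_r2:.3f}")

proto = eyemov.reversal_protocol()
print("phase-reversal drum amplitudes:",
      {d.day: d.drum_amplitude for d in proto.days}, "deg (table fixed at 5 deg)")

# gain drops 0.8 -> 0.4 during day 1; next morning it is back to 0.6:
# half of the adaptive change survived the night
c = eyemov.consolidation(dx_t0=0.8, dx_next_t0=0.6, dx_t30=0.4)
print(f"consolidation day1->2: {c:.1f} %")
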