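"""Eyeblink-conditioning session analysis with known CR probability.

Simulates one 240-trial acquisition session (20 blocks of 1 US-only +
10 paired + 1 CS-only) where half the CS trials carry a conditioned
response, then validates trials, detects CRs and reports CR%.
"""

import numpy as np

from cerebquant import eyeblink, synth

session = synth.simulate_eyeblink_session(synth.BlinkSimParams(cr_prob=0.5, seed=21))
proto = eyeblink.build_protocol()
print(f"protocol: {len(proto.blocks)} blocks, counts {proto.counts()}")
print(f"CS-US interval {proto.cs_us_interval:.0f} ms, CS {proto.cs_duration:.0f} ms, "
      f"US {proto.us_duration:.0f} ms")

for trial in session.trials:
    eyeblink.validate_trial(trial)
n_valid = sum(t.valid for t in session.trials)
cr_pct = eyeblink.cr_percentage(session.trials)
true_pct = 100.0 * session.truth.loc[session.truth.type != "us_only", "has_cr"].mean()
print(f"valid trials : {n_valid}/240")
print(f"CR%          : {cr_pct:.1f}  (ground truth {true_pct:.1f})")

ur_onsets, ur_peaks = [], []
for trial in session.trials:
    if trial.trial_type == "us_only" and trial.valid:
        m = eyeblink.ur_metrics(trial)
        if m.status == "ok":
            ur_onsets.append(m.onset_ms)
            ur_peaks.append(m.peak_ms)
print(f"UR onset     : {np.mean(ur_onsets):.1f} ms post-US, peak {np.mean(ur_peaks):.1f} ms")
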