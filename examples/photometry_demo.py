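"""Photometry round trip: modulated carrier in, outcome transients out.

Simulates the 167-Hz amplitude-modulated dopamine-sensor signal for a
session (success peaks 0.83 s and failure dips 1.6 s after each reach),
demodulates it with the band-pass + multitaper pipeline, z-scores
against a rolling 30-s baseline, and recovers the planted transients by
event-aligned averaging.
"""

import numpy as np

import cuedreach as cr
from cuedreach.photometry import align_transients, demodulate, rolling_zscore
from cuedreach.session import outcome_event_times

session, _ = cr.generate_session(
    cr.BehaviorGenConfig(n_trials=40, cue_gain=8.0, pellet_occupancy=0.5),
    seed=6)
trace, truth = cr.generate_photometry(session, seed=7)
print(f"raw trace: {trace.samples.size} samples at {trace.fs_hz:.0f} Hz, "
      f"carrier {trace.carrier_hz:.0f} Hz, "
      f"{len(truth.transients)} planted transients")

power = demodulate(trace)
z = rolling_zscore(power)
print(f"demodulated to {power.power.size} band-power samples at 100 Hz")

ev = outcome_event_times(session)
succ = np.concatenate([ev["cued_success"], ev["uncued_success"]])
fail = np.concatenate([ev["cued_failure"], ev["uncued_failure"]])
out = align_transients(z, {"success": succ, "failure": fail},
                       window=(-2.0, 4.0), baseline_window=(-2.0, -0.5))
ts = out["success"]["t"]
peak_t = ts[np.argmax(out["success"]["mean"])]
dip_t = ts[np.argmin(out["failure"]["mean"])]
print(f"success peak: z={out['success']['mean'].max():+.2f} at "
      f"{peak_t:+.2f} s after the reach (planted +0.83 s)")
print(f"failure dip:  z={out['failure']['mean'].min():+.2f} at "
      f"{dip_t:+.2f} s after the reach (planted +1.60 s)")

# The demodulated band power tracks the carrier envelope, so the planted
# peak and dip reappear at their injected latencies with the right signs.
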