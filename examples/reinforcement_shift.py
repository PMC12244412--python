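"""Trial-to-trial reinforcement: the three-trial bootstrap.

Plants a 0.5-Hz cued-reach reinforcement update in the generator, then
measures the change in (cued, uncued) reach rates from trial n-1 to
trial n+1 conditioned on a cued success at trial n -- and shows that the
backwards-time control (conditioning on trial n+2 instead) abolishes it.
"""

import numpy as np

import cuedreach as cr
from cuedreach.behavior import TrialClass
from cuedreach.reinforcement import (backwards_control, conditioned_shift,
                                     extract_triplets)

DELTA = 0.5  # Hz planted on the cued window after each cued success

cfg = cr.BehaviorGenConfig(n_trials=400, cue_gain=6.0,
                           reinforcement_delta=DELTA, pellet_occupancy=0.10)

b_prev, b_next, trials_all = [], [], []
for seed in range(40):
    session, truth = cr.generate_session(cfg, seed=seed)
    tset = extract_triplets(session.trials, TrialClass.cued_success,
                            classes=truth.trial_classes)
    if len(tset):
        b_prev.append(tset.behavior[[t[0] for t in tset.triplets]])
        b_next.append(tset.behavior[[t[2] for t in tset.triplets]])
    trials_all.append(session.trials)

bp, bn = np.vstack(b_prev), np.vstack(b_next)
point = bn.mean(0) - bp.mean(0)
print(f"{bp.shape[0]} cued-success triplets pooled from 40 sessions")
print(f"forward shift:  d_cued = {point[0]:+.3f} Hz (planted {DELTA}), "
      f"d_uncued = {point[1]:+.3f} Hz (planted 0)")

bw = [backwards_control(t, TrialClass.cued_success, n_boot=2, seed=s).delta_cued
      for s, t in enumerate(trials_all)]
print(f"backwards-time control: d_cued = {np.nanmean(bw):+.3f} Hz "
      "(a causal update acts forwards only)")

# The forward shift recovers the planted update on the cued axis while the
# uncued axis stays at zero; conditioning on the *later* trial leaves only
# correlational structure, so the backwards shift collapses toward zero.
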