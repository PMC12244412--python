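"""Behavioral metrics on a synthetic training session.

Generates one session from a mouse that responds to the cue, then
computes the discriminability index d' (z(hit) - z(FA), taking the
lower of two false-alarm windows), its learning stage, the within-
session learning flags, and P(cue | reach).
"""

import cuedreach as cr
from cuedreach.behavior import (learning_stage, p_cue_given_reach,
                                qc_filter_sessions, session_learned)

cfg = cr.BehaviorGenConfig(n_trials=300, cue_gain=6.0,
                           reinforcement_delta=0.2)
session, truth = cr.generate_session(cfg, seed=1)

res = cr.dprime(session.trials)
print(f"d' = {res.dprime:.3f}  (hit rate {res.hit_rate:.3f}, "
      f"FA rates {[round(f, 3) for f in res.fa_rates]}, "
      f"n = {res.n_trials} trials)")
print(f"learning stage: {learning_stage(res.dprime)}")

flags = session_learned(session.trials)
print(f"within-session contrasts: d1={flags.delta_d1:+.3f} "
      f"d2={flags.delta_d2:+.3f} d3={flags.delta_d3:+.3f} "
      f"-> learned={flags.learned}")

p, sd = p_cue_given_reach(session.trials, window_s=0.4)
print(f"P(cue preceded reach within 0.4 s) = {p:.3f} +/- {sd:.3f}")

kept, excluded = qc_filter_sessions([session.trials])
print(f"QC: {'kept' if kept else 'excluded'}")

# A positive d' means the mouse reaches more just after the cue than just
# before it; stages split at d' = 0.25 and 0.75.  The learned flag fires
# when any begin-to-end d' contrast exceeds 0.1.
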