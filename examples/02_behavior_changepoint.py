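"""Infer behavioral structure from a synthetic session and compare with truth.

The session change point is the largest single shift in the binary approach
sequence over CS+ trials (seeking -> not-seeking). Approach initiation per
trial is the change point of the kinematic approach likelihood q_i(t), a
normalised inverse-distance average of other trials' approach outcomes at
matched snout position/velocity.
"""

import numpy as np

from twocap import (
    SimConfig,
    approach_likelihood,
    cs_sensitivity,
    detect_approach_initiation,
    detect_drink_initiation,
    generate_session,
    session_change_point,
)

session = generate_session(SimConfig(n_neurons=2), seed=5)
trials, tracking = session.trials, session.tracking

plus = trials[trials.cs_type == "plus"].sort_values("cs_onset")
cp = session_change_point(plus.approach.astype(int).to_numpy())
print(f"session change point: CS+ trial {cp.index} "
      f"(planted {session.truth.change_point_trial}), magnitude {cp.magnitude:.2f}")

q = approach_likelihood(trials, tracking)
init = detect_approach_initiation(q, trials)
truth = session.truth.trials.set_index("trial")["approach_init_true"]
err = (init.set_index("trial")["approach_init"] - truth).abs().dropna()
print(f"approach initiation: {len(err)} trials, "
      f"median |error| vs planted truth {err.median():.2f} s")

drink = detect_drink_initiation(trials, tracking)
print(f"drink initiations detected on {int(drink.notna().sum())} trials "
      "(first snout entry within 9 px of the cued sipper during access)")
print(f"CS sensitivity: {cs_sensitivity(trials):.2f} "
      "(fraction of approaches on CS+ trials; 0.5 is chance)")
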