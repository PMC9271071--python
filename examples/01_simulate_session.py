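"""Generate one synthetic 2CAP session and write it as a session bundle.

A session is 48 CS+ and 48 CS- cued-access trials with pseudorandom
intertrial intervals, a planted high-to-low seeking switch, snout tracking,
and Poisson spike trains carrying four gain-scaled signals (seeking state,
cue, approach ramp, drink response).
"""

from twocap import SimConfig, generate_session, write_session_bundle
from twocap.synth import alternation_frequency

config = SimConfig(session_id="demo", group="P", liquid="alcohol", n_neurons=80)
session = generate_session(config, seed=1)

trials = session.trials
print(f"trials: {len(trials)} "
      f"({(trials.cs_type == 'plus').sum()} CS+, {(trials.cs_type == 'minus').sum()} CS-)")
print(f"CS-type alternation rate: {alternation_frequency(trials.cs_type.to_numpy()):.2f} "
      "(the task biases consecutive trials to differ ~60% of the time)")
print(f"planted seeking switch at CS+ trial {session.truth.change_point_trial}")
print(f"approach rate: {trials.approach.mean():.2f}, drink trials: {int(trials.drink.sum())}")
print(f"spikes: {len(session.spikes)} from {config.n_neurons} units "
      f"over {session.tracking.time[-1]:.0f} s")

path = write_session_bundle("scratch/demo_session", session)
print(f"bundle written to {path} (trials/tracking/spikes CSVs + waveforms + truth)")
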