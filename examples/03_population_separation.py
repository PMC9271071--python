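"""Subsampled PCA and PC-separation on two groups with different seeking gains.

Each group's neurons are reduced to concatenated trial-type mean profiles,
PCA is repeated over balanced random subsamples, stable PCs are selected by
the variance-ratio criterion, and representation strength is read out as the
per-time-bin Euclidean distance between the two trial types' trajectories
across stable PCs, averaged over a 20-bin epoch.
"""

from twocap import PipelineConfig, SimConfig, generate_session, run_separation_analysis
from twocap.io import bundle_from_session
from twocap.pipeline import analyze_session_behavior, build_group_data

groups = {}
for name, seek_gain in [("strong-seek", 2.0), ("weak-seek", 0.5)]:
    gains = {"seeking": seek_gain, "cue": 1.0, "approach": 1.0, "drink": 1.0}
    cfg = SimConfig(group=name, session_id=name, n_neurons=60, signal_gains=gains)
    bundle = bundle_from_session(generate_session(cfg, seed=3))
    pc = PipelineConfig()
    groups[name] = build_group_data(bundle, analyze_session_behavior(bundle, pc), pc)

result = run_separation_analysis(groups, n_iterations=30, n_per_group=40,
                                 n_components=10, seed=0)
print(f"stable PCs: {result.stability.n_stable} of {len(result.stability.stable)} "
      f"(variance ratio > 1)")
print("epoch mean PC separation by group "
      "(larger = stronger population representation of that variable):")
table = result.epoch_summaries.pivot(index="epoch", columns="group",
                                     values="mean_separation")
print(table.round(3).to_string())
print("\nThe group with the larger planted seeking gain shows the larger "
      "seeking-epoch separation; the other epochs, driven by equal gains, "
      "are comparable.")
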