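"""One-command pipeline: behavior -> preprocess -> population PCA -> waveforms.

Runs the full analysis over a set of session bundles and writes the result
tables (behavior summaries, stability, trajectories, separation series, epoch
summaries, unit classes and class-resolved drink-epoch rate changes) as CSVs
stamped with the pipeline config hash.  Re-running with identical inputs and
config reproduces the outputs byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import preprocess as pre
from . import poppca
from . import waveclass as wc
from .io import PipelineConfig, SessionBundle, load_session_bundle, write_table, read_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; names the stage and session."""


@dataclass
class SessionBehavior:
    """Behavioral inference for one session."""

    trials: pd.DataFrame              # augmented with times and surrogate flags
    change_point: beh.SessionChangePoint
    cs_sensitivity: float
    metrics: beh.SessionMetrics


def analyze_session_behavior(bundle: SessionBundle, config: PipelineConfig) -> SessionBehavior:
    """Change point, approach/drink initiation times, surrogates and metrics."""
    trials = bundle.trials.copy()
    plus = trials[trials["cs_type"] == "plus"].sort_values("cs_onset")
    scp = beh.session_change_point(plus["approach"].astype(int).to_numpy())

    qset = beh.approach_likelihood(trials, bundle.tracking, window=config.q_window,
                                   bin_width=config.bin_width)
    init = beh.detect_approach_initiation(qset, trials)
    trials = trials.merge(init[["trial", "approach_init"]], on="trial", how="left")

    cs_dur = float(bundle.manifest.get("cs_duration_s", 4.0))
    access = float(bundle.manifest.get("access_duration_s", 8.0))
    drink_times = beh.detect_drink_initiation(trials, bundle.tracking,
                                              radius=config.drink_radius_px,
                                              cs_duration=cs_dur, access_duration=access)
    trials["drink_time"] = trials["trial"].map(drink_times)
    # a detected arrival only counts as a drink time on drink trials
    trials.loc[~trials["drink"].astype(bool), "drink_time"] = np.nan

    trials = beh.assign_surrogate_times(trials, "approach", seed=config.seed + 1)
    trials = beh.assign_surrogate_times(trials, "drink", seed=config.seed + 2)
    metrics = beh.session_metrics(trials, bundle.tracking, radius=config.drink_radius_px,
                                  cs_duration=cs_dur, access_duration=access)
    return SessionBehavior(trials=trials, change_point=scp,
                           cs_sensitivity=beh.cs_sensitivity(trials), metrics=metrics)


def build_group_data(bundle: SessionBundle, session_behavior: SessionBehavior,
                     config: PipelineConfig) -> poppca.GroupData:
    """Smoothed, aligned, z-scored tensors plus trial-type labels for one session."""
    trials = session_behavior.trials
    duration = max(float(bundle.tracking.time[-1]),
                   float(bundle.spikes["spike_time"].max()) if len(bundle.spikes) else 0.0)
    counts = pre.bin_spikes(bundle.spikes, bin_width=config.bin_width, duration=duration)
    rates = pre.smooth_adaptive(counts, bundle.spikes)

    plus = trials[trials["cs_type"] == "plus"].sort_values("cs_onset")
    j_scp = session_behavior.change_point.index
    if j_scp is None:
        raise PipelineError(f"{bundle.session_id}: no session change point; "
                            "seeking split undefined")

    tensors, labels = {}, {}
    # a: CS+ aligned, split pre/post change point
    t_seek = pre.zscore_aligned(pre.extract_aligned(
        rates, plus["cs_onset"].to_numpy(), "cs_plus"))
    tensors["seek"] = t_seek
    labels["seek"] = (np.arange(len(plus))[t_seek.event_index] < (j_scp - 1))
    # b: all CS aligned, split by CS type
    all_cs = trials.sort_values("cs_onset")
    t_cue = pre.zscore_aligned(pre.extract_aligned(
        rates, all_cs["cs_onset"].to_numpy(), "cs"))
    tensors["cue"] = t_cue
    labels["cue"] = all_cs.iloc[t_cue.event_index]["cs_type"].eq("plus").to_numpy()
    # c: approach-initiation aligned (real or surrogate), split by approach
    t_app_events = (plus["cs_onset"] + plus["approach_init"]).to_numpy()
    t_app = pre.zscore_aligned(pre.extract_aligned(rates, t_app_events, "approach_init"))
    tensors["approach"] = t_app
    labels["approach"] = plus.iloc[t_app.event_index]["approach"].to_numpy(dtype=bool)
    # d: drink aligned (real or surrogate), split by drink
    t_drink_events = (plus["cs_onset"] + plus["drink_time"]).to_numpy()
    t_drink = pre.zscore_aligned(pre.extract_aligned(rates, t_drink_events, "drink"))
    tensors["drink"] = t_drink
    labels["drink"] = plus.iloc[t_drink.event_index]["drink"].to_numpy(dtype=bool)

    animal = bundle.manifest.get("animal_id", bundle.session_id)
    # unit ids made globally unique per session
    for t in tensors.values():
        t.unit_ids = [f"{bundle.session_id}:{u}" for u in t.unit_ids]
    return poppca.GroupData(tensors=tensors, labels=labels,
                            animals=np.full(len(rates.unit_ids), animal, dtype=object))


def run_pipeline(bundle_paths, config: PipelineConfig, out_dir) -> Path:
    """Execute the full analysis over session bundles and write results.

    Bundles are grouped by their manifest labels (group/liquid/test); units
    from sessions sharing labels are pooled.  Separation analyses and the
    waveform classification are run once over all groups.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundles = [load_session_bundle(p) if not isinstance(p, SessionBundle) else p
               for p in bundle_paths]
    chash = config.config_hash

    behavior_rows, session_groupdata, wave_rows = [], {}, []
    all_waveforms = []
    for b in bundles:
        try:
            sb = analyze_session_behavior(b, config)
        except Exception as err:
            raise PipelineError(f"behavior stage failed for {b.session_id}: {err}") from err
        behavior_rows.append({
            "session_id": b.session_id, "group": b.group_key,
            "change_point_trial": sb.change_point.index,
            "change_point_magnitude": sb.change_point.magnitude,
            "cs_sensitivity": sb.cs_sensitivity,
            "proportion_approached": sb.metrics.proportion_approached,
            "mean_time_at_sipper_s": float(sb.metrics.time_at_sipper.mean()),
            "mean_latency_s": float(sb.metrics.latency.mean()),
        })
        write_table(sb.trials, out / f"trials_{b.session_id}.csv", chash)
        try:
            gd = build_group_data(b, sb, config)
        except Exception as err:
            raise PipelineError(f"preprocess stage failed for {b.session_id}: {err}") from err
        session_groupdata.setdefault(b.group_key, []).append((b, gd, sb))
        for w in b.waveform_objects():
            w.unit_id = f"{b.session_id}:{w.unit_id}"
            all_waveforms.append(w)

    write_table(pd.DataFrame.from_records(behavior_rows), out / "behavior_summary.csv", chash)

    # profiles: per-session trial-type averages pooled within each group
    profiles = []
    for gkey, items in session_groupdata.items():
        for b, gd, _ in items:
            p = poppca.build_profile({gkey: gd})
            profiles.append(p)
    profile = pre.stack_profiles(profiles)

    group_units = {
        g: np.asarray([u for u, lab in zip(profile.unit_ids, profile.groups) if lab == g])
        for g in session_groupdata
    }
    try:
        design = poppca.SubsampleDesign(group_units=group_units,
                                        n_iterations=config.n_iterations,
                                        n_per_group=config.n_per_group, seed=config.seed)
        result = poppca.align_pc_signs(
            poppca.run_subsampled_pca(profile, design, n_components=config.n_components))
        stable = poppca.pc_stability(result)
    except Exception as err:
        raise PipelineError(f"pca stage failed: {err}") from err

    write_table(pd.DataFrame({
        "pc": np.arange(1, result.n_components + 1),
        "variance_ratio": stable.variance_ratio,
        "stable": stable.stable,
        "mean_explained_variance": stable.mean_explained_variance,
    }), out / "stability.csv", chash)

    traj_rows, sep_rows, epoch_rows = [], [], []
    for gkey in session_groupdata:
        traj = poppca.project_group(profile, result, gkey, stable=stable)
        for c, rank in enumerate(traj.pc_ranks):
            for name, (start, stop) in traj.segment_map.items():
                for i, v in enumerate(traj.data[start:stop, c]):
                    traj_rows.append({"group": gkey, "pc": int(rank) + 1, "segment": name,
                                      "bin": i, "value": v})
        for ep_name, ep in poppca.DEFAULT_EPOCHS.items():
            series = poppca.epoch_separation(traj, ep)
            for i, v in enumerate(series.values):
                sep_rows.append({"group": gkey, "epoch": ep_name, "bin": i, "value": v})
            summ = poppca.epoch_mean_separation(series, epoch=ep_name, group=gkey)
            epoch_rows.append({
                "group": gkey, "epoch": ep_name, "mean_separation": summ.mean,
                "sd_separation": float(np.std(summ.values, ddof=1)),
                "n_bins": summ.n_bins,
            })
    write_table(pd.DataFrame.from_records(traj_rows), out / "trajectories.csv", chash)
    write_table(pd.DataFrame.from_records(sep_rows), out / "separation.csv", chash)
    write_table(pd.DataFrame.from_records(epoch_rows), out / "epoch_summary.csv", chash)

    # waveform classification over all units, then per-group drink rate change
    try:
        features = wc.waveform_features(all_waveforms)
        labels = wc.classify_units(features, seed=config.seed)
    except Exception as err:
        raise PipelineError(f"waveform stage failed: {err}") from err
    write_table(labels, out / "unit_classes.csv", chash)

    drink_ep = poppca.DEFAULT_EPOCHS["drink"]
    change_rows = []
    for gkey, items in session_groupdata.items():
        for b, gd, sb in items:
            # rebuild an unscaled (Hz) drink-aligned tensor for rate changes
            duration = max(float(b.tracking.time[-1]),
                           float(b.spikes["spike_time"].max()) if len(b.spikes) else 0.0)
            counts = pre.bin_spikes(b.spikes, bin_width=config.bin_width, duration=duration)
            rates = pre.smooth_adaptive(counts, b.spikes)
            plus = sb.trials[sb.trials["cs_type"] == "plus"].sort_values("cs_onset")
            events = (plus["cs_onset"] + plus["drink_time"]).to_numpy()
            t_hz = pre.extract_aligned(rates, events, "drink")
            mask = plus.iloc[t_hz.event_index]["drink"].to_numpy(dtype=bool)
            unit_ids = [f"{b.session_id}:{u}" for u in t_hz.unit_ids]
            table = wc.epoch_rate_change_by_class(
                t_hz.data / config.bin_width, unit_ids, labels,
                drink_ep.window_b, mask)
            table.insert(0, "session_id", b.session_id)
            table.insert(0, "group", gkey)
            change_rows.append(table)
    if change_rows:
        write_table(pd.concat(change_rows, ignore_index=True),
                    out / "rate_change_by_class.csv", chash)

    config.to_yaml(out / "pipeline_config.yaml")
    (out / "config_hash.txt").write_text(chash + "\n", encoding="utf-8")
    logger.info("pipeline complete: %s", out)
    return out


REQUIRED_RESULTS = ["behavior_summary.csv", "stability.csv", "trajectories.csv",
                    "separation.csv", "epoch_summary.csv"]


def write_report(results_dir, out_dir=None) -> Path:
    """Summary tables and plots from a completed results directory.

    Produces a markdown summary, separation time-series plots per epoch and a
    stability bar chart.  Missing waveform-classification outputs degrade
    gracefully (the unit-class section is marked absent); missing core tables
    are an error listing every absent artifact.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = Path(results_dir)
    out = Path(out_dir) if out_dir else results / "report"
    out.mkdir(parents=True, exist_ok=True)
    missing = [name for name in REQUIRED_RESULTS if not (results / name).exists()]
    if missing:
        raise PipelineError(f"results directory incomplete; missing: {missing}")

    behavior = read_table(results / "behavior_summary.csv")
    stability = read_table(results / "stability.csv")
    separation = read_table(results / "separation.csv")
    epoch = read_table(results / "epoch_summary.csv")

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(stability["pc"], stability["variance_ratio"].clip(upper=10))
    ax.axhline(1.0, color="r", ls="--", lw=1)
    ax.set_xlabel("PC rank")
    ax.set_ylabel("variance ratio")
    ax.set_title("PC stability (ratio > 1 is stable)")
    fig.tight_layout()
    fig.savefig(out / "stability.png", dpi=100)
    plt.close(fig)

    for ep_name, sub in separation.groupby("epoch"):
        fig, ax = plt.subplots(figsize=(6, 3))
        for gkey, gsub in sub.groupby("group"):
            ax.plot(gsub["bin"] * 0.1, gsub["value"], label=gkey)
        ax.set_xlabel("time in epoch (s)")
        ax.set_ylabel("PC separation")
        ax.set_title(ep_name)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / f"separation_{ep_name}.png", dpi=100)
        plt.close(fig)

    def block(df: pd.DataFrame) -> str:
        return "```\n" + df.to_string(index=False) + "\n```"

    lines = ["# Analysis report", "", "## Behavior", "", block(behavior), "",
             "## PC stability", "", block(stability), "",
             "## Epoch mean separation", "", block(epoch), ""]
    classes_path = results / "unit_classes.csv"
    if classes_path.exists():
        classes = read_table(classes_path)
        counts = classes["label"].value_counts().rename_axis("label").reset_index(name="n")
        lines += ["## Unit classes", "", block(counts), ""]
    else:
        lines += ["## Unit classes", "", "_absent (waveform stage not run)_", ""]
    (out / "report.md").write_text("\n".join(lines), encoding="utf-8")
    return out
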