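"""Synthetic 2CAP session generator with a ground-truth channel.

Emulates a full cued-access drinking session -- trial schedule, approach
behavior with a sharp high-to-low seeking switch, snout tracking, and Poisson
spike trains whose rates carry four planted, gain-scaled signals (seeking
state, cue, approach ramp, drink response) plus two-class waveform templates.
Every generated quantity that the analysis is meant to recover (change-point
trial, initiation times, loadings, unit classes) is emitted on a separate
ground-truth channel that the analysis path never reads.

The defaults are the study conditions: 48 CS+ and 48 CS- trials, intertrial
intervals drawn from {20, 28, 36, 44, 56, 68, 96, 120} s, a 4 s CS followed
by 8 s of access on CS+ trials, a 3 s exclusion zone keeping CS- trials away
from CS+ boundaries, an approximately 60% chance that consecutive trials
differ in CS type, and a 95.08% chance that a correct approach leads to
drinking.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import TrackingTrace

DEFAULT_ITI_SET = (20.0, 28.0, 36.0, 44.0, 56.0, 68.0, 96.0, 120.0)
DEFAULT_GAINS = {"seeking": 1.0, "cue": 1.0, "approach": 1.0, "drink": 1.0}
SIGNALS = ("seeking", "cue", "approach", "drink")

#: spike-train simulation resolution (s)
SPIKE_DT = 0.001
#: waveform template length (samples) and sampling rate (Hz)
WAVEFORM_SAMPLES = 48
WAVEFORM_RATE_HZ = 30000.0


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class ScheduleError(RuntimeError):
    """Infeasible trial-schedule geometry."""


class SimulationError(RuntimeError):
    """Simulation failure (e.g. firing-rate overflow)."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic session.

    Trial structure and behavior probabilities default to the task as run;
    the neural side plants four latent signals whose per-group strength is
    set by ``signal_gains``.
    """

    # task schedule
    n_cs_plus: int = 48
    n_cs_minus: int = 48
    iti_set: tuple = DEFAULT_ITI_SET
    cs_duration: float = 4.0
    access_duration: float = 8.0
    cs_minus_exclusion: float = 3.0
    alternation_bias: float = 0.6
    session_start: float = 60.0
    # behavior
    change_point_trial: int = 25          # 1-based CS+ index of the first low-seeking trial
    p_approach_high: float = 0.9
    p_approach_low: float = 0.2
    p_correct_side: float = 0.9
    p_drink_given_correct: float = 0.9508
    # arena and tracking
    arena_width: float = 640.0
    arena_height: float = 480.0
    sipper_left: tuple = (40.0, 240.0)
    sipper_right: tuple = (600.0, 240.0)
    tracking_rate: float = 30.0
    tracking_noise_sd: float = 3.0
    approach_speed: float = 450.0          # px/s run speed along the chamber midline
    dart_duration: float = 0.1             # s, initial dart onto the midline
    latency_offset: float = 0.5            # launch latency = offset + Gamma(shape, scale), s
    latency_shape: float = 100.0
    latency_scale: float = 0.02
    # population
    n_neurons: int = 250
    baseline_rate: float = 4.0
    inhibitory_rate_factor: float = 2.5
    signal_gains: dict = field(default_factory=lambda: dict(DEFAULT_GAINS))
    loading_mean: float = 0.3              # mean of the per-neuron gamma loadings
    loading_spread: float = 0.35           # CV of the per-neuron gamma loadings
    ei_fraction: float = 0.15
    rate_cap: float = 200.0
    # labels
    group: str = "A"
    liquid: str = "alcohol"
    test: str = "first"
    session_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "p_approach_high": self.p_approach_high,
            "p_approach_low": self.p_approach_low,
            "p_correct_side": self.p_correct_side,
            "p_drink_given_correct": self.p_drink_given_correct,
            "alternation_bias": self.alternation_bias,
            "ei_fraction": self.ei_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        for name in ("cs_duration", "access_duration", "tracking_rate", "baseline_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if any(d <= 0 for d in self.iti_set):
            raise ConfigError("all intertrial intervals must be > 0")
        if not 1 <= self.change_point_trial <= self.n_cs_plus:
            raise ConfigError(
                f"change_point_trial={self.change_point_trial} outside [1, {self.n_cs_plus}]"
            )
        if set(self.signal_gains) != set(SIGNALS):
            raise ConfigError(f"signal_gains must have exactly the keys {SIGNALS}")
        if any(g < 0 for g in self.signal_gains.values()):
            raise ConfigError("signal gains must be nonnegative")
        if self.tracking_noise_sd * 6 > min(self.arena_width, self.arena_height) / 2:
            raise ConfigError("arena too small for the tracking noise amplitude")

    @property
    def trial_duration(self) -> float:
        return self.cs_duration + self.access_duration

    @property
    def sippers(self) -> dict:
        return {"left": tuple(self.sipper_left), "right": tuple(self.sipper_right)}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["iti_set"] = list(self.iti_set)
        d["sipper_left"] = list(self.sipper_left)
        d["sipper_right"] = list(self.sipper_right)
        return d


@dataclass
class GroundTruth:
    """Planted truth, kept on a channel the analysis never reads."""

    change_point_trial: int                   # 1-based CS+ index, first low trial
    trials: pd.DataFrame | None = None        # per-trial true times and flags
    loadings: pd.DataFrame | None = None      # per-unit loadings, class, baseline
    expected_counts: pd.Series | None = None  # per-unit integral of the rate


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

_DP_CACHE: dict = {}


def _completion_weights(n_plus: int, n_minus: int, bias: float, max_run: int):
    """Weighted completion counts for the count-constrained Markov sampler.

    A naive sequential draw with P(switch) = bias under-alternates once one
    CS type runs out; instead the sequence is drawn from the Markov law with
    switch probability ``bias`` *conditioned* on the exact trial counts (and
    on CS- runs no longer than ``max_run``, so every run fits inside an
    intertrial interval), via dynamic programming.

    Returns (Np, Nm): Np[p, m] is the weighted number of completions with p
    CS+ and m CS- remaining when the current trial is CS+; Nm[p, m, r]
    likewise when the current trial is CS- and the running CS- run has
    length r.
    """
    key = (n_plus, n_minus, bias, max_run)
    if key in _DP_CACHE:
        return _DP_CACHE[key]
    cap = min(max_run, n_minus)
    Np = np.zeros((n_plus + 1, n_minus + 1))
    Nm = np.zeros((n_plus + 1, n_minus + 1, cap + 2))
    Np[0, 0] = 1.0
    Nm[0, 0, :] = 1.0
    for p in range(n_plus + 1):
        for m in range(n_minus + 1):
            if p == 0 and m == 0:
                continue
            tot = 0.0
            if p > 0:
                tot += (1 - bias) * Np[p - 1, m]
            if m > 0:
                tot += bias * Nm[p, m - 1, 1]
            Np[p, m] = tot
            for r in range(1, cap + 1):
                tot = 0.0
                if p > 0:
                    tot += bias * Np[p - 1, m]
                if m > 0 and r < cap:
                    tot += (1 - bias) * Nm[p, m - 1, r + 1]
                Nm[p, m, r] = tot
    _DP_CACHE[key] = (Np, Nm)
    return Np, Nm


def _type_sequence(n_plus: int, n_minus: int, bias: float, rng,
                   max_minus_run: int | None = None) -> list[str]:
    """CS-type sequence with P(next trial differs) ~ bias and exact counts."""
    cap = n_minus if max_minus_run is None else max_minus_run
    if n_minus > 0 and cap < 1:
        raise ScheduleError("no intertrial interval can hold even one CS- trial")
    Np, Nm = _completion_weights(n_plus, n_minus, bias, cap)
    wp = Np[n_plus - 1, n_minus] if n_plus else 0.0
    wm = Nm[n_plus, n_minus - 1, 1] if n_minus else 0.0
    if wp + wm == 0:
        raise ScheduleError(
            f"no legal CS sequence with {n_plus} CS+, {n_minus} CS- and "
            f"CS- runs capped at {cap}"
        )
    if rng.random() < wp / (wp + wm):
        cur, run, p, m = 0, 0, n_plus - 1, n_minus
    else:
        cur, run, p, m = 1, 1, n_plus, n_minus - 1
    seq = ["plus" if cur == 0 else "minus"]
    while p + m:
        if cur == 0:
            wp = (1 - bias) * Np[p - 1, m] if p else 0.0
            wm = bias * Nm[p, m - 1, 1] if m else 0.0
        else:
            wp = bias * Np[p - 1, m] if p else 0.0
            wm = (1 - bias) * Nm[p, m - 1, run + 1] if (m and run < cap) else 0.0
        if rng.random() < wp / (wp + wm):
            cur, run, p = 0, 0, p - 1
        else:
            cur, run, m = 1, run + 1, m - 1
        seq.append("plus" if cur == 0 else "minus")
    return seq


def alternation_frequency(seq) -> float:
    """Fraction of consecutive trial pairs differing in CS type."""
    arr = np.asarray(seq)
    return float(np.mean(arr[1:] != arr[:-1]))


def generate_schedule(config: SimConfig, seed: int) -> pd.DataFrame:
    """Trial skeleton: CS type, cued side and onset time for every trial.

    CS+ onsets are separated by (trial duration + an intertrial interval
    drawn from ``config.iti_set``); each CS- sits strictly inside an
    intertrial gap, at least ``cs_minus_exclusion`` seconds from both
    flanking CS+ trial boundaries, with CS- trials at least one CS apart.
    The CS-type sequence is drawn so that consecutive trials differ with
    probability ~``alternation_bias``.
    """
    rng = np.random.default_rng(seed)
    iti_max = max(config.iti_set)
    gap_capacity = int(
        (iti_max - 2 * config.cs_minus_exclusion - config.cs_duration)
        // config.cs_duration
    ) + 1
    seq = _type_sequence(config.n_cs_plus, config.n_cs_minus,
                         config.alternation_bias, rng, max_minus_run=gap_capacity)

    # number of CS- between consecutive CS+ (gap 0 = before the first CS+)
    gaps = [0]
    for s in seq:
        if s == "plus":
            gaps.append(0)
        else:
            gaps[-1] += 1
    lead_count = gaps[0]
    mid = gaps[1:-1]      # one per intertrial gap
    trail_count = gaps[-1]

    excl, csd = config.cs_minus_exclusion, config.cs_duration

    def minus_span_needed(m: int) -> float:
        # onsets need (m-1)*cs_duration of spread inside the free interval
        return (m - 1) * csd

    # CS+ onsets, drawing each gap's ITI from the members that can hold its CS-
    onsets_plus = [config.session_start]
    itis = []
    for g, m in enumerate(mid):
        feasible = [iti for iti in config.iti_set
                    if (iti - 2 * excl - csd) >= minus_span_needed(m)]
        if not feasible:
            raise ScheduleError(
                f"no intertrial interval in {config.iti_set} can hold {m} CS- trials "
                f"with a {excl} s exclusion zone"
            )
        iti = float(rng.choice(feasible))
        itis.append(iti)
        onsets_plus.append(onsets_plus[-1] + config.trial_duration + iti)

    def place_minus(lo: float, hi: float, m: int) -> list[float]:
        """m CS- onsets in [lo, hi] with >= cs_duration spacing."""
        span = hi - lo - minus_span_needed(m)
        if m == 0:
            return []
        if span < 0:
            raise ScheduleError(f"cannot place {m} CS- trials in a {hi - lo:.1f} s window")
        u = np.sort(rng.uniform(0.0, span, size=m))
        return list(lo + u + csd * np.arange(m))

    onsets_minus = []
    # leading CS- (before the first CS+)
    if lead_count:
        hi = onsets_plus[0] - excl - csd
        lo = max(10.0, hi - lead_count * (csd + 20.0))
        onsets_minus += place_minus(lo, hi, lead_count)
    for g, m in enumerate(mid):
        lo = onsets_plus[g] + config.trial_duration + excl
        hi = onsets_plus[g + 1] - excl - csd
        onsets_minus += place_minus(lo, hi, m)
    if trail_count:
        lo = onsets_plus[-1] + config.trial_duration + excl
        onsets_minus += place_minus(lo, lo + trail_count * (csd + 20.0), trail_count)

    rows = []
    for t in onsets_plus:
        rows.append({"cs_type": "plus", "cs_onset": t,
                     "side": "left" if rng.random() < 0.5 else "right"})
    for t in onsets_minus:
        rows.append({"cs_type": "minus", "cs_onset": t, "side": "both"})
    table = pd.DataFrame.from_records(rows).sort_values("cs_onset", kind="stable")
    table.insert(0, "trial", np.arange(1, len(table) + 1))
    table["cs_plus_index"] = np.where(
        table["cs_type"].eq("plus"), table["cs_type"].eq("plus").cumsum(), 0
    )
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(
    schedule: pd.DataFrame, config: SimConfig, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Plant approach / correct / drink flags with a sharp seeking switch.

    CS+ trials before ``change_point_trial`` (1-based CS+ index) approach
    with ``p_approach_high``, trials at/after with ``p_approach_low``.
    Approaches pick the cued side with ``p_correct_side``; correct approaches
    drink with ``p_drink_given_correct``.  CS- trials approach at the same
    state-dependent rates (approaching a CS- carries no penalty) but never
    drink.
    """
    rng = np.random.default_rng(seed)
    trials = schedule.copy()
    plus_mask = trials["cs_type"] == "plus"
    switch_onset = trials.loc[
        plus_mask & (trials["cs_plus_index"] == config.change_point_trial), "cs_onset"
    ].iloc[0]

    approach = np.zeros(len(trials), dtype=bool)
    correct = np.zeros(len(trials), dtype=bool)
    drink = np.zeros(len(trials), dtype=bool)
    approach_side = np.array(["none"] * len(trials), dtype=object)

    for i, tr in trials.iterrows():
        high = tr["cs_onset"] < switch_onset
        p = config.p_approach_high if high else config.p_approach_low
        if rng.random() >= p:
            continue
        approach[i] = True
        if tr["cs_type"] == "plus":
            correct[i] = rng.random() < config.p_correct_side
            side = tr["side"] if correct[i] else ("left" if tr["side"] == "right" else "right")
            approach_side[i] = side
            if correct[i]:
                drink[i] = rng.random() < config.p_drink_given_correct
        else:
            approach_side[i] = "left" if rng.random() < 0.5 else "right"

    trials["approach"] = approach
    trials["correct"] = correct
    trials["drink"] = drink
    trials["approach_side"] = approach_side
    truth_trials = trials[["trial", "cs_type", "cs_plus_index",
                           "approach", "correct", "drink"]].copy()
    truth = GroundTruth(change_point_trial=config.change_point_trial, trials=truth_trials)
    return trials, truth


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return 3 * u ** 2 - 2 * u ** 3


def simulate_tracking(
    trials: pd.DataFrame, config: SimConfig, seed: int, truth: GroundTruth | None = None
) -> tuple[TrackingTrace, pd.DataFrame]:
    """Continuous snout trace with planted approach kinematics.

    Between trials the snout wanders (AR(1) around the arena centre, pushed
    out of a 40 px guard zone around each sipper).  On approach trials a
    latent initiation time is drawn uniformly in [0.5, cs_duration + 2] s
    after CS onset; the snout then follows a smoothstep path to the chosen
    sipper at ``approach_speed``, dwells, and blends back to the wander.
    Gaussian position noise (``tracking_noise_sd``) is added everywhere.

    Returns the trace and a per-trial truth table with the true initiation
    and (noiseless, in-access) sipper arrival times relative to CS onset.
    """
    rng = np.random.default_rng(seed)
    fr = config.tracking_rate
    dt = 1.0 / fr
    t_end = trials["cs_onset"].max() + config.trial_duration + 30.0
    t = np.arange(0.0, t_end, dt)
    n = t.size
    centre = np.array([config.arena_width / 2, config.arena_height / 2])

    # smooth wander: AR(1) around the centre, low-pass filtered so the snout
    # moves at realistic speeds instead of frame-to-frame jitter
    a = np.exp(-dt / 3.0)                       # ~3 s relaxation
    sd_eq = min(config.arena_width, config.arena_height) / 6.0
    noise = rng.normal(0.0, sd_eq * np.sqrt(1 - a * a), size=(n, 2))
    from scipy.ndimage import gaussian_filter1d
    from scipy.signal import lfilter
    base = centre + lfilter([1.0], [1.0, -a], noise, axis=0)
    base[:, 0] = np.clip(base[:, 0], 5.0, config.arena_width - 5.0)
    base[:, 1] = np.clip(base[:, 1], 5.0, config.arena_height - 5.0)
    # keep the wander out of a guard zone around each sipper
    guard = 40.0
    for sip in config.sippers.values():
        d = np.hypot(base[:, 0] - sip[0], base[:, 1] - sip[1])
        close = d < guard
        if close.any():
            vec = base[close] - np.asarray(sip)
            norm = np.maximum(np.hypot(vec[:, 0], vec[:, 1]), 1e-9)
            base[close] = np.asarray(sip) + vec / norm[:, None] * guard
    base = gaussian_filter1d(base, sigma=0.3 * fr, axis=0, mode="nearest")

    pos = base.copy()
    plus_onsets = np.sort(trials.loc[trials["cs_type"] == "plus", "cs_onset"].to_numpy())
    records = []
    for _, tr in trials.iterrows():
        rec = {"trial": int(tr["trial"]), "approach_init_true": np.nan,
               "arrival_true": np.nan, "drink_time_true": np.nan}
        if bool(tr["approach"]):
            onset = float(tr["cs_onset"])
            # latency concentrated like real launch latencies, support bounded by cs+2
            t_init = onset + min(
                config.latency_offset + rng.gamma(config.latency_shape, config.latency_scale),
                config.cs_duration + 2.0,
            )
            side = tr["approach_side"]
            if side not in config.sippers:
                side = "left" if rng.random() < 0.5 else "right"
            target = np.asarray(config.sippers[side])
            i0 = int(np.searchsorted(t, t_init))
            if i0 >= n:
                records.append(rec)
                continue
            start = pos[i0].copy()
            # stereotyped approach: dart onto the chamber midline, then run
            # along it to the sipper at a fixed speed
            dart = config.dart_duration
            run = max(abs(target[0] - start[0]) / config.approach_speed, 0.1)
            travel = dart + run
            # dwell: drink and correct-approach trials wait out the access,
            # wrong-side and CS- approaches linger a few seconds then leave
            if bool(tr["drink"]) or bool(tr["correct"]):
                t_leave = onset + config.trial_duration
            else:
                t_leave = t_init + travel + 4.0
            t_blend = t_leave + 2.0
            # a lingering CS- dwell must not bleed into the next CS+ trial
            nxt = plus_onsets[np.searchsorted(plus_onsets, onset + 1e-9)] \
                if np.searchsorted(plus_onsets, onset + 1e-9) < plus_onsets.size else np.inf
            if tr["cs_type"] == "minus" and t_blend > nxt - 0.5:
                t_blend = nxt - 0.5
                t_leave = t_blend - 2.0
            i1 = min(int(np.searchsorted(t, t_blend)), n)
            seg_t = t[i0:i1]
            ud = _smoothstep((seg_t - t_init) / dart)
            ur = np.clip((seg_t - t_init - dart) / run, 0.0, 1.0)
            seg = np.empty((seg_t.size, 2))
            seg[:, 0] = start[0] + (target[0] - start[0]) * ur
            seg[:, 1] = start[1] + (target[1] - start[1]) * ud
            leaving = seg_t > t_leave
            if leaving.any():
                ub = np.clip((seg_t[leaving] - t_leave) / 2.0, 0.0, 1.0)[:, None]
                seg[leaving] = target + (base[i0:i1][leaving] - target) * _smoothstep(ub.ravel())[:, None]
            pos[i0:i1] = seg

            rec["approach_init_true"] = t_init - onset
            # noiseless first entry into the 9 px radius
            d_seg = np.hypot(seg[:, 0] - target[0], seg[:, 1] - target[1])
            inside = np.flatnonzero(d_seg <= 9.0)
            if inside.size:
                rec["arrival_true"] = float(seg_t[inside[0]] - onset)
                if bool(tr["drink"]):
                    access0 = onset + config.cs_duration
                    in_access = np.flatnonzero((d_seg <= 9.0) & (seg_t >= access0))
                    if in_access.size:
                        rec["drink_time_true"] = float(seg_t[in_access[0]] - onset)
        records.append(rec)

    if config.tracking_noise_sd > 0:
        pos = pos + rng.normal(0.0, config.tracking_noise_sd, size=pos.shape)
    trace = TrackingTrace(time=t, x=pos[:, 0], y=pos[:, 1],
                          sippers=config.sippers, frame_rate=fr)
    times = pd.DataFrame.from_records(records)
    if truth is not None and truth.trials is not None:
        truth.trials = truth.trials.merge(times, on="trial", how="left")
    return trace, times


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _add_kernel(channel: np.ndarray, t_grid_n: int, start: float, values: np.ndarray) -> None:
    i0 = int(round(start / SPIKE_DT))
    i1 = min(i0 + values.size, t_grid_n)
    if i1 <= max(i0, 0):
        return
    lo = max(i0, 0)
    channel[lo:i1] = np.maximum(channel[lo:i1], values[lo - i0:i1 - i0])


def _signal_channels(trials: pd.DataFrame, times: pd.DataFrame, config: SimConfig,
                     t_end: float) -> np.ndarray:
    """(4, T) latent signal channels on the spike-simulation grid."""
    n = int(np.ceil(t_end / SPIKE_DT))
    g = np.zeros((4, n), dtype=np.float32)
    tt = trials.merge(times, on="trial", how="left")
    switch = tt.loc[
        (tt["cs_type"] == "plus") & (tt["cs_plus_index"] == config.change_point_trial),
        "cs_onset",
    ].iloc[0]

    # cue: onset transient plus a sustained component while the light is on,
    # with a short decay after CS offset
    tau_cue = 0.4
    k_t = np.arange(0.0, config.cs_duration + 0.5, SPIKE_DT)
    transient = (k_t / tau_cue) * np.exp(1 - k_t / tau_cue)
    sustained = np.where(k_t < config.cs_duration, 0.5,
                         0.5 * (1 - (k_t - config.cs_duration) / 0.5))
    cue_kernel = np.maximum(transient, sustained).astype(np.float32)
    tau_drink = 0.5
    k_t = np.arange(0.0, 3.0, SPIKE_DT)
    drink_kernel = ((k_t / tau_drink) * np.exp(1 - k_t / tau_drink)).astype(np.float32)
    ramp_up = np.linspace(0.0, 1.0, int(3.0 / SPIKE_DT), dtype=np.float32)
    ramp_down = np.linspace(1.0, 0.0, int(0.5 / SPIKE_DT), dtype=np.float32)
    approach_kernel = np.concatenate([ramp_up, ramp_down])

    for _, tr in tt.iterrows():
        onset = float(tr["cs_onset"])
        if tr["cs_type"] == "plus":
            if onset < switch:  # seeking offset on pre-change-point trials only
                _add_kernel(g[0], n, onset - 10.0, np.ones(int(10.0 / SPIKE_DT), dtype=np.float32))
            _add_kernel(g[1], n, onset, cue_kernel)
        if bool(tr["approach"]) and np.isfinite(tr.get("approach_init_true", np.nan)):
            t_init = onset + float(tr["approach_init_true"])
            _add_kernel(g[2], n, t_init - 3.0, approach_kernel)
        if bool(tr["drink"]) and np.isfinite(tr.get("drink_time_true", np.nan)):
            t_drink = onset + float(tr["drink_time_true"])
            _add_kernel(g[3], n, t_drink, drink_kernel)
    return g


def _waveform_template(kind: str, rng) -> np.ndarray:
    """Two-class depolarisation templates: narrow-fast vs broad-slow."""
    t_ms = np.arange(WAVEFORM_SAMPLES) * 1000.0 / WAVEFORM_RATE_HZ
    trough = 0.5
    if kind == "inhibitory":
        sd_tr, peak_dt, sd_pk, amp = 0.06, 0.22, 0.10, 0.5
    else:
        sd_tr, peak_dt, sd_pk, amp = 0.10, 0.55, 0.25, 0.5
    w = (-np.exp(-((t_ms - trough) ** 2) / (2 * sd_tr ** 2))
         + amp * np.exp(-((t_ms - trough - peak_dt) ** 2) / (2 * sd_pk ** 2)))
    return w + rng.normal(0.0, 0.01, size=w.shape)


def simulate_population(
    trials: pd.DataFrame,
    times: pd.DataFrame,
    config: SimConfig,
    seed: int,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, dict, GroundTruth]:
    """Poisson spike trains whose log-rates carry the four planted signals.

    Each unit i fires at

        lambda_i(t) = b_i * exp( sum_s L_is * gain_s * g_s(t) )

    with per-unit loadings L_is drawn from a gamma distribution (mean 1,
    CV ``loading_spread``), group gains from ``signal_gains``, and channels
    g_s: a pre-CS seeking offset on pre-change-point CS+ trials, a cue
    transient after CS+ onset, a 3 s ramp into approach initiation, and a
    transient after drink time.  Spikes are drawn as an inhomogeneous Poisson
    process at 1 ms resolution (baseline + thinned excess).  Waveforms come
    from narrow-fast (putative inhibitory) or broad-slow (putative
    excitatory) templates.

    Returns (spike table, {unit_id: waveform array}, ground truth with
    loadings, classes and expected spike counts).
    """
    rng = np.random.default_rng(seed)
    t_end = trials["cs_onset"].max() + config.trial_duration + 30.0
    g = _signal_channels(trials, times, config, t_end)
    active = np.flatnonzero((g > 0).any(axis=0))
    g_act = g[:, active].astype(np.float64)
    n_bins = g.shape[1]

    cv, mean = config.loading_spread, config.loading_mean
    if cv > 0:
        shape = 1.0 / cv ** 2
        loadings = rng.gamma(shape, mean * cv ** 2, size=(config.n_neurons, 4))
        # bounded tail keeps the worst-case rate below the cap
        loadings = np.minimum(loadings, mean * (1.0 + 4.0 * cv))
    else:
        loadings = np.full((config.n_neurons, 4), mean)
    gains = np.array([config.signal_gains[s] for s in SIGNALS])
    is_inh = rng.random(config.n_neurons) < config.ei_fraction
    baselines = np.where(is_inh, config.baseline_rate * config.inhibitory_rate_factor,
                         config.baseline_rate)

    unit_ids = [f"u{i:04d}" for i in range(config.n_neurons)]
    all_units, all_times = [], []
    expected = {}
    waveforms = {}
    for i, uid in enumerate(unit_ids):
        b = baselines[i]
        lam_act = b * np.exp((loadings[i] * gains) @ g_act)
        if lam_act.size and lam_act.max() > config.rate_cap:
            raise SimulationError(
                f"unit {uid} rate {lam_act.max():.1f} Hz exceeds the {config.rate_cap} Hz cap"
            )
        expected[uid] = b * n_bins * SPIKE_DT + float((lam_act - b).sum() * SPIKE_DT)
        # baseline: homogeneous Poisson over the whole session
        n0 = rng.poisson(b * n_bins * SPIKE_DT)
        spikes = rng.uniform(0.0, n_bins * SPIKE_DT, size=n0)
        # excess: inhomogeneous part, supported on the active bins only
        extra_counts = rng.poisson((lam_act - b) * SPIKE_DT)
        nz = np.flatnonzero(extra_counts)
        if nz.size:
            reps = extra_counts[nz]
            starts = active[nz] * SPIKE_DT
            offs = rng.uniform(0.0, SPIKE_DT, size=int(reps.sum()))
            spikes = np.concatenate([spikes, np.repeat(starts, reps) + offs])
        spikes.sort()
        all_units.append(np.full(spikes.size, uid, dtype=object))
        all_times.append(spikes)
        kind = "inhibitory" if is_inh[i] else "excitatory"
        waveforms[uid] = _waveform_template(kind, rng)

    spike_table = pd.DataFrame({
        "unit_id": np.concatenate(all_units) if all_units else [],
        "spike_time": np.concatenate(all_times) if all_times else [],
    })
    loadings_df = pd.DataFrame(loadings, columns=[f"loading_{s}" for s in SIGNALS])
    loadings_df.insert(0, "unit_id", unit_ids)
    loadings_df["true_class"] = np.where(is_inh, "inhibitory", "excitatory")
    loadings_df["baseline_rate"] = baselines
    if truth is None:
        truth = GroundTruth(change_point_trial=config.change_point_trial)
    truth.loadings = loadings_df
    truth.expected_counts = pd.Series(expected, name="expected_count")
    return spike_table, waveforms, truth


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

@dataclass
class SessionData:
    """One fully synthetic session plus its ground truth."""

    config: SimConfig
    trials: pd.DataFrame
    tracking: TrackingTrace
    spikes: pd.DataFrame
    waveforms: dict
    truth: GroundTruth


def generate_session(config: SimConfig, seed: int | None = None) -> SessionData:
    """Generate a complete session bundle deterministically from one seed."""
    root = config.seed if seed is None else seed
    ss = np.random.SeedSequence(root)
    s_sched, s_beh, s_trk, s_pop = [int(x) for x in ss.generate_state(4)]
    schedule = generate_schedule(config, s_sched)
    trials, truth = simulate_behavior(schedule, config, s_beh)
    tracking, times = simulate_tracking(trials, config, s_trk, truth)
    spikes, waveforms, truth = simulate_population(trials, times, config, s_pop, truth)
    return SessionData(config=config, trials=trials, tracking=tracking,
                       spikes=spikes, waveforms=waveforms, truth=truth)
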