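"""Behavioral structure inference for 2CAP sessions.

A 2CAP session is a sequence of cued-access trials (CS+ with fluid access,
CS- without).  This module infers the latent behavioral structure that the
population analysis conditions on:

* the *session change point* -- the trial at which an animal switches from a
  high-approach ("seeking") to a low-approach ("not seeking") state,
* per-trial *approach initiation* times, found as the change point of a
  kinematic approach-likelihood trace,
* per-trial *drink initiation* times (first snout entry into the sipper
  radius during access),
* surrogate event times for trials without a real event, and
* descriptive session metrics (CS sensitivity, latency, sipper occupancy)
  and the compulsive/non-compulsive session phenotype rules.

All change points are the global optimum of a single-split piecewise-constant
mean fit (exhaustive residual-sum-of-squares minimisation), the single-change
behavior of Matlab's ``findchangepts``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: distance (px) from the sipper at which the animal counts as "at the sipper"
DRINK_RADIUS_PX = 9.0
#: regulariser for inverse-distance weights, in z-units
WEIGHT_EPS = 1e-6
#: minimum segment length for all single-split change points (bins or trials)
MIN_SEGMENT = 2


class BehaviorError(ValueError):
    """Invalid input to a behavioral inference routine."""


# ---------------------------------------------------------------------------
# change-point engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionChangePoint:
    """Result of a single-split piecewise-constant mean fit.

    ``index`` is 1-based and names the first element of the post-change
    segment; it is ``None`` for constant sequences (no change point).
    """

    index: int | None
    magnitude: float
    rss_drop: float


def session_change_point(sequence, min_segment: int = MIN_SEGMENT) -> SessionChangePoint:
    """Largest-magnitude single change point of a sequence.

    Fits a two-segment piecewise-constant mean model at every admissible
    split (each segment at least ``min_segment`` elements long) and returns
    the split minimising the total residual sum of squares.  Ties break
    toward the earliest split.  Constant sequences carry no change point.

    Parameters
    ----------
    sequence : array-like
        Values in trial (or bin) order, e.g. the binary approach sequence
        over CS+ trials or an approach-likelihood trace.
    min_segment : int
        Minimum length of each segment.

    Returns
    -------
    SessionChangePoint
        ``index`` (1-based first post-change element), ``magnitude``
        (absolute difference of segment means) and ``rss_drop`` (residual
        error removed by splitting).
    """
    x = np.asarray(sequence, dtype=float)
    if x.ndim != 1 or x.size < 2 * min_segment or x.size < 4:
        raise BehaviorError(
            f"change-point sequence must be 1-D with >= {max(4, 2 * min_segment)} "
            f"elements, got shape {x.shape}"
        )
    if np.ptp(x) == 0.0:
        return SessionChangePoint(index=None, magnitude=0.0, rss_drop=0.0)

    n = x.size
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    ks = np.arange(min_segment, n - min_segment + 1)  # pre-segment lengths
    s1 = c1[ks - 1]
    s2 = c2[ks - 1]
    rss_pre = s2 - s1 * s1 / ks
    s1p = c1[-1] - s1
    s2p = c2[-1] - s2
    rss_post = s2p - s1p * s1p / (n - ks)
    rss = rss_pre + rss_post
    # earliest split wins ties; tolerance absorbs prefix-sum rounding noise
    tol = 1e-9 * max(1.0, float(c2[-1]))
    best = int(np.argmax(rss <= rss.min() + tol))
    k = int(ks[best])
    mean_pre = s1[best] / k
    mean_post = s1p[best] / (n - k)
    rss_total = c2[-1] - c1[-1] ** 2 / n
    return SessionChangePoint(
        index=k + 1,
        magnitude=float(abs(mean_post - mean_pre)),
        rss_drop=float(rss_total - rss[best]),
    )


# ---------------------------------------------------------------------------
# approach likelihood and initiation
# ---------------------------------------------------------------------------

@dataclass
class TrackingTrace:
    """Snout position over a session.

    ``time`` (s, strictly increasing), ``x``/``y`` (px) and the two sipper
    coordinates.  Gaps (NaNs) are allowed and flagged downstream.
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sippers: dict[str, tuple[float, float]]
    frame_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.time) == len(self.x) == len(self.y)):
            raise BehaviorError("tracking arrays must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise BehaviorError("tracking time grid must be strictly increasing")


@dataclass
class ApproachLikelihoodSet:
    """Per-trial approach likelihood q_i(t) with the weights that built it."""

    q: np.ndarray              # (n_trials, n_bins)
    weights: np.ndarray        # (n_trials, n_trials, n_bins), row-normalised
    trial_index: np.ndarray    # 1-based trial numbers of the rows
    rel_times: np.ndarray      # bin start times (s) relative to CS+ onset
    bin_width: float
    excluded: list = field(default_factory=list)


def _resample_xy(tracking: TrackingTrace, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.interp(times, tracking.time, tracking.x)
    y = np.interp(times, tracking.time, tracking.y)
    return x, y


def approach_likelihood(
    trials: pd.DataFrame,
    tracking: TrackingTrace,
    window: tuple[float, float] = (0.0, 12.0),
    bin_width: float = 0.1,
    eps: float = WEIGHT_EPS,
) -> ApproachLikelihoodSet:
    """Kinematic approach likelihood q_i(t) for every CS+ trial.

    At each time bin the snout state of trial *i* -- position and velocity,
    z-scored per dimension over all trials and bins -- is compared with every
    other trial *j* at the matched relative time.  Trials whose kinematics
    look like approach trials inherit their approach status through
    normalised inverse-distance weights:

        q_i(t) = sum_{j != i} w_ij(t) p_j,   w_ij(t) prop. 1 / (d_ij(t) + eps)

    where p_j is the binary approach status of trial j.
    """
    plus = trials[trials["cs_type"] == "plus"]
    if len(plus) < 2:
        raise BehaviorError("approach_likelihood needs at least two CS+ trials")
    rel = np.arange(window[0], window[1] + bin_width / 2, bin_width)

    rows, kept, excluded = [], [], []
    for _, tr in plus.iterrows():
        times = tr["cs_onset"] + rel
        x, y = _resample_xy(tracking, times)
        if np.all(~np.isfinite(x)) or np.all(~np.isfinite(y)):
            excluded.append(int(tr["trial"]))
            continue
        vx = np.gradient(x, bin_width)
        vy = np.gradient(y, bin_width)
        rows.append(np.stack([x, y, vx, vy], axis=-1))
        kept.append(int(tr["trial"]))
    if excluded:
        logger.warning("approach_likelihood: excluded trials with missing tracking: %s", excluded)
    if len(rows) < 2:
        raise BehaviorError("fewer than two CS+ trials with usable tracking")

    z = np.stack(rows)  # (n, T, 4)
    mu = z.mean(axis=(0, 1), keepdims=True)
    sd = z.std(axis=(0, 1), keepdims=True)
    sd[sd == 0] = 1.0
    z = (z - mu) / sd

    p = plus.set_index("trial").loc[kept, "approach"].to_numpy(dtype=float)
    diff = z[:, None, :, :] - z[None, :, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))          # (n, n, T)
    w = 1.0 / (d + eps)
    n = w.shape[0]
    w[np.arange(n), np.arange(n), :] = 0.0
    w /= w.sum(axis=1, keepdims=True)
    q = np.einsum("ijt,j->it", w, p)
    return ApproachLikelihoodSet(
        q=q, weights=w, trial_index=np.asarray(kept), rel_times=rel,
        bin_width=bin_width, excluded=excluded,
    )


def detect_approach_initiation(
    qset: ApproachLikelihoodSet, trials: pd.DataFrame
) -> pd.DataFrame:
    """Approach initiation time per approach trial.

    The initiation time is the single-split RSS change point of the trial's
    approach-likelihood trace; the returned time is the first bin of the
    post-change segment, in seconds relative to CS+ onset.  Trials with a
    flat likelihood are flagged (``approach_init`` NaN, ``flat`` True).
    """
    plus = trials.set_index("trial")
    records = []
    for row, trial in enumerate(qset.trial_index):
        if not bool(plus.loc[trial, "approach"]):
            continue
        cp = session_change_point(qset.q[row])
        if cp.index is None:
            logger.warning("trial %d: flat approach likelihood, initiation undefined", trial)
            records.append({"trial": int(trial), "approach_init": np.nan, "flat": True})
        else:
            t_ai = qset.rel_times[cp.index - 1]
            records.append({"trial": int(trial), "approach_init": float(t_ai), "flat": False})
    return pd.DataFrame.from_records(records, columns=["trial", "approach_init", "flat"])


def assign_surrogate_times(
    trials: pd.DataFrame, kind: str, seed: int
) -> pd.DataFrame:
    """Give event-less trials a time drawn from the session's real events.

    ``kind`` is ``"approach"`` (fills ``approach_init`` on no-approach CS+
    trials) or ``"drink"`` (fills ``drink_time`` on no-drink CS+ trials).
    Surrogate times are drawn uniformly with replacement from the real event
    times of the same session; real-event trials are left untouched.
    """
    if kind not in ("approach", "drink"):
        raise BehaviorError(f"unknown surrogate kind {kind!r}")
    col = "approach_init" if kind == "approach" else "drink_time"
    flag = "approach" if kind == "approach" else "drink"
    out = trials.copy()
    if col not in out.columns:
        out[col] = np.nan
    plus = out["cs_type"] == "plus"
    real = out.loc[plus & out[flag].astype(bool), col].dropna().to_numpy()
    if real.size == 0:
        raise BehaviorError(f"no real {kind} events to draw surrogate times from")
    targets = out.index[plus & ~out[flag].astype(bool)]
    rng = np.random.default_rng(seed)
    out.loc[targets, col] = rng.choice(real, size=len(targets), replace=True)
    surr_col = f"surrogate_{kind}"
    out[surr_col] = False
    out.loc[targets, surr_col] = True
    return out


# ---------------------------------------------------------------------------
# drinking and session metrics
# ---------------------------------------------------------------------------

def detect_drink_initiation(
    trials: pd.DataFrame,
    tracking: TrackingTrace,
    radius: float = DRINK_RADIUS_PX,
    cs_duration: float = 4.0,
    access_duration: float = 8.0,
) -> pd.Series:
    """First in-access snout entry into the cued sipper's radius, per CS+ trial.

    Returns drink times in seconds relative to CS+ onset (NaN when the snout
    never enters the radius during access).
    """
    if not tracking.sippers:
        raise BehaviorError("tracking trace has no sipper coordinates")
    times = {}
    for _, tr in trials[trials["cs_type"] == "plus"].iterrows():
        side = tr["side"]
        if side not in tracking.sippers:
            raise BehaviorError(f"no sipper coordinate for side {side!r}")
        sx, sy = tracking.sippers[side]
        t0 = tr["cs_onset"] + cs_duration
        mask = (tracking.time >= t0) & (tracking.time < t0 + access_duration)
        d = np.hypot(tracking.x[mask] - sx, tracking.y[mask] - sy)
        hit = np.flatnonzero(d <= radius)
        times[int(tr["trial"])] = (
            float(tracking.time[mask][hit[0]] - tr["cs_onset"]) if hit.size else np.nan
        )
    return pd.Series(times, name="drink_time")


def cs_sensitivity(trials: pd.DataFrame) -> float:
    """Fraction of all approaches that happened on CS+ trials (chance 0.5)."""
    app = trials["approach"].astype(bool)
    total = int(app.sum())
    if total == 0:
        raise BehaviorError("no approaches in session; CS sensitivity undefined")
    return float((app & (trials["cs_type"] == "plus")).sum() / total)


@dataclass
class SessionMetrics:
    """Descriptive behavior of one session."""

    time_at_sipper: pd.Series        # s within radius during access, per CS+ trial
    latency: pd.Series               # CS+ onset -> first radius entry (s), per trial
    proportion_approached: float
    occupancy: np.ndarray            # P(at cued sipper) per relative bin, CS+ trials
    occupancy_times: np.ndarray      # bin times relative to CS+ onset (s)


def session_metrics(
    trials: pd.DataFrame,
    tracking: TrackingTrace,
    radius: float = DRINK_RADIUS_PX,
    cs_duration: float = 4.0,
    access_duration: float = 8.0,
    occupancy_window: tuple[float, float] = (-10.0, 20.0),
    bin_width: float = 0.1,
) -> SessionMetrics:
    """Time at sipper, approach latency, approach proportion and occupancy."""
    plus = trials[trials["cs_type"] == "plus"]
    dt = 1.0 / tracking.frame_rate
    rel = np.arange(occupancy_window[0], occupancy_window[1], bin_width)

    time_at, latency, occ_rows = {}, {}, []
    for _, tr in plus.iterrows():
        trial = int(tr["trial"])
        sip = tracking.sippers.get(tr["side"])
        onset = tr["cs_onset"]
        # time at either sipper during access
        t0 = onset + cs_duration
        mask = (tracking.time >= t0) & (tracking.time < t0 + access_duration)
        at_any = np.zeros(int(mask.sum()), dtype=bool)
        for sx, sy in tracking.sippers.values():
            at_any |= np.hypot(tracking.x[mask] - sx, tracking.y[mask] - sy) <= radius
        time_at[trial] = float(at_any.sum() * dt)
        # latency to first entry of any sipper radius within CS+ + access
        mask2 = (tracking.time >= onset) & (tracking.time < t0 + access_duration)
        at_any2 = np.zeros(int(mask2.sum()), dtype=bool)
        for sx, sy in tracking.sippers.values():
            at_any2 |= np.hypot(tracking.x[mask2] - sx, tracking.y[mask2] - sy) <= radius
        hit = np.flatnonzero(at_any2)
        latency[trial] = float(tracking.time[mask2][hit[0]] - onset) if hit.size else np.nan
        # occupancy of the cued sipper on a relative-time grid
        if sip is not None:
            x, y = _resample_xy(tracking, onset + rel)
            occ_rows.append(np.hypot(x - sip[0], y - sip[1]) <= radius)

    occupancy = (
        np.mean(np.stack(occ_rows), axis=0) if occ_rows else np.zeros(rel.size)
    )
    return SessionMetrics(
        time_at_sipper=pd.Series(time_at, name="time_at_sipper"),
        latency=pd.Series(latency, name="latency"),
        proportion_approached=float(trials["approach"].astype(bool).mean()),
        occupancy=occupancy,
        occupancy_times=rel,
    )


# ---------------------------------------------------------------------------
# session phenotype
# ---------------------------------------------------------------------------

#: |z| threshold on within-strain alcohol+quinine consumption
PHENOTYPE_Z_THRESHOLD = 1.4
#: percent-decrease-in-consumption threshold
PHENOTYPE_DECREASE_THRESHOLD = 50.0

DEFAULT_STRAIN_LABELS = {"P": "compulsive", "Wistar": "non-compulsive"}


def classify_session_phenotype(
    records: pd.DataFrame,
    strain_defaults: dict[str, str] | None = None,
    z_threshold: float = PHENOTYPE_Z_THRESHOLD,
    decrease_threshold: float = PHENOTYPE_DECREASE_THRESHOLD,
) -> pd.DataFrame:
    """Compulsive / non-compulsive session labels with reclassification.

    ``records`` needs columns ``strain``, ``alcohol_consumption`` (the
    immediately preceding alcohol session) and ``quinine_consumption``.
    The alcohol+quinine consumption is z-scored within strain.  A session
    from a compulsive-default strain is reclassified non-compulsive when its
    z-score is below -1.4 *and* its percent decrease exceeds 50%; a session
    from a non-compulsive-default strain is reclassified compulsive when its
    z-score exceeds +1.4 *and* its percent decrease is below 50%.
    """
    defaults = DEFAULT_STRAIN_LABELS if strain_defaults is None else strain_defaults
    out = records.copy()
    out["z"] = np.nan
    for strain, grp in out.groupby("strain"):
        if len(grp) < 2:
            raise BehaviorError(
                f"strain {strain!r} has {len(grp)} session(s); z-score undefined"
            )
        v = grp["quinine_consumption"].to_numpy(dtype=float)
        out.loc[grp.index, "z"] = (v - v.mean()) / v.std(ddof=1)
    out["percent_decrease"] = 100.0 * (
        out["alcohol_consumption"] - out["quinine_consumption"]
    ) / out["alcohol_consumption"]

    labels, reclassified = [], []
    for _, r in out.iterrows():
        default = defaults.get(r["strain"])
        if default is None:
            raise BehaviorError(f"no default phenotype for strain {r['strain']!r}")
        label, flipped = default, False
        if default == "compulsive" and r["z"] < -z_threshold and r["percent_decrease"] > decrease_threshold:
            label, flipped = "non-compulsive", True
        elif default == "non-compulsive" and r["z"] > z_threshold and r["percent_decrease"] < decrease_threshold:
            label, flipped = "compulsive", True
        labels.append(label)
        reclassified.append(flipped)
    out["label"] = labels
    out["reclassified"] = reclassified
    return out
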