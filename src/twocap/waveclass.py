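"""Putative excitatory/inhibitory unit classification from mean waveforms.

Extracellular waveforms of fast-spiking (putative inhibitory) units
repolarise faster than those of regular-spiking (putative excitatory) units.
Each unit's largest-amplitude mean waveform is rescaled so its trough
(maximum hyperpolarisation) sits at -1 and its post-trough depolarisation
peak at +1; the times from the trough to 50% and to 95% of that rise (t50,
t95) summarise depolarisation speed.  Units are partitioned by a seeded
2-means on the standardised (t50, t95) plane -- the cluster with the faster
depolarisation (smaller mean t95) is putative inhibitory -- and points far
from their centroid are set aside as outliers.  The labels are explicitly
*putative*: waveform shape cannot separate all interneuron classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: rescaled depolarisation levels for the two delays (on the [-1, 1] scale)
LEVEL_50 = 0.0
LEVEL_95 = 0.9
#: per-standardised-feature distance (in cluster SDs) beyond which a unit is an outlier
OUTLIER_SD = 4.0
#: minimum number of units for a reliable 2-means split
MIN_UNITS = 10

LABEL_EXC = "putative_excitatory"
LABEL_INH = "putative_inhibitory"
LABEL_OUT = "outlier"


class WaveformError(ValueError):
    """Degenerate waveform or classification input."""


@dataclass
class Waveform:
    """A mean spike waveform (arbitrary amplitude units)."""

    samples: np.ndarray
    sample_rate_hz: float
    unit_id: object = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 16:
            raise WaveformError("waveform must have at least 16 samples")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz


def normalize_waveform(w: Waveform) -> Waveform:
    """Affine-rescale so the trough is -1 and the post-trough peak +1."""
    v = w.samples
    trough = int(np.argmin(v))
    if trough >= v.size - 1:
        raise WaveformError("waveform trough at the final sample; no post-trough rise")
    post = v[trough:]
    m, M = v[trough], post.max()
    if M == m:
        raise WaveformError("flat waveform: trough equals post-trough maximum")
    return Waveform(samples=(2.0 * v - (M + m)) / (M - m),
                    sample_rate_hz=w.sample_rate_hz, unit_id=w.unit_id)


def depolarization_delays(w: Waveform) -> tuple[float, float]:
    """(t50, t95) in ms, measured from the trough of a normalised waveform.

    t50 / t95 are the first times the post-trough rise crosses 50% / 95% of
    the trough-to-peak range (levels 0.0 and 0.9 on the [-1, 1] scale), with
    linear interpolation between samples.  A rise that never reaches the 95%
    level is an error (the unit is an outlier).
    """
    v = w.samples
    trough = int(np.argmin(v))
    rise = v[trough:]
    if rise.max() < LEVEL_95:
        raise WaveformError(
            f"unit {w.unit_id!r}: post-trough rise never reaches the 95% level"
        )

    def first_crossing(level: float) -> float:
        above = np.flatnonzero(rise >= level)
        k = int(above[0])
        if k == 0:
            return 0.0
        frac = (level - rise[k - 1]) / (rise[k] - rise[k - 1])
        return (k - 1 + frac) * w.dt_ms

    t50 = first_crossing(LEVEL_50)
    t95 = first_crossing(LEVEL_95)
    return t50, t95


def waveform_features(waveforms: list[Waveform]) -> pd.DataFrame:
    """Normalise every waveform and tabulate (t50, t95); failures are outliers."""
    rows = []
    for w in waveforms:
        try:
            t50, t95 = depolarization_delays(normalize_waveform(w))
            rows.append({"unit_id": w.unit_id, "t50": t50, "t95": t95, "failed": False})
        except WaveformError as err:
            logger.warning("waveform feature failure: %s", err)
            rows.append({"unit_id": w.unit_id, "t50": np.nan, "t95": np.nan, "failed": True})
    return pd.DataFrame.from_records(rows)


def classify_units(features: pd.DataFrame, seed: int = 0,
                   outlier_sd: float = OUTLIER_SD) -> pd.DataFrame:
    """Label units putative excitatory / inhibitory / outlier from (t50, t95).

    A seeded 2-means on the standardised feature plane replaces the manual
    clustering; the cluster with the smaller mean t95 (faster depolarisation)
    is putative inhibitory.  Units farther than ``outlier_sd`` cluster SDs
    from their centroid along either standardised feature become outliers, as
    do units whose features could not be measured.
    """
    ok = features[~features["failed"].astype(bool)]
    if len(ok) < MIN_UNITS:
        raise WaveformError(
            f"only {len(ok)} units with measurable features; need >= {MIN_UNITS}"
        )
    X = ok[["t50", "t95"]].to_numpy(dtype=float)
    labels = np.full(len(X), LABEL_OUT, dtype=object)
    active = np.ones(len(X), dtype=bool)
    # iterate: cluster, peel off far points (and degenerate singleton
    # clusters, which a far point would otherwise hijack), re-cluster
    for _ in range(3):
        if active.sum() < MIN_UNITS:
            break
        Xa = X[active]
        mu, sd = Xa.mean(axis=0), Xa.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Xa - mu) / sd
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(Z)
        assign = km.labels_
        inh_cluster = int(np.argmin([Xa[assign == c, 1].mean() for c in (0, 1)]))
        labels[active] = np.where(assign == inh_cluster, LABEL_INH, LABEL_EXC)
        newly_out = np.zeros(len(Xa), dtype=bool)
        for c in (0, 1):
            members = assign == c
            if members.sum() < 2:
                newly_out |= members
                continue
            spread = Z[members].std(axis=0)
            spread[spread == 0] = np.inf  # zero-variance feature cannot flag outliers
            dev = np.abs(Z[members] - km.cluster_centers_[c]) / spread
            far = (dev > outlier_sd).any(axis=1)
            newly_out[np.flatnonzero(members)[far]] = True
        if not newly_out.any():
            break
        idx = np.flatnonzero(active)[newly_out]
        labels[idx] = LABEL_OUT
        active[idx] = False

    out = features.copy()
    out["label"] = LABEL_OUT
    out.loc[ok.index, "label"] = labels
    assert (out.loc[~out["failed"], "t50"] <= out.loc[~out["failed"], "t95"]).all(), \
        "t50 must not exceed t95"
    return out


def epoch_rate_change_by_class(
    tensor_rates_hz: np.ndarray,
    unit_ids: list,
    labels: pd.DataFrame,
    epoch: slice,
    event_mask: np.ndarray,
) -> pd.DataFrame:
    """Per-class firing-rate change in an epoch between event and non-event trials.

    ``tensor_rates_hz`` is a (units, trials, bins) event-aligned rate tensor in
    Hz (unsmoothed or smoothed, but not z-scored); ``epoch`` selects relative
    bins; ``event_mask`` flags the event trials (e.g. drink trials).  Each
    unit's change is its mean epoch rate on event trials minus on non-event
    trials; changes are aggregated per waveform class (mean, SEM, n).
    """
    event_mask = np.asarray(event_mask, dtype=bool)
    per_unit = (
        tensor_rates_hz[:, event_mask][:, :, epoch].mean(axis=(1, 2))
        - tensor_rates_hz[:, ~event_mask][:, :, epoch].mean(axis=(1, 2))
    )
    lab = labels.set_index("unit_id")["label"]
    df = pd.DataFrame({"unit_id": unit_ids, "change_hz": per_unit})
    df["label"] = df["unit_id"].map(lab)
    rows = []
    for label, grp in df.groupby("label"):
        n = len(grp)
        if n == 0:
            continue
        rows.append({
            "label": label,
            "mean_change_hz": float(grp["change_hz"].mean()),
            "sem_change_hz": float(grp["change_hz"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "n_units": n,
        })
    present = {r["label"] for r in rows}
    for label in (LABEL_EXC, LABEL_INH):
        if label not in present:
            logger.warning("epoch_rate_change_by_class: no units of class %s", label)
    return pd.DataFrame.from_records(rows)
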