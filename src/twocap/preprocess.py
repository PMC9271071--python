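"""Spike-train preprocessing: binning, adaptive smoothing, event alignment,
z-scoring, trial-type averaging and profile concatenation.

The pipeline turns raw spike times into one *concatenated profile* per
neuron: the eight z-scored trial-type mean traces

    A_i(t) = [a+, a-, b+, b-, c+, c-, d+, d-]

where a is CS+-aligned activity split by seeking state, b is CS-aligned
activity split by CS type, c is approach-initiation-aligned activity split by
approach outcome, and d is drink-aligned activity split by drink outcome.
With the default windows the profile is 2*(301 + 301 + 71 + 201) = 1748 bins
long; it is the observation vector fed to the population PCA.

Conventions (fixed package-wide): 100 ms half-open bins [t, t+0.1); relative
bin 0 contains the event time; all times in seconds; trial indices 1-based;
bin indices 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)

#: default analysis bin width, s ("100 ms bins (10 Hz)")
BIN_WIDTH = 0.1
#: smoothing-kernel SD as a fraction of each neuron's mean inter-spike interval
KERNEL_SD_ISI_RATIO = 0.25
#: Gaussian kernel truncation, in SDs
KERNEL_TRUNCATE = 4.0

#: inclusive relative-bin windows per alignment (100 ms bins)
DEFAULT_WINDOWS: dict[str, tuple[int, int]] = {
    "cs_plus": (-100, 200),
    "cs": (-100, 200),
    "approach_init": (-50, 20),
    "drink": (-100, 100),
}

#: canonical segment order of the concatenated profile
SEGMENT_ORDER = (
    "seek_high", "seek_low",       # a+, a-  (CS+ aligned, pre/post change point)
    "cs_plus", "cs_minus",         # b+, b-  (CS aligned, by CS type)
    "approach", "no_approach",     # c+, c-  (approach-initiation aligned)
    "drink", "no_drink",           # d+, d-  (drink aligned)
)


class PreprocessError(ValueError):
    """Invalid input to a preprocessing step."""


# ---------------------------------------------------------------------------
# binning and smoothing
# ---------------------------------------------------------------------------

@dataclass
class RateMatrix:
    """Units x time-bins activity with its bin geometry.

    ``data`` holds spike counts per bin (or smoothed counts after
    :func:`smooth_adaptive`); :attr:`rates_hz` converts to Hz.
    """

    data: np.ndarray
    unit_ids: list
    bin_width: float = BIN_WIDTH
    t0: float = 0.0
    kernel_sd_s: dict = field(default_factory=dict)   # per-unit smoothing SD (s)
    unsmoothed_units: list = field(default_factory=list)

    @property
    def rates_hz(self) -> np.ndarray:
        return self.data / self.bin_width

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    def row(self, unit_id) -> np.ndarray:
        return self.data[self.unit_ids.index(unit_id)]


def _spike_times_by_unit(spikes: pd.DataFrame) -> dict:
    out = {}
    for unit, grp in spikes.groupby("unit_id", sort=True):
        t = grp["spike_time"].to_numpy(dtype=float)
        if t.size and t.min() < 0:
            raise PreprocessError(f"unit {unit!r} has negative spike times")
        if np.any(np.diff(t) < 0):
            raise PreprocessError(f"unit {unit!r} has unsorted spike times")
        out[unit] = t
    return out


def bin_spikes(
    spikes: pd.DataFrame, bin_width: float = BIN_WIDTH, duration: float | None = None,
    unit_ids: list | None = None,
) -> RateMatrix:
    """Histogram spike times into half-open bins [k*bw, (k+1)*bw).

    ``spikes`` is a table with columns ``unit_id`` and ``spike_time`` (s,
    sorted and nonnegative per unit).  The bin count per unit sums to the
    unit's total spike count.  ``unit_ids`` may name the full unit set so
    spike-less units still get a (zero) row.
    """
    by_unit = _spike_times_by_unit(spikes)
    if unit_ids is not None:
        by_unit = {u: by_unit.get(u, np.empty(0)) for u in unit_ids}
    max_t = max((t[-1] for t in by_unit.values() if t.size), default=0.0)
    if duration is None:
        duration = max_t
    if duration < max_t:
        raise PreprocessError(f"duration {duration} s is before the last spike at {max_t} s")
    n_bins = max(int(np.ceil(duration / bin_width)), 1)
    data = np.zeros((len(by_unit), n_bins))
    unit_ids = list(by_unit)
    for i, unit in enumerate(unit_ids):
        t = by_unit[unit]
        if not t.size:
            continue
        idx = np.floor(t / bin_width).astype(int)
        idx[idx >= n_bins] = n_bins - 1  # spike exactly at `duration`
        data[i] = np.bincount(idx, minlength=n_bins)
    return RateMatrix(data=data, unit_ids=unit_ids, bin_width=bin_width)


def smooth_adaptive(counts: RateMatrix, spikes: pd.DataFrame) -> RateMatrix:
    """Per-neuron Gaussian smoothing with SD = 1/4 of the mean ISI.

    The kernel SD adapts to each neuron's firing rate: one quarter of that
    neuron's mean inter-spike interval, constant over the session.  The
    kernel is truncated at +/-4 SD and applied with reflecting boundaries,
    which preserves constants exactly and conserves the total spike count.
    Units with fewer than two spikes (mean ISI undefined) pass through
    unsmoothed and are flagged.
    """
    by_unit = _spike_times_by_unit(spikes)
    data = counts.data.copy()
    kernel_sd, unsmoothed = {}, []
    for i, unit in enumerate(counts.unit_ids):
        t = by_unit.get(unit, np.empty(0))
        if t.size < 2:
            unsmoothed.append(unit)
            logger.warning("unit %r has <2 spikes; passed through unsmoothed", unit)
            continue
        sd_s = KERNEL_SD_ISI_RATIO * float(np.diff(t).mean())
        kernel_sd[unit] = sd_s
        data[i] = gaussian_filter1d(
            counts.data[i], sigma=sd_s / counts.bin_width,
            mode="reflect", truncate=KERNEL_TRUNCATE,
        )
    return RateMatrix(
        data=data, unit_ids=list(counts.unit_ids), bin_width=counts.bin_width,
        t0=counts.t0, kernel_sd_s=kernel_sd, unsmoothed_units=unsmoothed,
    )


# ---------------------------------------------------------------------------
# event alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedTensor:
    """Units x events x relative-bins slices of a rate matrix."""

    data: np.ndarray
    alignment: str
    window: tuple[int, int]
    unit_ids: list
    event_index: np.ndarray        # indices (into the supplied event list) kept
    event_times: np.ndarray        # absolute event times kept (s)
    dropped: list = field(default_factory=list)
    zscored: bool = False
    constant_units: list = field(default_factory=list)

    @property
    def rel_bins(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1] + 1)

    @property
    def n_events(self) -> int:
        return self.data.shape[1]


def extract_aligned(
    rates: RateMatrix,
    events,
    alignment: str,
    window: tuple[int, int] | None = None,
) -> AlignedTensor:
    """One window of activity per event, relative bin 0 containing the event.

    Events whose window would run past either end of the recording (or whose
    time is NaN) are dropped and logged; extracting zero events is an error.
    """
    if window is None:
        if alignment not in DEFAULT_WINDOWS:
            raise PreprocessError(f"no default window for alignment {alignment!r}")
        window = DEFAULT_WINDOWS[alignment]
    w0, w1 = window
    events = np.asarray(events, dtype=float)
    slices, kept, times, dropped = [], [], [], []
    for j, ev in enumerate(events):
        if not np.isfinite(ev):
            dropped.append(j)
            continue
        b = int(np.floor(ev / rates.bin_width))
        lo, hi = b + w0, b + w1 + 1
        if lo < 0 or hi > rates.n_bins:
            dropped.append(j)
            continue
        slices.append(rates.data[:, lo:hi])
        kept.append(j)
        times.append(ev)
    if dropped:
        logger.warning(
            "extract_aligned(%s): dropped %d event(s) outside the recording: %s",
            alignment, len(dropped), dropped,
        )
    if not slices:
        raise PreprocessError(f"no events survived alignment {alignment!r}")
    data = np.stack(slices, axis=1)  # (units, events, bins)
    return AlignedTensor(
        data=data, alignment=alignment, window=(w0, w1),
        unit_ids=list(rates.unit_ids), event_index=np.asarray(kept),
        event_times=np.asarray(times), dropped=dropped,
    )


def zscore_aligned(tensor: AlignedTensor, sd_floor: float = 1e-12) -> AlignedTensor:
    """z-score each unit over all (trial, bin) cells of the alignment.

    Constant-rate units map to all-zeros and are flagged.
    """
    data = tensor.data
    mu = data.mean(axis=(1, 2), keepdims=True)
    sd = data.std(axis=(1, 2), keepdims=True)
    constant = sd[:, 0, 0] <= sd_floor
    safe_sd = np.where(sd <= sd_floor, 1.0, sd)
    z = (data - mu) / safe_sd
    z[constant] = 0.0
    flagged = [u for u, c in zip(tensor.unit_ids, constant) if c]
    if flagged:
        logger.warning("zscore_aligned(%s): constant units zeroed: %s", tensor.alignment, flagged)
    return AlignedTensor(
        data=z, alignment=tensor.alignment, window=tensor.window,
        unit_ids=list(tensor.unit_ids), event_index=tensor.event_index,
        event_times=tensor.event_times, dropped=list(tensor.dropped),
        zscored=True, constant_units=flagged,
    )


# ---------------------------------------------------------------------------
# trial-type averaging and concatenation
# ---------------------------------------------------------------------------

def average_trial_types(
    tensor: AlignedTensor,
    in_first: np.ndarray,
    names: tuple[str, str] = ("first", "second"),
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Mean trace per unit for the two cells of a trial partition.

    ``in_first`` is a boolean mask over the tensor's events (True -> first
    cell).  Returns (mean_first, mean_second, (n_first, n_second)).
    """
    mask = np.asarray(in_first, dtype=bool)
    if mask.shape != (tensor.n_events,):
        raise PreprocessError(
            f"partition mask has shape {mask.shape}, expected ({tensor.n_events},)"
        )
    n1, n2 = int(mask.sum()), int((~mask).sum())
    for n, name in ((n1, names[0]), (n2, names[1])):
        if n == 0:
            raise PreprocessError(
                f"trial partition cell {name!r} is empty for alignment {tensor.alignment!r}"
            )
    return tensor.data[:, mask].mean(axis=1), tensor.data[:, ~mask].mean(axis=1), (n1, n2)


@dataclass
class ConcatenatedProfile:
    """Per-neuron concatenation of the eight trial-type mean traces."""

    data: np.ndarray                       # (units, total_bins)
    unit_ids: list
    segment_map: dict[str, tuple[int, int]]  # name -> (start, stop) 0-based, stop exclusive
    groups: np.ndarray | None = None       # per-unit group label
    animals: np.ndarray | None = None      # per-unit animal id

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    def segment(self, name: str) -> np.ndarray:
        start, stop = self.segment_map[name]
        return self.data[:, start:stop]

    def segment_slice(self, name: str) -> slice:
        start, stop = self.segment_map[name]
        return slice(start, stop)


def concatenate_profiles(segments: dict[str, np.ndarray], unit_ids: list,
                         groups: np.ndarray | None = None,
                         animals: np.ndarray | None = None) -> ConcatenatedProfile:
    """Join the eight per-unit mean traces in the canonical segment order.

    With the default windows the result is 1748 bins long; the emitted
    segment map covers every bin exactly once.
    """
    missing = [name for name in SEGMENT_ORDER if name not in segments]
    if missing:
        raise PreprocessError(f"missing trial-type segments: {missing}")
    n_units = len(unit_ids)
    parts, seg_map, offset = [], {}, 0
    for name in SEGMENT_ORDER:
        seg = np.asarray(segments[name], dtype=float)
        if seg.shape[0] != n_units:
            raise PreprocessError(
                f"segment {name!r} has {seg.shape[0]} units, expected {n_units}"
            )
        parts.append(seg)
        seg_map[name] = (offset, offset + seg.shape[1])
        offset += seg.shape[1]
    return ConcatenatedProfile(
        data=np.concatenate(parts, axis=1), unit_ids=list(unit_ids),
        segment_map=seg_map, groups=groups, animals=animals,
    )


def stack_profiles(profiles: list[ConcatenatedProfile]) -> ConcatenatedProfile:
    """Pool units from several profiles (e.g. sessions) into one.

    All profiles must share the same segment map.
    """
    if not profiles:
        raise PreprocessError("no profiles to stack")
    seg_map = profiles[0].segment_map
    for p in profiles[1:]:
        if p.segment_map != seg_map:
            raise PreprocessError("profiles have mismatched segment maps")
    groups = (
        np.concatenate([np.asarray(p.groups) for p in profiles])
        if all(p.groups is not None for p in profiles) else None
    )
    animals = (
        np.concatenate([np.asarray(p.animals) for p in profiles])
        if all(p.animals is not None for p in profiles) else None
    )
    return ConcatenatedProfile(
        data=np.concatenate([p.data for p in profiles], axis=0),
        unit_ids=[u for p in profiles for u in p.unit_ids],
        segment_map=dict(seg_map), groups=groups, animals=animals,
    )
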