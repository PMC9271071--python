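"""Subsampled PCA with stability selection and PC-separation readouts.

Population sizes differ across experimental groups, so a single PCA would be
dominated by the larger group.  Instead PCA is repeated over many random
subsamples drawing the *same* number of neurons from every group (by default
500 iterations of 200 neurons per group, neurons as variables and the 1748
concatenated time bins as observations).  Components are matched across
iterations by explained-variance rank and sign-aligned against the
cross-iteration mean trace.  A component is *stable* when the variance of
its mean trace over time exceeds the variance of the iteration-to-iteration
deviations (variance ratio > 1); only stable PCs enter the readout.

The readout is *PC separation*: the per-time-bin Euclidean distance, across
stable PCs, between a group's projected trajectories for two trial types
(seeking vs not-seeking, CS+ vs CS-, approach vs no-approach, drink vs
no-drink).  Epoch means of this distance are the representation-strength
summaries compared across groups; shuffle and leave-one-out controls rerun
the whole stack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import AlignedTensor, ConcatenatedProfile, average_trial_types, concatenate_profiles, stack_profiles

logger = logging.getLogger(__name__)

#: sentinel for an infinite variance ratio (zero cross-iteration deviation)
RATIO_CAP = np.inf
#: maximum sign-alignment passes
MAX_ALIGN_PASSES = 10


class PCAError(ValueError):
    """Invalid input to a population-PCA step."""


# ---------------------------------------------------------------------------
# subsample design and PCA iterations
# ---------------------------------------------------------------------------

@dataclass
class SubsampleDesign:
    """Which units each PCA iteration draws, balanced across groups."""

    group_units: dict[str, np.ndarray]
    n_iterations: int = 500
    n_per_group: int = 200
    seed: int = 0
    selections: list[dict[str, np.ndarray]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        for group, units in self.group_units.items():
            units = np.asarray(units)
            self.group_units[group] = units
            if units.size < self.n_per_group:
                raise PCAError(
                    f"group {group!r} has {units.size} units; "
                    f"subsampling needs >= {self.n_per_group}"
                )
        if not self.selections:
            rng = np.random.default_rng(self.seed)
            self.selections = [
                {
                    g: rng.choice(u, size=self.n_per_group, replace=False)
                    for g, u in self.group_units.items()
                }
                for _ in range(self.n_iterations)
            ]

    def iteration_units(self, k: int) -> np.ndarray:
        """Unit ids of iteration k, groups concatenated in key order."""
        return np.concatenate([self.selections[k][g] for g in self.group_units])


@dataclass
class PCAIterationResult:
    """Per-iteration coefficients, score traces and explained variance."""

    coefficients: np.ndarray   # (iters, m_units, K)
    scores: np.ndarray         # (iters, bins, K) -- raw projections X @ f
    means: np.ndarray          # (iters, m_units) per-unit centering means
    explained_variance_ratio: np.ndarray  # (iters, K)
    unit_ids: np.ndarray       # (iters, m_units)
    design: SubsampleDesign
    aligned: bool = False

    @property
    def n_iterations(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_components(self) -> int:
        return self.coefficients.shape[2]

    def centered_scores(self, k: int) -> np.ndarray:
        """Scores of the centered matrix, iteration k."""
        return self.scores[k] - self.means[k] @ self.coefficients[k]


def run_subsampled_pca(
    profile: ConcatenatedProfile,
    design: SubsampleDesign,
    n_components: int | None = None,
) -> PCAIterationResult:
    """PCA on every subsample, neurons as variables, time bins as observations.

    Each iteration builds the (bins x selected-units) matrix, centers each
    unit over time and decomposes it; components are ordered by explained
    variance.  Coefficients are orthonormal per iteration; stored scores are
    the raw projections ``X @ f`` so that group projections of a whole-sample
    group reproduce them exactly.
    """
    pos = {u: i for i, u in enumerate(profile.unit_ids)}
    m = design.n_per_group * len(design.group_units)
    k_max = min(m, profile.n_bins)
    K = k_max if n_components is None else min(n_components, k_max)

    coeffs = np.empty((design.n_iterations, m, K))
    scores = np.empty((design.n_iterations, profile.n_bins, K))
    means = np.empty((design.n_iterations, m))
    evr = np.empty((design.n_iterations, K))
    ids = np.empty((design.n_iterations, m), dtype=object)
    for k in range(design.n_iterations):
        units = design.iteration_units(k)
        rows = [pos[u] for u in units]
        X = profile.data[rows].T              # (bins, units)
        mu = X.mean(axis=0)
        _, s, vt = np.linalg.svd(X - mu, full_matrices=False)
        f = vt[:K].T
        coeffs[k] = f
        scores[k] = X @ f
        means[k] = mu
        var = s ** 2
        total = var.sum()
        evr[k] = var[:K] / total if total > 0 else 0.0
        ids[k] = units
    logger.info("subsampled PCA: %d iterations of %d units (%d per group), %d PCs kept",
                design.n_iterations, m, design.n_per_group, K)
    return PCAIterationResult(
        coefficients=coeffs, scores=scores, means=means,
        explained_variance_ratio=evr, unit_ids=ids, design=design,
    )


def align_pc_signs(result: PCAIterationResult) -> PCAIterationResult:
    """Flip iterations whose score trace is inverted relative to the mean PC.

    PCA signs are arbitrary; iterations anti-correlated with the
    cross-iteration mean trace of their rank are multiplied by -1, the mean
    is recomputed, and the pass repeats until no flips occur (at most 10
    passes).  Zero-variance traces are excluded from the correlation.
    """
    if result.n_iterations < 2:
        raise PCAError("sign alignment needs at least two iterations")
    scores = result.scores.copy()
    coeffs = result.coefficients.copy()
    centered = scores - scores.mean(axis=1, keepdims=True)
    sds = centered.std(axis=1)                      # (iters, K)
    degenerate = sds == 0
    if degenerate.any():
        logger.warning("align_pc_signs: %d zero-variance score trace(s) excluded",
                       int(degenerate.sum()))
    for _ in range(MAX_ALIGN_PASSES):
        mean_trace = scores.mean(axis=0)            # (bins, K)
        mc = mean_trace - mean_trace.mean(axis=0, keepdims=True)
        # exact mirror pairs cancel the mean; seed such ranks from iteration 0
        cancelled = mc.std(axis=0) < 1e-12 * np.maximum(sds.max(axis=0), 1e-300)
        if cancelled.any():
            mc[:, cancelled] = centered[0][:, cancelled]
        corr_num = np.einsum("kbj,bj->kj", centered, mc)
        flip = (corr_num < 0) & ~degenerate
        if not flip.any():
            break
        for j in range(result.n_components):
            rows = np.flatnonzero(flip[:, j])
            scores[rows, :, j] *= -1
            coeffs[rows, :, j] *= -1
            centered[rows, :, j] *= -1
    return replace(result, scores=scores, coefficients=coeffs, aligned=True)


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

@dataclass
class StablePCSet:
    """Variance-ratio stability of each PC rank, with the mean traces."""

    variance_ratio: np.ndarray   # (K,)
    stable: np.ndarray           # (K,) bool; ratio > 1
    mean_scores: np.ndarray      # (bins, K) iteration-mean, sign-aligned traces
    mean_explained_variance: np.ndarray  # (K,)

    @property
    def stable_ranks(self) -> np.ndarray:
        """0-based ranks of the stable PCs."""
        return np.flatnonzero(self.stable)

    @property
    def n_stable(self) -> int:
        return int(self.stable.sum())


def pc_stability(result: PCAIterationResult) -> StablePCSet:
    """Flag PCs whose mean trace varies more over time than across iterations.

    ratio_j = var_t( <e_j(t)>_iters ) / var( e_j - <e_j> over bins & iters );
    stable iff ratio > 1.  A zero deviation variance (identical traces every
    iteration) reports an infinite ratio and is stable.
    """
    if not result.aligned:
        result = align_pc_signs(result)
    mean_trace = result.scores.mean(axis=0)                # (bins, K)
    num = mean_trace.var(axis=0)                           # (K,)
    dev = result.scores - mean_trace[None]
    den = dev.reshape(-1, result.n_components).var(axis=0)
    # identical traces every iteration: deviation variance is zero up to
    # rounding; report the infinite sentinel
    zero_den = den <= 1e-12 * np.maximum(num, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(~zero_den, num / den, RATIO_CAP)
    return StablePCSet(
        variance_ratio=ratio,
        stable=ratio > 1.0,
        mean_scores=mean_trace,
        mean_explained_variance=result.explained_variance_ratio.mean(axis=0),
    )


# ---------------------------------------------------------------------------
# group projections and separation
# ---------------------------------------------------------------------------

@dataclass
class GroupTrajectory:
    """Iteration-mean projection of one group onto selected PC ranks."""

    data: np.ndarray             # (bins, n_ranks)
    group: str
    pc_ranks: np.ndarray         # 0-based PC ranks of the columns
    segment_map: dict[str, tuple[int, int]]

    def segment(self, name: str) -> np.ndarray:
        start, stop = self.segment_map[name]
        return self.data[start:stop]


def project_group(
    profile: ConcatenatedProfile,
    result: PCAIterationResult,
    group: str,
    stable: StablePCSet | None = None,
) -> GroupTrajectory:
    """Project one group's neurons through every iteration's coefficients.

    E_{j,k}(t) = sum_{i in G_k} f_{i,j,k} A_i(t) over the group's selected
    units of iteration k, averaged over iterations.  If a stability set is
    given only stable ranks are emitted.
    """
    design = result.design
    if group not in design.group_units:
        raise PCAError(f"unknown group {group!r}; design has {list(design.group_units)}")
    pos = {u: i for i, u in enumerate(profile.unit_ids)}
    groups = list(design.group_units)
    gi = groups.index(group)
    lo, hi = gi * design.n_per_group, (gi + 1) * design.n_per_group

    total = np.zeros((profile.n_bins, result.n_components))
    for k in range(result.n_iterations):
        units = design.selections[k][group]
        rows = [pos[u] for u in units]
        A = profile.data[rows].T                  # (bins, n_per_group)
        total += A @ result.coefficients[k][lo:hi]
    traj = total / result.n_iterations
    ranks = np.arange(result.n_components)
    if stable is not None:
        ranks = stable.stable_ranks
        traj = traj[:, ranks]
    return GroupTrajectory(data=traj, group=group, pc_ranks=ranks,
                           segment_map=dict(profile.segment_map))


@dataclass
class SeparationSeries:
    """Per-bin Euclidean distance between two trajectories across PCs."""

    values: np.ndarray
    n_pcs: int
    bin_width: float = 0.1


def pc_separation(traj1: np.ndarray, traj2: np.ndarray,
                  bin_width: float = 0.1) -> SeparationSeries:
    """Euclidean distance across stable PCs at matched time bins."""
    a = np.atleast_2d(np.asarray(traj1, dtype=float))
    b = np.atleast_2d(np.asarray(traj2, dtype=float))
    if a.shape != b.shape:
        raise PCAError(f"trajectory windows differ in shape: {a.shape} vs {b.shape}")
    values = np.sqrt(((a - b) ** 2).sum(axis=-1))
    return SeparationSeries(values=values, n_pcs=a.shape[-1], bin_width=bin_width)


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Epoch:
    """A 20-bin comparison window between two trajectory slices.

    ``segments`` names the two trial-type segments compared; ``window_a`` /
    ``window_b`` are bin slices *within* each segment.  For the cue-onset
    epoch both segments are the CS+ trace and the windows differ (pre-CS
    -2.4..-0.5 s vs CS 0..1.9 s); for all others the windows match.
    """

    name: str
    segments: tuple[str, str]
    window_a: slice
    window_b: slice


def _rel_slice(window_start_bin: int, lo_s: float, hi_s: float, bw: float = 0.1) -> slice:
    lo = int(round(lo_s / bw)) - window_start_bin
    hi = int(round(hi_s / bw)) - window_start_bin
    return slice(lo, hi + 1)


#: 20-bin default epochs (segment-relative bin slices, 100 ms bins)
DEFAULT_EPOCHS: dict[str, Epoch] = {
    # -2.5..-0.6 s before CS+, before the CS but clear of it
    "seeking": Epoch("seeking", ("seek_high", "seek_low"),
                     _rel_slice(-100, -2.5, -0.6), _rel_slice(-100, -2.5, -0.6)),
    # paired windows on the CS+ trace: pre-CS -2.4..-0.5 s vs CS 0..1.9 s
    "cue_onset": Epoch("cue_onset", ("cs_plus", "cs_plus"),
                       _rel_slice(-100, -2.4, -0.5), _rel_slice(-100, 0.0, 1.9)),
    # CS+ vs CS- at 2.0..3.9 s of the CS, past the shared onset transient
    "cs_discrimination": Epoch("cs_discrimination", ("cs_plus", "cs_minus"),
                               _rel_slice(-100, 2.0, 3.9), _rel_slice(-100, 2.0, 3.9)),
    # -3.0..-1.1 s before approach initiation, clear of movement onset
    "approach": Epoch("approach", ("approach", "no_approach"),
                      _rel_slice(-50, -3.0, -1.1), _rel_slice(-50, -3.0, -1.1)),
    # 0..1.9 s after drink time
    "drink": Epoch("drink", ("drink", "no_drink"),
                   _rel_slice(-100, 0.0, 1.9), _rel_slice(-100, 0.0, 1.9)),
}

#: label key (trial partition) that each epoch's trial types come from
EPOCH_LABEL_KEY = {
    "seeking": "seek", "cue_onset": "cue", "cs_discrimination": "cue",
    "approach": "approach", "drink": "drink",
}


@dataclass
class EpochSummary:
    """The per-bin separation values of one epoch and their mean."""

    epoch: str
    group: str
    values: np.ndarray
    mean: float
    n_bins: int


def epoch_separation(traj: GroupTrajectory, epoch: Epoch) -> SeparationSeries:
    """Separation series of one epoch of a group trajectory."""
    a = traj.segment(epoch.segments[0])[epoch.window_a]
    b = traj.segment(epoch.segments[1])[epoch.window_b]
    return pc_separation(a, b)


def epoch_mean_separation(series: SeparationSeries, epoch_window: slice | None = None,
                          epoch: str = "", group: str = "") -> EpochSummary:
    """Per-bin epoch separation values and their mean.

    ``epoch_window`` selects bins within an already-computed separation
    series (pass None when the series covers exactly the epoch).
    """
    values = series.values if epoch_window is None else series.values[epoch_window]
    if values.size == 0:
        raise PCAError("epoch window lies outside the separation series")
    return EpochSummary(epoch=epoch, group=group, values=values,
                        mean=float(values.mean()), n_bins=int(values.size))


# ---------------------------------------------------------------------------
# the assembled analysis, shuffle null and leave-one-out
# ---------------------------------------------------------------------------

@dataclass
class GroupData:
    """One group's z-scored aligned tensors and trial-type labels.

    ``tensors`` maps the four alignments ('seek', 'cue', 'approach',
    'drink') to z-scored :class:`AlignedTensor` objects; ``labels`` maps the
    same keys to boolean arrays over that tensor's events (True = first trial
    type: pre-change-point / CS+ / approach / drink).  ``animals`` optionally
    assigns each unit to an animal for leave-one-out.
    """

    tensors: dict[str, AlignedTensor]
    labels: dict[str, np.ndarray]
    animals: np.ndarray | None = None


SEGMENTS_BY_KEY = {
    "seek": ("seek_high", "seek_low"),
    "cue": ("cs_plus", "cs_minus"),
    "approach": ("approach", "no_approach"),
    "drink": ("drink", "no_drink"),
}


def build_profile(groups: dict[str, GroupData]) -> ConcatenatedProfile:
    """Average each group's trial types and concatenate into one profile set."""
    per_group = []
    for name, gd in groups.items():
        segments = {}
        for key, (seg_a, seg_b) in SEGMENTS_BY_KEY.items():
            tensor = gd.tensors[key]
            mean_a, mean_b, _ = average_trial_types(tensor, gd.labels[key],
                                                    names=(seg_a, seg_b))
            segments[seg_a] = mean_a
            segments[seg_b] = mean_b
        unit_ids = [f"{name}/{u}" for u in gd.tensors["seek"].unit_ids]
        per_group.append(concatenate_profiles(
            segments, unit_ids,
            groups=np.full(len(unit_ids), name, dtype=object),
            animals=gd.animals,
        ))
    return stack_profiles(per_group)


@dataclass
class AnalysisResult:
    """Full subsampled-PCA analysis output for a set of groups."""

    profile: ConcatenatedProfile
    pca: PCAIterationResult
    stability: StablePCSet
    trajectories: dict[str, GroupTrajectory]
    epoch_summaries: pd.DataFrame     # group x epoch mean separations
    separations: dict[tuple[str, str], SeparationSeries]


def run_separation_analysis(
    groups: dict[str, GroupData],
    n_iterations: int = 500,
    n_per_group: int = 200,
    n_components: int | None = 20,
    seed: int = 0,
    epochs: dict[str, Epoch] | None = None,
    design: SubsampleDesign | None = None,
) -> AnalysisResult:
    """Profiles -> subsampled PCA -> stability -> projections -> separations."""
    epochs = DEFAULT_EPOCHS if epochs is None else epochs
    profile = build_profile(groups)
    if design is None:
        group_units = {
            g: np.asarray([u for u, lab in zip(profile.unit_ids, profile.groups) if lab == g])
            for g in groups
        }
        design = SubsampleDesign(group_units=group_units, n_iterations=n_iterations,
                                 n_per_group=n_per_group, seed=seed)
    result = align_pc_signs(run_subsampled_pca(profile, design, n_components=n_components))
    stable = pc_stability(result)
    if stable.n_stable == 0:
        logger.warning("no stable PCs; falling back to PC 1 for separations")
        stable = replace(stable, stable=np.arange(len(stable.stable)) == 0)

    trajectories, separations, rows = {}, {}, []
    for g in groups:
        traj = project_group(profile, result, g, stable=stable)
        trajectories[g] = traj
        for ep_name, ep in epochs.items():
            series = epoch_separation(traj, ep)
            separations[(g, ep_name)] = series
            summary = epoch_mean_separation(series, epoch=ep_name, group=g)
            rows.append({"group": g, "epoch": ep_name, "mean_separation": summary.mean,
                         "n_bins": summary.n_bins})
    return AnalysisResult(
        profile=profile, pca=result, stability=stable, trajectories=trajectories,
        epoch_summaries=pd.DataFrame.from_records(rows), separations=separations,
    )


def shuffle_null(
    groups: dict[str, GroupData],
    epoch_name: str,
    n_shuffles: int = 100,
    shuffle_seed: int = 0,
    permutations: list[dict[str, np.ndarray]] | None = None,
    **analysis_kwargs,
) -> pd.DataFrame:
    """Null distribution of epoch mean separation under trial-type shuffling.

    The trial-type labels feeding the epoch's comparison are permuted within
    each group (session), the full analysis is recomputed, and the epoch mean
    separation recorded.  ``shuffle_seed`` drives the permutations (the
    subsample-design seed goes through ``analysis_kwargs``); ``permutations``
    may supply explicit permutations (one dict of group -> index array per
    shuffle), and the identity permutation reproduces the observed value
    exactly.
    """
    key = EPOCH_LABEL_KEY[epoch_name]
    rng = np.random.default_rng(shuffle_seed)
    if permutations is None:
        permutations = [
            {g: rng.permutation(len(gd.labels[key])) for g, gd in groups.items()}
            for _ in range(n_shuffles)
        ]
    rows = []
    for s, perm in enumerate(permutations):
        shuffled = {}
        for g, gd in groups.items():
            labels = dict(gd.labels)
            labels[key] = np.asarray(gd.labels[key])[perm[g]]
            shuffled[g] = GroupData(tensors=gd.tensors, labels=labels, animals=gd.animals)
        res = run_separation_analysis(shuffled, **analysis_kwargs)
        sub = res.epoch_summaries[res.epoch_summaries["epoch"] == epoch_name]
        for _, r in sub.iterrows():
            rows.append({"shuffle": s, "group": r["group"],
                         "mean_separation": r["mean_separation"]})
    return pd.DataFrame.from_records(rows)


def leave_one_out(
    groups: dict[str, GroupData],
    **analysis_kwargs,
) -> pd.DataFrame:
    """Epoch summaries with each animal held out in turn.

    Units are tagged with animal ids (``GroupData.animals``); for every
    animal the whole analysis is rerun without that animal's units.
    Holdouts that empty a group or leave it below the subsample size are
    skipped with a log message.
    """
    animal_ids = sorted({
        a for gd in groups.values() if gd.animals is not None for a in gd.animals
    })
    if not animal_ids:
        raise PCAError("leave_one_out needs per-unit animal ids")
    n_per_group = analysis_kwargs.get("n_per_group", 200)
    rows = []
    for holdout in animal_ids:
        reduced, ok = {}, True
        for g, gd in groups.items():
            keep = np.asarray(gd.animals) != holdout
            if keep.sum() < max(1, n_per_group):
                logger.warning("holdout %r leaves group %r with %d units; skipped",
                               holdout, g, int(keep.sum()))
                ok = False
                break
            tensors = {
                key: replace(t, data=t.data[keep],
                             unit_ids=[u for u, k in zip(t.unit_ids, keep) if k])
                for key, t in gd.tensors.items()
            }
            reduced[g] = GroupData(tensors=tensors, labels=gd.labels,
                                   animals=np.asarray(gd.animals)[keep])
        if not ok:
            continue
        res = run_separation_analysis(reduced, **analysis_kwargs)
        for _, r in res.epoch_summaries.iterrows():
            rows.append({"holdout": holdout, "group": r["group"], "epoch": r["epoch"],
                         "mean_separation": r["mean_separation"]})
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# firing-rate change at the session change point
# ---------------------------------------------------------------------------

def rate_change_at_changepoint(
    per_trial_rates: np.ndarray,
    j_scp: int,
    jitter_max: int = 2,
    n_random: int = 100,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Observed firing-rate change at the change point vs a trial-jittered null.

    ``per_trial_rates`` is (units, trials) mean rates in trial order; the
    observed value is the mean over units of the absolute rate change between
    the two trials adjacent to the change point (``j_scp`` 1-based, first
    post-change trial).  The null re-centers at ``j_scp + u`` with u drawn
    uniformly from {-jitter_max..jitter_max} \\ {0}.
    """
    rates = np.asarray(per_trial_rates, dtype=float)
    n_trials = rates.shape[1]
    if not (jitter_max + 2 <= j_scp <= n_trials - jitter_max):
        raise PCAError(
            f"change point {j_scp} too close to the session edge for +/-{jitter_max} jitter"
        )

    def delta(center: int) -> float:
        return float(np.abs(rates[:, center - 1] - rates[:, center - 2]).mean())

    observed = delta(j_scp)
    rng = np.random.default_rng(seed)
    offsets = np.concatenate([np.arange(-jitter_max, 0), np.arange(1, jitter_max + 1)])
    null = np.array([delta(j_scp + int(u)) for u in rng.choice(offsets, size=n_random)])
    return observed, null
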