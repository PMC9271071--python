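"""Shared fixtures and builders for the test suite.

All synthetic inputs are generated at test time; reduced problem sizes
(24 CS+ / 24 CS- trials, short intertrial intervals, tens of neurons and
subsample iterations) keep the suite fast while preserving the structure of
a full session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from twocap.io import PipelineConfig, bundle_from_session
from twocap.pipeline import analyze_session_behavior, build_group_data
from twocap.poppca import GroupData
from twocap.preprocess import AlignedTensor
from twocap.synth import SimConfig, generate_session

#: reduced session geometry used throughout the suite
SMALL_SESSION = dict(
    n_cs_plus=24, n_cs_minus=24, iti_set=(20.0, 28.0, 36.0), change_point_trial=13,
)


def small_config(**overrides) -> SimConfig:
    kw = dict(SMALL_SESSION)
    kw.update(overrides)
    return SimConfig(**kw)


def make_group_data(seed: int, n_neurons: int = 50, group: str = "g",
                    pipeline: PipelineConfig | None = None,
                    **config_overrides) -> tuple[GroupData, "SessionData"]:
    """Full behavior+preprocess stack for one reduced synthetic session."""
    cfg = small_config(group=group, session_id=group, n_neurons=n_neurons,
                       **config_overrides)
    sess = generate_session(cfg, seed=seed)
    bundle = bundle_from_session(sess)
    pc = pipeline or PipelineConfig()
    sb = analyze_session_behavior(bundle, pc)
    return build_group_data(bundle, sb, pc), sess


def toy_tensor(data: np.ndarray, alignment: str = "cs_plus",
               window: tuple[int, int] | None = None) -> AlignedTensor:
    """Wrap a (units, trials, bins) array as an aligned tensor."""
    data = np.asarray(data, dtype=float)
    if window is None:
        window = (0, data.shape[2] - 1)
    return AlignedTensor(
        data=data, alignment=alignment, window=window,
        unit_ids=[f"u{i}" for i in range(data.shape[0])],
        event_index=np.arange(data.shape[1]),
        event_times=np.arange(data.shape[1], dtype=float),
    )


def toy_groups(seed: int = 0, n_units: int = 30, n_trials: int = 16,
               seek_effect: float = 2.0, noise: float = 0.5) -> dict[str, GroupData]:
    """Minimal GroupData with a planted seeking-state rate offset.

    The four alignments all carry ``n_trials`` events; the 'seek' partition
    splits trials in half, and pre-change trials get a per-unit offset of
    size ``seek_effect`` on the CS+-aligned tensor.
    """
    rng = np.random.default_rng(seed)
    windows = {"seek": 301, "cue": 301, "approach": 71, "drink": 201}
    alignments = {"seek": "cs_plus", "cue": "cs", "approach": "approach_init",
                  "drink": "drink"}
    win_bounds = {"seek": (-100, 200), "cue": (-100, 200),
                  "approach": (-50, 20), "drink": (-100, 100)}
    loadings = rng.normal(1.0, 0.3, size=n_units)
    tensors, labels = {}, {}
    half = n_trials // 2
    for key, nbins in windows.items():
        data = rng.normal(0.0, noise, size=(n_units, n_trials, nbins))
        if key == "seek":
            data[:, :half, :] += seek_effect * loadings[:, None, None]
        tensors[key] = toy_tensor(data, alignments[key], win_bounds[key])
        labels[key] = np.arange(n_trials) < half
    return {"g": GroupData(tensors=tensors, labels=labels,
                           animals=np.asarray([f"a{i % 3}" for i in range(n_units)]))}


@pytest.fixture(scope="session")
def session_small():
    """One reduced synthetic session shared across tests."""
    return generate_session(small_config(n_neurons=40), seed=7)


@pytest.fixture(scope="session")
def behavior_small(session_small):
    bundle = bundle_from_session(session_small)
    pc = PipelineConfig()
    return bundle, analyze_session_behavior(bundle, pc), pc
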