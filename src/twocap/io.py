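"""Session-bundle I/O, validation and pipeline configuration.

A *session bundle* is a directory holding one recording session as plain
columnar tables (CSV, comma, UTF-8, header row) plus one binary array
container for the waveforms and a YAML manifest:

    manifest.yaml     session id, group labels, file names, conventions
    trials.csv        trial, cs_type, side, cs_onset, approach, correct, drink
    tracking.csv      time, x, y
    spikes.csv        unit_id, spike_time (sorted within unit)
    waveforms.npz     one array per unit id
    truth_trials.csv  ground-truth channel (synthetic bundles only)
    truth_units.csv   ground-truth loadings/classes (synthetic bundles only)

The manifest's ``conventions`` block pins the binning and coordinate
conventions; loading cross-checks every table and reports all violations at
once.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import TrackingTrace
from .synth import SessionData, SimConfig
from .waveclass import Waveform

MANIFEST_NAME = "manifest.yaml"
FLOAT_FORMAT = "%.17g"   # full double round-trip precision

CONVENTIONS = {
    "bin_width_s": 0.1,
    "time_origin": "session start (s)",
    "coordinates": "px",
    "trial_index": "1-based, time order",
}


class BundleError(ValueError):
    """A session bundle failed validation; lists every violation."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("session bundle invalid:\n  - " + "\n  - ".join(violations))


@dataclass
class SessionBundle:
    """One loaded, validated session."""

    path: Path
    manifest: dict
    trials: pd.DataFrame
    tracking: TrackingTrace
    spikes: pd.DataFrame
    waveforms: dict[str, np.ndarray]
    truth_trials: pd.DataFrame | None = None
    truth_units: pd.DataFrame | None = None
    report: dict = field(default_factory=dict)

    @property
    def session_id(self) -> str:
        return self.manifest["session_id"]

    @property
    def group_key(self) -> str:
        lab = self.manifest["labels"]
        return f"{lab['group']}/{lab['liquid']}/{lab['test']}"

    @property
    def waveform_rate_hz(self) -> float:
        return float(self.manifest.get("waveform_rate_hz", 30000.0))

    def waveform_objects(self) -> list[Waveform]:
        return [Waveform(samples=w, sample_rate_hz=self.waveform_rate_hz, unit_id=u)
                for u, w in self.waveforms.items()]


def bundle_from_session(session: SessionData) -> SessionBundle:
    """Wrap a generated session as an in-memory bundle (no disk round trip)."""
    cfg = session.config
    manifest = {
        "session_id": cfg.session_id,
        "labels": {"group": cfg.group, "liquid": cfg.liquid, "test": cfg.test},
        "files": {}, "conventions": dict(CONVENTIONS),
        "tracking_rate_hz": cfg.tracking_rate, "waveform_rate_hz": 30000.0,
        "sippers": {k: list(v) for k, v in cfg.sippers.items()},
        "cs_duration_s": cfg.cs_duration, "access_duration_s": cfg.access_duration,
        "n_units": cfg.n_neurons,
    }
    return SessionBundle(path=Path("."), manifest=manifest, trials=session.trials,
                         tracking=session.tracking, spikes=session.spikes,
                         waveforms=session.waveforms,
                         truth_trials=session.truth.trials,
                         truth_units=session.truth.loadings)


def write_session_bundle(path, session: SessionData) -> Path:
    """Write a generated session to a bundle directory (deterministic bytes)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = session.config
    session.trials.to_csv(path / "trials.csv", index=False, float_format=FLOAT_FORMAT)
    pd.DataFrame({
        "time": session.tracking.time, "x": session.tracking.x, "y": session.tracking.y,
    }).to_csv(path / "tracking.csv", index=False, float_format=FLOAT_FORMAT)
    session.spikes.to_csv(path / "spikes.csv", index=False, float_format=FLOAT_FORMAT)
    np.savez(path / "waveforms.npz", **session.waveforms)
    if session.truth.trials is not None:
        session.truth.trials.to_csv(path / "truth_trials.csv", index=False,
                                    float_format=FLOAT_FORMAT)
    if session.truth.loadings is not None:
        truth_units = session.truth.loadings.copy()
        if session.truth.expected_counts is not None:
            truth_units["expected_count"] = truth_units["unit_id"].map(
                session.truth.expected_counts
            )
        truth_units.to_csv(path / "truth_units.csv", index=False, float_format=FLOAT_FORMAT)
    manifest = {
        "session_id": cfg.session_id,
        "labels": {"group": cfg.group, "liquid": cfg.liquid, "test": cfg.test},
        "files": {
            "trials": "trials.csv", "tracking": "tracking.csv", "spikes": "spikes.csv",
            "waveforms": "waveforms.npz",
        },
        "conventions": dict(CONVENTIONS),
        "tracking_rate_hz": cfg.tracking_rate,
        "waveform_rate_hz": 30000.0,
        "sippers": {k: list(v) for k, v in cfg.sippers.items()},
        "cs_duration_s": cfg.cs_duration,
        "access_duration_s": cfg.access_duration,
        "n_units": cfg.n_neurons,
        "sim_config": cfg.to_dict(),
        "truth_change_point_trial": session.truth.change_point_trial,
    }
    with open(path / MANIFEST_NAME, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def load_session_bundle(path) -> SessionBundle:
    """Load and validate a session bundle, collecting every violation."""
    path = Path(path)
    violations: list[str] = []
    mf_path = path / MANIFEST_NAME
    if not mf_path.exists():
        raise BundleError([f"missing manifest: {mf_path}"])
    with open(mf_path, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    for key in ("session_id", "labels", "files", "conventions"):
        if key not in manifest:
            violations.append(f"manifest lacks required key {key!r}")
    files = manifest.get("files", {})
    for role in ("trials", "tracking", "spikes", "waveforms"):
        name = files.get(role)
        if name is None:
            violations.append(f"manifest names no {role} file")
        elif not (path / name).exists():
            violations.append(f"missing {role} file: {path / name}")
    if violations:
        raise BundleError(violations)

    trials = pd.read_csv(path / files["trials"], float_precision="round_trip")
    tracking_df = pd.read_csv(path / files["tracking"], float_precision="round_trip")
    spikes = pd.read_csv(path / files["spikes"], float_precision="round_trip")
    with np.load(path / files["waveforms"]) as npz:
        waveforms = {k: npz[k] for k in npz.files}

    required = {"trials": ({"trial", "cs_type", "side", "cs_onset", "approach",
                            "correct", "drink"}, trials),
                "tracking": ({"time", "x", "y"}, tracking_df),
                "spikes": ({"unit_id", "spike_time"}, spikes)}
    for name, (cols, df) in required.items():
        missing = cols - set(df.columns)
        if missing:
            violations.append(f"{name}.csv lacks columns {sorted(missing)}")
    if not violations:
        if trials["trial"].duplicated().any():
            violations.append("duplicated trial indices in trials.csv")
        for unit, grp in spikes.groupby("unit_id"):
            t = grp["spike_time"].to_numpy()
            bad = np.flatnonzero(np.diff(t) < 0)
            if bad.size:
                violations.append(
                    f"unit {unit!r}: unsorted spike times at row {grp.index[bad[0] + 1]}"
                )
            if t.size and t.min() < 0:
                violations.append(f"unit {unit!r}: negative spike times")
        spike_units = set(spikes["unit_id"].unique())
        wf_units = set(waveforms)
        if spike_units - wf_units:
            violations.append(
                f"units with spikes but no waveform: {sorted(spike_units - wf_units)[:5]}"
            )
    if violations:
        raise BundleError(violations)

    tracking = TrackingTrace(
        time=tracking_df["time"].to_numpy(), x=tracking_df["x"].to_numpy(),
        y=tracking_df["y"].to_numpy(),
        sippers={k: tuple(v) for k, v in manifest.get("sippers", {}).items()},
        frame_rate=float(manifest.get("tracking_rate_hz", 30.0)),
    )
    truth_trials = truth_units = None
    if (path / "truth_trials.csv").exists():
        truth_trials = pd.read_csv(path / "truth_trials.csv",
                                   float_precision="round_trip")
    if (path / "truth_units.csv").exists():
        truth_units = pd.read_csv(path / "truth_units.csv",
                                  float_precision="round_trip")
    report = {
        "n_trials": len(trials),
        "n_units": len(waveforms),
        "n_spikes": len(spikes),
        "violations": [],
    }
    return SessionBundle(path=path, manifest=manifest, trials=trials, tracking=tracking,
                         spikes=spikes, waveforms=waveforms, truth_trials=truth_trials,
                         truth_units=truth_units, report=report)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tunable of the analysis pipeline, with a provenance hash.

    The defaults are the study configuration: 100 ms bins, the four alignment
    windows, 500 PCA iterations of 200 neurons per group, 20-bin epochs, a
    9 px drink radius.  Unknown keys are rejected when loading from a file,
    and the config hash is stamped into every output file.
    """

    seed: int = 0
    bin_width: float = 0.1
    n_iterations: int = 500
    n_per_group: int = 200
    n_components: int = 20
    drink_radius_px: float = 9.0
    q_window: tuple = (0.0, 12.0)
    jitter_max: int = 2
    epochs: dict = field(default_factory=dict)   # name -> {segments, window_a, window_b} overrides

    def to_dict(self) -> dict:
        d = asdict(self)
        d["q_window"] = list(self.q_window)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        d = dict(d)
        if "q_window" in d:
            d["q_window"] = tuple(d["q_window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def write_table(df: pd.DataFrame, path, config_hash: str) -> None:
    """Write a CSV with the config hash in a leading comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")
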