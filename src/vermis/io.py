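"""Session-bundle file format.

A session bundle is a directory holding delimited-text tables (trials,
events, units), an HDF5 container with the 1-kHz eye traces, an optional
ground-truth JSON (synthetic sessions), and a manifest.  Event times are
stored in ms: simple-spike and mossy-fiber events relative to saccade
onset, complex spikes relative to saccade offset (the alignment is part of
the format contract, never implicit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

FORMAT_VERSION = 1

__all__ = [
    "SessionBundle",
    "BundleIntegrityError",
    "BundleVersionError",
    "read_bundle",
    "write_bundle",
    "save_matrices",
    "load_matrices",
]


class BundleIntegrityError(ValueError):
    """Referential-integrity violation inside a session bundle."""


class BundleVersionError(ValueError):
    """Unknown or missing bundle format version."""


@dataclass
class SessionBundle:
    """In-memory session: trial table, event table, unit table, traces."""

    trials: pd.DataFrame
    events: pd.DataFrame
    units: pd.DataFrame
    traces: dict = field(default_factory=dict)
    ground_truth: dict | None = None
    manifest: dict = field(default_factory=lambda: {"format_version": FORMAT_VERSION})

    def validate(self) -> None:
        if "format_version" not in self.manifest:
            raise BundleVersionError("manifest missing format_version")
        if self.manifest["format_version"] != FORMAT_VERSION:
            raise BundleVersionError(
                f"unsupported format_version {self.manifest['format_version']!r}"
            )
        known = set(self.trials["trial_index"].astype(int))
        if len(self.events):
            referenced = set(self.events["trial_index"].astype(int))
            orphans = referenced - known
            if orphans:
                raise BundleIntegrityError(
                    f"events reference unknown trials: {sorted(orphans)[:5]}"
                )
        for df, col in ((self.events, "time_ms"),):
            if len(df) and not np.isfinite(df[col].to_numpy(float)).all():
                raise BundleIntegrityError(f"non-finite values in {col}")

    def centrifugal_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["type"] == "centrifugal"]


def write_bundle(bundle: SessionBundle, path) -> Path:
    """Write a bundle directory; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.validate()
    bundle.trials.to_csv(path / "trials.tsv", sep="\t", index=False)
    bundle.events.to_csv(path / "events.tsv", sep="\t", index=False)
    bundle.units.to_csv(path / "units.tsv", sep="\t", index=False)
    with h5py.File(path / "traces.h5", "w") as fh:
        for ti, tr in bundle.traces.items():
            g = fh.create_group(f"trial_{int(ti):05d}")
            g.create_dataset("position", data=np.asarray(tr["position"], float))
            g.create_dataset("velocity", data=np.asarray(tr["velocity"], float))
    if bundle.ground_truth is not None:
        (path / "ground_truth.json").write_text(
            json.dumps(bundle.ground_truth, indent=1, default=_jsonify)
        )
    (path / "manifest.json").write_text(json.dumps(bundle.manifest, indent=1))
    return path


def read_bundle(path) -> SessionBundle:
    """Load and validate a bundle directory."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise BundleVersionError(f"missing manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    trials = pd.read_csv(path / "trials.tsv", sep="\t")
    events = pd.read_csv(path / "events.tsv", sep="\t")
    units = pd.read_csv(path / "units.tsv", sep="\t", keep_default_na=False)
    traces = {}
    trace_path = path / "traces.h5"
    if trace_path.exists():
        with h5py.File(trace_path, "r") as fh:
            for name in fh:
                ti = int(name.split("_")[1])
                traces[ti] = {
                    "position": fh[name]["position"][:],
                    "velocity": fh[name]["velocity"][:],
                }
    gt_path = path / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else None
    bundle = SessionBundle(
        trials=trials,
        events=events,
        units=units,
        traces=traces,
        ground_truth=ground_truth,
        manifest=manifest,
    )
    bundle.validate()
    return bundle


def events_by_unit(bundle: SessionBundle, kind: str) -> dict:
    """Per-unit, per-trial event-time arrays.

    Returns ``{unit_id: {"spikes": {trial: array}, "cs": {trial: array}}}``
    for units of the given kind ("MF" or "PC").  Spike times are relative
    to saccade onset; CS times relative to saccade offset.
    """
    out = {}
    unit_rows = bundle.units[bundle.units["kind"] == kind]
    spike_kind = "SS" if kind == "PC" else "MF"
    ev = bundle.events
    for uid in unit_rows["unit_id"]:
        sub = ev[ev["unit_id"] == uid]
        spikes = {
            int(ti): g["time_ms"].to_numpy(float)
            for ti, g in sub[sub["event_kind"] == spike_kind].groupby("trial_index")
        }
        cs = {
            int(ti): g["time_ms"].to_numpy(float)
            for ti, g in sub[sub["event_kind"] == "CS"].groupby("trial_index")
        }
        out[uid] = {"spikes": spikes, "cs": cs}
    return out


# ----------------------------------------------------------------------
# generic matrix container (rate models, manifolds, network weights)
# ----------------------------------------------------------------------

def save_matrices(path, groups: dict) -> Path:
    """Save nested {group: {name: array-or-scalar}} dictionaries to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        for gname, content in groups.items():
            g = fh.create_group(str(gname))
            for key, value in content.items():
                g.create_dataset(str(key), data=np.asarray(value))
    return path


def load_matrices(path) -> dict:
    out: dict = {}
    with h5py.File(path, "r") as fh:
        for gname in fh:
            out[gname] = {k: fh[gname][k][()] for k in fh[gname]}
    return out


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
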