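"""Session-bundle file formats and result serialization.

A session bundle is one directory of plain-text files:

* ``signals.csv`` — wide table: ``time_s`` plus one column per channel; a
  channel sampled at a different native rate may instead ship as its own
  ``signals_<name>.csv`` (columns ``time_s``, ``value``).
* ``events.csv`` — ``onset_s, amplitude_ma, width_ms, rate_hz, duration_s``.
* ``meta.json`` — grounded flag, nerve condition, experiment kind,
  luminance class, session id.

Units are normalized to mA / ms / Hz / s / cm/s at read time.  Results are
written as TSV (tables) and JSON (fits, bootstrap summaries) and round-trip
losslessly.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .session import Channel, SessionMeta, SessionRecord, StimTrain

logger = logging.getLogger("vnspupil")

EVENT_COLUMNS = ("onset_s", "amplitude_ma", "width_ms", "rate_hz")


class BundleFormatError(ValueError):
    pass


def read_session_bundle(path: str | Path) -> SessionRecord:
    """Read and validate one session bundle directory."""
    path = Path(path)
    events_file = path / "events.csv"
    meta_file = path / "meta.json"
    if not events_file.exists():
        raise BundleFormatError(f"missing events.csv in {path}")

    events = pd.read_csv(events_file)
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            raise BundleFormatError(f"events.csv missing mandatory column {col!r}")
    if "duration_s" not in events.columns:
        events["duration_s"] = 10.0
    if events["onset_s"].duplicated().any():
        warnings.warn("events.csv contains repeated onsets; keeping both entries")
    trains = [StimTrain(onset=float(r.onset_s), amplitude=float(r.amplitude_ma),
                        width=float(r.width_ms), rate=float(r.rate_hz),
                        duration=float(r.duration_s))
              for r in events.itertuples()]

    channels: dict[str, Channel] = {}
    wide = path / "signals.csv"
    if wide.exists():
        df = pd.read_csv(wide)
        if "time_s" not in df.columns:
            raise BundleFormatError("signals.csv missing mandatory column 'time_s'")
        t = df["time_s"].to_numpy(dtype=float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise BundleFormatError("signals.csv timestamps are not strictly increasing")
        for col in df.columns:
            if col != "time_s":
                channels[col] = Channel(t, df[col].to_numpy(dtype=float))
    for extra in sorted(path.glob("signals_*.csv")):
        name = extra.stem[len("signals_"):]
        df = pd.read_csv(extra)
        for col in ("time_s", "value"):
            if col not in df.columns:
                raise BundleFormatError(f"{extra.name} missing mandatory column {col!r}")
        t = df["time_s"].to_numpy(dtype=float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise BundleFormatError(f"{extra.name} timestamps are not strictly increasing")
        channels[name] = Channel(t, df["value"].to_numpy(dtype=float))
    if not channels:
        raise BundleFormatError(f"no signals.csv or signals_*.csv in {path}")

    meta = SessionMeta()
    if meta_file.exists():
        d = json.loads(meta_file.read_text())
        meta = SessionMeta(
            grounded=bool(d.get("grounded", False)),
            nerve_condition=d.get("nerve_condition", "intact"),
            experiment_kind=d.get("experiment_kind", "parameter_exploration"),
            luminance_class=d.get("luminance_class", "standard"),
            session_id=d.get("session_id", path.name),
            extra={k: v for k, v in d.items()
                   if k not in ("grounded", "nerve_condition", "experiment_kind",
                                "luminance_class", "session_id")},
        )
    logger.info("read bundle %s: %d channels, %d events", path, len(channels), len(trains))
    return SessionRecord(channels=channels, events=trains, meta=meta)


def write_session_bundle(record: SessionRecord, path: str | Path,
                         truth: dict | None = None,
                         float_format: str = "%.17g") -> Path:
    """Write a SessionRecord as a bundle directory (one CSV per channel)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    record.event_frame().drop(columns=["charge_uc"]).to_csv(
        path / "events.csv", index=False, float_format=float_format)
    for name, ch in record.channels.items():
        pd.DataFrame({"time_s": ch.times, "value": ch.values}).to_csv(
            path / f"signals_{name}.csv", index=False, float_format=float_format)
    m = record.meta
    (path / "meta.json").write_text(json.dumps({
        "grounded": m.grounded, "nerve_condition": m.nerve_condition,
        "experiment_kind": m.experiment_kind, "luminance_class": m.luminance_class,
        "session_id": m.session_id, **m.extra,
    }, indent=2))
    if truth is not None:
        (path / "truth.json").write_text(json.dumps(truth, indent=2))
    return path


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_results(trial_table: pd.DataFrame | None, fits: dict | None,
                  path: str | Path, seed: int | None = None) -> Path:
    """Write a trial table (TSV) and fit summaries (JSON) under ``path``."""
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create output directory {path}: {err}") from err
    if trial_table is not None:
        trial_table.to_csv(path / "trial_table.tsv", sep="\t", index=False,
                           float_format="%.17g")
    if fits:
        payload = _jsonable(fits)
        if seed is not None:
            payload["seed"] = seed
        (path / "fits.json").write_text(json.dumps(payload, indent=2))
    return path


def read_trial_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")
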