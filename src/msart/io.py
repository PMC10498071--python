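"""Trial-log serialization and configuration files.

A session log is stored as a flat UTF-8 CSV (one row per trial, fixed
column set) plus a JSON sidecar next to it (same stem, ``.json``) holding
the configuration snapshot, the seed, responder metadata, the terminal
mode state and a schema version.  Readers reject unknown schema majors and
malformed logs with row-level diagnostics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from msart.engine import ModeState, SessionConfig, SessionLog, TrialRecord

SCHEMA_VERSION = "1.0"

LOG_COLUMNS = [
    "index",
    "onset_s",
    "fixation_ms",
    "digit",
    "stim_class",
    "mode",
    "response",
    "rt_ms",
    "outcome",
    "corrected",
]


class LogFormatError(ValueError):
    """Malformed trial log or sidecar."""


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_log(path: str | Path, log: SessionLog) -> Path:
    """Write the trial CSV and its JSON sidecar; returns the CSV path."""
    path = Path(path)
    df = log.to_frame()
    df["rt_ms"] = df["rt_ms"].map(lambda v: "" if v is None or pd.isna(v) else f"{v:g}")
    df["corrected"] = df["corrected"].map(lambda b: "true" if b else "false")
    df.to_csv(path, index=False, lineterminator="\n")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "config": log.config.to_dict(),
        "responder": log.responder_meta,
        "terminal_state": dataclasses.asdict(log.terminal_state),
        "practice": log.practice,
        "n_trials": len(log),
    }
    sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    return path


def read_log(path: str | Path) -> SessionLog:
    """Read a trial CSV + sidecar back into a SessionLog.

    Raises LogFormatError on a missing/extra column, an empty file, an
    unknown schema major, or non-monotone onsets, naming the offending
    column or row.
    """
    path = Path(path)
    sc_path = sidecar_path(path)
    if not path.exists():
        raise LogFormatError(f"no such log: {path}")
    if not sc_path.exists():
        raise LogFormatError(f"missing sidecar: {sc_path}")
    raw = path.read_text(encoding="utf-8")
    if not raw.strip():
        raise LogFormatError(f"{path}: empty file")

    sidecar = json.loads(sc_path.read_text(encoding="utf-8"))
    version = str(sidecar.get("schema_version", ""))
    major = version.split(".", 1)[0]
    if major != SCHEMA_VERSION.split(".", 1)[0]:
        raise LogFormatError(f"{sc_path}: unsupported schema version {version!r}")

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise LogFormatError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in LOG_COLUMNS]
    if extra:
        raise LogFormatError(f"{path}: unexpected column(s) {extra}")

    config = SessionConfig.from_dict(sidecar["config"])
    trials: list[TrialRecord] = []
    prev_onset = -1.0
    for row_no, row in enumerate(df.to_dict("records"), start=2):
        try:
            rt = None if row["rt_ms"] == "" else float(row["rt_ms"])
            rec = TrialRecord(
                index=int(row["index"]),
                onset=float(row["onset_s"]),
                fixation_ms=int(row["fixation_ms"]),
                digit=int(row["digit"]),
                stim_class=str(row["stim_class"]),
                mode_at_onset=int(row["mode"]),
                response=str(row["response"]),
                rt_ms=rt,
                outcome=str(row["outcome"]),
                corrected=str(row["corrected"]).lower() in ("true", "1"),
            )
        except (TypeError, ValueError) as exc:
            raise LogFormatError(f"{path}: row {row_no}: {exc}") from exc
        if rec.onset <= prev_onset:
            raise LogFormatError(f"{path}: row {row_no}: onset {rec.onset} not increasing")
        prev_onset = rec.onset
        trials.append(rec)

    terminal = sidecar.get("terminal_state")
    return SessionLog(
        config=config,
        trials=trials,
        responder_meta=sidecar.get("responder", {}),
        terminal_state=ModeState(**terminal) if terminal else ModeState(),
        practice=bool(sidecar.get("practice", False)),
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) configuration file into a plain dict with
    optional ``session`` and ``responder`` sections."""
    import yaml

    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise LogFormatError(f"{path}: config must be a mapping")
    return data


def config_hash(config: SessionConfig, extra: dict | None = None) -> str:
    payload = {"config": config.to_dict()}
    if extra:
        payload["extra"] = extra
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_metrics_csv(path: str | Path, summaries: dict) -> Path:
    """Per-session metrics table: one row per session id."""
    rows = [{"session_id": sid, **s.to_dict()} for sid, s in summaries.items()]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")
    return Path(path)


def write_windows_csv(path: str | Path, windows: dict) -> Path:
    """Long-format per-window table: session_id, window, metric, value."""
    rows = []
    for sid, ws in windows.items():
        for w in ws:
            d = w.to_dict()
            idx = d.pop("window_index")
            for metric, value in d.items():
                rows.append({"session_id": sid, "window": idx, "metric": metric, "value": value})
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")
    return Path(path)
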