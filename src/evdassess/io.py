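"""File formats: versioned CSV tables, the line-oriented EVD log, configs.

Every CSV written by this package starts with a schema comment line, e.g.::

    # schema: evd-trials v1

Readers verify the schema name and version and refuse files they do not
understand, so silent column drift cannot corrupt an analysis.

The EVD simulator log is a UTF-8, tab-delimited, line-oriented file, one
event per line::

    <ISO-8601 timestamp with ms> \\t <participant_id> \\t <trial_id> \\t <event_label> \\t <JSON payload>

Targeting trials carry ``event_label == "evd_trial"`` with the full
trajectory/target/timing payload.  Malformed lines never abort a parse: they
are collected into a diagnostics list with their line numbers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import pandas as pd
import yaml

from .cohort import CohortConfig, SyntheticCohort
from .exceptions import DataIntegrityError

__all__ = [
    "SCHEMAS",
    "write_table",
    "read_table",
    "read_evd_trials",
    "read_smr_trials",
    "write_evd_log",
    "read_evd_log",
    "LineDiagnostic",
    "write_fixture",
    "load_config",
]

#: schema-name -> current version
SCHEMAS = {
    "evd-trials": 1,
    "smr-trials": 1,
    "evd-measures": 1,
    "smr-summaries": 1,
    "smr-difficulty": 1,
    "performance": 1,
}

EVD_TRIAL_COLUMNS = [
    "participant_id", "trial_id",
    "entry_x", "entry_y", "entry_z",
    "dir_x", "dir_y", "dir_z",
    "depth",
    "target_x", "target_y", "target_z", "target_r",
    "ideal_dir_x", "ideal_dir_y", "ideal_dir_z",
    "task_time_s",
]

LOG_EVENT_TRIAL = "evd_trial"


def write_table(df: pd.DataFrame, path, schema: str, full_precision: bool = False) -> Path:
    """Write a CSV with its schema header; 6 significant digits by default."""
    if schema not in SCHEMAS:
        raise DataIntegrityError(f"unknown schema {schema!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# schema: {schema} v{SCHEMAS[schema]}\n")
        df.to_csv(fh, index=False, float_format=None if full_precision else "%.6g")
    return path


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a schema-versioned CSV, rejecting unknown schemas/versions."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        expected = f"# schema: {schema} v{SCHEMAS[schema]}"
        if header != expected:
            raise DataIntegrityError(
                f"{path}: expected schema header {expected!r}, found {header!r}"
            )
        return pd.read_csv(fh)


def read_evd_trials(path) -> pd.DataFrame:
    df = read_table(path, "evd-trials")
    missing = [c for c in EVD_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataIntegrityError(f"{path}: missing EVD trial columns {missing}")
    return df


def read_smr_trials(path) -> pd.DataFrame:
    return read_table(path, "smr-trials")


@dataclass(frozen=True)
class LineDiagnostic:
    line_number: int
    message: str
    content: str


def write_evd_log(trials: pd.DataFrame, path, start=None, step_s: float = 1.0) -> Path:
    """Serialize a trial table as a time-stamped simulator log.

    Timestamps are synthetic but strictly non-decreasing (``step_s`` apart),
    as a real session log would be.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = start or datetime(2019, 7, 1, 9, 0, 0)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for _, row in trials.iterrows():
            payload = {c: row[c] for c in EVD_TRIAL_COLUMNS if c not in
                       ("participant_id", "trial_id")}
            payload = {k: (float(v) if isinstance(v, (int, float)) else v)
                       for k, v in payload.items()}
            stamp = t.strftime("%Y-%m-%dT%H:%M:%S.") + f"{t.microsecond // 1000:03d}"
            fh.write("\t".join([
                stamp, str(row["participant_id"]), str(row["trial_id"]),
                LOG_EVENT_TRIAL, json.dumps(payload, sort_keys=True),
            ]) + "\n")
            t = t + timedelta(seconds=step_s)
    return path


def read_evd_log(path) -> tuple[pd.DataFrame, list[LineDiagnostic]]:
    """Parse a simulator log line-by-line into a trial table.

    Returns the table of successfully parsed ``evd_trial`` events plus a list
    of per-line diagnostics for malformed records.  An empty file yields an
    empty table and a warning.  A file in which no line parses raises
    :class:`~evdassess.exceptions.DataIntegrityError`.
    """
    path = Path(path)
    rows: list[dict] = []
    diagnostics: list[LineDiagnostic] = []
    n_lines = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) != 5:
                diagnostics.append(LineDiagnostic(lineno, f"expected 5 tab-separated fields, got {len(parts)}", line))
                continue
            stamp, pid, trial_id, label, payload = parts
            try:
                datetime.strptime(stamp, "%Y-%m-%dT%H:%M:%S.%f")
            except ValueError:
                diagnostics.append(LineDiagnostic(lineno, f"unparseable timestamp {stamp!r}", line))
                continue
            if label != LOG_EVENT_TRIAL:
                continue  # other event types pass through silently
            try:
                data = json.loads(payload)
            except json.JSONDecodeError as exc:
                diagnostics.append(LineDiagnostic(lineno, f"bad payload JSON: {exc}", line))
                continue
            missing = [c for c in EVD_TRIAL_COLUMNS
                       if c not in ("participant_id", "trial_id") and c not in data]
            if missing:
                diagnostics.append(LineDiagnostic(lineno, f"payload missing fields {missing}", line))
                continue
            rows.append({"participant_id": pid, "trial_id": trial_id, **data})
    if n_lines == 0:
        warnings.warn(f"{path}: log file contains no records", stacklevel=2)
    elif not rows and diagnostics:
        raise DataIntegrityError(f"{path}: no parseable trial records ({len(diagnostics)} bad lines)")
    df = pd.DataFrame(rows, columns=EVD_TRIAL_COLUMNS)
    return df, diagnostics


def write_fixture(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write a cohort to disk in the formats the pipeline consumes.

    Emits the EVD trial CSV and log, the same/different trial CSV, the
    ground-truth abilities, and an echo of the generating config; returns the
    path of each artefact.  Tables round-trip losslessly (full precision).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "evd_trials": write_table(cohort.evd_trials, directory / "evd_trials.csv",
                                  "evd-trials", full_precision=True),
        "evd_log": write_evd_log(cohort.evd_trials, directory / "evd_trials.log"),
        "smr_trials": write_table(cohort.smr_trials, directory / "smr_trials.csv",
                                  "smr-trials", full_precision=True),
    }
    abilities = directory / "abilities.csv"
    cohort.abilities.to_csv(abilities, index=False)
    paths["abilities"] = abilities
    config_path = directory / "config.json"
    config_path.write_text(json.dumps(cohort.config.to_dict(), indent=2, sort_keys=True))
    paths["config"] = config_path
    return paths


def load_config(path) -> CohortConfig:
    """Load a cohort config from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    return CohortConfig.from_dict(data)
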