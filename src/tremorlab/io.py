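"""Plain-text I/O for trial logs, cohort tables and results.

Everything round-trips through delimited text (TSV/CSV) or JSON so that
session logs and analysis outputs stay human-readable and diffable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .cohort import CANONICAL_COLUMNS
from .staircase import ThresholdEstimate, TrialRecord

TRIAL_LOG_COLUMNS = [f.name for f in dataclasses.fields(TrialRecord)]


def write_trial_log(log: Iterable[TrialRecord], path: str | Path) -> None:
    """One TrialRecord per row, tab-separated, with header."""
    df = pd.DataFrame([dataclasses.asdict(t) for t in log])
    df.to_csv(path, sep="\t", index=False)


def read_trial_log(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    return [TrialRecord(**{k: row[k] for k in TRIAL_LOG_COLUMNS})
            for _, row in df.iterrows()]


def write_threshold(estimate: ThresholdEstimate, path: str | Path) -> None:
    payload = {
        "modality": estimate.modality,
        "threshold": estimate.threshold,
        "retained_reversals": list(estimate.retained_reversals),
        "dropped_reversals": list(estimate.dropped_reversals),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_cohort(path: str | Path, require_all: bool = False) -> pd.DataFrame:
    """Read a cohort table (comma- or tab-separated, sniffed from the
    header line) and validate the group column."""
    text_head = Path(path).open().readline()
    sep = "\t" if "\t" in text_head else ","
    df = pd.read_csv(path, sep=sep)
    if "group" not in df.columns:
        raise ValueError("cohort table must have a 'group' column")
    if df["group"].isna().any():
        raise ValueError("cohort table has missing group labels")
    if require_all:
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)
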