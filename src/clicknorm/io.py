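"""Readers and writers for the canonical trial CSV and run configuration.

Trial CSV dialect: UTF-8, comma-separated, one row per trial, header

    participant_id,trial_index,correct_side,choice,click_01,...,click_20

Click columns hold +1/-1 (left/right ear); ``correct_side`` and ``choice``
hold ``L``/``R`` (``choice`` may be empty for stimulus-only files).  Click
*times* are not stored per row; they are implied by the protocol block of
the sidecar configuration (JSON or YAML):

    {"protocol": {"n_clicks": 20, "inter_click_interval_s": 0.05,
                  "stimulus_duration_s": 1.0, "p_correct_ear": 0.55,
                  "p_correct_left": 0.5}}
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import (
    LEFT,
    RIGHT,
    ClickTrain,
    Dataset,
    TaskProtocol,
    TrialRecord,
)


class TrialFormatError(ValueError):
    """A malformed row or header in a trial CSV."""


def _click_columns(n_clicks: int) -> list[str]:
    return [f"click_{i:02d}" for i in range(1, n_clicks + 1)]


def write_trials(dataset: Dataset, path) -> None:
    """Write a dataset to the canonical trial CSV (deterministic order)."""
    cols = _click_columns(dataset.protocol.n_clicks)
    rows = []
    for t in dataset.trials:
        row = {
            "participant_id": t.participant_id,
            "trial_index": t.trial_index,
            "correct_side": t.correct_side,
            "choice": t.choice if t.choice is not None else "",
        }
        row.update({c: int(s) for c, s in zip(cols, t.train.signs)})
        rows.append(row)
    df = pd.DataFrame(rows, columns=["participant_id", "trial_index",
                                     "correct_side", "choice", *cols])
    df.to_csv(path, index=False)


def read_trials(path, protocol: TaskProtocol | None = None) -> Dataset:
    """Read a canonical trial CSV into one Dataset (all participants).

    Click times are attached from ``protocol`` (default: the standard
    20-click protocol).  Raises :class:`TrialFormatError` naming the row and
    column for any click value outside {+1, -1}.
    """
    protocol = protocol if protocol is not None else TaskProtocol()
    cols = _click_columns(protocol.n_clicks)
    df = pd.read_csv(path, keep_default_na=False)
    expected = ["participant_id", "trial_index", "correct_side", "choice", *cols]
    if list(df.columns) != expected:
        unknown = [c for c in df.columns if c not in expected]
        missing = [c for c in expected if c not in df.columns]
        raise TrialFormatError(
            f"header mismatch: unknown columns {unknown}, missing {missing}"
        )
    trials = []
    times = protocol.click_times
    for idx, row in df.iterrows():
        signs = np.empty(protocol.n_clicks, dtype=int)
        for j, c in enumerate(cols):
            v = row[c]
            try:
                v = int(v)
            except (TypeError, ValueError):
                v = 0
            if v not in (-1, 1):
                raise TrialFormatError(
                    f"row {idx + 2}: column {c} must be +1 or -1, got {row[c]!r}"
                )
            signs[j] = v
        side = str(row["correct_side"])
        if side not in (LEFT, RIGHT):
            raise TrialFormatError(
                f"row {idx + 2}: correct_side must be L or R, got {side!r}"
            )
        raw_choice = str(row["choice"]).strip()
        if raw_choice == "":
            choice = None
        elif raw_choice in (LEFT, RIGHT):
            choice = raw_choice
        else:
            raise TrialFormatError(
                f"row {idx + 2}: choice must be L, R, or empty, got {raw_choice!r}"
            )
        trials.append(
            TrialRecord(
                train=ClickTrain(times, signs, protocol.stimulus_duration),
                correct_side=side,
                choice=choice,
                participant_id=str(row["participant_id"]),
                trial_index=int(row["trial_index"]),
            )
        )
    return Dataset(trials, protocol)


def split_by_participant(dataset: Dataset) -> dict[str, Dataset]:
    """Per-participant datasets keyed by participant id (insertion order)."""
    out: dict[str, list] = {}
    for t in dataset.trials:
        out.setdefault(t.participant_id, []).append(t)
    return {pid: Dataset(ts, dataset.protocol) for pid, ts in out.items()}


# --- configuration ---------------------------------------------------------

def load_config(path) -> dict:
    """Load a JSON (.json) or YAML (.yml/.yaml) run configuration."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json":
        return json.loads(text)
    if path.suffix in (".yml", ".yaml"):
        return yaml.safe_load(text)
    raise ValueError(f"unsupported config extension {path.suffix!r}")


def protocol_from_config(config: dict) -> TaskProtocol:
    """Build a TaskProtocol from the ``protocol`` config block (if present)."""
    block = config.get("protocol", {})
    return TaskProtocol(
        n_clicks=block.get("n_clicks", 20),
        inter_click_interval=block.get("inter_click_interval_s", 0.05),
        stimulus_duration=block.get("stimulus_duration_s", 1.0),
        p_correct_ear=block.get("p_correct_ear", 0.55),
        p_correct_left=block.get("p_correct_left", 0.5),
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
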