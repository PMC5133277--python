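"""CSV and YAML interchange for trial tables, cursor samples and configs.

All tables are UTF-8 CSV with a header row and "." as the decimal
separator.  The trial table has one row per verification trial; the samples
table one row per 60-Hz cursor sample, joinable on
(participant_id, trial_index).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

TRIAL_COLUMNS = [
    "participant_id", "trial_index", "scene_id", "plausibility", "congruency",
    "order", "counterbalance", "response", "correct", "rt_s", "correct_side",
]
SAMPLE_COLUMNS = ["participant_id", "trial_index", "t_ms", "x_px", "y_px"]


def write_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    trials[[c for c in TRIAL_COLUMNS if c in trials.columns]].to_csv(path, index=False)
    return path


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "correct" in df.columns:
        df["correct"] = df["correct"].astype(bool)
    return df


def write_samples(samples: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    samples[SAMPLE_COLUMNS].to_csv(path, index=False)
    return path


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path
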