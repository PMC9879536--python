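"""CSV / YAML schemas and validation for pipeline artifacts."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .model import PARAM_NAMES, AgentParameters, to_unbounded
from .task import TRIAL_COLUMNS, RewardWalk, common_destination

__all__ = [
    "TrialTableError",
    "read_trial_table",
    "write_trial_table",
    "write_walks",
    "params_to_row",
    "write_params_table",
]


class TrialTableError(ValueError):
    """A trial table failed schema or consistency validation."""


def validate_trial_table(frame: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialTableError(f"missing trial-table columns: {missing}")
    for col in ("choice1", "state2", "choice2", "reward"):
        bad = ~frame[col].isin([0, 1])
        if bad.any():
            row = int(frame.index[bad][0])
            raise TrialTableError(f"row {row}: {col}={frame.loc[row, col]!r} not in {{0,1}}")
    bad_label = ~frame["transition"].isin(["common", "rare"])
    if bad_label.any():
        row = int(frame.index[bad_label][0])
        raise TrialTableError(f"row {row}: unknown transition label")
    expected_common = frame["state2"].to_numpy() == np.vectorize(common_destination)(
        frame["choice1"].to_numpy()
    )
    labelled_common = (frame["transition"] == "common").to_numpy()
    bad = expected_common != labelled_common
    if bad.any():
        row = int(frame.index[bad][0])
        raise TrialTableError(
            f"row {row}: transition label contradicts the common mapping "
            f"(choice1={frame.loc[row, 'choice1']}, state2={frame.loc[row, 'state2']})"
        )


def read_trial_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a trial-table CSV (schema of `twostep.task.TRIAL_COLUMNS`)."""
    frame = pd.read_csv(path, dtype={"subject_id": str})
    validate_trial_table(frame)
    return frame[TRIAL_COLUMNS]


def write_trial_table(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    validate_trial_table(frame)
    frame[TRIAL_COLUMNS].to_csv(path, index=False)


def write_walks(walks: list[RewardWalk], path: Union[str, Path]) -> None:
    """Sidecar CSV of latent reward probabilities (p00, p01, p10, p11)."""
    rows = []
    for sess, walk in enumerate(walks, start=1):
        for t in range(walk.n_trials):
            rows.append({
                "session": sess, "trial": t + 1,
                "p00": repr(walk.probs[t, 0]), "p01": repr(walk.probs[t, 1]),
                "p10": repr(walk.probs[t, 2]), "p11": repr(walk.probs[t, 3]),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def params_to_row(subject_id: str, params: AgentParameters) -> dict:
    """One CSV row with the 7 native and 7 unbounded parameter values."""
    row: dict = {"subject_id": subject_id}
    native = params.as_array()
    unbounded = to_unbounded(params)
    for k, name in enumerate(PARAM_NAMES):
        row[name] = native[k]
    for k, name in enumerate(PARAM_NAMES):
        row[f"unbounded_{name}"] = unbounded[k]
    return row


def write_params_table(rows: list[dict], path: Union[str, Path]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def dataclass_to_yaml(obj, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(obj), fh, sort_keys=False)
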