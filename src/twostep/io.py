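"""Trial-log readers and result writers.

Canonical trial schema (CSV, one row per trial): ``subject_id, trial,
choice1 (0/1), state2 (1/2), choice2 (0/1), outcome (0/1)`` with an
optional ``transition`` column (1 common / 0 rare) that is recomputed
from (choice1, state2) against the configured true structure when
absent.  External datasets with different headers are supported through
a column-mapping dict.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .fitting import FitResult
from .task import SessionData, TaskConfig, TrialRecord, transition_label

__all__ = ["read_trials", "write_trials", "write_fit_results", "read_fit_results"]

CANONICAL_COLUMNS = ("subject_id", "trial", "choice1", "state2", "choice2", "outcome")

_DOMAINS = {"choice1": (0, 1), "state2": (1, 2), "choice2": (0, 1), "outcome": (0, 1)}


def read_trials(
    path: str | Path,
    config: Optional[TaskConfig] = None,
    column_map: Optional[dict[str, str]] = None,
) -> list[SessionData]:
    """Read per-subject sessions from a delimited trial log.

    ``column_map`` maps canonical names to the file's actual headers,
    e.g. ``{"choice1": "stim_1_chosen"}``.  Raises ``ValueError`` naming
    the offending row on any schema violation.
    """
    config = config or TaskConfig()
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    for col, dom in _DOMAINS.items():
        bad = ~df[col].isin(dom)
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based + header line
            raise ValueError(f"invalid {col} value {df.loc[bad, col].iloc[0]!r} at file row {row}")
    sessions = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("trial")
        trials = []
        for i, (_, row) in enumerate(grp.iterrows(), start=1):
            if int(row["trial"]) != i:
                raise ValueError(f"subject {sid}: trial indices not contiguous at {row['trial']}")
            a1, s2 = int(row["choice1"]), int(row["state2"])
            trans = (
                int(row["transition"])
                if "transition" in grp.columns and not pd.isna(row.get("transition"))
                else transition_label(config, a1, s2)
            )
            trials.append(
                TrialRecord(t=i, a1=a1, s2=s2, transition=trans, a2=int(row["choice2"]), o=int(row["outcome"]))
            )
        cfg = dataclasses.replace(config, n_trials=len(trials))
        sessions.append(SessionData(config=cfg, trials=trials, subject_id=str(sid)))
    return sessions


def write_trials(sessions: Sequence[SessionData], path: str | Path) -> None:
    """Write sessions to the canonical CSV schema."""
    rows = []
    for ses in sessions:
        for tr in ses.trials:
            rows.append({
                "subject_id": ses.subject_id, "trial": tr.t, "choice1": tr.a1,
                "state2": tr.s2, "choice2": tr.a2, "outcome": tr.o,
                "transition": tr.transition,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fit_results(fits: Sequence[FitResult], path: str | Path) -> None:
    """Lossless JSON dump of fit results."""
    payload = [dataclasses.asdict(fr) for fr in fits]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fit_results(path: str | Path) -> list[FitResult]:
    payload = json.loads(Path(path).read_text())
    return [FitResult(**item) for item in payload]
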