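"""Tidy CSV / JSON input-output with embedded provenance.

Every artifact written here carries the fully resolved configuration as a
leading comment block (CSV) or a ``"provenance"`` key (JSON), so a result
file alone identifies the seed, preset, and integration dialect that
produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .protocol import ParticipantResult

__all__ = [
    "trials_to_frame",
    "write_trials",
    "read_trials",
    "read_provenance",
    "write_json",
]

TRIAL_CSV_COLUMNS = [
    "participant", "age_group", "condition", "trial_label", "laterality",
    "selected_hand", "m_P", "m_NP", "u_P_final", "u_NP_final", "seed",
]

_PROVENANCE_PREFIX = "# provenance: "


def trials_to_frame(results: list[ParticipantResult]) -> pd.DataFrame:
    """Flatten participant results to one row per trial."""
    rows = []
    for r in results:
        for cond, records in r.trials.items():
            for rec in records:
                rows.append(
                    {
                        "participant": r.participant,
                        "age_group": r.age_group,
                        "condition": cond,
                        "trial_label": rec.spec.label,
                        "laterality": rec.spec.laterality,
                        "selected_hand": rec.outcome.selected,
                        "m_P": rec.m_p,
                        "m_NP": rec.m_np,
                        "u_P_final": rec.outcome.final_state.u_p,
                        "u_NP_final": rec.outcome.final_state.u_np,
                        "seed": r.seed,
                    }
                )
    return pd.DataFrame(rows, columns=TRIAL_CSV_COLUMNS)


def write_trials(frame: pd.DataFrame, path: str | Path,
                 provenance: dict | None = None) -> None:
    """Write a trial-level CSV with a provenance comment header."""
    path = Path(path)
    with path.open("w") as fh:
        if provenance is not None:
            fh.write(_PROVENANCE_PREFIX + json.dumps(provenance, sort_keys=True) + "\n")
        frame.to_csv(fh, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial-level CSV written by :func:`write_trials`."""
    return pd.read_csv(path, comment="#")


def read_provenance(path: str | Path) -> dict | None:
    """Recover the provenance block from a CSV, if present."""
    with Path(path).open() as fh:
        first = fh.readline()
    if first.startswith(_PROVENANCE_PREFIX):
        return json.loads(first[len(_PROVENANCE_PREFIX):])
    return None


def write_json(obj: dict, path: str | Path, provenance: dict | None = None) -> None:
    """Write a JSON artifact, embedding provenance when given."""
    payload = dict(obj)
    if provenance is not None:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
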