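"""Serialization of set catalogs and tabular results."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import SubjectSet


def sets_to_json(sets: list[SubjectSet], path: str | Path) -> None:
    payload = [
        {
            "label": s.label,
            "subject_ids": s.subject_ids,
            "feature_ids": s.feature_ids,
            "membership_scores": {k: round(v, 8) for k, v in s.membership_scores.items()},
            "cohesion": round(float(s.cohesion), 8) if s.cohesion == s.cohesion else None,
            "feature_values": {k: round(v, 8) for k, v in s.feature_values.items()},
        }
        for s in sets
    ]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def sets_from_json(path: str | Path) -> list[SubjectSet]:
    payload = json.loads(Path(path).read_text())
    out = []
    for d in payload:
        out.append(
            SubjectSet(
                label=d["label"],
                subject_ids=d["subject_ids"],
                feature_ids=d["feature_ids"],
                membership_scores=d.get("membership_scores", {}),
                cohesion=float("nan") if d.get("cohesion") is None else d["cohesion"],
                feature_values=d.get("feature_values", {}),
            )
        )
    return out


def catalog_frame(sets: list[SubjectSet]) -> pd.DataFrame:
    """One row per set: label, sizes, cohesion."""
    return pd.DataFrame(
        {
            "label": [s.label for s in sets],
            "n_subjects": [len(s.subject_ids) for s in sets],
            "n_features": [len(s.feature_ids) for s in sets],
            "cohesion": [s.cohesion for s in sets],
        }
    )


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV output (fixed float format, no index)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
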