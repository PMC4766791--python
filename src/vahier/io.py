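"""CSV readers/writers for VA records and reference labels.

Record CSV layout: first column ``death_id``, then one column per symptom id.
Binary responses are coded ``Y`` / ``N`` / ``DK`` / blank (missing); numeric
columns hold plain numbers. An optional column-mapping JSON object translates
arbitrary questionnaire headers to internal symptom ids.

Reference-label CSV layout: ``death_id`` plus a pipe-separated ``causes``
column (co-morbid sets allowed).
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import pandas as pd

from .errors import UsageError
from .reference_harmonizer import ReferenceLabel
from .rules_engine import RuleSet, VARecord

_RESPONSE_CODES = {
    "Y": "yes", "YES": "yes", "1": "yes",
    "N": "no", "NO": "no", "0": "no",
    "DK": "dont_know", "DONT_KNOW": "dont_know",
    "": "missing", "NA": "missing", "MISSING": "missing",
}
_CODE_FOR = {"yes": "Y", "no": "N", "dont_know": "DK", "missing": ""}


def _decode_response(raw, column: str) -> str:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return "missing"
    key = str(raw).strip().upper()
    if key not in _RESPONSE_CODES:
        raise UsageError(f"column {column!r}: unrecognized response code {raw!r}")
    return _RESPONSE_CODES[key]


def read_records_csv(
    path, ruleset: RuleSet, *, column_map: Mapping[str, str] | str | Path | None = None
) -> list[VARecord]:
    """Load VA records, using ``ruleset``'s symptom dictionary to type columns.

    ``column_map`` (a mapping or a path to a JSON object) renames CSV headers
    to internal symptom ids before typing; unmapped columns keep their header.
    Columns not in the symptom dictionary are ignored.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "death_id":
        raise UsageError("first column must be 'death_id'")
    if isinstance(column_map, (str, Path)):
        column_map = json.loads(Path(column_map).read_text())
    if column_map:
        df = df.rename(columns=dict(column_map))
    if df["death_id"].duplicated().any():
        dupes = df.loc[df["death_id"].duplicated(), "death_id"].tolist()
        raise UsageError(f"duplicate death_id values: {dupes[:5]}")

    dictionary = ruleset.symptom_dictionary
    records = []
    for row in df.itertuples(index=False):
        data = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        responses: dict[str, str] = {}
        numerics: dict[str, float] = {}
        for col, raw in zip(df.columns, row):
            if col == "death_id" or col not in dictionary:
                continue
            if dictionary[col].kind == "binary":
                responses[col] = _decode_response(raw, col)
            else:
                text = str(raw).strip()
                if text not in ("", "NA"):
                    numerics[col] = float(text)
        records.append(
            VARecord(
                death_id=str(data["death_id"]),
                age_group=ruleset.age_group,
                responses=responses,
                numerics=numerics,
            )
        )
    return records


def write_records_csv(path, records: Sequence[VARecord], ruleset: RuleSet) -> None:
    """Write records with one column per dictionary symptom, in dictionary order."""
    columns = list(ruleset.symptom_dictionary)
    rows = []
    for record in records:
        row: dict[str, object] = {"death_id": record.death_id}
        for sid in columns:
            if ruleset.symptom_dictionary[sid].kind == "binary":
                row[sid] = _CODE_FOR[record.responses.get(sid, "missing")]
            else:
                value = record.numerics.get(sid)
                row[sid] = "" if value is None else value
        rows.append(row)
    pd.DataFrame(rows, columns=["death_id", *columns]).to_csv(path, index=False)


def read_reference_labels_csv(path, age_group: str) -> list[ReferenceLabel]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for required in ("death_id", "causes"):
        if required not in df.columns:
            raise UsageError(f"labels CSV must have a {required!r} column")
    labels = []
    for death_id, causes in zip(df["death_id"], df["causes"]):
        cause_set = frozenset(c.strip() for c in str(causes).split("|") if c.strip())
        labels.append(ReferenceLabel(str(death_id), cause_set, age_group))
    return labels


def write_reference_labels_csv(path, labels: Sequence[ReferenceLabel]) -> None:
    df = pd.DataFrame(
        {
            "death_id": [lab.death_id for lab in labels],
            "causes": ["|".join(sorted(lab.causes)) for lab in labels],
        }
    )
    df.to_csv(path, index=False)


def write_assignments_csv(path, assignments: Mapping[str, str]) -> None:
    pd.DataFrame(
        {"death_id": list(assignments), "cause": list(assignments.values())}
    ).to_csv(path, index=False)
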