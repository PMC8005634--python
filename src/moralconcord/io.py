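"""Delimited-text I/O for survey responses, participants, and score tables.

Responses are long format, one row per (participant, item): the participant's
own answer, 0/1 tick flags per concern for each side, catch-all flags, and the
1-based index of the argument wording shown per concern. TSV is the default;
comma is selectable. Column order is deterministic so regression tests can be
bit-exact.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd

from .records import (
    POSITIONS,
    ParticipantRecord,
    ResponseRecord,
    validate_responses,
)
from .taxonomy import ConcernTaxonomy

_PARTICIPANT_COLUMNS = [
    "participant_id",
    "sex",
    "age",
    "ideology",
    "ideology_scale",
    "education",
    "verbal_ability",
    "country",
    "population_label",
]

_INT_ATTRS = {"age", "ideology_scale", "verbal_ability"}


def _sep(fmt: str) -> str:
    return {"tsv": "\t", "csv": ","}[fmt]


def response_columns(taxonomy: ConcernTaxonomy) -> list[str]:
    cols = ["participant_id", "item_id", "own_answer"]
    cols += [f"own_{c}" for c in taxonomy.concerns]
    cols += [f"other_{c}" for c in taxonomy.concerns]
    cols += ["other_reason_own", "other_reason_other"]
    cols += [f"shown_{c}" for c in taxonomy.concerns]
    return cols


def write_responses(
    path: str | Path,
    responses: Sequence[ResponseRecord],
    taxonomy: ConcernTaxonomy,
    fmt: str = "tsv",
) -> None:
    rows = []
    for r in responses:
        row: dict[str, object] = {
            "participant_id": r.participant_id,
            "item_id": r.item_id,
            "own_answer": r.own_answer,
            "other_reason_own": int(r.other_reason_own),
            "other_reason_other": int(r.other_reason_other),
        }
        for c in taxonomy.concerns:
            row[f"own_{c}"] = int(c in r.own_side_ticks)
            row[f"other_{c}"] = int(c in r.other_side_ticks)
            row[f"shown_{c}"] = taxonomy.argument_index(c, r.shown_arguments[c])
        rows.append(row)
    df = pd.DataFrame(rows, columns=response_columns(taxonomy))
    df.to_csv(path, sep=_sep(fmt), index=False)


def read_responses(
    path: str | Path, taxonomy: ConcernTaxonomy, fmt: str = "tsv"
) -> list[ResponseRecord]:
    """Read and validate a long-format responses file.

    Raises ``ValueError`` with the offending row number for unknown concern
    columns, bad positions, out-of-range argument indices, or duplicate
    (participant, item) pairs.
    """
    df = pd.read_csv(path, sep=_sep(fmt), dtype=str)
    required = response_columns(taxonomy)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra_ticks = [
        c
        for c in df.columns
        if (c.startswith("own_") or c.startswith("other_"))
        and c not in required
        and c not in ("other_reason_own", "other_reason_other")
    ]
    if extra_ticks:
        labels = sorted({c.split("_", 1)[1] for c in extra_ticks})
        raise ValueError(f"{path}: tick column(s) for unknown concern label(s) {labels}")

    responses: list[ResponseRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        d = row._asdict()
        own_answer = d["own_answer"]
        if own_answer not in POSITIONS:
            raise ValueError(f"{path} row {i}: own_answer {own_answer!r} not in {POSITIONS}")
        shown = {}
        for c in taxonomy.concerns:
            idx = int(d[f"shown_{c}"])
            if not 1 <= idx <= len(taxonomy.arguments[c]):
                raise ValueError(f"{path} row {i}: shown_{c} index {idx} out of range")
            shown[c] = taxonomy.arguments[c][idx - 1]
        responses.append(
            ResponseRecord(
                participant_id=str(d["participant_id"]),
                item_id=str(d["item_id"]),
                own_answer=own_answer,
                shown_arguments=shown,
                own_side_ticks=frozenset(
                    c for c in taxonomy.concerns if int(d[f"own_{c}"]) == 1
                ),
                other_side_ticks=frozenset(
                    c for c in taxonomy.concerns if int(d[f"other_{c}"]) == 1
                ),
                other_reason_own=bool(int(d["other_reason_own"])),
                other_reason_other=bool(int(d["other_reason_other"])),
            )
        )
    try:
        validate_responses(responses, taxonomy)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return responses


def write_participants(path: str | Path, participants: Sequence[ParticipantRecord], fmt: str = "tsv") -> None:
    rows = []
    for p in participants:
        rows.append({col: getattr(p, col) for col in _PARTICIPANT_COLUMNS})
    df = pd.DataFrame(rows, columns=_PARTICIPANT_COLUMNS)
    df.to_csv(path, sep=_sep(fmt), index=False)


def read_participants(path: str | Path, fmt: str = "tsv") -> list[ParticipantRecord]:
    df = pd.read_csv(path, sep=_sep(fmt), dtype=str, keep_default_na=False)
    missing = [c for c in _PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    out: list[ParticipantRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        kwargs: dict[str, object] = {}
        for col in _PARTICIPANT_COLUMNS:
            val = d[col]
            if val == "" or val is None:
                val = "" if col == "population_label" else None
            elif col in _INT_ATTRS:
                val = int(float(val))
            kwargs[col] = val
        pid = kwargs["participant_id"]
        if pid in seen:
            raise ValueError(f"{path} row {i}: duplicate participant_id {pid!r}")
        seen.add(str(pid))
        out.append(ParticipantRecord(**kwargs))  # type: ignore[arg-type]
    return out


def read_study(
    responses_path: str | Path,
    participants_path: str | Path,
    taxonomy: ConcernTaxonomy,
    fmt: str = "tsv",
) -> tuple[list[ParticipantRecord], list[ResponseRecord]]:
    """Read a full study (participants + responses), cross-validating IDs."""
    participants = read_participants(participants_path, fmt=fmt)
    responses = read_responses(responses_path, taxonomy, fmt=fmt)
    known = {p.participant_id for p in participants}
    orphans = sorted({r.participant_id for r in responses} - known)
    if orphans:
        warnings.warn(
            f"{len(orphans)} respondent id(s) in {responses_path} missing from "
            f"{participants_path} (e.g. {orphans[:3]})",
            stacklevel=2,
        )
    return participants, responses
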