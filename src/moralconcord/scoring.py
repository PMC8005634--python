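"""Argument applicability scores and paired score vectors.

The applicability score of a concern for an opinion is the proportion of a
population's respondents to the item who ticked that concern's argument as
applying to that opinion — pooling own-side and other-side judgments, since
the score is defined over *individuals*, not supporters. Counts are kept
exact (integer ticks over integer judgments) until export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .records import Judgment, OpinionId, ParticipantRecord


class CellCount(NamedTuple):
    """Tick and judgment tallies for one (opinion, concern) cell."""

    ticks: int
    judgments: int

    @property
    def score(self) -> Fraction:
        return Fraction(self.ticks, self.judgments)


@dataclass
class ScoreTable:
    """Applicability scores for one population: (opinion, concern) -> counts."""

    population_label: str
    cells: dict[tuple[OpinionId, str], CellCount] = field(default_factory=dict)

    def score(self, opinion: OpinionId, concern: str) -> Fraction:
        return self.cells[(opinion, concern)].score

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def opinions(self) -> list[OpinionId]:
        return sorted({op for op, _ in self.cells})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "item_id": op.item_id,
                "position": op.position,
                "concern": concern,
                "ticks": cc.ticks,
                "judgments": cc.judgments,
                "score": float(cc.score),
            }
            for (op, concern), cc in sorted(self.cells.items())
        ]
        return pd.DataFrame(
            rows, columns=["item_id", "position", "concern", "ticks", "judgments", "score"]
        )

    def write(self, path: str | Path, fmt: str = "tsv") -> None:
        df = self.to_frame()
        df["score"] = df["score"].map(lambda s: f"{s:.6f}")
        df.to_csv(path, sep={"tsv": "\t", "csv": ","}[fmt], index=False)

    @classmethod
    def read(cls, path: str | Path, population_label: str = "", fmt: str = "tsv") -> "ScoreTable":
        df = pd.read_csv(path, sep={"tsv": "\t", "csv": ","}[fmt])
        cells = {
            (OpinionId(str(r.item_id), str(r.position)), str(r.concern)): CellCount(
                int(r.ticks), int(r.judgments)
            )
            for r in df.itertuples(index=False)
        }
        return cls(population_label=population_label, cells=cells)


def applicability_scores(
    judgments: Iterable[Judgment],
    participants: Sequence[ParticipantRecord] | None = None,
    participant_filter: Callable[[ParticipantRecord], bool] | None = None,
    min_judgments: int = 1,
    perspective: str = "both",
    population_label: str = "",
) -> ScoreTable:
    """Tally applicability scores over participants passing a filter.

    Each participant contributes exactly one judgment per (opinion, concern)
    cell they responded to, regardless of perspective; ``perspective`` may be
    ``"own"`` or ``"other"`` to restrict to one side (used by the
    opinion-based analysis). Cells with fewer than ``min_judgments``
    judgments are omitted.
    """
    if perspective not in ("both", "own", "other"):
        raise ValueError(f"perspective must be both|own|other, got {perspective!r}")
    allowed: set[str] | None = None
    if participant_filter is not None:
        if participants is None:
            raise ValueError("participant_filter requires the participants list")
        allowed = {p.participant_id for p in participants if participant_filter(p)}
        if not allowed:
            warnings.warn(
                f"participant filter for {population_label!r} matched no participants",
                stacklevel=2,
            )
    ticks: dict[tuple[OpinionId, str], int] = {}
    totals: dict[tuple[OpinionId, str], int] = {}
    for j in judgments:
        if allowed is not None and j.participant_id not in allowed:
            continue
        if perspective != "both" and j.perspective != perspective:
            continue
        key = (j.opinion, j.concern)
        totals[key] = totals.get(key, 0) + 1
        if j.applies:
            ticks[key] = ticks.get(key, 0) + 1
    cells = {
        key: CellCount(ticks.get(key, 0), n)
        for key, n in totals.items()
        if n >= min_judgments
    }
    return ScoreTable(population_label=population_label, cells=cells)


class PairedCell(NamedTuple):
    opinion: OpinionId
    concern: str
    score_1: float
    score_2: float
    n_1: int
    n_2: int


@dataclass
class PairedScores:
    """Two populations' scores aligned on their common populated cells."""

    entries: list[PairedCell]
    label_1: str = ""
    label_2: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def score_1(self) -> np.ndarray:
        return np.array([e.score_1 for e in self.entries], dtype=float)

    @property
    def score_2(self) -> np.ndarray:
        return np.array([e.score_2 for e in self.entries], dtype=float)

    @property
    def concerns(self) -> list[str]:
        return sorted({e.concern for e in self.entries})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "item_id": e.opinion.item_id,
                    "position": e.opinion.position,
                    "concern": e.concern,
                    "score_1": e.score_1,
                    "score_2": e.score_2,
                    "n_1": e.n_1,
                    "n_2": e.n_2,
                }
                for e in self.entries
            ],
            columns=["item_id", "position", "concern", "score_1", "score_2", "n_1", "n_2"],
        )


def pair_scores(table_1: ScoreTable, table_2: ScoreTable) -> PairedScores:
    """Align two score tables on the intersection of their populated cells.

    Pairwise-complete: a cell enters only if both tables observed it. Entries
    come out in deterministic (item_id, position, concern) order.
    """
    common = sorted(set(table_1.cells) & set(table_2.cells))
    if not common:
        warnings.warn(
            f"score tables {table_1.population_label!r} and "
            f"{table_2.population_label!r} share no populated cells",
            stacklevel=2,
        )
    entries = []
    for op, concern in common:
        c1 = table_1.cells[(op, concern)]
        c2 = table_2.cells[(op, concern)]
        entries.append(
            PairedCell(op, concern, float(c1.score), float(c2.score), c1.judgments, c2.judgments)
        )
    return PairedScores(
        entries=entries,
        label_1=table_1.population_label,
        label_2=table_2.population_label,
    )
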