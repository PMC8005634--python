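"""End-to-end study orchestration: subgroup construction, per-comparison
agreement + resampling null, opinion-based splits, and report generation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import AgreementResult, agreement_result, boxplot_summary
from .io import write_participants, write_responses
from .nulls import NullResult, random_split_null, stratified_split_null
from .records import (
    AFFIRMATIVE,
    Judgment,
    NEGATIVE,
    OpinionId,
    ParticipantRecord,
    ResponseRecord,
    derive_judgments,
    opposite,
)
from .scoring import PairedCell, PairedScores, applicability_scores, pair_scores
from .simulate import SimConfig, simulate_study, write_truth
from .taxonomy import ConcernTaxonomy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """A rule that partitions eligible participants into two subsamples.

    Supported attributes: ``sex`` (female/male), ``age`` (sample-median split,
    median-valued respondents on the younger side), ``ideology`` (binary
    liberal/conservative), ``ideology_scale`` (left 0-3 vs right 7-10 by
    default, the middle excluded), ``education`` (higher/lower),
    ``verbal_ability`` (>= threshold vs below, default 8), ``country`` (a
    named pair), ``population_label`` (a named pair). Participants missing
    the attribute are excluded.
    """

    attribute: str
    label: str = ""
    left_max: int = 3  # ideology_scale: left wing is 0..left_max
    right_min: int = 7  # ideology_scale: right wing is right_min..10
    verbal_threshold: int = 8
    pair: tuple[str, str] | None = None  # for country / population_label

    @property
    def name(self) -> str:
        return self.label or self.attribute


def demographic_split(
    participants: Sequence[ParticipantRecord], spec: SplitSpec
) -> tuple[list[ParticipantRecord], list[ParticipantRecord]]:
    """Apply a SplitSpec, returning the two disjoint participant sets."""
    attr = spec.attribute
    side1: list[ParticipantRecord] = []
    side2: list[ParticipantRecord] = []
    if attr == "age":
        ages = [p.age for p in participants if p.age is not None]
        if not ages:
            raise ValueError("age split: no participant has an age")
        median = float(np.median(ages))
        for p in participants:
            if p.age is None:
                continue
            (side1 if p.age <= median else side2).append(p)
    elif attr in ("sex", "ideology", "education"):
        first = {"sex": "female", "ideology": "liberal", "education": "higher"}[attr]
        second = {"sex": "male", "ideology": "conservative", "education": "lower"}[attr]
        for p in participants:
            val = getattr(p, attr)
            if val == first:
                side1.append(p)
            elif val == second:
                side2.append(p)
    elif attr == "ideology_scale":
        for p in participants:
            if p.ideology_scale is None:
                continue
            if p.ideology_scale <= spec.left_max:
                side1.append(p)
            elif p.ideology_scale >= spec.right_min:
                side2.append(p)
    elif attr == "verbal_ability":
        for p in participants:
            if p.verbal_ability is None:
                continue
            (side1 if p.verbal_ability >= spec.verbal_threshold else side2).append(p)
    elif attr in ("country", "population_label"):
        if spec.pair is None:
            raise ValueError(f"{attr} split requires a pair of labels")
        a, b = spec.pair
        for p in participants:
            val = getattr(p, attr)
            if val == a:
                side1.append(p)
            elif val == b:
                side2.append(p)
    else:
        raise ValueError(f"unknown split attribute {attr!r}")
    if len(side1) < 2 or len(side2) < 2:
        raise ValueError(
            f"split {spec.name!r}: a side has fewer than 2 participants "
            f"({len(side1)} vs {len(side2)})"
        )
    logger.info("split %s: %d vs %d participants", spec.name, len(side1), len(side2))
    return side1, side2


@dataclass
class ComparisonRow:
    """One line of a study report: a comparison, its agreement, and its null."""

    label: str
    n_1: int
    n_2: int
    agreement: AgreementResult
    null: NullResult
    paired: PairedScores | None = None

    def to_dict(self) -> dict:
        a, nl = self.agreement, self.null
        return {
            "comparison": self.label,
            "n_1": self.n_1,
            "n_2": self.n_2,
            "n_pairs": a.n_pairs,
            "ccc": a.ccc,
            "ccc_ci_lower": a.ccc_ci_lower,
            "ccc_ci_upper": a.ccc_ci_upper,
            "pearson": a.pearson,
            "expected_ccc": nl.expected_ccc,
            "p_value": nl.p_value,
            "n_splits": nl.n_splits,
        }


@dataclass
class StudyReport:
    rows: list[ComparisonRow]
    boxplot: object
    scatter: dict[str, PairedScores]
    config_echo: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.rows])

    def write(self, out_dir: str | Path, fmt: str = "tsv") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sep = {"tsv": "\t", "csv": ","}[fmt]
        df = self.to_frame()
        for col in ("ccc", "ccc_ci_lower", "ccc_ci_upper", "pearson", "expected_ccc", "p_value"):
            df[col] = df[col].map(lambda v: f"{v:.6f}" if pd.notna(v) else "")
        df.to_csv(out / f"report.{fmt}", sep=sep, index=False)
        for label, paired in self.scatter.items():
            paired.to_frame().to_csv(out / f"scatter_{label}.{fmt}", sep=sep, index=False)
        (out / "config_echo.txt").write_text(self.config_echo + "\n", encoding="utf-8")


def compare_split(
    participants: Sequence[ParticipantRecord],
    judgments: Sequence[Judgment],
    spec: SplitSpec,
    n_splits: int = 1000,
    seed: int | None = None,
    min_judgments: int = 1,
) -> ComparisonRow:
    """Agreement + random-split null for one demographic/population comparison."""
    side1, side2 = demographic_split(participants, spec)
    ids1 = {p.participant_id for p in side1}
    ids2 = {p.participant_id for p in side2}
    t1 = applicability_scores(
        judgments, participants, lambda p: p.participant_id in ids1,
        min_judgments=min_judgments, population_label=f"{spec.name}:1",
    )
    t2 = applicability_scores(
        judgments, participants, lambda p: p.participant_id in ids2,
        min_judgments=min_judgments, population_label=f"{spec.name}:2",
    )
    paired = pair_scores(t1, t2)
    agg = agreement_result(paired)
    pooled = side1 + side2
    pooled_ids = {p.participant_id for p in pooled}
    null = random_split_null(
        pooled,
        [j for j in judgments if j.participant_id in pooled_ids],
        split_sizes=(len(side1), len(side2)),
        n_splits=n_splits,
        seed=seed,
        min_judgments=min_judgments,
        observed_ccc=agg.ccc,
    )
    return ComparisonRow(spec.name, len(side1), len(side2), agg, null, paired)


def opinion_split_paired(
    responses: Sequence[ResponseRecord],
    judgments: Sequence[Judgment],
    min_holders: int = 5,
) -> tuple[PairedScores, dict[str, tuple[list[str], list[str]]], list[OpinionId]]:
    """Supporter-vs-opponent paired scores and the per-item strata.

    For each retained opinion P, score vector 1 is built from P's holders'
    own-side judgments of P, and score vector 2 from the opposite holders'
    other-side judgments of P. Opinions where either side has fewer than
    ``min_holders`` holders are dropped (and reported).
    """
    holders: dict[OpinionId, list[str]] = {}
    for r in responses:
        holders.setdefault(OpinionId(r.item_id, r.own_answer), []).append(r.participant_id)
    item_ids = sorted({r.item_id for r in responses})
    own_table = applicability_scores(judgments, perspective="own", population_label="supporters")
    other_table = applicability_scores(judgments, perspective="other", population_label="opponents")

    entries: list[PairedCell] = []
    strata: dict[str, tuple[list[str], list[str]]] = {}
    dropped: list[OpinionId] = []
    concerns = sorted({j.concern for j in judgments})
    for item_id in item_ids:
        aff = OpinionId(item_id, AFFIRMATIVE)
        neg = OpinionId(item_id, NEGATIVE)
        n_aff = len(holders.get(aff, []))
        n_neg = len(holders.get(neg, []))
        if min(n_aff, n_neg) < min_holders:
            for op, n_own in ((aff, n_aff), (neg, n_neg)):
                dropped.append(op)
            continue
        strata[item_id] = (holders[aff], holders[neg])
        for op in (aff, neg):
            opp = OpinionId(item_id, opposite(op.position))
            for c in concerns:
                c1 = own_table.cells[(op, c)]
                c2 = other_table.cells[(op, c)]
                entries.append(
                    PairedCell(op, c, float(c1.score), float(c2.score), c1.judgments, c2.judgments)
                )
    if dropped:
        logger.info(
            "opinion split: dropped %d opinion(s) below min_holders=%d: %s",
            len(dropped), min_holders, [f"{o.item_id}:{o.position}" for o in dropped],
        )
    if not entries:
        raise ValueError(f"no opinions retained at min_holders={min_holders}")
    paired = PairedScores(entries=entries, label_1="supporters", label_2="opponents")
    return paired, strata, dropped


def opinion_split_analysis(
    responses: Sequence[ResponseRecord],
    participants: Sequence[ParticipantRecord],
    min_holders: int = 5,
    n_splits: int = 1000,
    seed: int | None = None,
    taxonomy: ConcernTaxonomy | None = None,
) -> tuple[AgreementResult, NullResult, int]:
    """Do supporters and opponents of each opinion agree on its arguments?

    Compares the applicability scores implied by supporters' own-side ticks
    with those implied by opponents' other-side ticks, over all retained
    (opinion, concern) cells, with an item-stratified random-split null.
    Returns (agreement, null, number of opinions used).
    """
    if taxonomy is None:
        raise ValueError("taxonomy is required to derive judgments")
    judgments = derive_judgments(responses, taxonomy)
    paired, strata, _ = opinion_split_paired(responses, judgments, min_holders=min_holders)
    agg = agreement_result(paired)
    retained_items = set(strata)
    null = stratified_split_null(
        [j for j in judgments if j.opinion.item_id in retained_items],
        strata,
        n_splits=n_splits,
        seed=seed,
        observed_ccc=agg.ccc,
    )
    n_opinions = 2 * len(strata)
    return agg, null, n_opinions


DEFAULT_COMPARISONS = (
    SplitSpec("sex", label="women_vs_men"),
    SplitSpec("age", label="younger_vs_older"),
    SplitSpec("ideology", label="liberals_vs_conservatives"),
    SplitSpec("education", label="higher_vs_lower_education"),
    SplitSpec("verbal_ability", label="higher_vs_lower_verbal"),
)


def run_study(
    sim_config: SimConfig | None = None,
    data: tuple[Sequence[ParticipantRecord], Sequence[ResponseRecord]] | None = None,
    taxonomy: ConcernTaxonomy | None = None,
    comparisons: Sequence[SplitSpec] = DEFAULT_COMPARISONS,
    n_splits: int = 1000,
    seed: int = 0,
    min_judgments: int = 1,
    out_dir: str | Path | None = None,
    fmt: str = "tsv",
    write_sim_data: bool = False,
) -> StudyReport:
    """Full pipeline: simulate or load data, derive judgments, run every
    comparison's agreement + null, and assemble (optionally write) the report.

    Per-comparison null seeds are spawned deterministically from ``seed``, so
    a rerun with the same inputs is byte-identical.
    """
    if (sim_config is None) == (data is None):
        raise ValueError("provide exactly one of sim_config or data")
    if sim_config is not None:
        taxonomy = sim_config.taxonomy
        participants, responses, truth = simulate_study(sim_config)
    else:
        if taxonomy is None:
            raise ValueError("taxonomy is required when passing data")
        participants, responses = list(data[0]), list(data[1])
        truth = None
    judgments = derive_judgments(responses, taxonomy)
    logger.info(
        "study: %d participants, %d responses, %d judgments",
        len(participants), len(responses), len(judgments),
    )
    comparison_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(len(comparisons))
    ]
    rows: list[ComparisonRow] = []
    scatter: dict[str, PairedScores] = {}
    for spec, cseed in zip(comparisons, comparison_seeds):
        row = compare_split(
            participants, judgments, spec,
            n_splits=n_splits, seed=cseed, min_judgments=min_judgments,
        )
        rows.append(row)
        scatter[spec.name] = row.paired
    full_table = applicability_scores(judgments, population_label="full_sample")
    box = boxplot_summary(full_table, concern_order=taxonomy.concerns)
    report = StudyReport(
        rows=rows,
        boxplot=box,
        scatter=scatter,
        config_echo=repr(sim_config) if sim_config is not None else f"data: external, seed={seed}",
        seed=seed,
    )
    if out_dir is not None:
        report.write(out_dir, fmt=fmt)
        if write_sim_data and sim_config is not None:
            out = Path(out_dir)
            write_participants(out / f"participants.{fmt}", participants, fmt=fmt)
            write_responses(out / f"responses.{fmt}", responses, taxonomy, fmt=fmt)
            write_truth(out / f"truth.{fmt}", truth, fmt=fmt)
    return report
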