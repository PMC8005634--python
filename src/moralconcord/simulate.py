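"""Synthetic argument-attribution survey generator with known ground truth.

The generator emulates the study design that the package analyses: a set of
dichotomous moral items, ~100 raters per item, each respondent judging a
random subset of items, seeing one randomly drawn argument wording per
concern, and ticking concerns for both their own answer and the opposite one.
Ticks are Bernoulli draws from latent per-(opinion, concern) applicability
probabilities theta; populations may disagree via a log-odds perturbation of
size tau, and own- vs other-side judging may disagree via a per-cell log-odds
offset of size kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .records import (
    AFFIRMATIVE,
    NEGATIVE,
    MoralItem,
    OpinionId,
    ParticipantRecord,
    ResponseRecord,
)
from .taxonomy import DEFAULT_TAXONOMY, ConcernTaxonomy

_EPS = 1e-6  # clamp for exact-0/1 latent scores before the logit transform

DistSpec = tuple  # ("beta", a, b) | ("uniform", lo, hi) | ("point", value)


def _draw(spec: DistSpec, rng: np.random.Generator, size) -> np.ndarray:
    kind = spec[0]
    if kind == "beta":
        return rng.beta(spec[1], spec[2], size=size)
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size=size)
    if kind == "point":
        return np.full(size, float(spec[1]))
    raise ValueError(f"unknown distribution spec {spec!r}")


@dataclass(frozen=True)
class TrueScoreMatrix:
    """Latent applicability probabilities theta over opinions x concerns."""

    opinions: tuple[OpinionId, ...]
    concerns: tuple[str, ...]
    theta: np.ndarray  # shape (n_opinions, n_concerns)

    def __post_init__(self) -> None:
        t = np.asarray(self.theta, dtype=float)
        if t.shape != (len(self.opinions), len(self.concerns)):
            raise ValueError("theta shape does not match opinions x concerns")
        if np.any(t < 0) or np.any(t > 1):
            raise ValueError("theta values must lie in [0, 1]")

    def __getitem__(self, key: tuple[OpinionId, str]) -> float:
        op, concern = key
        return float(
            self.theta[self.opinions.index(op), self.concerns.index(concern)]
        )


@dataclass(frozen=True)
class GroupConfig:
    """One simulated population: size, group discrepancy, and demographics."""

    label: str
    n_participants: int
    tau: float = 0.0  # log-odds discrepancy of this group's theta from the base
    compression: float = 1.0  # shrink of theta toward the grand mean (distinctiveness)
    country: str | None = None
    demographics: Mapping[str, Callable[[np.random.Generator, int], np.ndarray]] | None = None

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError(f"group {self.label!r}: n_participants must be positive")
        if self.tau < 0:
            raise ValueError(f"group {self.label!r}: tau must be >= 0")
        if not 0.0 <= self.compression <= 1.0:
            raise ValueError(f"group {self.label!r}: compression must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a simulated multi-population study."""

    n_items: int
    groups: tuple[GroupConfig, ...]
    taxonomy: ConcernTaxonomy = DEFAULT_TAXONOMY
    items_per_participant: int = 19
    theta_prior: DistSpec = ("beta", 0.8, 1.6)
    concern_offsets: Mapping[str, float] | None = None  # log-odds shifts per concern
    opinion_prevalence: DistSpec = ("beta", 2.0, 2.0)
    perspective_discrepancy: float = 0.0  # kappa, log-odds sd of the other-side offset
    within_concern_argument_sd: float = 0.0  # log-odds sd of per-wording effects
    other_reason_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items <= 0:
            raise ValueError("n_items must be positive")
        if not self.groups:
            raise ValueError("at least one group is required")
        if not 1 <= self.items_per_participant <= self.n_items:
            raise ValueError("items_per_participant must be in 1..n_items")
        if self.perspective_discrepancy < 0:
            raise ValueError("perspective_discrepancy must be >= 0")
        if self.within_concern_argument_sd < 0:
            raise ValueError("within_concern_argument_sd must be >= 0")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")

    @property
    def opinions(self) -> tuple[OpinionId, ...]:
        ops: list[OpinionId] = []
        for i in range(self.n_items):
            item = f"item{i:03d}"
            ops.append(OpinionId(item, AFFIRMATIVE))
            ops.append(OpinionId(item, NEGATIVE))
        return tuple(ops)

    @property
    def items(self) -> tuple[MoralItem, ...]:
        return tuple(
            MoralItem(item_id=f"item{i:03d}", text=f"Synthetic moral question {i}")
            for i in range(self.n_items)
        )


def _streams(config: SimConfig) -> list[np.random.Generator]:
    """Deterministic, role-separated random streams derived from the seed.

    Stream roles: 0 theta, 1 prevalence, 2 perspective offsets, 3 argument
    wording offsets, 4+g one stream per group. Keeping roles fixed means the
    latent truth is identical across configs that differ only in group sizes.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(4 + len(config.groups))
    return [np.random.default_rng(c) for c in children]


def draw_true_scores(config: SimConfig) -> TrueScoreMatrix:
    """Draw the base latent applicability matrix from the theta prior.

    Optional per-concern offsets shift each concern's scores on the log-odds
    scale (e.g. to make fairness and liberty the most broadly applicable
    concerns, as in real argument-attribution data).
    """
    rng = _streams(config)[0]
    concerns = config.taxonomy.concerns
    n_op = 2 * config.n_items
    theta = _draw(config.theta_prior, rng, (n_op, len(concerns)))
    if config.concern_offsets:
        unknown = set(config.concern_offsets) - set(concerns)
        if unknown:
            raise ValueError(f"concern_offsets for unknown concern(s) {sorted(unknown)}")
        offsets = np.array([config.concern_offsets.get(c, 0.0) for c in concerns])
        theta = expit(logit(np.clip(theta, _EPS, 1 - _EPS)) + offsets)
    return TrueScoreMatrix(opinions=config.opinions, concerns=tuple(concerns), theta=theta)


def perturb_group_scores(
    base: TrueScoreMatrix, tau: float, seed: int | np.random.Generator
) -> TrueScoreMatrix:
    """Perturb a latent score matrix by N(0, tau) noise on the log-odds scale.

    tau = 0 returns the base unchanged. Scores exactly at 0 or 1 are clamped
    to [1e-6, 1 - 1e-6] before the transform so the logit is finite.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0:
        return base
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clipped = np.clip(base.theta, _EPS, 1 - _EPS)
    eps = rng.normal(0.0, tau, size=clipped.shape)
    return replace(base, theta=expit(logit(clipped) + eps))


def _compress(theta: np.ndarray, factor: float) -> np.ndarray:
    if factor >= 1.0:
        return theta
    grand = theta.mean()
    return grand + factor * (theta - grand)


def _default_demographics(
    rng: np.random.Generator, n: int, country: str
) -> dict[str, np.ndarray]:
    return {
        "sex": np.where(rng.random(n) < 0.5, "female", "male"),
        "age": np.clip(np.rint(rng.normal(39.0, 12.0, n)), 18, 88).astype(int),
        "ideology": np.where(rng.random(n) < 0.5, "liberal", "conservative"),
        "ideology_scale": rng.integers(0, 11, n),
        "education": np.where(rng.random(n) < 0.5, "higher", "lower"),
        "verbal_ability": rng.binomial(10, 0.65, n),
        "country": np.full(n, country, dtype=object),
    }


def simulate_study(
    config: SimConfig,
) -> tuple[list[ParticipantRecord], list[ResponseRecord], dict[str, TrueScoreMatrix]]:
    """Simulate a full multi-population argument-attribution study.

    Returns participants, responses, and the per-group latent truth used to
    generate the ticks (for test oracles). Deterministic given the config's
    seed: identical configs yield identical output, byte-for-byte after I/O.
    """
    streams = _streams(config)
    concerns = config.taxonomy.concerns
    n_c = len(concerns)
    n_args = {c: len(config.taxonomy.arguments[c]) for c in concerns}

    base = draw_true_scores(config)
    prevalence = _draw(config.opinion_prevalence, streams[1], config.n_items)

    # Per-cell other-side offset, shared by every respondent judging a cell
    # from outside their own position; a per-respondent draw would average out
    # and leave population-level scores unaffected.
    kappa = config.perspective_discrepancy
    delta = (
        streams[2].normal(0.0, kappa, size=base.theta.shape)
        if kappa > 0
        else np.zeros_like(base.theta)
    )
    arg_sd = config.within_concern_argument_sd
    max_args = max(n_args.values())
    arg_offsets = (
        streams[3].normal(0.0, arg_sd, size=(n_c, max_args))
        if arg_sd > 0
        else np.zeros((n_c, max_args))
    )

    participants: list[ParticipantRecord] = []
    responses: list[ResponseRecord] = []
    truth: dict[str, TrueScoreMatrix] = {}
    item_ids = [it.item_id for it in config.items]

    for g_idx, group in enumerate(config.groups):
        rng = streams[4 + g_idx]
        theta_g = perturb_group_scores(base, group.tau, rng)
        theta_arr = _compress(theta_g.theta, group.compression)
        truth[group.label] = replace(base, theta=theta_arr)
        logit_own = logit(np.clip(theta_arr, _EPS, 1 - _EPS))
        logit_other = logit_own + delta

        n = group.n_participants
        country = group.country or group.label
        demo = dict(_default_demographics(rng, n, country))
        if group.demographics:
            for attr, gen in group.demographics.items():
                demo[attr] = np.asarray(gen(rng, n))
        pids = [f"{group.label}_p{i:05d}" for i in range(n)]
        for i, pid in enumerate(pids):
            participants.append(
                ParticipantRecord(
                    participant_id=pid,
                    sex=str(demo["sex"][i]),
                    age=int(demo["age"][i]),
                    ideology=str(demo["ideology"][i]),
                    ideology_scale=int(demo["ideology_scale"][i]),
                    education=str(demo["education"][i]),
                    verbal_ability=int(demo["verbal_ability"][i]),
                    country=str(demo["country"][i]),
                    population_label=group.label,
                )
            )

        ipp = config.items_per_participant
        # Uniform without-replacement item assignment, vectorized over people.
        item_mat = np.argsort(rng.random((n, config.n_items)), axis=1)[:, :ipp]
        aff = rng.random((n, ipp)) < prevalence[item_mat]
        own_op = 2 * item_mat + (~aff).astype(int)  # 2i affirmative, 2i+1 negative
        opp_op = 2 * item_mat + aff.astype(int)
        shown = rng.integers(0, max_args, size=(n, ipp, n_c))
        for ci, c in enumerate(concerns):  # respect shorter argument lists
            if n_args[c] != max_args:
                shown[:, :, ci] = shown[:, :, ci] % n_args[c]
        lo_own = logit_own[own_op] + arg_offsets[np.arange(n_c), shown]
        lo_opp = logit_other[opp_op] + arg_offsets[np.arange(n_c), shown]
        ticks_own = rng.random((n, ipp, n_c)) < expit(lo_own)
        ticks_other = rng.random((n, ipp, n_c)) < expit(lo_opp)
        reason_flags = rng.random((n, ipp, 2)) < config.other_reason_rate

        for i in range(n):
            pid = pids[i]
            for k in range(ipp):
                item = item_ids[item_mat[i, k]]
                responses.append(
                    ResponseRecord(
                        participant_id=pid,
                        item_id=item,
                        own_answer=AFFIRMATIVE if aff[i, k] else NEGATIVE,
                        shown_arguments={
                            c: config.taxonomy.arguments[c][shown[i, k, ci]]
                            for ci, c in enumerate(concerns)
                        },
                        own_side_ticks=frozenset(
                            c for ci, c in enumerate(concerns) if ticks_own[i, k, ci]
                        ),
                        other_side_ticks=frozenset(
                            c for ci, c in enumerate(concerns) if ticks_other[i, k, ci]
                        ),
                        other_reason_own=bool(reason_flags[i, k, 0]),
                        other_reason_other=bool(reason_flags[i, k, 1]),
                    )
                )
    return participants, responses, truth


def write_truth(path, truth: Mapping[str, TrueScoreMatrix], fmt: str = "tsv") -> None:
    """Export latent truth matrices as a tidy file (group, item, position, concern, theta)."""
    import pandas as pd

    rows = []
    for label, mat in truth.items():
        for oi, op in enumerate(mat.opinions):
            for ci, concern in enumerate(mat.concerns):
                rows.append(
                    {
                        "group": label,
                        "item_id": op.item_id,
                        "position": op.position,
                        "concern": concern,
                        "theta": f"{mat.theta[oi, ci]:.8f}",
                    }
                )
    pd.DataFrame(rows, columns=["group", "item_id", "position", "concern", "theta"]).to_csv(
        path, sep={"tsv": "\t", "csv": ","}[fmt], index=False
    )


# ---------------------------------------------------------------------------
# Design presets mirroring the three study designs the generator emulates:
# a US-like single sample (98 items, ~110 raters/item, 19 items/person), a
# UK-like single sample (108 items, ~100 raters/item), and a shared-27-item
# cross-country design (~100 raters/item per country).


def us_like(seed: int = 0, **overrides) -> SimConfig:
    defaults = dict(
        n_items=98,
        groups=(GroupConfig(label="us", n_participants=568, country="US"),),
        items_per_participant=19,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def uk_like(seed: int = 0, **overrides) -> SimConfig:
    defaults = dict(
        n_items=108,
        groups=(GroupConfig(label="uk", n_participants=903, country="UK"),),
        items_per_participant=12,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def shared27(
    seed: int = 0, labels: Sequence[str] = ("country_a", "country_b"), **overrides
) -> SimConfig:
    defaults = dict(
        n_items=27,
        groups=tuple(
            GroupConfig(label=lab, n_participants=300, country=lab.upper()) for lab in labels
        ),
        items_per_participant=9,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
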