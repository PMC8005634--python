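"""Resampling nulls for the hypothesis of perfect population-level agreement.

Even if two populations agree perfectly, two finite samples will not: each
cell's score carries binomial sampling error, so the observed CCC is below 1.
The reference value is therefore obtained by simulation: pool the two
samples, repeatedly split the pool at random into subsamples of the original
sizes, and record the CCC between the two halves. The mean of these split
CCCs is the *expected CCC under perfect true agreement*, and the p-value is
the proportion of split CCCs strictly below the observed between-group CCC.

For opinion-based comparisons the respondents judging an item are split
within each item (a global split would break the per-item supporter/opponent
group sizes), implemented here as the stratified variant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .agreement import ccc
from .records import AFFIRMATIVE, Judgment, NEGATIVE, OpinionId, ParticipantRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullResult:
    """Outcome of a random-split resampling null."""

    observed_ccc: float | None
    expected_ccc: float
    split_cccs: tuple[float, ...]
    p_value: float | None
    n_splits: int
    n_1: int
    n_2: int
    seed: int | None
    n_discarded: int = 0

    def central_interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        arr = np.asarray(self.split_cccs)
        return (float(np.quantile(arr, lo)), float(np.quantile(arr, 1.0 - lo)))


def _p_value(
    split_cccs: np.ndarray, observed: float | None, conservative: bool
) -> float | None:
    if observed is None:
        return None
    r = int(np.sum(split_cccs < observed))  # ties count as not lower
    b = split_cccs.size
    return (r + 1) / (b + 1) if conservative else r / b


class SplitEngine:
    """Sparse tick/judgment matrices over participants x cells, for fast
    recomputation of both halves' score vectors under arbitrary splits."""

    def __init__(self, judgments: Iterable[Judgment]):
        pid_index: dict[str, int] = {}
        cell_index: dict[tuple[OpinionId, str], int] = {}
        rows: list[int] = []
        cols: list[int] = []
        vals: list[int] = []
        for j in judgments:
            r = pid_index.setdefault(j.participant_id, len(pid_index))
            c = cell_index.setdefault((j.opinion, j.concern), len(cell_index))
            rows.append(r)
            cols.append(c)
            vals.append(1 if j.applies else 0)
        if not rows:
            raise ValueError("no judgments supplied")
        shape = (len(pid_index), len(cell_index))
        ij = (np.array(rows), np.array(cols))
        self.ticks = sparse.csr_matrix((np.array(vals, dtype=float), ij), shape=shape)
        self.counts = sparse.csr_matrix((np.ones(len(rows)), ij), shape=shape)
        self.pid_index = pid_index
        self.cell_index = cell_index
        self.total_ticks = np.asarray(self.ticks.sum(axis=0)).ravel()
        self.total_counts = np.asarray(self.counts.sum(axis=0)).ravel()

    @property
    def n_participants(self) -> int:
        return self.ticks.shape[0]

    def membership_vector(self, participant_ids: Iterable[str]) -> np.ndarray:
        v = np.zeros(self.n_participants)
        for pid in participant_ids:
            v[self.pid_index[pid]] = 1.0
        return v

    def split_ccc(self, side1: np.ndarray, min_judgments: int = 1) -> float | None:
        """CCC between the two halves implied by a 0/1 membership vector.

        Returns None when fewer than two cells are populated on both sides.
        """
        t1 = side1 @ self.ticks
        n1 = side1 @ self.counts
        t2 = self.total_ticks - t1
        n2 = self.total_counts - n1
        mask = (n1 >= min_judgments) & (n2 >= min_judgments)
        if int(mask.sum()) < 2:
            return None
        return ccc(t1[mask] / n1[mask], t2[mask] / n2[mask])

    def weighted_ccc(
        self, w1: np.ndarray, w2: np.ndarray, min_judgments: int = 1
    ) -> float | None:
        """CCC between two multiplicity-weighted pseudo-samples (bootstrap)."""
        t1, n1 = w1 @ self.ticks, w1 @ self.counts
        t2, n2 = w2 @ self.ticks, w2 @ self.counts
        mask = (n1 >= min_judgments) & (n2 >= min_judgments)
        if int(mask.sum()) < 2:
            return None
        return ccc(t1[mask] / n1[mask], t2[mask] / n2[mask])


def random_split_null(
    participants: Sequence[ParticipantRecord] | Sequence[str],
    judgments: Sequence[Judgment],
    split_sizes: tuple[int, int],
    n_splits: int = 1000,
    seed: int | None = None,
    min_judgments: int = 1,
    observed_ccc: float | None = None,
    conservative: bool = False,
) -> NullResult:
    """Random-split null for a demographic or cross-population comparison.

    Participants (with all their judgments) are partitioned uniformly at
    random into subsamples of sizes ``split_sizes``, ``n_splits`` times; each
    replicate recomputes both halves' score tables over pairwise-complete
    cells and their CCC. Replicates with an empty paired set are discarded
    (and the run aborts if more than 1% are).
    """
    pids = [p if isinstance(p, str) else p.participant_id for p in participants]
    n1, n2 = split_sizes
    if n1 + n2 != len(pids):
        raise ValueError(
            f"split sizes {split_sizes} must sum to the pooled participant count {len(pids)}"
        )
    if n1 < 1 or n2 < 1 or n_splits < 1:
        raise ValueError("split sizes and n_splits must be positive")
    engine = SplitEngine(j for j in judgments if j.participant_id in set(pids))
    order = np.array([engine.pid_index[p] for p in pids])
    rng = np.random.default_rng(seed)
    cccs: list[float] = []
    discarded = 0
    for _ in range(n_splits):
        perm = rng.permutation(len(pids))
        side1 = np.zeros(engine.n_participants)
        side1[order[perm[:n1]]] = 1.0
        val = engine.split_ccc(side1, min_judgments=min_judgments)
        if val is None:
            discarded += 1
            logger.info("discarded a split replicate with an empty paired set")
        else:
            cccs.append(val)
    if discarded > 0.01 * n_splits:
        raise RuntimeError(
            f"{discarded}/{n_splits} split replicates had empty paired sets; "
            "the data are too sparse for this split"
        )
    arr = np.array(cccs)
    return NullResult(
        observed_ccc=observed_ccc,
        expected_ccc=float(arr.mean()),
        split_cccs=tuple(arr),
        p_value=_p_value(arr, observed_ccc, conservative),
        n_splits=len(cccs),
        n_1=n1,
        n_2=n2,
        seed=seed,
        n_discarded=discarded,
    )


def _item_tick_tensors(
    judgments: Sequence[Judgment],
    strata: Mapping[str, tuple[Sequence[str], Sequence[str]]],
):
    """Per item: respondents' tick indicators for both positions, as an array
    (n_respondents, 2 positions, n_concerns), plus the side-1 size."""
    concerns = sorted({j.concern for j in judgments})
    c_index = {c: i for i, c in enumerate(concerns)}
    by_item: dict[str, dict] = {}
    for item_id, (side1, side2) in strata.items():
        if len(side1) == 0 or len(side2) == 0:
            raise ValueError(f"item {item_id!r}: one side of the stratum is empty")
        resp = list(side1) + list(side2)
        by_item[item_id] = {
            "resp_index": {pid: i for i, pid in enumerate(resp)},
            "n1": len(side1),
            "ticks": np.zeros((len(resp), 2, len(concerns))),
            "seen": np.zeros((len(resp), 2, len(concerns)), dtype=bool),
        }
    pos_index = {AFFIRMATIVE: 0, NEGATIVE: 1}
    for j in judgments:
        entry = by_item.get(j.opinion.item_id)
        if entry is None:
            continue
        r = entry["resp_index"].get(j.participant_id)
        if r is None:
            continue
        p = pos_index[j.opinion.position]
        c = c_index[j.concern]
        entry["ticks"][r, p, c] = 1.0 if j.applies else 0.0
        entry["seen"][r, p, c] = True
    dropped = []
    for item_id, entry in list(by_item.items()):
        if not entry["seen"].all():
            raise ValueError(
                f"item {item_id!r}: some stratum respondents lack a full two-sided judgment"
            )
        n = entry["ticks"].shape[0]
        if entry["n1"] < 2 or n - entry["n1"] < 2:
            dropped.append(item_id)
            del by_item[item_id]
    if dropped:
        logger.info("dropped %d item(s) with < 2 respondents on a side: %s", len(dropped), dropped)
    if not by_item:
        raise ValueError("no items retained: every stratum has a side with < 2 respondents")
    return by_item, concerns, dropped


def stratified_split_null(
    judgments: Sequence[Judgment],
    strata: Mapping[str, tuple[Sequence[str], Sequence[str]]],
    n_splits: int = 1000,
    seed: int | None = None,
    observed_ccc: float | None = None,
    min_judgments: int = 1,
    conservative: bool = False,
) -> NullResult:
    """Item-stratified random-split null for opinion-based comparisons.

    ``strata`` maps each item to its two respondent sets (originally the
    item's supporters of the affirmative and of the negative answer). Each
    replicate reshuffles respondents *within each item* into pseudo-sides of
    the original sizes; the pseudo-supporters' judgments of their assigned
    position form score vector 1 and the pseudo-opponents' judgments of that
    same position form score vector 2, exactly mirroring the observed
    supporter-vs-opponent pairing.
    """
    by_item, concerns, _ = _item_tick_tensors(judgments, strata)
    rng = np.random.default_rng(seed)
    cccs: list[float] = []
    discarded = 0
    n1_total = sum(e["n1"] for e in by_item.values())
    n2_total = sum(e["ticks"].shape[0] - e["n1"] for e in by_item.values())
    for _ in range(n_splits):
        v1: list[np.ndarray] = []
        v2: list[np.ndarray] = []
        for entry in by_item.values():
            n = entry["ticks"].shape[0]
            n1 = entry["n1"]
            perm = rng.permutation(n)
            m1 = entry["ticks"][perm[:n1]].mean(axis=0)  # (2, n_concerns)
            m2 = entry["ticks"][perm[n1:]].mean(axis=0)
            # pseudo-side-1 holds the affirmative: own view of aff, other view of neg
            v1.append(m1[0])
            v2.append(m2[0])
            v1.append(m2[1])
            v2.append(m1[1])
        x = np.concatenate(v1)
        y = np.concatenate(v2)
        val = ccc(x, y)
        cccs.append(val)
    arr = np.array(cccs)
    return NullResult(
        observed_ccc=observed_ccc,
        expected_ccc=float(arr.mean()),
        split_cccs=tuple(arr),
        p_value=_p_value(arr, observed_ccc, conservative),
        n_splits=len(cccs),
        n_1=n1_total,
        n_2=n2_total,
        seed=seed,
        n_discarded=discarded,
    )


def bootstrap_ccc_ci(
    judgments: Sequence[Judgment],
    group1_ids: Sequence[str],
    group2_ids: Sequence[str],
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    min_judgments: int = 1,
) -> tuple[float, float]:
    """Participant-level percentile bootstrap interval for the CCC.

    Respondents are resampled with replacement within each population and
    both score tables and the CCC recomputed per replicate.
    """
    engine = SplitEngine(judgments)
    idx1 = np.array([engine.pid_index[p] for p in group1_ids])
    idx2 = np.array([engine.pid_index[p] for p in group2_ids])
    rng = np.random.default_rng(seed)
    vals: list[float] = []
    for _ in range(n_boot):
        w1 = np.zeros(engine.n_participants)
        w2 = np.zeros(engine.n_participants)
        draw1 = np.bincount(rng.integers(0, idx1.size, idx1.size), minlength=idx1.size)
        draw2 = np.bincount(rng.integers(0, idx2.size, idx2.size), minlength=idx2.size)
        w1[idx1] = draw1
        w2[idx2] = draw2
        val = engine.weighted_ccc(w1, w2, min_judgments=min_judgments)
        if val is not None:
            vals.append(val)
    if not vals:
        raise RuntimeError("all bootstrap replicates degenerate")
    lo = (1.0 - level) / 2.0
    arr = np.array(vals)
    return (float(np.quantile(arr, lo)), float(np.quantile(arr, 1.0 - lo)))
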