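"""Random-split and item-stratified resampling nulls."""

import numpy as np
import pytest

import moralconcord as mc
from conftest import make_response


def _study_judgments(small_study, taxonomy):
    _, participants, responses, _ = small_study
    return participants, mc.derive_judgments(responses, taxonomy)


def test_same_seed_reproduces_split_cccs(taxonomy, small_study):
    participants, judgments = _study_judgments(small_study, taxonomy)
    a = mc.random_split_null(participants, judgments, (40, 40), n_splits=25, seed=5)
    b = mc.random_split_null(participants, judgments, (40, 40), n_splits=25, seed=5)
    assert a.split_cccs == b.split_cccs
    assert a.expected_ccc == pytest.approx(np.mean(a.split_cccs))


def test_expected_ccc_below_one_with_finite_samples(taxonomy, small_study):
    participants, judgments = _study_judgments(small_study, taxonomy)
    null = mc.random_split_null(participants, judgments, (40, 40), n_splits=25, seed=6)
    assert null.expected_ccc < 1.0
    assert all(c < 1.0 for c in null.split_cccs)


def test_p_zero_when_observed_below_every_split(taxonomy, small_study):
    participants, judgments = _study_judgments(small_study, taxonomy)
    null = mc.random_split_null(
        participants, judgments, (40, 40), n_splits=25, seed=7, observed_ccc=-1.0
    )
    assert null.p_value == 0.0


def test_ties_count_as_not_lower(taxonomy):
    # two identical respondents: every (1,1) split yields the same CCC,
    # so with observed equal to it the strict proportion is exactly 0
    rows = [make_response(p, own={"harm"}, other={"liberty"}) for p in ("p1", "p2")]
    judgments = mc.derive_judgments(rows, taxonomy)
    split_val = mc.random_split_null(["p1", "p2"], judgments, (1, 1), n_splits=5, seed=1).split_cccs[0]
    null = mc.random_split_null(
        ["p1", "p2"], judgments, (1, 1), n_splits=5, seed=1, observed_ccc=split_val
    )
    assert null.p_value == 0.0


def test_conservative_p_value_variant(taxonomy, small_study):
    participants, judgments = _study_judgments(small_study, taxonomy)
    null = mc.random_split_null(
        participants, judgments, (40, 40), n_splits=20, seed=8,
        observed_ccc=-1.0, conservative=True,
    )
    assert null.p_value == pytest.approx(1 / 21)


def test_split_sizes_must_sum_to_pool(taxonomy, small_study):
    participants, judgments = _study_judgments(small_study, taxonomy)
    with pytest.raises(ValueError, match="sum"):
        mc.random_split_null(participants, judgments, (40, 30), n_splits=5, seed=1)


def test_abort_when_splits_degenerate(taxonomy):
    # two respondents to different items share no cells: every split's paired
    # set is empty, which must abort with a diagnostic
    rows = [make_response("p1", item="item000"), make_response("p2", item="item001")]
    judgments = mc.derive_judgments(rows, taxonomy)
    with pytest.raises(RuntimeError, match="empty paired"):
        mc.random_split_null(["p1", "p2"], judgments, (1, 1), n_splits=10, seed=2)


def test_stratified_matches_global_split_in_expectation(taxonomy, small_study):
    """With strata taken from a global two-way partition, the item-stratified
    null and the global random-split null target the same expected CCC."""
    _, participants, responses, _ = small_study
    judgments = mc.derive_judgments(responses, taxonomy)
    glob = mc.random_split_null(participants, judgments, (40, 40), n_splits=400, seed=11)

    group = {p.participant_id: p.population_label for p in participants}
    strata = {}
    for r in responses:
        strata.setdefault(r.item_id, ([], []))[
            0 if group[r.participant_id] == "g1" else 1
        ].append(r.participant_id)
    strat = mc.stratified_split_null(judgments, strata, n_splits=400, seed=12)
    diff = abs(glob.expected_ccc - strat.expected_ccc)
    se_of_diff = np.sqrt(
        np.var(glob.split_cccs) / 400 + np.var(strat.split_cccs) / 400
    )
    assert diff < 3 * se_of_diff


def test_stratified_rejects_empty_side(taxonomy):
    rows = [make_response("p1"), make_response("p2")]
    judgments = mc.derive_judgments(rows, taxonomy)
    with pytest.raises(ValueError, match="empty"):
        mc.stratified_split_null(judgments, {"item000": (["p1", "p2"], [])}, n_splits=5, seed=1)


def test_bootstrap_ci_valid_and_deterministic(taxonomy, small_study):
    """The optional participant-level bootstrap yields a proper, reproducible
    interval. (Its location is biased low at small raters-per-item because
    resampling adds multiplicity noise to every cell; the asymptotic interval
    is the primary method.)"""
    _, participants, responses, _ = small_study
    judgments = mc.derive_judgments(responses, taxonomy)
    ids1 = [p.participant_id for p in participants if p.population_label == "g1"]
    ids2 = [p.participant_id for p in participants if p.population_label == "g2"]
    lo, hi = mc.bootstrap_ccc_ci(judgments, ids1, ids2, n_boot=200, seed=13)
    assert -1.0 <= lo < hi <= 1.0
    assert (lo, hi) == mc.bootstrap_ccc_ci(judgments, ids1, ids2, n_boot=200, seed=13)
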