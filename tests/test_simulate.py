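"""Generator checks against closed forms, determinism, and study-design counts."""

import numpy as np
import pytest
from scipy import integrate, stats

import moralconcord as mc


def _one_group(n, n_items=6, ipp=4, seed=0, **cfg_kw):
    return mc.SimConfig(
        n_items=n_items, items_per_participant=ipp, seed=seed,
        groups=(mc.GroupConfig("g", n),), **cfg_kw,
    )


def test_point_mass_prior_gives_constant_theta():
    cfg = _one_group(5, theta_prior=("point", 0.5))
    truth = mc.draw_true_scores(cfg)
    assert np.all(truth.theta == 0.5)


def test_true_scores_deterministic_given_seed():
    cfg = _one_group(5, seed=11)
    a = mc.draw_true_scores(cfg)
    b = mc.draw_true_scores(cfg)
    assert np.array_equal(a.theta, b.theta)


def test_beta_prior_matches_closed_form_mean():
    # Beta(2,2) has mean 1/2; >10,000 Monte-Carlo draws pin it to +-0.01
    cfg = _one_group(5, n_items=700, ipp=1, theta_prior=("beta", 2.0, 2.0), seed=3)
    truth = mc.draw_true_scores(cfg)
    assert truth.theta.size >= 10_000
    assert abs(truth.theta.mean() - 0.5) < 0.01


def test_concern_offsets_shift_medians():
    cfg = _one_group(
        5, n_items=200, ipp=1, seed=5,
        concern_offsets={"fairness": 1.5, "liberty": 1.5},
    )
    truth = mc.draw_true_scores(cfg)
    medians = {c: np.median(truth.theta[:, i]) for i, c in enumerate(truth.concerns)}
    top_two = sorted(medians, key=medians.get, reverse=True)[:2]
    assert set(top_two) == {"fairness", "liberty"}


def test_perturb_tau_zero_is_identity():
    cfg = _one_group(5)
    base = mc.draw_true_scores(cfg)
    assert mc.perturb_group_scores(base, 0.0, seed=1) is base


def test_perturb_matches_logit_normal_moments():
    # theta = 0.5 everywhere, so logit(theta') ~ N(0, sigma^2): compare the
    # empirical mean/variance of theta' with numerical integration of the
    # logit-normal at sigma = 5.
    sigma = 5.0
    cfg = _one_group(5, n_items=625, ipp=1, theta_prior=("point", 0.5), seed=9)
    base = mc.draw_true_scores(cfg)
    pert = mc.perturb_group_scores(base, sigma, seed=10)
    vals = pert.theta.ravel()
    assert vals.size == 10_000

    def moment(k):
        f = lambda z: (1.0 / (1.0 + np.exp(-z))) ** k * stats.norm.pdf(z, scale=sigma)
        return integrate.quad(f, -60, 60, limit=200)[0]

    m1, m2 = moment(1), moment(2)
    assert abs(vals.mean() - m1) < 0.02
    assert abs(vals.var() - (m2 - m1**2)) < 0.02


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_perturbation_size_monotone_in_tau(seed):
    cfg = _one_group(5, n_items=100, ipp=1, seed=seed)
    base = mc.draw_true_scores(cfg)
    shifts = [
        np.abs(mc.perturb_group_scores(base, tau, seed=seed + 100).theta - base.theta).mean()
        for tau in (0.0, 0.3, 1.0)
    ]
    assert shifts[0] < shifts[1] < shifts[2]


def test_saturated_theta_ticks_everything(taxonomy):
    cfg = _one_group(50, theta_prior=("point", 1.0), seed=13)
    _, responses, _ = mc.simulate_study(cfg)
    for r in responses:
        assert r.own_side_ticks == frozenset(taxonomy.concerns)
        assert r.other_side_ticks == frozenset(taxonomy.concerns)


def test_study_with_98_items_covers_196_opinions(taxonomy):
    cfg = mc.us_like(seed=2, groups=(mc.GroupConfig("us", 60, country="US"),))
    _, responses, _ = mc.simulate_study(cfg)
    judgments = mc.derive_judgments(responses, taxonomy)
    assert len({j.opinion for j in judgments}) == 196


def test_empirical_score_converges_to_theta(taxonomy):
    # single item, theta = 0.3: binomial SE with 5,000 raters is ~0.0065
    cfg = _one_group(5000, n_items=1, ipp=1, theta_prior=("point", 0.3), seed=17)
    _, responses, _ = mc.simulate_study(cfg)
    table = mc.applicability_scores(mc.derive_judgments(responses, taxonomy))
    devs = [abs(float(cell.score) - 0.3) for cell in table.cells.values()]
    assert np.mean(devs) < 0.02
    assert max(devs) < 0.03


def test_consistency_scoretable_recovers_truth(taxonomy):
    cfg = _one_group(5000, n_items=8, ipp=4, seed=19)
    _, responses, truth = mc.simulate_study(cfg)
    table = mc.applicability_scores(mc.derive_judgments(responses, taxonomy))
    mat = truth["g"]
    devs = [
        abs(float(table.score(op, c)) - mat[(op, c)])
        for op in mat.opinions
        for c in mat.concerns
    ]
    assert max(devs) <= 0.03


def test_ratings_per_item_accounting():
    cfg = _one_group(120, n_items=27, ipp=11, seed=23)
    _, responses, _ = mc.simulate_study(cfg)
    counts = {}
    for r in responses:
        counts[r.item_id] = counts.get(r.item_id, 0) + 1
    p = cfg.items_per_participant / cfg.n_items
    expected = 120 * p
    sd = np.sqrt(120 * p * (1 - p))
    assert len(counts) == 27
    for n in counts.values():
        assert abs(n - expected) <= 3 * sd


def test_simulation_deterministic_and_files_byte_identical(tmp_path, taxonomy, small_study):
    cfg, participants, responses, _ = small_study
    participants2, responses2, _ = mc.simulate_study(cfg)
    assert responses2 == responses
    assert participants2 == participants
    a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
    mc.write_responses(a, responses, taxonomy)
    mc.write_responses(b, responses2, taxonomy)
    assert a.read_bytes() == b.read_bytes()


def test_group_size_zero_rejected():
    with pytest.raises(ValueError, match="positive"):
        mc.GroupConfig("g", 0)


def test_items_per_participant_bounded():
    with pytest.raises(ValueError):
        mc.SimConfig(n_items=3, items_per_participant=4, groups=(mc.GroupConfig("g", 5),))
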