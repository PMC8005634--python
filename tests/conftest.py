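import pytest
from hypothesis import settings

import moralconcord as mc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def taxonomy():
    return mc.default_taxonomy()


@pytest.fixture(scope="session")
def small_study():
    """A small two-population study with no true group discrepancy."""
    cfg = mc.SimConfig(
        n_items=6,
        items_per_participant=4,
        seed=42,
        groups=(mc.GroupConfig("g1", 40), mc.GroupConfig("g2", 40)),
    )
    participants, responses, truth = mc.simulate_study(cfg)
    return cfg, participants, responses, truth


def make_response(pid, item="item000", answer=mc.AFFIRMATIVE, own=(), other=(), taxonomy=None):
    """Hand-built response with the first wording of each concern shown."""
    tax = taxonomy or mc.DEFAULT_TAXONOMY
    return mc.ResponseRecord(
        participant_id=pid,
        item_id=item,
        own_answer=answer,
        shown_arguments={c: tax.arguments[c][0] for c in tax.concerns},
        own_side_ticks=frozenset(own),
        other_side_ticks=frozenset(other),
    )
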