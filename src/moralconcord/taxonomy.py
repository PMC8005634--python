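"""Moral-concern taxonomy: eight kinds of moral concern, each voiced by three
specific argument wordings, plus a catch-all "some other reason" option.

The default taxonomy extends the moral-foundations argument list (harm,
fairness, ingroup loyalty, authority, purity) with liberty, physical
violence, and government-overreach concerns, for 24 arguments in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

DEFAULT_CATCH_ALL = "some other reason"

_DEFAULT_ARGUMENTS: dict[str, tuple[str, ...]] = {
    "harm": (
        "Someone suffers emotionally",
        "Someone cares for someone weak or vulnerable",
        "Someone is cruel",
    ),
    "fairness": (
        "Some people are treated differently from others",
        "Someone acts unfairly",
        "Someone is denied his or her rights",
    ),
    "ingroup": (
        "Someone's action shows love for his or her country",
        "Someone does something to betray his or her group",
        "Someone shows a lack of loyalty",
    ),
    "authority": (
        "Someone shows a lack of respect for authority",
        "Someone conforms to the traditions of society",
        "Someone creates disruption to the order in our country",
    ),
    "purity": (
        "Someone violates standards of purity and decency",
        "Someone does something disgusting",
        "Someone acts in a way that God would approve of",
    ),
    "liberty": (
        "Everyone is free to do as they wanted",
        "Someone's freedom of choice is restricted",
        "Everyone is free to decide what group norms or traditions they want to follow",
    ),
    "violence": (
        "Violence is used",
        "Someone is killed",
        "Someone is physically harmed",
    ),
    "government": (
        "It goes beyond what the government's responsibility should be",
        "It is expensive for the government",
        "The government would handle it poorly",
    ),
}


class TaxonomyError(ValueError):
    """Raised when a taxonomy file is malformed or violates an invariant."""


@dataclass(frozen=True)
class ConcernTaxonomy:
    """An ordered set of moral concerns and their concrete argument wordings.

    Parameters
    ----------
    concerns:
        Concern labels in presentation order.
    arguments:
        Mapping from concern label to the tuple of argument texts that voice
        that concern.
    catch_all_label:
        Label of the catch-all option shown alongside the concern arguments.
        Ticks of this option are recorded but never scored.
    """

    concerns: tuple[str, ...]
    arguments: Mapping[str, tuple[str, ...]]
    catch_all_label: str = DEFAULT_CATCH_ALL

    def __post_init__(self) -> None:
        if len(set(self.concerns)) != len(self.concerns):
            raise TaxonomyError("concern labels must be unique")
        if set(self.concerns) != set(self.arguments):
            raise TaxonomyError("arguments must be given for exactly the listed concerns")
        texts: list[str] = []
        for concern in self.concerns:
            args = tuple(self.arguments[concern])
            if not args:
                raise TaxonomyError(f"concern {concern!r} has no arguments")
            texts.extend(args)
        if len(set(texts)) != len(texts):
            dupes = sorted({t for t in texts if texts.count(t) > 1})
            raise TaxonomyError(f"duplicate argument text(s): {dupes}")

    @property
    def n_concerns(self) -> int:
        return len(self.concerns)

    @property
    def n_arguments(self) -> int:
        return sum(len(self.arguments[c]) for c in self.concerns)

    def argument_index(self, concern: str, text: str) -> int:
        """1-based index of an argument wording within its concern's list."""
        return self.arguments[concern].index(text) + 1


def default_taxonomy() -> ConcernTaxonomy:
    """The built-in eight-concern, 24-argument taxonomy."""
    return ConcernTaxonomy(
        concerns=tuple(_DEFAULT_ARGUMENTS),
        arguments={c: tuple(a) for c, a in _DEFAULT_ARGUMENTS.items()},
    )


DEFAULT_TAXONOMY = default_taxonomy()


def load_taxonomy(path: str | Path | None = None) -> ConcernTaxonomy:
    """Load a concern taxonomy from a YAML file, or return the default.

    The file maps each concern label to a list of argument strings, either at
    the top level or under a ``concerns:`` key; an optional ``catch_all:`` key
    overrides the catch-all label.
    """
    if path is None:
        return default_taxonomy()
    raw_text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(raw_text)
    except yaml.YAMLError as exc:  # report the offending line
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise TaxonomyError(f"cannot parse taxonomy file {path}{where}: {exc}") from exc
    if not isinstance(data, dict):
        raise TaxonomyError(f"taxonomy file {path} must be a mapping")
    catch_all = data.pop("catch_all", DEFAULT_CATCH_ALL)
    mapping = data.get("concerns", data)
    if not isinstance(mapping, dict) or not mapping:
        raise TaxonomyError(f"taxonomy file {path}: no concerns found")
    arguments = {}
    for concern, args in mapping.items():
        if isinstance(args, str) or not isinstance(args, (list, tuple)):
            raise TaxonomyError(
                f"taxonomy file {path}: concern {concern!r} must map to a list of strings"
            )
        arguments[str(concern)] = tuple(str(a) for a in args)
    return ConcernTaxonomy(
        concerns=tuple(arguments), arguments=arguments, catch_all_label=str(catch_all)
    )
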