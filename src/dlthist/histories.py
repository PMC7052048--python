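"""Evolutionary histories: the gene-tree objects, validation and I/O.

A history is an ordered rooted unary-binary tree of gene lineages.  Every
node carries an event label -- speciation ``S``, duplication ``D``,
horizontal transfer ``T``, loss ``L`` or ``Extant`` -- and the species
(or time-sliced) node the gene lives in.  The size of a history is its
number of ``Extant`` leaves; loss leaves do not count.  By convention the
novel copy created by a duplication or transfer is the right child.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .species_trees import SpeciesTree, TimeSlicedTree, TreeError

__all__ = [
    "SPECIATION",
    "DUPLICATION",
    "TRANSFER",
    "LOSS",
    "EXTANT",
    "HistoryNode",
    "History",
    "EventProfile",
    "event_profile",
    "validate_history",
    "serialize_history",
    "parse_history",
]

SPECIATION = "S"
DUPLICATION = "D"
TRANSFER = "T"
LOSS = "L"
EXTANT = "Extant"

_EVENTS = {SPECIATION, DUPLICATION, TRANSFER, LOSS, EXTANT}

Context = Union[SpeciesTree, TimeSlicedTree]


@dataclass(frozen=True)
class HistoryNode:
    """Immutable gene-tree node: event, species label, ordered children."""

    event: str
    species: str
    children: tuple["HistoryNode", ...] = ()

    def __post_init__(self) -> None:
        if self.event not in _EVENTS:
            raise ValueError(f"unknown event {self.event!r}")


@dataclass(frozen=True)
class History:
    """An evolutionary history (gene tree with event and species maps)."""

    root: HistoryNode

    @property
    def size(self) -> int:
        """Number of extant leaves."""
        return sum(1 for n in self.walk() if n.event == EXTANT)

    def walk(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


@dataclass(frozen=True)
class EventProfile:
    """Event tallies of a history; the score counts D + L + T."""

    speciations: int
    duplications: int
    transfers: int
    losses: int
    extant: int

    @property
    def score(self) -> int:
        return self.duplications + self.losses + self.transfers


def event_profile(h: History) -> EventProfile:
    counts = {e: 0 for e in _EVENTS}
    for node in h.walk():
        counts[node.event] += 1
    return EventProfile(
        speciations=counts[SPECIATION],
        duplications=counts[DUPLICATION],
        transfers=counts[TRANSFER],
        losses=counts[LOSS],
        extant=counts[EXTANT],
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _children_of(context: Context, node) -> tuple:
    return node.children


def validate_history(h: History, context: Context, model) -> list[str]:
    """Check every structural constraint of a history; return violations.

    An empty report means the history is valid for ``context`` under
    ``model``.  Violations are reported as human-readable strings, one per
    offending node, rather than raised.
    """
    from .counting import ModelSpec  # local import to avoid a cycle

    if not isinstance(model, ModelSpec):
        model = ModelSpec(model)
    ranked = isinstance(context, TimeSlicedTree)
    report: list[str] = []

    def species(label: str):
        try:
            return context.node(label)
        except TreeError:
            return None

    def rec(x: HistoryNode, parent: Optional[HistoryNode]) -> None:
        u = species(x.species)
        if u is None:
            report.append(f"unknown species label {x.species!r}")
            return
        arity = len(x.children)
        if arity == 0:
            if x.event not in (EXTANT, LOSS):
                report.append(f"leaf at {x.species} has event {x.event}")
            if x.event == EXTANT and not u.is_leaf:
                report.append(f"extant gene mapped to ancestral species {x.species}")
            if x.event == LOSS and (
                parent is None or parent.event != SPECIATION
            ):
                report.append(f"loss at {x.species} not under a speciation")
        elif arity == 1:
            if x.event != SPECIATION:
                report.append(f"unary node at {x.species} has event {x.event}")
        elif arity == 2:
            if x.event not in (SPECIATION, DUPLICATION, TRANSFER):
                report.append(f"binary node at {x.species} has event {x.event}")
        else:
            report.append(f"node at {x.species} has {arity} children")

        if x.event == SPECIATION:
            kids = _children_of(context, u)
            if len(kids) == 2:
                if arity != 2:
                    report.append(
                        f"speciation at binary species {x.species} must have "
                        "two children"
                    )
                else:
                    if x.children[0].species != kids[0].label:
                        report.append(
                            "speciation children species mismatch at "
                            f"{x.species} (left)"
                        )
                    if x.children[1].species != kids[1].label:
                        report.append(
                            "speciation children species mismatch at "
                            f"{x.species} (right)"
                        )
                    n_loss = sum(1 for c in x.children if c.event == LOSS)
                    if model.speciation_loss and n_loss != 1:
                        report.append(
                            f"speciation at {x.species} must lose exactly one "
                            "lineage in the speciation-loss model"
                        )
            elif len(kids) == 1:
                if arity != 1:
                    report.append(
                        f"speciation at unary species {x.species} must have "
                        "one child"
                    )
                elif x.children[0].species != kids[0].label:
                    report.append(
                        f"speciation child species mismatch at {x.species}"
                    )
            else:
                report.append(f"speciation at extant species {x.species}")
        elif x.event == DUPLICATION:
            if not model.allows_duplication_at(context, u):
                report.append(
                    f"duplication at time-slice node {x.species} not allowed "
                    f"in {model.name}"
                )
            for side, c in zip(("left", "right"), x.children):
                if c.species != x.species:
                    report.append(
                        f"duplication children species mismatch at "
                        f"{x.species} ({side})"
                    )
        elif x.event == TRANSFER:
            if not model.has_transfer:
                report.append(f"transfer at {x.species} in model {model.name}")
            elif arity == 2:
                if x.children[0].species != x.species:
                    report.append(
                        f"transfer original copy leaves donor at {x.species}"
                    )
                receivers = {v.label for v in context.incomparable(u)}
                if x.children[1].species not in receivers:
                    report.append(
                        f"transfer receiver {x.children[1].species} not "
                        f"incomparable with donor {x.species}"
                    )
        for c in x.children:
            rec(c, x)

    rec(h.root, None)
    return report


# ---------------------------------------------------------------------------
# Serialization: NHX-annotated Newick (our own dialect, unary nodes allowed)
# ---------------------------------------------------------------------------


def serialize_history(h: History) -> str:
    """One-line annotated Newick: ``species[&&NHX:event=..:species=..]``."""

    def rec(node: HistoryNode) -> str:
        inner = ""
        if node.children:
            inner = "(" + ",".join(rec(c) for c in node.children) + ")"
        return (
            f"{inner}{node.species}"
            f"[&&NHX:event={node.event}:species={node.species}]"
        )

    return rec(h.root) + ";"


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str):
        raise TreeError(f"bad history string at position {self.pos}: {msg}")

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse_node(self) -> HistoryNode:
        children: list[HistoryNode] = []
        if self.peek() == "(":
            self.pos += 1
            children.append(self.parse_node())
            while self.peek() == ",":
                self.pos += 1
                children.append(self.parse_node())
            if self.peek() != ")":
                self.error("expected ')'")
            self.pos += 1
        start = self.pos
        while self.peek() not in ("", "[", ",", ")", ";"):
            self.pos += 1
        name = self.text[start : self.pos]
        if self.peek() != "[":
            self.error("expected NHX annotation '['")
        end = self.text.find("]", self.pos)
        if end < 0:
            self.error("unterminated NHX annotation")
        comment = self.text[self.pos + 1 : end]
        self.pos = end + 1
        if not comment.startswith("&&NHX"):
            self.error("not an NHX annotation")
        tags = dict(
            item.split("=", 1) for item in comment.split(":")[1:] if "=" in item
        )
        if "event" not in tags or "species" not in tags:
            self.error("missing event/species tags")
        species = tags["species"]
        if name and name != species:
            self.error(f"node name {name!r} disagrees with species tag")
        try:
            return HistoryNode(tags["event"], species, tuple(children))
        except ValueError as exc:
            self.error(str(exc))


def parse_history(text: str, context: Context) -> History:
    """Parse a serialized history and bind it to ``context``.

    Raises :class:`TreeError` on malformed text or unknown species labels.
    """
    parser = _Parser(text.strip())
    root = parser.parse_node()
    if parser.peek() == ";":
        parser.pos += 1
    if parser.pos != len(parser.text):
        parser.error("trailing characters")
    h = History(root)
    for node in h.walk():
        context.node(node.species)  # raises TreeError if unknown
    return h
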