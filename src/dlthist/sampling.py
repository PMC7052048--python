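"""Uniform random generation of histories from the counting tables.

This is the classical recursive method: starting from ``H[root, n]``, each
grammar alternative (extant leaf, speciation, duplication, transfer) is
drawn with probability proportional to its count, then the size ``n`` is
split across products with probability proportional to the count of the
resulting pair, and for a transfer the receiver is drawn proportionally to
its subtree count.  Because this factorization mirrors the counting
recurrences exactly, the output distribution is uniform over all histories
of size ``n``.

All randomness for one call comes from a single ``random.Random`` stream
seeded with the caller's integer seed; alternatives are always examined in
the same documented order (leaf, speciation product splits by increasing
left size then lost-right then lost-left, duplication splits, transfer
receivers in tree order), so samples are reproducible across platforms.
"""

from __future__ import annotations

import random
from typing import Optional, Union

from .counting import CountTables
from .histories import (
    DUPLICATION,
    EXTANT,
    LOSS,
    SPECIATION,
    TRANSFER,
    EventProfile,
    History,
    HistoryNode,
    event_profile,
    parse_history,
    serialize_history,
    validate_history,
)

__all__ = [
    "sample_history",
    "sample_histories",
    "History",
    "HistoryNode",
    "EventProfile",
    "event_profile",
    "validate_history",
    "serialize_history",
    "parse_history",
]


def _pick_split(rng: random.Random, weights: list[int], total: int) -> int:
    """Index i with probability weights[i]/total (cumulative scan)."""
    r = rng.randrange(total)
    acc = 0
    for i, w in enumerate(weights):
        acc += w
        if r < acc:
            return i
    raise AssertionError("inconsistent weights")  # pragma: no cover


def sample_history(
    tables: CountTables, n: int, seed: Optional[int] = None, rng=None
) -> History:
    """Draw one history of size ``n`` uniformly at random.

    Either an integer ``seed`` or an existing ``random.Random`` stream may
    be supplied.  Raises if no history of size ``n`` exists.
    """
    if rng is None:
        rng = random.Random(seed)
    if tables.history_count(n) == 0:
        raise ValueError(f"no histories of size {n} for this tree/model")
    H, S, D, T = tables.H, tables.S, tables.D, tables.T
    context, model = tables.context, tables.model

    def gen(u, m: int) -> HistoryNode:
        leaf_term = 1 if (u.is_leaf and m == 1) else 0
        s = 0 if u.is_leaf else S[u][m]
        weights = [leaf_term, s, D[u][m], T[u][m]]
        choice = _pick_split(rng, weights, sum(weights))
        if choice == 0:
            return HistoryNode(EXTANT, u.label, ())
        if choice == 1:
            if len(u.children) == 1:
                return HistoryNode(SPECIATION, u.label, (gen(u.children[0], m),))
            ul, ur = u.children
            if model.speciation_loss:
                sub = [H[ul][m], H[ur][m]]
                which = _pick_split(rng, sub, sum(sub))
                if which == 0:
                    kids = (gen(ul, m), HistoryNode(LOSS, ur.label, ()))
                else:
                    kids = (HistoryNode(LOSS, ul.label, ()), gen(ur, m))
                return HistoryNode(SPECIATION, u.label, kids)
            sub = [H[ul][i] * H[ur][m - i] for i in range(1, m)]
            sub.append(H[ul][m])  # right lineage lost
            sub.append(H[ur][m])  # left lineage lost
            which = _pick_split(rng, sub, S[u][m])
            if which < m - 1:
                i = which + 1
                kids = (gen(ul, i), gen(ur, m - i))
            elif which == m - 1:
                kids = (gen(ul, m), HistoryNode(LOSS, ur.label, ()))
            else:
                kids = (HistoryNode(LOSS, ul.label, ()), gen(ur, m))
            return HistoryNode(SPECIATION, u.label, kids)
        if choice == 2:
            sub = [H[u][i] * H[u][m - i] for i in range(1, m)]
            i = _pick_split(rng, sub, D[u][m]) + 1
            return HistoryNode(DUPLICATION, u.label, (gen(u, i), gen(u, m - i)))
        receivers = context.incomparable(u)
        sub = [
            H[u][i] * H[v][m - i] for v in receivers for i in range(1, m)
        ]
        which = _pick_split(rng, sub, T[u][m])
        v = receivers[which // (m - 1)]
        i = which % (m - 1) + 1
        return HistoryNode(TRANSFER, u.label, (gen(u, i), gen(v, m - i)))

    return History(gen(context.root, n))


def sample_histories(
    tables: CountTables, n: int, num: int, seed: int
) -> list[History]:
    """``num`` independent uniform samples from one seeded stream."""
    rng = random.Random(seed)
    return [sample_history(tables, n, rng=rng) for _ in range(num)]
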