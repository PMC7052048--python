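"""Dynamic-programming counts of histories, and a brute-force oracle.

For each node ``u`` of the (possibly time-sliced) species tree and each
history size ``n`` we tabulate

* ``H[u, n]`` -- histories of size ``n`` within the subtree of ``u``,
* ``S[u, n]``/``D[u, n]``/``T[u, n]`` -- those starting with a speciation,
  duplication or transfer,

with the recurrences::

    H[u, n] = S[u, n] + D[u, n] + T[u, n]          (internal u)
    H[u, n] = [n == 1] + D[u, n] + T[u, n]         (leaf u)
    S[u, n] = sum_m H[ul, m] H[ur, n-m] + H[ul, n] + H[ur, n]
    D[u, n] = sum_m H[u, m] H[u, n-m]
    T[u, n] = sum_{v incomparable with u} sum_m H[u, m] H[v, n-m]

where the two single terms in ``S`` are speciations losing one lineage.
Transfers are dropped in the DL models; in ranked models incomparability
means "same time slice".  All counts are exact Python integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .histories import (
    DUPLICATION,
    EXTANT,
    LOSS,
    SPECIATION,
    TRANSFER,
    History,
    HistoryNode,
)
from .species_trees import SpeciesTree, TimeSlicedTree

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "CountTables",
    "build_count_tables",
    "history_count",
    "growth_estimate",
    "enumerate_histories",
]

MODEL_NAMES = ("uDL", "rDL", "uDLT", "rDLT", "rDT-SL")

Context = Union[SpeciesTree, TimeSlicedTree]


@dataclass(frozen=True)
class ModelSpec:
    """One of the five evolutionary models.

    ``uDL``/``rDL``: duplication + loss (unranked / ranked species tree);
    ``uDLT``/``rDLT``: adds horizontal transfer, time-consistent only in the
    ranked variant; ``rDT-SL``: ranked duplication + transfer where every
    speciation is immediately followed by the loss of one lineage.
    """

    name: str

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.name!r}; expected one of {MODEL_NAMES}"
            )

    @property
    def requires_ranking(self) -> bool:
        return self.name.startswith("r")

    @property
    def has_transfer(self) -> bool:
        return self.name in ("uDLT", "rDLT", "rDT-SL")

    @property
    def speciation_loss(self) -> bool:
        """True iff binary speciations always lose one lineage (rDT-SL)."""
        return self.name == "rDT-SL"

    def allows_duplication_at(self, context: Context, node) -> bool:
        """In rDL the unary time-slice nodes are pure pass-throughs: the
        model tracks no transfer timing, so duplications are only placed on
        the species nodes themselves and rDL counts coincide with uDL."""
        if self.name == "rDL" and getattr(node, "is_unary", False):
            return False
        return True

    def check_context(self, context: Context) -> None:
        if self.requires_ranking and not isinstance(context, TimeSlicedTree):
            raise ValueError(
                f"model {self.name} needs a time-sliced (ranked) tree"
            )
        if not self.requires_ranking and not isinstance(context, SpeciesTree):
            raise ValueError(f"model {self.name} needs an unranked tree")


def _as_model(model) -> ModelSpec:
    return model if isinstance(model, ModelSpec) else ModelSpec(model)


class CountTables:
    """Filled DP tables ``H``/``S``/``D``/``T`` for one (context, model)."""

    def __init__(self, context: Context, model: ModelSpec, n_max: int):
        if n_max < 1:
            raise ValueError("n_max must be >= 1")
        model = _as_model(model)
        model.check_context(context)
        self.context = context
        self.model = model
        self.n_max = n_max
        nodes = context.postorder()
        self.H = {u: [0] * (n_max + 1) for u in nodes}
        self.S = {u: [0] * (n_max + 1) for u in nodes}
        self.D = {u: [0] * (n_max + 1) for u in nodes}
        self.T = {u: [0] * (n_max + 1) for u in nodes}
        receivers = {}
        if model.has_transfer:
            receivers = {u: context.incomparable(u) for u in nodes}
        H, S, D, T = self.H, self.S, self.D, self.T
        for n in range(1, n_max + 1):
            for u in nodes:
                if model.allows_duplication_at(context, u):
                    Hu = H[u]
                    D[u][n] = sum(Hu[m] * Hu[n - m] for m in range(1, n))
                if model.has_transfer:
                    Hu = H[u]
                    T[u][n] = sum(
                        Hu[m] * H[v][n - m]
                        for v in receivers[u]
                        for m in range(1, n)
                    )
                if u.is_leaf:
                    base = 1 if n == 1 else 0
                elif len(u.children) == 1:
                    S[u][n] = H[u.children[0]][n]
                    base = S[u][n]
                else:
                    ul, ur = u.children
                    if model.speciation_loss:
                        S[u][n] = H[ul][n] + H[ur][n]
                    else:
                        S[u][n] = (
                            sum(H[ul][m] * H[ur][n - m] for m in range(1, n))
                            + H[ul][n]
                            + H[ur][n]
                        )
                    base = S[u][n]
                H[u][n] = base + D[u][n] + T[u][n]

    @property
    def root(self):
        return self.context.root

    def history_count(self, n: int) -> int:
        if not 1 <= n <= self.n_max:
            raise ValueError(f"size {n} outside tabulated range 1..{self.n_max}")
        return self.H[self.root][n]

    def counts(self) -> list[int]:
        """The sequence ``H[root, 1..n_max]``."""
        return [self.H[self.root][n] for n in range(1, self.n_max + 1)]


def build_count_tables(context: Context, model, n_max: int) -> CountTables:
    """Fill the counting tables for ``context`` under ``model`` up to ``n_max``."""
    return CountTables(context, _as_model(model), n_max)


def history_count(tables: CountTables, n: int) -> int:
    """Number of histories of size ``n`` constrained by the species tree."""
    return tables.history_count(n)


def growth_estimate(tables: CountTables, n: int) -> float:
    """Finite-size estimate ``H[root, n] / H[root, n-1]`` of the growth factor."""
    if n < 2:
        raise ValueError("growth estimate needs n >= 2")
    num = tables.history_count(n)
    den = tables.history_count(n - 1)
    if den == 0:
        raise ZeroDivisionError(f"no histories of size {n - 1}")
    return num / den


# ---------------------------------------------------------------------------
# Brute-force enumeration oracle (tiny instances only)
# ---------------------------------------------------------------------------

_ENUM_MAX_K = 4
_ENUM_MAX_N = 6


def enumerate_histories(
    context: Context, model, n: int, _cap: bool = True
) -> list[History]:
    """Exhaustive list of all histories of size ``n`` (brute-force oracle).

    Expands the history grammar directly, without the counting tables, so
    its cardinality can be compared against :func:`history_count`.  Guarded
    by an explicit size cap; it is meant for tiny trees only.
    """
    model = _as_model(model)
    model.check_context(context)
    k = context.k if isinstance(context, TimeSlicedTree) else context.k
    if _cap and (k > _ENUM_MAX_K or n > _ENUM_MAX_N):
        raise ValueError(
            f"enumeration capped at k <= {_ENUM_MAX_K}, n <= {_ENUM_MAX_N}"
        )
    memo: dict[tuple, tuple[HistoryNode, ...]] = {}

    def enum(u, m: int) -> tuple[HistoryNode, ...]:
        key = (id(u), m)
        if key in memo:
            return memo[key]
        out: list[HistoryNode] = []
        if u.is_leaf:
            if m == 1:
                out.append(HistoryNode(EXTANT, u.label, ()))
        elif len(u.children) == 1:
            (uc,) = u.children
            out.extend(
                HistoryNode(SPECIATION, u.label, (c,)) for c in enum(uc, m)
            )
        else:
            ul, ur = u.children
            if not model.speciation_loss:
                for i in range(1, m):
                    for a in enum(ul, i):
                        for b in enum(ur, m - i):
                            out.append(
                                HistoryNode(SPECIATION, u.label, (a, b))
                            )
            for a in enum(ul, m):
                out.append(
                    HistoryNode(
                        SPECIATION,
                        u.label,
                        (a, HistoryNode(LOSS, ur.label, ())),
                    )
                )
            for b in enum(ur, m):
                out.append(
                    HistoryNode(
                        SPECIATION,
                        u.label,
                        (HistoryNode(LOSS, ul.label, ()), b),
                    )
                )
        if model.allows_duplication_at(context, u):
            for i in range(1, m):
                for a in enum(u, i):
                    for b in enum(u, m - i):
                        out.append(HistoryNode(DUPLICATION, u.label, (a, b)))
        if model.has_transfer:
            for v in context.incomparable(u):
                for i in range(1, m):
                    for a in enum(u, i):
                        for b in enum(v, m - i):
                            out.append(HistoryNode(TRANSFER, u.label, (a, b)))
        memo[key] = tuple(out)
        return memo[key]

    return [History(rootnode) for rootnode in enum(context.root, n)]
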