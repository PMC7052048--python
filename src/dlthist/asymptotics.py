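"""Singularity analysis for the unranked duplication-loss model.

For a species tree S the generating function of DL-history counts satisfies
``H_u(z) = (1 - sqrt(R_u(z))) / 2`` where the radicands obey::

    R_u(z) = 1 - 4z                                           (leaf)
    R_u(z) = -4 + 3 sqrt(R_ul) + 3 sqrt(R_ur) - sqrt(R_ul R_ur)   (internal)

``R_u`` decreases from ``R_u(0) = 1`` and its unique root ``rho_u`` in
``(0, 1/4]`` is the dominant singularity of ``H_u``; the counts then grow
like ``gamma rho^{-n} n^{-3/2}`` with
``gamma = sqrt(-rho R'_root(rho)) / (4 sqrt(pi))``.

Closed forms are provided for the two extremal families: the caterpillar
(fixed point of a sequence of rational functions) and the complete binary
tree (a quadratic-map iteration), both of which the generic numeric solver
must reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Optional

import mpmath as mp

from .species_trees import Node, SpeciesTree

__all__ = [
    "OutOfDomainError",
    "RadicandSystem",
    "SingularityResult",
    "CaterpillarAsymptotics",
    "CompleteBinaryAsymptotics",
    "radicand_value",
    "dominant_singularity",
    "asymptotic_constant",
    "caterpillar_singularity",
    "caterpillar_constant",
    "complete_binary_singularity",
    "complete_binary_constant",
    "asymptotic_count",
    "round_growth",
    "round_constant",
]

_DPS = 60
_CLAMP = mp.mpf("1e-40")  # tolerate roundoff at a child's exact singularity


class OutOfDomainError(ArithmeticError):
    """A nested radicand went negative: z lies beyond a child's singularity."""


class RadicandSystem:
    """Evaluator for the nested radicands ``R_u(z)`` of a species tree."""

    def __init__(self, tree: SpeciesTree):
        self.tree = tree

    def value(self, u: Node, z) -> mp.mpf:
        """``R_u(z)`` by recursive evaluation over the subtree of ``u``."""
        with mp.workdps(_DPS):
            zz = mp.mpf(z)

            def rec(node: Node) -> mp.mpf:
                if node.is_leaf:
                    return 1 - 4 * zz
                rl, rr = rec(node.left), rec(node.right)
                return (
                    -4
                    + 3 * self._sqrt(rl)
                    + 3 * self._sqrt(rr)
                    - self._sqrt(rl * rr)
                )

            return rec(u)

    @staticmethod
    def _sqrt(x):
        if x < 0:
            if x > -_CLAMP:
                return mp.mpf(0)
            raise OutOfDomainError("negative radicand")
        return mp.sqrt(x)


def radicand_value(system: RadicandSystem, u: Node, z) -> float:
    return float(system.value(u, z))


@dataclass
class SingularityResult:
    """Dominant singularity and leading constant of a counting series."""

    rho: float
    growth: float
    gamma: Optional[float] = None


def _per_node_rho(tree: SpeciesTree, tol) -> dict[Node, mp.mpf]:
    """rho_u for every node, bottom-up by bracketed bisection.

    ``R_u`` is strictly decreasing with ``R_u(0) = 1``; it is finite on
    ``[0, min(rho_children)]`` and already negative there, so bisection on
    that bracket is guaranteed to converge to the unique simple root.
    """
    system = RadicandSystem(tree)
    rho: dict[Node, mp.mpf] = {}
    with mp.workdps(_DPS):
        tol = mp.mpf(tol)
        for node in tree.postorder():
            if node.is_leaf:
                rho[node] = mp.mpf(1) / 4
                continue
            hi = min(rho[c] for c in node.children)
            lo = mp.mpf(0)
            for _ in range(200):
                mid = (lo + hi) / 2
                if system.value(node, mid) > 0:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < mp.mpf("1e-30"):
                    break
            rho[node] = (lo + hi) / 2
    return rho


def dominant_singularity(tree: SpeciesTree, tol: float = 1e-14) -> SingularityResult:
    """Find ``rho`` with ``|R_root(rho)| <= tol`` and the growth ``1/rho``."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    rho = _per_node_rho(tree, tol)[tree.root]
    return SingularityResult(rho=float(rho), growth=float(1 / rho))


def asymptotic_constant(tree: SpeciesTree, rho: float) -> float:
    """Leading constant ``gamma = sqrt(-rho R'(rho)) / (4 sqrt(pi))``.

    The derivative of the root radicand at its singularity is estimated by
    a central finite difference in extended precision (the radicand is
    analytic past ``rho``, up to the children's singularities).
    """
    system = RadicandSystem(tree)
    with mp.workdps(_DPS):
        r = mp.mpf(rho)
        h = r * mp.mpf("1e-12")
        deriv = (system.value(tree.root, r + h) - system.value(tree.root, r - h)) / (
            2 * h
        )
        gamma = mp.sqrt(-r * deriv) / (4 * mp.sqrt(mp.pi))
        return float(gamma)


def analyze(tree: SpeciesTree, tol: float = 1e-14) -> SingularityResult:
    """Convenience: dominant singularity together with the constant."""
    res = dominant_singularity(tree, tol)
    res.gamma = asymptotic_constant(tree, res.rho)
    return res


# ---------------------------------------------------------------------------
# Closed forms: caterpillar trees
# ---------------------------------------------------------------------------


@dataclass
class CaterpillarAsymptotics:
    """Fixed point ``X_k`` and singularity ``lambda_k = (1 - X_k^2)/4``."""

    k: int
    X: float
    lam: float

    @property
    def growth(self) -> float:
        return 1.0 / self.lam


def _s_value(X, k: int):
    """s_k(X) via s_1 = 0, s_j = (3X - 4 - s_{j-1}^2) / (X - 3)."""
    s = mp.mpf(0)
    for _ in range(2, k + 1):
        s = (3 * X - 4 - s * s) / (X - 3)
    return s


def caterpillar_singularity(k: int) -> CaterpillarAsymptotics:
    """Solve ``s_k(X) = X`` for the minimal root in (0, 1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return CaterpillarAsymptotics(1, 0.0, 0.25)
    with mp.workdps(_DPS):

        def f(X):
            return _s_value(X, k) - X

        # bracket the minimal positive root with a fast float scan, then
        # bisect in extended precision
        def f_float(x: float) -> float:
            s = 0.0
            for _ in range(2, k + 1):
                s = (3 * x - 4 - s * s) / (x - 3)
            return s - x

        grid = 4096
        bracket = None
        prev_x, prev_f = 0.0, f_float(0.0)
        for i in range(1, grid + 1):
            x = min(i / grid, 1 - 1e-12)
            fx = f_float(x)
            if prev_f > 0 and fx <= 0:
                bracket = (prev_x, x)
                break
            prev_x, prev_f = x, fx
        if bracket is None:
            raise ArithmeticError(f"no root bracketed for caterpillar k={k}")
        lo, hi = mp.mpf(bracket[0]), mp.mpf(bracket[1])
        while hi - lo > mp.mpf("1e-40"):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
        X = (lo + hi) / 2
        lam = (1 - X * X) / 4
        return CaterpillarAsymptotics(k, float(X), float(lam))


def caterpillar_constant(k: int) -> float:
    """Leading constant ``alpha_k`` for the caterpillar CT_k.

    Computed from the derivative recurrence of the transformed radicands
    ``P~_j`` at the fixed point ``X_k``::

        P~_1 = X^2,  P~_j = (3X - 4) - (X - 3) sqrt(P~_{j-1})
        P~_1' = 2X,  P~_j' = 3 - sqrt(P~_{j-1}) + (3 - X) P~_{j-1}' / (2 sqrt(P~_{j-1}))
        alpha_k = sqrt(lambda_k P~_k'(X_k) / (8 pi X_k))
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    with mp.workdps(_DPS):
        if k == 1:
            return float(1 / (4 * mp.sqrt(mp.pi)))
        res = caterpillar_singularity(k)
        X = mp.mpf(res.X)
        lam = (1 - X * X) / 4
        p = X * X
        d = 2 * X
        for _ in range(2, k + 1):
            sq = mp.sqrt(p)
            d = 3 - sq + (3 - X) * d / (2 * sq)
            p = (3 * X - 4) - (X - 3) * sq
        alpha = mp.sqrt(lam * d / (8 * mp.pi * X))
        return float(alpha)


# ---------------------------------------------------------------------------
# Closed forms: complete binary trees
# ---------------------------------------------------------------------------


@dataclass
class CompleteBinaryAsymptotics:
    """Iterate ``q_h`` and singularity ``mu_h = (1 - q_h)/4`` for CB_h."""

    h: int
    q: float
    mu: float

    @property
    def growth(self) -> float:
        return 1.0 / self.mu


def _q_sequence(h: int):
    q = mp.mpf(0)
    qs = [q]
    for _ in range(h):
        q = (3 - mp.sqrt(5 - q)) ** 2
        qs.append(q)
    return qs


def complete_binary_singularity(h: int) -> CompleteBinaryAsymptotics:
    """Iterate ``q_0 = 0, q_{h+1} = (3 - sqrt(5 - q_h))^2``; mu = (1-q)/4."""
    if h < 0:
        raise ValueError("h must be >= 0")
    with mp.workdps(_DPS):
        q = _q_sequence(h)[-1]
        mu = (1 - q) / 4
        return CompleteBinaryAsymptotics(h, float(q), float(mu))


def complete_binary_constant(h: int) -> float:
    """Leading constant ``beta_h`` for the complete binary tree CB_h.

    From the derivative recurrence ``Q_h'(z) = (3/sqrt(Q_{h-1}) - 1) Q_{h-1}'``
    with ``Q_0' = -4`` and ``Q_{h-i}(mu_h) = q_i``::

        beta_h = sqrt( mu_h / (4 pi) * prod_{i=1}^{h} (3 / sqrt(q_i) - 1) )
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    with mp.workdps(_DPS):
        qs = _q_sequence(h)
        mu = (1 - qs[-1]) / 4
        prod = mp.mpf(1)
        for q in qs[1:]:
            prod *= 3 / mp.sqrt(q) - 1
        return float(mp.sqrt(mu / (4 * mp.pi) * prod))


# ---------------------------------------------------------------------------
# First-order asymptotic count and table-style rounding
# ---------------------------------------------------------------------------


def asymptotic_count(res: SingularityResult, n: int, log: bool = False) -> float:
    """First-order estimate ``gamma rho^{-n} n^{-3/2}`` of the count.

    With ``log=True`` the natural logarithm is returned instead (useful
    when the count overflows a double).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if res.gamma is None:
        raise ValueError("result carries no constant; call analyze() first")
    with mp.workdps(_DPS):
        val = mp.log(mp.mpf(res.gamma)) - n * mp.log(mp.mpf(res.rho)) - mp.mpf(
            "1.5"
        ) * mp.log(n)
        return float(val) if log else float(mp.e**val)


def _round(x: float, places: int) -> float:
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def round_growth(x: float) -> float:
    """Growth factors are reported to 2 decimals (round half even)."""
    return _round(x, 2)


def round_constant(x: float) -> float:
    """Leading constants are reported to 4 decimals (round half even)."""
    return _round(x, 4)
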