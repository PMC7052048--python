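# Methods

## Objects and conventions

A species tree is a rooted binary tree with a unique label per node; the
label set's total (string) order makes the tree ordered: children are
stored left-to-right in increasing label order.  Internal nodes without a
user-supplied label are auto-labeled `'@' + smallest leaf label + subtree
leaf count`, which is deterministic and collision-free (two comparable
nodes differ in leaf count, two incomparable nodes in smallest leaf) and
keeps generated labels disjoint from typical user labels.  Branch lengths
in Newick input are parsed and ignored; non-binary nodes are rejected.

A history is an ordered rooted unary-binary gene tree with event map
`e ∈ {S, D, T, L, Extant}` and species map `s`.  Constraints: leaves carry
`Extant` or `L`; binary internal nodes carry `S`, `D` or `T`; unary
internal nodes carry `S`; speciation children follow the species children
in order; duplication children stay at `s(x)` with the novel copy on the
right; a transfer keeps its original copy at the donor (left child) and
places the novel copy in a species incomparable with the donor.  Losses
occur only as one-child-lost speciations — otherwise an arbitrary number
of dup-then-lose detours would make every size class infinite.  The size
of a history counts its `Extant` leaves only, and `H[u, 0] = 0` for every
node: with this boundary the recurrences need no special cases.

## Rankings and time slices

A ranking gives internal nodes distinct ranks `1..k-1` (ancestors first)
and all leaves rank `k`.  Every edge crossing a rank boundary `i` is
subdivided by a unary node placed in slice `i` (labeled with the species
below plus one prime per slice above it), so slice `i ≤ k-1` holds exactly
one binary node and `i-1` unary nodes and slice `k` holds the `k` leaves.
In ranked models the receivers of a transfer are the other nodes of the
donor's slice, which makes every history time-consistent.  In the
*unranked* DLT model incomparability is the plain ancestor relation and
time-inconsistent histories are deliberately not filtered out; this is a
property of the model, not an omission.

Uniform random rankings are drawn as uniform linear extensions of the
internal-node forest: recursively sample extensions of the child subtrees
and merge two sequences of lengths a and b by taking the next element from
the first with probability a/(a+b), which makes every interleaving
equally likely.  Exhaustive ranking enumeration (used for the
species-tree-independence checks) generates all interleavings instead.

## Models

| model  | tree    | transfers | notes |
|--------|---------|-----------|-------|
| uDL    | unranked| no        | |
| rDL    | ranked  | no        | unary slice nodes are pure pass-throughs |
| uDLT   | unranked| to any incomparable node | time consistency not enforced |
| rDLT   | ranked  | within the donor's slice | duplications/transfers also at unary nodes |
| rDT-SL | ranked  | within the donor's slice | every speciation loses one lineage |

The rDL choice is a genuine design decision: placing duplications on the
unary slice nodes would distinguish "a duplication before speciation time
i" from "after", strictly enlarging the count (already at k=3, n=2 it
yields 20 instead of 19).  Since the DL dynamics are blind to time slices,
we treat unary nodes as pass-throughs, which makes rDL and uDL counts
provably identical — a cross-check the test suite asserts for all shapes
with up to 6 leaves.  The ranked transfer models, by contrast, must place
events on unary nodes (a transfer's donor or receiver is usually a plain
branch segment), and the rDT-SL events graph carries duplication
self-loops on every node.

## Counting and sampling

Counts are exact Python integers throughout (they exceed 2^64 at moderate
sizes) and are serialized as decimal strings in JSON.  The DP iterates
sizes outermost and nodes in post-order innermost: `S[u,n]` needs the
children's values at the same size, while `D` and `T` only combine sizes
strictly below `n`, so a single pass suffices and no fixed point is
needed.  Per-node incomparable sets are collected once per table build.

The sampler applies the recursive method to the same factorization: first
the alternative (extant leaf / speciation / duplication / transfer)
proportionally to its table mass, then the size split `(m, n−m)` by a
cumulative scan, then the transfer receiver proportionally to
`H[v, n−m]`.  Uniformity therefore holds by construction and is verified
empirically by chi-square tests against exhaustively enumerated supports.
All randomness for one operation comes from a single seeded
`random.Random` stream with a fixed alternative order, so samples are
reproducible across platforms.  The Boustrophedon split order is a
constant-factor optimization only and is not implemented; the cumulative
scan is already linear in `n` per node.

Sampled histories materialize loss leaves explicitly (including the
forced losses of rDT-SL) and keep the unary pass-through nodes of ranked
trees, so that the species map is complete; serialization uses an
NHX-style annotated Newick dialect (`[&&NHX:event=..:species=..]`) with a
round-trip parser.

## Brute-force oracles

`enumerate_histories` expands the grammar exhaustively (capped at 4
leaves / size 6) and is the independent ground truth for the DP counts,
the sampler's support, and the transport bijection.  A second,
structurally different oracle enumerates rDT-SL histories by walking the
events graph's speciation/duplication/transfer edges; both oracles must
produce identical history sets.

## Asymptotics (unranked DL model)

Writing `H_u(z) = (1 − √R_u(z))/2` turns the generating-function system
into the radicand recurrence `R_leaf = 1 − 4z`,
`R_u = −4 + 3√R_ul + 3√R_ur − √(R_ul R_ur)`.  Each `R_u` decreases from
`R_u(0) = 1` and vanishes before any inner radicand does, so the dominant
singularity `ρ_u` is bracketed by `(0, min ρ_child)` and found by
bisection (the default tolerance is 1e-14; the bisection actually runs to
1e-30 in 60-digit arithmetic, which is cheap).  Newton iteration is
avoided deliberately: the derivative degenerates near the children's
singularities.  The leading constant is
`γ = √(−ρ R'_root(ρ)) / (4√π)`, with `R'` estimated by a central finite
difference of relative step 1e-12 in the same extended precision — `R` is
analytic past ρ up to the children's singularities, so the stencil is
safe.  Counts then satisfy `h(n) = γ ρ⁻ⁿ n^(−3/2) (1 + O(1/n))`.

Closed forms for the extremal families serve as the authoritative oracle
for the generic solver (agreement to 1e-9 on ρ, 1e-8 on γ is asserted):

* caterpillar: `s_1(X) = 0`, `s_k(X) = (3X − 4 − s_{k−1}²)/(X − 3)`; the
  minimal root of `s_k(X) = X` in (0,1) gives `λ_k = (1 − X_k²)/4`.  The
  constant is computed from the derivative recurrence of the transformed
  radicands, `P̃_1' = 2X`,
  `P̃_j' = 3 − √P̃_{j−1} + (3 − X) P̃_{j−1}' / (2√P̃_{j−1})`, as
  `α_k = √(λ_k P̃_k'(X_k) / (8π X_k))`; this is the unrolled product-sum
  form evaluated incrementally, and `α_1 = 1/(4√π)` is handled directly.
* complete binary: `q_0 = 0`, `q_{h+1} = (3 − √(5 − q_h))²`,
  `μ_h = (1 − q_h)/4`, and
  `β_h = √( μ_h/(4π) · Π_{i=1..h} (3/√q_i − 1) )`, obtained by iterating
  `Q_h'(z) = (3/√Q_{h−1} − 1) Q_{h−1}'` down to `Q_0' = −4`.  This form
  reproduces the reference table for every height checked (0–4) and
  matches the finite-difference solver to 1e-8.

Reported values mirror the field's convention: growth factors to 2
decimals, constants to 4 decimals, round-half-even.  For the transfer
models no singular analysis is attempted (the functional systems are not
amenable to the same nested-radical argument); the growth factor is
instead estimated by the exact-count ratio `h(n)/h(n−1)`, whose relative
error at n = 50 is within 5% of the true value for every tree with at
most 6 leaves (the `n^(−3/2)` factor predicts a ≈3% underestimate, which
is what the tests observe).

## Random trees

`random_topology` draws uniformly over *unordered binary shapes*
(Wedderburn–Etherington counting) by unranking a uniform index: splits
`(i, n−i)` are weighted by `w(i)·w(n−i)`, and the even split uses
triangular unranking over unordered shape pairs.  Uniformity over shapes
(not over labeled or ordered trees) matches how the history counts behave
— they depend only on the shape — and is validated by chi-square tests at
10⁴ draws for 4–6 leaves.

## Events graph and transport

The events graph of a time-sliced tree has one node per sliced-tree node
labeled with its set of reachable leaves (numbered 1..k left to right),
speciation edges to children, a duplication self-loop everywhere and
complete transfer digraphs within each slice.  An rDT-SL history is
encoded by deleting loss leaves and labeling each remaining node with
`(time slice, leftmost extant descendant leaf)`; since each slice's leaf
sets partition {1..k}, the pair identifies a unique graph node *in any
ranked tree of the same size*, so decoding the same encoded tree against
another events graph transports the history bijectively.  Losses are
reinserted deterministically on decode (the lost side of a speciation is
the child not containing the surviving lineage).  The encoded root's leaf
label is determined by the history itself rather than treated as a free
choice; the bijection tests (round trips and full-set image equality)
confirm this convention is self-consistent.  Graph-construction flags can
drop duplication or transfer edges for the reduced model variants, but
only the full rDT-SL path is exercised by the main checks.

## Problem sizes and scope

The structural theorems are verified exhaustively where the combinatorics
are small (all shapes and rankings for k ≤ 5–6, brute-force enumeration
for k ≤ 3–4 and sizes ≤ 4–6) and by sampling elsewhere.  The experiment
drivers run at reduced scale as a deliberate design choice — e.g. score
distributions over one random 16-leaf tree with 10³ samples of size 30,
which already separates the uDL and uDLT score means cleanly — while the
full-scale sweeps (hundreds of trees up to 25 leaves, size 50) remain
available through the CLI by raising the parameters.

Known limitations: the generator's `random.Random` stream ties
reproducibility to CPython's Mersenne Twister; the asymptotic machinery
covers only the unranked DL model; unranked DLT histories may be
time-inconsistent by model definition; histories are parameterized by
total size, not by a per-species gene distribution; and reconciliations
(unordered duplication children) are a different combinatorial object
that this package does not count.
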