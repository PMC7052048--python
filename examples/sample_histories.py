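"""Draw uniform random histories and summarize their event profiles.

Samples 500 histories with 10 extant genes on a random 8-species tree,
in the uDL and uDLT models, and prints the mean number of events of each
kind.  The evolutionary score (duplications + losses + transfers) is the
parsimony cost of the history; random histories are far from parsimonious,
and allowing transfers lowers the typical score because one transfer can
replace several duplication-loss detours.
"""

import random

from dlthist import (
    build_count_tables,
    event_profile,
    random_topology,
    sample_history,
    serialize_history,
)

tree = random_topology(8, seed=7)
print(f"species tree: {tree.newick()}")

n, num = 10, 500
for model in ("uDL", "uDLT"):
    tables = build_count_tables(tree, model, n)
    rng = random.Random(42)
    profiles = [
        event_profile(sample_history(tables, n, rng=rng)) for _ in range(num)
    ]
    mean = lambda xs: sum(xs) / len(xs)
    print(
        f"{model}: total histories of size {n} = {tables.history_count(n)}\n"
        f"      mean S = {mean([p.speciations for p in profiles]):.2f}, "
        f"D = {mean([p.duplications for p in profiles]):.2f}, "
        f"T = {mean([p.transfers for p in profiles]):.2f}, "
        f"L = {mean([p.losses for p in profiles]):.2f}, "
        f"score = {mean([p.score for p in profiles]):.2f}"
    )

tables = build_count_tables(tree, "uDL", 3)
print("\none uniform size-3 uDL history, serialized:")
print(serialize_history(sample_history(tables, 3, seed=1)))
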