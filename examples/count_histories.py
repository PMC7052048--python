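"""Count gene-family histories of each size for a small species tree.

Builds the 3-species tree ((A,B),C), fills the duplication-loss counting
tables and prints the number of possible evolutionary histories with n
extant genes, for n = 1..8, in the uDL and uDLT models.  Each number is
the exact size of the search space a reconciliation method would face for
a gene family of that size; the uDLT column shows how dramatically
horizontal transfer enlarges that space.
"""

from dlthist import build_count_tables, parse_newick

tree = parse_newick("((A,B)X,C)R;")
udl = build_count_tables(tree, "uDL", 8)
udlt = build_count_tables(tree, "uDLT", 8)

print(f"species tree: {tree.newick()}  (k = {tree.k})")
print(f"{'n':>3} {'uDL histories':>15} {'uDLT histories':>15} {'ratio':>10}")
for n in range(1, 9):
    a, b = udl.history_count(n), udlt.history_count(n)
    print(f"{n:>3} {a:>15} {b:>15} {b / a:>10.1f}")
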