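"""Exact asymptotics of history counts in the duplication-loss model.

The number of uDL-histories grows like gamma * rho^-n / n^(3/2).  This
script computes the growth factor 1/rho and the constant gamma for the
two extremal tree shapes (caterpillar = most histories, complete binary =
fewest) with the closed-form solvers, checks them against the generic
numeric singularity solver, and compares the first-order asymptotic
prediction with the exact count at n = 40.
"""

from dlthist import (
    analyze,
    asymptotic_count,
    build_count_tables,
    caterpillar_constant,
    caterpillar_singularity,
    complete_binary_constant,
    complete_binary_singularity,
    make_caterpillar,
    make_complete_binary,
)

print(f"{'tree':>6} {'k':>3} {'growth 1/rho':>13} {'gamma':>8} {'generic':>13}")
for k in (2, 4, 8, 16):
    ct = caterpillar_singularity(k)
    generic = analyze(make_caterpillar(k))
    print(
        f"  CT_{k:<3}{k:>3} {ct.growth:>13.2f} "
        f"{caterpillar_constant(k):>8.4f} {generic.growth:>13.2f}"
    )
for h in (1, 2, 3, 4):
    cb = complete_binary_singularity(h)
    generic = analyze(make_complete_binary(h))
    print(
        f"  CB_{h:<3}{2**h:>3} {cb.growth:>13.2f} "
        f"{complete_binary_constant(h):>8.4f} {generic.growth:>13.2f}"
    )

tree = make_caterpillar(3)
res = analyze(tree)
exact = build_count_tables(tree, "uDL", 40).history_count(40)
approx = asymptotic_count(res, 40)
print(
    f"\nCT_3, n=40: exact count = {exact}\n"
    f"            first-order asymptotic = {approx:.4e} "
    f"(relative error {approx / exact - 1:+.2%})"
)
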