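"""Ranked species trees, time slices and species-tree independence.

A ranking orders the speciation events in time; subdividing the tree at
every rank boundary yields time slices, and a time-consistent transfer
must stay inside its donor's slice.  In the reduced rDT-SL model (every
speciation is followed by a loss) the number of histories does not depend
on the ranked species tree at all: this script builds every ranked tree
with 4 and 5 leaves and prints their common count vector, then transports
a sampled history between two different 4-leaf ranked trees through their
events graphs.
"""

from dlthist import (
    build_events_graph,
    build_time_slices,
    count_dtsl,
    encode_history,
    enumerate_rankings,
    enumerate_topologies,
    sample_history,
    serialize_history,
    transport_history,
)
from dlthist.counting import build_count_tables

for k in (4, 5):
    vectors = set()
    ranked = 0
    for shape in enumerate_topologies(k):
        for ranking in enumerate_rankings(shape):
            sliced = build_time_slices(shape, ranking)
            vectors.add(tuple(count_dtsl(sliced, 8).counts()))
            ranked += 1
    assert len(vectors) == 1
    print(f"k={k}: all {ranked} ranked trees share the rDT-SL count vector")
    print(f"      {list(next(iter(vectors)))}")

shapes = enumerate_topologies(4)
src = build_time_slices(shapes[0], enumerate_rankings(shapes[0])[0])
dst = build_time_slices(shapes[1], enumerate_rankings(shapes[1])[0])
g_src, g_dst = build_events_graph(src), build_events_graph(dst)

h = sample_history(count_dtsl(src, 4), 4, seed=11)
moved = transport_history(encode_history(h, g_src), g_src, g_dst)
print(f"\nhistory on    {src.tree.newick()}:\n  {serialize_history(h)}")
print(f"transported to {dst.tree.newick()}:\n  {serialize_history(moved)}")

# the same machinery covers the full rDLT model (transfers within slices)
sliced = build_time_slices(shapes[1], enumerate_rankings(shapes[1])[0])
rdlt = build_count_tables(sliced, "rDLT", 8)
print(f"\nrDLT counts on the second tree: {rdlt.counts()}")
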