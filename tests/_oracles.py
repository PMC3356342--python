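"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation code paths they check:
the mapping oracle scans every genome offset with numpy windows, and
the clustering oracle does exhaustive triple enumeration plus naive
repeated pairwise merging.
"""

from itertools import combinations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from utiliseq.core_model import revcomp


def exhaustive_map(seq: str, read: str):
    """All candidate placements (pos0, strand, mismatches) of a 50-bp read
    on a single-contig genome under the <=2-mismatch 5'-half rule, with the
    full footprint required to fit."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    win = sliding_window_view(arr, 25)
    cands = set()
    q5 = np.frombuffer(read[:25].encode(), dtype=np.uint8)
    mm = (win != q5).sum(axis=1)
    for p in np.flatnonzero(mm <= 2):
        if p + 50 <= len(seq):
            cands.add((int(p), "+", int(mm[p])))
    rc = revcomp(read)
    q5m = np.frombuffer(rc[25:].encode(), dtype=np.uint8)
    mm2 = (win != q5m).sum(axis=1)
    for q in np.flatnonzero(mm2 <= 2):
        p = int(q) - 25
        if p >= 0:
            cands.add((p, "-", int(mm2[q])))
    return cands


def naive_triangle_families(edges):
    """Exhaustive 3-clique listing followed by naive repeated merging of
    any two clusters sharing at least two members."""
    vertices = sorted({v for e in edges for v in e})
    eset = {frozenset(e) for e in edges}
    clusters = [
        set(t) for t in combinations(vertices, 3)
        if all(frozenset(p) in eset for p in combinations(t, 2))
    ]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if len(clusters[i] & clusters[j]) >= 2:
                    clusters[i] |= clusters.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted((frozenset(c) for c in clusters), key=sorted)
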