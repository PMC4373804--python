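"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own graph machinery
(pure-Python BFS, double loops) so network tests compare two independent
routes to the same answer.
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd
import pytest

from hapcol import fixture_path, read_incidence
from hapcol.haplotypes import Haplotype, HaplotypeTable


def make_table(seqs, islands=None, counts=None, outgroups=(), ids=None):
    """Build a HaplotypeTable by hand for tests.

    ``islands``: per-haplotype list of island names (default one shared
    island); ``counts``: per-haplotype count on each of its islands
    (default 1 each).
    """
    n = len(seqs)
    ids = ids or [f"x{i + 1}" for i in range(n)]
    islands = islands or [["I1"]] * n
    counts = counts or [[1] * len(isl) for isl in islands]
    all_islands = sorted({i for isl in islands for i in isl})
    mat = pd.DataFrame(0, index=ids, columns=all_islands, dtype=int)
    for hid, isl, cnt in zip(ids, islands, counts):
        for island, c in zip(isl, cnt):
            mat.loc[hid, island] += c
    haps = tuple(Haplotype(hid, s) for hid, s in zip(ids, seqs))
    ogs = tuple(Haplotype(f"og{i + 1}", s) for i, s in enumerate(outgroups))
    return HaplotypeTable(haplotypes=haps, counts=mat,
                          outgroup_haplotypes=ogs)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def bf_hamming(a: str, b: str) -> int:
    """Position-by-position substitution count, unambiguous bases only."""
    return sum(1 for x, y in zip(a, b)
               if x != y and x in "ACGT" and y in "ACGT")


def _bfs_connected(a, b, adjacency) -> bool:
    seen, stack = {a}, [a]
    while stack:
        node = stack.pop()
        if node == b:
            return True
        for nb in adjacency.get(node, ()):
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return False


def oracle_msn_connections(seqs_by_id: dict, max_steps=None) -> set:
    """Minimum-spanning-network connections by the threshold-graph
    characterization: pair (a, b) at distance d is retained iff a and b
    are disconnected in the graph of all pairs at distance < d."""
    ids = sorted(seqs_by_id)
    dist = {(a, b): bf_hamming(seqs_by_id[a], seqs_by_id[b])
            for a, b in combinations(ids, 2)}
    retained = set()
    for (a, b), d in dist.items():
        if d == 0 or (max_steps is not None and d > max_steps):
            continue
        adjacency = {}
        for (u, v), dd in dist.items():
            if 0 < dd < d:
                adjacency.setdefault(u, set()).add(v)
                adjacency.setdefault(v, set()).add(u)
        if not _bfs_connected(a, b, adjacency):
            retained.add((a, b, d))
    return retained


def oracle_on_cycle(graph_edges, node) -> bool:
    """Brute force: node lies on a cycle iff some incident edge can be
    removed while leaving its endpoints connected."""
    adjacency = {}
    for u, v in graph_edges:
        adjacency.setdefault(u, set()).add(v)
        adjacency.setdefault(v, set()).add(u)
    for nb in adjacency.get(node, set()):
        pruned = {k: set(v) for k, v in adjacency.items()}
        pruned[node].discard(nb)
        pruned[nb].discard(node)
        if _bfs_connected(node, nb, pruned):
            return True
    return False


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def xylocopa_table():
    return read_incidence(fixture_path("xylocopa_incidence.tsv"))


@pytest.fixture(scope="session")
def species_summary_path():
    return fixture_path("species_colonization_summary.tsv")


def replica_network_table():
    """Haplotype table whose network mirrors the carpenter-bee structure:
    two interior haplotypes (the first with six connections, on six
    islands with 53 samples) and seven tips, with an outgroup three
    substitutions from the dominant interior haplotype."""
    base = "AAAAAAAAAAAA"

    def mut(seq, *sites):
        s = list(seq)
        for p in sites:
            s[p] = "T"
        return "".join(s)

    c1 = base  # dominant interior
    c2 = mut(base, 5)  # second interior, one step from c1
    tips_c1 = [mut(base, p) for p in range(5)]  # five tips off c1
    tips_c2 = [mut(c2, p) for p in (6, 7)]  # two tips off c2
    outgroup = mut(base, 8, 9, 10)  # three steps from c1
    seqs = [c1, c2] + tips_c1 + tips_c2
    islands = ([["A", "B", "C", "D", "E", "F"], ["A", "B", "G"]]
               + [["A"]] * 5 + [["H"]] * 2)
    counts = [[30, 6, 5, 4, 4, 4], [15, 6, 4]] + [[3]] * 5 + [[4]] * 2
    return make_table(seqs, islands=islands, counts=counts,
                      outgroups=[outgroup])
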