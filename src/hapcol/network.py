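"""Parsimony haplotype network construction and ancestrality ranking.

The network connects observed haplotypes by edges representing single
nucleotide substitutions; a connection of k > 1 substitutions is expanded
into a path through k-1 inferred (unobserved) intermediate nodes, the
"missing haplotypes" of classical statistical-parsimony figures.

Construction is a deterministic minimum-spanning-network (MSN) variant:
candidate haplotype pairs are examined in order of increasing substitution
distance (ties by lexicographic id pair) and a connection is retained when
it joins two previously unconnected groups *or* ties the minimal joining
distance between those groups.  Retained ties create loops, which are
flagged as homoplasy (ambiguity in the mutational path) rather than
arbitrarily broken.

Ancestrality ranking applies the classical coalescent expectations for
identifying old haplotypes: few mutation steps to the outgroup, high
connectivity (interior position), and wide geographic/sample distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError, UnsupportedOperationError
from .haplotypes import HaplotypeTable


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------

def _encode(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences as byte arrays plus an unambiguous-base mask."""
    arr = np.frombuffer("".join(seqs).encode("ascii"),
                        dtype=np.uint8).reshape(len(seqs), -1).copy()
    mask = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    return arr, mask


def pairwise_distances(table: HaplotypeTable,
                       include_outgroups: bool = False) -> pd.DataFrame:
    """Substitution (Hamming) distances between haplotype sequences.

    Only positions where both sequences carry an unambiguous canonical base
    are compared; ambiguity codes and gaps contribute no mismatches.
    """
    haps = list(table.haplotypes)
    if include_outgroups:
        haps += list(table.outgroup_haplotypes)
    if any(h.sequence is None for h in haps):
        raise UnsupportedOperationError(
            "pairwise distances require sequences; this table is "
            "incidence-only")
    ids = [h.haplotype_id for h in haps]
    seqs = [h.sequence for h in haps]
    if len({len(s) for s in seqs}) > 1:
        raise InputError("haplotype sequences have unequal lengths")
    arr, mask = _encode(seqs)
    n = len(seqs)
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        diff = (arr != arr[i]) & mask & mask[i]
        dist[i] = diff.sum(axis=1)
    return pd.DataFrame(dist, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Connection:
    """A retained connection between two observed haplotypes."""
    a: str
    b: str
    steps: int
    intermediates: tuple  # k-1 inferred node ids for a k-step connection


@dataclass
class HaplotypeNetwork:
    """Observed haplotypes plus inferred intermediates, single-step edges."""

    graph: nx.Graph
    connections: tuple  # tuple of Connection
    observed: tuple  # observed haplotype ids, sorted

    @property
    def inferred(self) -> tuple:
        return tuple(n for n, d in self.graph.nodes(data=True)
                     if not d["observed"])

    @property
    def components(self) -> list:
        """Partition of observed haplotypes into connected subgraphs."""
        comps = []
        for comp in nx.connected_components(self.graph):
            obs = sorted(n for n in comp if self.graph.nodes[n]["observed"])
            if obs:
                comps.append(obs)
        return sorted(comps)

    def loop_flags(self) -> dict:
        """node -> True if the node lies on a cycle.

        A node is on a cycle iff one of its incident edges is not a bridge.
        """
        bridges = set(frozenset(e) for e in nx.bridges(self.graph))
        return {
            n: any(frozenset((n, nb)) not in bridges
                   for nb in self.graph.neighbors(n))
            for n in self.graph.nodes
        }

    def degree_observed(self, haplotype_id: str) -> int:
        """Number of distinct observed haplotypes directly connected to
        this one by a retained connection (through any intermediates)."""
        others = set()
        for c in self.connections:
            if c.a == haplotype_id:
                others.add(c.b)
            elif c.b == haplotype_id:
                others.add(c.a)
        return len(others)


def build_network(table: HaplotypeTable, max_steps: int | None = None,
                  include_outgroups: bool = False) -> HaplotypeNetwork:
    """Build the parsimony haplotype network.

    ``max_steps`` is the connection limit in substitutions; ``None`` means
    unlimited (every haplotype set yields a single connected network, the
    appropriate default for a single-species dataset).  The construction is
    invariant to input order: candidates are sorted by (distance,
    lexicographic id pair).
    """
    if table.n_haplotypes == 0:
        raise InputError("cannot build a network from an empty table")
    dist = pairwise_distances(table, include_outgroups=include_outgroups)
    ids = sorted(dist.index)

    graph = nx.Graph()
    for hid in ids:
        graph.add_node(hid, observed=True)

    # Kruskal-like sweep with ties retained.  Union-find state is frozen
    # while a distance level is processed, so every pair at distance d that
    # joins the same two components is kept (-> loops flagged downstream).
    parent = {hid: hid for hid in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    candidates = sorted(
        (int(dist.loc[a, b]), a, b) for a, b in combinations(ids, 2))
    connections: list[Connection] = []
    m_counter = 0
    i = 0
    while i < len(candidates):
        d = candidates[i][0]
        if max_steps is not None and d > max_steps:
            break
        level = []
        while i < len(candidates) and candidates[i][0] == d:
            level.append(candidates[i])
            i += 1
        if d == 0:
            continue  # identical sequences collapse upstream; defensive
        retained = []
        for d_, a, b in level:
            if find(a) != find(b):
                retained.append((a, b))
        for a, b in retained:
            inter = []
            prev = a
            for _ in range(d - 1):
                m_counter += 1
                mid = f"m{m_counter}"
                inter.append(mid)
                graph.add_node(mid, observed=False)
                graph.add_edge(prev, mid)
                prev = mid
            graph.add_edge(prev, b)
            connections.append(Connection(a, b, d, tuple(inter)))
        for a, b in retained:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    return HaplotypeNetwork(graph=graph, connections=tuple(connections),
                            observed=tuple(ids))


# ---------------------------------------------------------------------------
# Classification / lineages
# ---------------------------------------------------------------------------

def classify_nodes(net: HaplotypeNetwork) -> dict:
    """node -> 'isolated' (degree 0), 'tip' (1) or 'interior' (>= 2).

    Degree counts edges toward both observed and inferred neighbours.
    """
    out = {}
    for n in net.graph.nodes:
        deg = net.graph.degree[n]
        out[n] = "isolated" if deg == 0 else "tip" if deg == 1 else "interior"
    return out


def lineages(net: HaplotypeNetwork, cut=None) -> list:
    """Partition observed haplotypes into lineages.

    With ``cut=None`` the partition is the network's connected components;
    with an explicit edge set, the components after removing those edges
    (e.g. severing the long internal branch separating two island groups).
    """
    if cut is None:
        return net.components
    g = net.graph.copy()
    for edge in cut:
        u, v = edge
        if not g.has_edge(u, v):
            raise InputError(f"cut edge {edge!r} not in network")
        g.remove_edge(u, v)
    comps = []
    for comp in nx.connected_components(g):
        obs = sorted(n for n in comp if g.nodes[n]["observed"])
        if obs:
            comps.append(obs)
    return sorted(comps)


# ---------------------------------------------------------------------------
# Ancestrality ranking
# ---------------------------------------------------------------------------

@dataclass
class AncestralityReport:
    """Coalescent-criteria ranking of haplotypes, most ancestral first.

    Criteria, compared lexicographically: fewest mutation steps to the
    nearest outgroup haplotype (raw Hamming distance, defined even when the
    outgroup exceeds the network connection limit); most connections to
    observed haplotypes; widest distribution (islands, then samples).
    """

    frame: pd.DataFrame  # indexed by haplotype_id
    no_outgroup: bool = False

    def rank1(self) -> str:
        return self.frame.sort_values("rank").index[0]


def ancestrality_rank(net: HaplotypeNetwork, table: HaplotypeTable,
                      outgroup_ids=None) -> AncestralityReport:
    """Rank observed ingroup haplotypes by the three ancestrality criteria.

    Without an outgroup the steps criterion is omitted and the report is
    flagged as no-outgroup mode.
    """
    outgroup_ids = set(outgroup_ids or
                       (h.haplotype_id for h in table.outgroup_haplotypes))
    island_sets = table.island_sets()
    sample_counts = table.sample_counts()
    ingroup_ids = [h.haplotype_id for h in table.haplotypes
                   if h.haplotype_id in set(net.observed)]

    no_outgroup = not outgroup_ids
    steps = {}
    if not no_outgroup:
        dist = pairwise_distances(table, include_outgroups=True)
        known = [o for o in sorted(outgroup_ids) if o in dist.index]
        if not known:
            raise InputError(
                f"outgroup ids {sorted(outgroup_ids)} not found in table")
        for hid in ingroup_ids:
            steps[hid] = int(min(dist.loc[hid, o] for o in known))

    rows = []
    for hid in ingroup_ids:
        rows.append({
            "haplotype_id": hid,
            "steps_to_outgroup": None if no_outgroup else steps[hid],
            "degree": net.degree_observed(hid),
            "n_islands": len(island_sets.get(hid, ())),
            "n_samples": sample_counts.get(hid, 0),
        })

    def key(row):
        base = (-row["degree"], -row["n_islands"], -row["n_samples"])
        if not no_outgroup:
            base = (row["steps_to_outgroup"],) + base
        return base

    rows.sort(key=lambda r: (key(r), r["haplotype_id"]))
    keys = [key(r) for r in rows]
    for i, row in enumerate(rows):
        row["rank"] = i + 1
        row["tied"] = keys.count(keys[i]) > 1
    frame = pd.DataFrame(rows).set_index("haplotype_id")
    return AncestralityReport(frame=frame, no_outgroup=no_outgroup)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_edgelist(net: HaplotypeNetwork, path) -> None:
    """Edge list TSV: node_a, node_b, inferred_a, inferred_b (0/1 flags)."""
    rows = []
    for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
        rows.append({
            "node_a": u, "node_b": v,
            "inferred_a": int(not net.graph.nodes[u]["observed"]),
            "inferred_b": int(not net.graph.nodes[v]["observed"]),
        })
    pd.DataFrame(rows, columns=["node_a", "node_b", "inferred_a",
                                "inferred_b"]).to_csv(path, sep="\t",
                                                      index=False)


def write_graphml(net: HaplotypeNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def classification_frame(net: HaplotypeNetwork) -> pd.DataFrame:
    cls = classify_nodes(net)
    loops = net.loop_flags()
    rows = [{"node": n, "observed": int(net.graph.nodes[n]["observed"]),
             "class": cls[n], "on_loop": int(loops[n])}
            for n in sorted(net.graph.nodes)]
    return pd.DataFrame(rows)
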