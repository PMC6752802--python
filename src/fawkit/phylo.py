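"""Distances, neighbor-joining trees, and haplotype networks.

Three pieces of machinery behind the population comparisons:

* pairwise Tamura–Nei (TN93) distances between COIB259 sequences,
  feeding a Saitou–Nei neighbor-joining tree for species identification;
* collapsing of identical aligned haplotypes into counted nodes and a
  minimum-spanning network over mutational steps (an epsilon=0
  statistical-parsimony stand-in: all tied minimum-weight alternatives
  are retained), used to contrast low-diversity interbreeding
  populations (edges of one or two steps) with isolated ones (clouds
  eight or more steps apart);
* great-circle distances between collection sites for the
  distance-from-anchor annotations on network figures.

The TN93 distance uses the empirical base frequencies of each pair and
pairwise deletion of sites with ambiguity codes or gaps.  Mutational
steps between haplotypes count substitutions per column and each
maximal gap run as a single step (an indel is one event regardless of
length).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "TN93SaturationError",
    "tn93_distance",
    "DistanceMatrix",
    "PhyloTree",
    "nj_tree",
    "HaploNode",
    "HaploNetwork",
    "mutational_steps",
    "collapse_haplotypes",
    "build_network",
    "min_separation",
    "haversine_km",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0


class TN93SaturationError(ValueError):
    """The observed divergence is too large for the TN93 correction
    (logarithm of a non-positive argument)."""


def _compare_sites(a: str, b: str) -> tuple[Counter, int, int, int, int]:
    """Pairwise-deletion site comparison: pooled base counts, number of
    compared sites, and counts of A<->G, C<->T and transversion
    differences."""
    pool: Counter = Counter()
    n = p1 = p2 = q = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        pool[x] += 1
        pool[y] += 1
        if x != y:
            pair = frozenset((x, y))
            if pair == frozenset("AG"):
                p1 += 1
            elif pair == frozenset("CT"):
                p2 += 1
            else:
                q += 1
    return pool, n, p1, p2, q


def tn93_distance(seq_a: str, seq_b: str) -> float:
    """Tamura–Nei (1993) distance in substitutions/site.

    Sites where either sequence carries a non-ACGT code are excluded
    pairwise; base frequencies are empirical over the two sequences at
    the compared sites.  Raises :class:`TN93SaturationError` when the
    correction is undefined and :class:`ValueError` on length mismatch
    or when no sites are comparable.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    pool, n, np1, np2, nq = _compare_sites(seq_a, seq_b)
    if n == 0:
        raise ValueError("no comparable (ACGT/ACGT) sites")
    if np1 == np2 == nq == 0:
        return 0.0
    tot = 2 * n
    ga, gc, gg, gt = (pool[b] / tot for b in "ACGT")
    gr, gy = ga + gg, gc + gt
    p1, p2, q = np1 / n, np2 / n, nq / n

    if gr == 0 or gy == 0 or (ga * gg == 0 and p1 > 0) or (gc * gt == 0 and p2 > 0):
        raise TN93SaturationError(
            "degenerate base composition for observed differences"
        )

    k1 = 2 * ga * gg / gr if gr > 0 else 0.0
    k2 = 2 * gt * gc / gy if gy > 0 else 0.0
    k3 = 2 * (gr * gy - ga * gg * gy / gr - gt * gc * gr / gy)

    d = 0.0
    w3 = 1 - q / (2 * gr * gy)
    if w3 <= 0:
        raise TN93SaturationError("transversion saturation")
    if k1 > 0:
        w1 = 1 - p1 / k1 - q / (2 * gr)
        if w1 <= 0:
            raise TN93SaturationError("purine-transition saturation")
        d -= k1 * math.log(w1)
    if k2 > 0:
        w2 = 1 - p2 / k2 - q / (2 * gy)
        if w2 <= 0:
            raise TN93SaturationError("pyrimidine-transition saturation")
        d -= k2 * math.log(w2)
    d -= k3 * math.log(w3)
    return d


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("non-zero diagonal")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")

    @classmethod
    def from_sequences(
        cls,
        seqs: Mapping[str, str] | Sequence[tuple[str, str]],
        metric=tn93_distance,
        deletion: str = "pairwise",
    ) -> "DistanceMatrix":
        """Pairwise distance matrix over labelled sequences.

        ``deletion='complete'`` first drops every column where any
        sequence has a non-ACGT code, then applies the metric;
        ``'pairwise'`` leaves exclusion to the metric per pair.
        """
        items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
        labels = [k for k, _ in items]
        strings = [v.upper() for _, v in items]
        if deletion == "complete" and strings:
            keep = [
                i
                for i in range(len(strings[0]))
                if all(s[i] in "ACGT" for s in strings)
            ]
            strings = ["".join(s[i] for i in keep) for s in strings]
        elif deletion != "pairwise":
            raise ValueError(f"unknown deletion mode: {deletion}")
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = metric(strings[i], strings[j])
        return cls(labels, d)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(path)


class PhyloTree:
    """Unrooted tree with non-negative branch lengths over leaf labels."""

    def __init__(self, graph: nx.Graph, leaves: Sequence[str]):
        self.graph = graph
        self.leaves = list(leaves)

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths (the tree metric)."""
        n = len(self.leaves)
        d = np.zeros((n, n))
        lengths = dict(
            nx.all_pairs_dijkstra_path_length(self.graph, weight="length")
        )
        for i, a in enumerate(self.leaves):
            for j, b in enumerate(self.leaves):
                if i < j:
                    d[i, j] = d[j, i] = lengths[a][b]
        return DistanceMatrix(self.leaves, d)

    def to_newick(self, fmt: str = "%.10g") -> str:
        """Serialize as Newick, rooted for display at an arbitrary
        internal node (the unrooted topology is unchanged)."""
        internal = [v for v in self.graph if v not in set(self.leaves)]
        root = internal[0] if internal else self.leaves[0]

        def render(node, parent) -> str:
            children = [w for w in self.graph[node] if w != parent]
            if not children:
                return str(node)
            inner = ",".join(
                f"{render(c, node)}:{fmt % self.graph[node][c]['length']}"
                for c in children
            )
            return f"({inner})"

        return render(root, None) + ";"


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor-joining.

    Deterministic: ties in the Q-criterion are broken by the lowest
    (row, column) index pair in the current node ordering.  Negative
    branch-length estimates are clamped to zero with the deficit moved
    to the sibling branch of the join, preserving the joined pair's
    path length.  On an additive input matrix the output tree's
    path-length matrix reproduces the input.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor-joining requires at least 3 taxa")
    if len(set(matrix.labels)) != n:
        raise ValueError("duplicate labels")

    g = nx.Graph()
    active: list[object] = list(matrix.labels)
    d = {
        (a, b): matrix.d[i, j]
        for i, a in enumerate(matrix.labels)
        for j, b in enumerate(matrix.labels)
    }

    def dist(a, b):
        return 0.0 if a == b else d[(a, b)]

    next_internal = 0
    while len(active) > 2:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active) for a in active}
        best, best_q = None, math.inf
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                qv = (m - 2) * dist(a, b) - r[a] - r[b]
                if qv < best_q - 1e-15:
                    best_q, best = qv, (i, j)
        i, j = best
        a, b = active[i], active[j]
        u = f"_nj{next_internal}"
        next_internal += 1
        la = 0.5 * dist(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        lb = dist(a, b) - la
        # clamp negatives, shifting the deficit to the sibling branch
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        g.add_edge(a, u, length=max(la, 0.0))
        g.add_edge(b, u, length=max(lb, 0.0))
        for c in active:
            if c is a or c is b:
                continue
            d[(u, c)] = d[(c, u)] = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
        active = [c for c in active if c is not a and c is not b] + [u]

    a, b = active
    g.add_edge(a, b, length=max(dist(a, b), 0.0))
    return PhyloTree(g, matrix.labels)


# ---------------------------------------------------------------------------
# haplotype networks


@dataclass
class HaploNode:
    """A unique haplotype: its sequence, total specimen count, and the
    per-site breakdown of that count."""

    sequence: str
    count: int
    site_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class HaploNetwork:
    """Collapsed haplotypes joined by mutational-step edges.

    ``graph`` nodes are indices into ``nodes``; every edge carries
    ``steps`` and ``in_mst`` attributes.  Removing the edges with
    ``in_mst=False`` leaves a spanning tree.
    """

    nodes: list[HaploNode]
    graph: nx.Graph

    def edges(self) -> list[tuple[int, int, int]]:
        return sorted(
            (min(u, v), max(u, v), data["steps"])
            for u, v, data in self.graph.edges(data=True)
        )


def mutational_steps(a: str, b: str) -> int:
    """Mutational steps between two aligned haplotypes: one step per
    substituted column plus one step per maximal run of gap columns
    (an indel of any length is a single event)."""
    if len(a) != len(b):
        raise ValueError("aligned haplotypes must have equal length")
    steps = 0
    in_gap_run = False
    for x, y in zip(a.upper(), b.upper()):
        gap = (x == "-") != (y == "-")
        if gap:
            if not in_gap_run:
                steps += 1
            in_gap_run = True
            continue
        in_gap_run = False
        if x == "-" and y == "-":
            continue
        if x != y:
            steps += 1
    return steps


def collapse_haplotypes(
    sequences: Mapping[str, str],
    specimen_to_site: Mapping[str, str],
) -> list[HaploNode]:
    """Collapse identical aligned sequences into counted nodes.

    ``sequences`` maps specimen id to its aligned haplotype (records
    flagged as frameshift heterozygotes must already be excluded).
    Nodes are ordered by count descending, then sequence — a
    determinism contract for downstream exports.
    """
    buckets: dict[str, Counter] = {}
    for spec_id, seq in sequences.items():
        site = specimen_to_site[spec_id]
        buckets.setdefault(seq.upper(), Counter())[site] += 1
    nodes = [
        HaploNode(seq, sum(sites.values()), dict(sorted(sites.items())))
        for seq, sites in buckets.items()
    ]
    nodes.sort(key=lambda nd: (-nd.count, nd.sequence))
    return nodes


def build_network(nodes: Sequence[HaploNode]) -> HaploNetwork:
    """Minimum-spanning network over mutational steps (epsilon = 0).

    Kruskal grouped by weight level: at each successive step count,
    every edge at that count joining components that were distinct when
    the level began is added, so all tied minimum alternatives are
    retained (three haplotypes pairwise one step apart keep the
    triangle).  The first edge accepted per component merge is marked
    ``in_mst`` so that an actual spanning tree can be recovered.
    """
    if not nodes:
        raise ValueError("network requires at least one haplotype")
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    n = len(nodes)
    if n == 1:
        return HaploNetwork(list(nodes), g)

    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            edges.append((mutational_steps(nodes[i].sequence, nodes[j].sequence), i, j))
    edges.sort()

    parent = list(range(n))
    mst_parent = list(range(n))

    def find(par, x):
        while par[x] != x:
            par[x] = par[par[x]]
            x = par[x]
        return x

    k = 0
    n_components = n
    while k < len(edges) and n_components > 1:
        w = edges[k][0]
        level = []
        while k < len(edges) and edges[k][0] == w:
            level.append(edges[k])
            k += 1
        # components as of the start of this weight level: every edge at
        # this weight joining them is a tied minimum and is retained
        comp_at_start = {i: find(parent, i) for i in range(n)}
        for w_, i, j in level:
            if comp_at_start[i] == comp_at_start[j]:
                continue
            ri, rj = find(mst_parent, i), find(mst_parent, j)
            in_mst = ri != rj
            if in_mst:
                mst_parent[ri] = rj
            g.add_edge(i, j, steps=w_, in_mst=in_mst)
        for w_, i, j in level:
            ri, rj = find(parent, i), find(parent, j)
            if ri != rj:
                parent[ri] = rj
                n_components -= 1
    return HaploNetwork(list(nodes), g)


def min_separation(
    network: HaploNetwork,
    sites_a: Iterable[str],
    sites_b: Iterable[str],
) -> int:
    """Minimum mutational steps between the haplotypes private to one
    site partition and those present in another.

    A haplotype observed in both partitions makes the separation 0.
    Raises on an empty partition (including the degenerate case of a
    partition with no private haplotypes).
    """
    set_a, set_b = set(sites_a), set(sites_b)
    if not set_a or not set_b:
        raise ValueError("both site partitions must be non-empty")
    if set_a == set_b:
        raise ValueError("degenerate partition: the two site sets are identical")
    in_a = [nd for nd in network.nodes if set_a & nd.site_counts.keys()]
    in_b = [nd for nd in network.nodes if set_b & nd.site_counts.keys()]
    if not in_a or not in_b:
        raise ValueError("a partition contains no haplotypes")
    shared = {id(nd) for nd in in_a} & {id(nd) for nd in in_b}
    if shared:
        return 0
    private_a = [nd for nd in in_a if not (nd.site_counts.keys() - set_a)]
    if not private_a:
        raise ValueError("partition 1 has no private haplotypes")
    return min(
        mutational_steps(x.sequence, y.sequence) for x in private_a for y in in_b
    )


def network_to_edgelist_frame(network: HaploNetwork):
    """Edge list as a DataFrame (hap indices, steps, MST membership)."""
    import pandas as pd

    rows = [
        {"hap_a": min(u, v), "hap_b": max(u, v),
         "steps": data["steps"], "in_mst": data["in_mst"]}
        for u, v, data in network.graph.edges(data=True)
    ]
    return (
        pd.DataFrame(rows, columns=["hap_a", "hap_b", "steps", "in_mst"])
        .sort_values(["hap_a", "hap_b"])
        .reset_index(drop=True)
    )


def network_to_nexus(network: HaploNetwork) -> str:
    """NEXUS export (taxa + characters + a traits block of per-site
    counts) in the dialect popular network-drawing tools consume."""
    names = [f"Hap_{i}" for i in range(len(network.nodes))]
    sites = sorted({s for nd in network.nodes for s in nd.site_counts})
    L = len(network.nodes[0].sequence) if network.nodes else 0
    out = ["#NEXUS", "", "BEGIN TAXA;", f"DIMENSIONS NTAX={len(names)};",
           "TAXLABELS " + " ".join(names) + ";", "END;", "",
           "BEGIN CHARACTERS;",
           f"DIMENSIONS NCHAR={L};",
           "FORMAT DATATYPE=DNA MISSING=N GAP=-;", "MATRIX"]
    for name, nd in zip(names, network.nodes):
        out.append(f"{name} {nd.sequence}")
    out += [";", "END;", "", "BEGIN TRAITS;",
            f"Dimensions NTRAITS={len(sites)};",
            "Format labels=yes missing=? separator=Comma;",
            "TraitLabels " + " ".join(sites) + ";", "Matrix"]
    for name, nd in zip(names, network.nodes):
        counts = ",".join(str(nd.site_counts.get(s, 0)) for s in sites)
        out.append(f"{name} {counts}")
    out += [";", "END;", ""]
    return "\n".join(out)


def haversine_km(site_a, site_b, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance between two points (CollectionSite objects
    or ``(lat, lon)`` pairs, decimal degrees) on a sphere of the given
    radius."""

    def coords(s):
        if hasattr(s, "latitude"):
            return float(s.latitude), float(s.longitude)
        lat, lon = s
        return float(lat), float(lon)

    lat1, lon1 = coords(site_a)
    lat2, lon2 = coords(site_b)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * radius_km * math.asin(min(1.0, math.sqrt(h)))
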