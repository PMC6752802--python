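"""Independent oracle implementations used by the test suite.

These deliberately re-derive expected values through code paths
separate from the package implementation: the TN93 closed form coded
directly from the published formula with array-based counting, and
additive distance matrices built from explicit random trees.
"""

import math

import numpy as np


def tn93_oracle(a: str, b: str) -> float:
    """Tamura-Nei 1993 distance, straight from the closed form."""
    xs = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    ys = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    bases = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)
    acgt = np.isin(xs, bases) & np.isin(ys, bases)
    xs, ys = xs[acgt], ys[acgt]
    n = len(xs)
    freq = {c: ((xs == c).sum() + (ys == c).sum()) / (2 * n) for c in bases}
    gA, gC, gG, gT = (freq[ord(c)] for c in "ACGT")
    gR, gY = gA + gG, gC + gT
    diff = xs != ys
    purines = bases[[0, 2]]
    pyrimidines = bases[[1, 3]]
    is_ag = diff & np.isin(xs, purines) & np.isin(ys, purines)
    is_ct = diff & np.isin(xs, pyrimidines) & np.isin(ys, pyrimidines)
    P1 = is_ag.sum() / n
    P2 = is_ct.sum() / n
    Q = (diff & ~is_ag & ~is_ct).sum() / n
    if P1 == P2 == Q == 0:
        return 0.0
    term1 = (
        -2 * gA * gG / gR * math.log(1 - gR * P1 / (2 * gA * gG) - Q / (2 * gR))
        if gA * gG > 0
        else 0.0
    )
    term2 = (
        -2 * gT * gC / gY * math.log(1 - gY * P2 / (2 * gT * gC) - Q / (2 * gY))
        if gT * gC > 0
        else 0.0
    )
    term3 = -2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY) * math.log(
        1 - Q / (2 * gR * gY)
    )
    return term1 + term2 + term3


def random_sequence_pair(rng, length=259, n_subs=10):
    a = rng.integers(0, 4, size=length)
    b = a.copy()
    if n_subs:
        pos = rng.choice(length, size=n_subs, replace=False)
        b[pos] = (b[pos] + rng.integers(1, 4, size=n_subs)) % 4
    to_s = lambda arr: "".join("ACGT"[i] for i in arr)
    return to_s(a), to_s(b)


def random_additive_matrix(rng, n_taxa):
    """Random binary tree with uniform branch lengths -> its path-length
    matrix (additive by construction)."""
    import networkx as nx

    from fawkit.phylo import DistanceMatrix

    g = nx.Graph()
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = list(labels)
    nxt = 0
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        u = f"i{nxt}"
        nxt += 1
        g.add_edge(nodes[i], u, length=rng.uniform(0.1, 2.0))
        g.add_edge(nodes[j], u, length=rng.uniform(0.1, 2.0))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [u]
    g.add_edge(nodes[0], nodes[1], length=rng.uniform(0.1, 2.0))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    d = np.array(
        [[lengths[a][b] if a != b else 0.0 for b in labels] for a in labels]
    )
    return DistanceMatrix(labels, d)
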