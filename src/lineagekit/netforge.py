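"""Median-joining haplotype networks and small-scale maximum parsimony.

Median-joining (MJ) networks combine the minimum spanning network (the union
of all minimum spanning trees, optionally relaxed by a tolerance ``epsilon``)
with inferred "median" (Steiner) haplotypes: for triplets of mutually close
nodes the per-site majority consensus is added when it shortens the network.
The construction here follows the classic MJ iteration — relaxed MSN, median
addition within ``epsilon`` of the minimal connection cost, pruning of
obsolete medians — and is deterministic under input reordering.

The parsimony half provides weighted Fitch lengths on fixed topologies and
an exhaustive search over all unrooted binary topologies for desk-scale taxon
counts, plus an exact minimum Steiner-tree solver (Dreyfus-Wagner dynamic
programme over the site-state product graph) usable as an independent check
of network length on tiny inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import networkx as nx

from .mtio import (HaplotypeRecord, HypervariableExclusionSet,
                   filter_hypervariable)

MAX_TAXA = 2000


class NetworkSizeError(ValueError):
    pass


# --------------------------------------------------------------------------
# Character matrix
# --------------------------------------------------------------------------

@dataclass
class CharacterMatrix:
    """Taxa x sites discrete states with per-site weights.

    ``positions`` traces each column back to an rCRS coordinate (or any
    stable site label); ``multiplicities`` and ``groups`` carry the collapse
    bookkeeping from :func:`condense`.
    """

    taxa: list
    states: np.ndarray          # (n_taxa, n_sites) object/int array
    positions: list
    weights: np.ndarray = None  # per-site, default 1
    multiplicities: list = None
    groups: list = None         # per-taxon dict group -> count

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=object)
        if self.states.ndim == 1:
            self.states = self.states.reshape(len(self.taxa), -1)
        if self.weights is None:
            self.weights = np.ones(self.states.shape[1])
        self.weights = np.asarray(self.weights, dtype=float)
        if self.multiplicities is None:
            self.multiplicities = [1] * len(self.taxa)
        if self.groups is None:
            self.groups = [{} for _ in self.taxa]

    @property
    def n_taxa(self):
        return len(self.taxa)

    @property
    def n_sites(self):
        return self.states.shape[1]

    def distance(self, u, v) -> float:
        """Weighted Hamming distance between two state vectors."""
        u = np.asarray(u, dtype=object)
        v = np.asarray(v, dtype=object)
        return float(np.sum(self.weights[np.nonzero(u != v)[0]]))


def condense(haplotypes: Sequence[HaplotypeRecord],
             excl: Optional[HypervariableExclusionSet] = None,
             ) -> CharacterMatrix:
    """Collapse identical haplotypes and drop invariant sites.

    Sites are the union of (filtered) variant identities over the shared
    covered-range overlap; states are presence/absence of each variant.
    """
    if not haplotypes:
        raise ValueError("no haplotypes")
    filtered = [set(filter_hypervariable(h.variants, excl))
                for h in haplotypes]

    overlap = _coverage_mask(haplotypes[0].covered_range)
    for h in haplotypes[1:]:
        overlap &= _coverage_mask(h.covered_range)
    if not overlap.any():
        raise ValueError("haplotype records share no covered range")

    def in_overlap(pos):
        return bool(overlap[pos - 1])

    site_vars = sorted(
        {v for vs in filtered for v in vs if in_overlap(v.position)},
        key=lambda v: (v.position, v.kind, str(v.alt), v.is_back_mutation))

    rows: dict[tuple, dict] = {}
    order = []
    for h, vs in zip(haplotypes, filtered):
        key = tuple(1 if v in vs else 0 for v in site_vars)
        if key not in rows:
            rows[key] = {"label": h.sample_id, "mult": 0, "groups": {}}
            order.append(key)
        rows[key]["mult"] += 1
        g = h.ethnic_group or h.population
        rows[key]["groups"][g] = rows[key]["groups"].get(g, 0) + 1

    keys = order
    states = np.array([list(k) for k in keys], dtype=object)
    if states.size == 0:
        states = states.reshape(len(keys), 0)
    # drop invariant sites after collapsing
    keep = [j for j in range(states.shape[1])
            if len({states[i, j] for i in range(states.shape[0])}) > 1]
    states = states[:, keep] if keys else states
    site_vars = [site_vars[j] for j in keep]
    return CharacterMatrix(
        taxa=[rows[k]["label"] for k in keys],
        states=states,
        positions=[v.position for v in site_vars],
        multiplicities=[rows[k]["mult"] for k in keys],
        groups=[rows[k]["groups"] for k in keys],
    )


def _coverage_mask(intervals) -> np.ndarray:
    from .mtio import RCRS_LENGTH
    mask = np.zeros(RCRS_LENGTH, dtype=bool)
    for lo, hi in intervals:
        if lo <= hi:
            mask[lo - 1:hi] = True
        else:  # wraps through 16569
            mask[lo - 1:] = True
            mask[:hi] = True
    return mask


# --------------------------------------------------------------------------
# Median-joining network
# --------------------------------------------------------------------------

@dataclass
class HapGraph:
    """A haplotype network: observed nodes plus inferred medians."""

    graph: nx.Graph                # node attrs: states, multiplicity, groups,
    epsilon: int                   # is_median; edge attr: positions (tuple)
    total_length: float            # MST length over the final node set

    @property
    def median_nodes(self):
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    def to_gml(self, path):
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(n, multiplicity=int(d["multiplicity"]),
                       is_median=int(d["is_median"]),
                       states="".join(str(s) for s in d["states"]),
                       groups=";".join(f"{k}:{v}"
                                       for k, v in sorted(d["groups"].items())))
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, positions=";".join(str(p)
                                                for p in d["positions"]))
        nx.write_gml(g, path)

    def write_edges_tsv(self, path_or_buf):
        close = isinstance(path_or_buf, str)
        fh = open(path_or_buf, "w") if close else path_or_buf
        try:
            fh.write("node1\tnode2\tpositions\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t"
                         + ";".join(str(p) for p in d["positions"]) + "\n")
        finally:
            if close:
                fh.close()

    def write_nodes_tsv(self, path_or_buf):
        close = isinstance(path_or_buf, str)
        fh = open(path_or_buf, "w") if close else path_or_buf
        try:
            fh.write("node\tmultiplicity\tis_median\tgroups\n")
            for n, d in sorted(self.graph.nodes(data=True)):
                groups = ";".join(f"{k}:{v}"
                                  for k, v in sorted(d["groups"].items()))
                fh.write(f"{n}\t{d['multiplicity']}\t"
                         f"{int(d['is_median'])}\t{groups}\n")
        finally:
            if close:
                fh.close()


def _pairwise_distances(vectors, weights):
    n = len(vectors)
    D = np.zeros((n, n))
    arr = np.array([list(v) for v in vectors], dtype=object)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.sum(weights[np.nonzero(arr[i] != arr[j])[0]]))
            D[i, j] = D[j, i] = d
    return D

def _minimax(D):
    """Minimax (bottleneck) distances via Floyd-Warshall-style DP."""
    M = D.copy()
    n = len(M)
    for k in range(n):
        M = np.minimum(M, np.maximum.outer(M[:, k], M[k, :]))
    return M


def _msn_links(D, epsilon):
    """Links of the epsilon-relaxed minimum spanning network.

    A pair is linked iff its direct distance is within ``epsilon`` of the
    bottleneck (minimax) cost of connecting it; at ``epsilon = 0`` this is
    exactly the union of all minimum spanning trees.
    """
    M = _minimax(D)
    n = len(D)
    return [(i, j) for i in range(n) for j in range(i + 1, n)
            if D[i, j] <= M[i, j] + epsilon + 1e-9]


def _medians(u, v, w):
    """Per-site majority consensus vectors of a triplet.

    Sites where all three states differ (multistate ties) branch into all
    three choices; combinations are capped to keep the search desk-scale.
    """
    choices = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            choices.append((a,))
        elif b == c:
            choices.append((b,))
        else:
            choices.append(tuple(dict.fromkeys((a, b, c))))
    total = 1
    for ch in choices:
        total *= len(ch)
        if total > 4096:
            raise NetworkSizeError("too many multistate median ties")
    return [tuple(m) for m in itertools.product(*choices)]


def mj_network(matrix: CharacterMatrix, epsilon: int = 0) -> HapGraph:
    """Build a median-joining network from a condensed character matrix."""
    if matrix.n_taxa > MAX_TAXA:
        raise NetworkSizeError(
            f"{matrix.n_taxa} taxa exceeds the {MAX_TAXA}-taxon guard")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    weights = matrix.weights

    # canonical input order: by state vector, so the run is order-stable
    order = sorted(range(matrix.n_taxa),
                   key=lambda i: tuple(str(s) for s in matrix.states[i]))
    vectors = [tuple(matrix.states[i]) for i in order]
    labels = [matrix.taxa[i] for i in order]
    mults = [matrix.multiplicities[i] for i in order]
    groups = [dict(matrix.groups[i]) for i in order]
    observed = set(vectors)

    median_counter = itertools.count(1)
    names = {vec: lab for vec, lab in zip(vectors, labels)}

    for _ in range(200):  # convergence guard; tiny inputs converge fast
        D = _pairwise_distances(vectors, weights)
        links = _msn_links(D, epsilon)
        linked = set(links)
        n = len(vectors)
        candidates = {}
        for i, j, k in itertools.combinations(range(n), 3):
            present = sum(p in linked for p in
                          ((i, j), (i, k), (j, k)))
            if present < 2:
                continue
            for m in _medians(vectors[i], vectors[j], vectors[k]):
                if m in names:
                    continue
                ma = np.asarray(m, dtype=object)
                cost = sum(
                    float(np.sum(weights[np.nonzero(
                        ma != np.asarray(vectors[t], dtype=object))[0]]))
                    for t in (i, j, k))
                if m not in candidates or cost < candidates[m]:
                    candidates[m] = cost
        if not candidates:
            break
        lam_min = min(candidates.values())
        new = sorted([m for m, c in candidates.items()
                      if c <= lam_min + epsilon + 1e-9])
        for m in new:
            names[m] = f"mv{next(median_counter)}"
            vectors.append(m)
            mults.append(0)
            groups.append({})

    # prune medians whose removal does not lengthen the network
    def mst_length(vecs):
        if len(vecs) == 1:
            return 0.0
        D = _pairwise_distances(vecs, weights)
        T = nx.minimum_spanning_tree(nx.from_numpy_array(D))
        return float(sum(d["weight"] for _, _, d in T.edges(data=True)))

    changed = True
    while changed:
        changed = False
        base = mst_length(vectors)
        for idx in range(len(vectors) - 1, -1, -1):
            if vectors[idx] in observed:
                continue
            trial = vectors[:idx] + vectors[idx + 1:]
            if mst_length(trial) <= base + 1e-9:
                del vectors[idx], mults[idx], groups[idx]
                changed = True
                break

    # final graph: relaxed MSN over the surviving node set
    D = _pairwise_distances(vectors, weights)
    links = _msn_links(D, epsilon)
    g = nx.Graph()
    for vec, mult, grp in zip(vectors, mults, groups):
        g.add_node(names[vec], states=vec, multiplicity=mult, groups=grp,
                   is_median=vec not in observed)
    for i, j in links:
        u, v = np.asarray(vectors[i], dtype=object), \
               np.asarray(vectors[j], dtype=object)
        diff = tuple(matrix.positions[s] for s in np.nonzero(u != v)[0])
        g.add_edge(names[vectors[i]], names[vectors[j]], positions=diff,
                   weight=D[i, j])
    return HapGraph(graph=g, epsilon=epsilon, total_length=mst_length(vectors))


# --------------------------------------------------------------------------
# Exact Steiner-tree reference (desk scale)
# --------------------------------------------------------------------------

def steiner_minimum_length(matrix: CharacterMatrix,
                           max_graph_nodes: int = 20000) -> float:
    """Exact minimum Steiner-tree length over the site-state product graph.

    Terminals are the observed haplotypes; candidate Steiner points are all
    combinations of observed per-site states, adjacent when they differ at a
    single site (edge weight = that site's weight).  Solved by the
    Dreyfus-Wagner dynamic programme on the metric closure (weighted Hamming
    distance), exact but exponential in terminal count: a reference for tiny
    inputs, not a construction algorithm.
    """
    per_site = [tuple(sorted({str(matrix.states[i, j])
                              for i in range(matrix.n_taxa)}))
                for j in range(matrix.n_sites)]
    total = 1
    for ch in per_site:
        total *= len(ch)
        if total > max_graph_nodes:
            raise NetworkSizeError("state-product graph too large")
    nodes = [tuple(c) for c in itertools.product(*per_site)]
    index = {v: i for i, v in enumerate(nodes)}
    arr = np.array([list(v) for v in nodes], dtype=object)
    w = matrix.weights
    V = len(nodes)
    dist = np.zeros((V, V))
    for i in range(V):
        neq = arr != arr[i]
        dist[i] = neq @ w

    terminals = sorted({index[tuple(str(s) for s in matrix.states[i])]
                        for i in range(matrix.n_taxa)})
    k = len(terminals)
    if k <= 1:
        return 0.0
    full = (1 << k) - 1
    INF = np.inf
    dp = np.full((full + 1, V), INF)
    for t, term in enumerate(terminals):
        dp[1 << t] = dist[term]
    for S in range(1, full + 1):
        if S & (S - 1) == 0:
            continue
        best = np.full(V, INF)
        sub = (S - 1) & S
        while sub:
            comp = S ^ sub
            if sub < comp:  # each split once
                best = np.minimum(best, dp[sub] + dp[comp])
            sub = (sub - 1) & S
        # relax through the metric closure
        dp[S] = np.min(best[None, :] + dist, axis=1)
    return float(dp[full].min())


# --------------------------------------------------------------------------
# Parsimony
# --------------------------------------------------------------------------

def fitch_length(tree, matrix: CharacterMatrix) -> float:
    """Weighted Fitch parsimony length of a (rooted or unrooted) topology.

    ``tree`` is a nested tuple of taxon labels, e.g. ``(("a", "b"),
    ("c", "d"))``; the score is invariant under root placement.
    """
    leaves = _tree_leaves(tree)
    if set(leaves) != set(matrix.taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    row = {t: i for i, t in enumerate(matrix.taxa)}
    total = 0.0
    for j in range(matrix.n_sites):
        changes = 0

        def fitch(node):
            nonlocal changes
            if not isinstance(node, tuple):
                return {matrix.states[row[node], j]}
            sets = [fitch(child) for child in node]
            acc = sets[0]
            for s in sets[1:]:
                inter = acc & s
                if inter:
                    acc = inter
                else:
                    acc = acc | s
                    changes += 1
            return acc

        fitch(tree)
        total += changes * matrix.weights[j]
    return total


def _tree_leaves(tree):
    if not isinstance(tree, tuple):
        return [tree]
    out = []
    for child in tree:
        out.extend(_tree_leaves(child))
    return out


def _rooted_topologies(labels):
    if len(labels) == 1:
        yield labels[0]
        return
    for t in _rooted_topologies(labels[:-1]):
        yield from _insert_everywhere(t, labels[-1])


def _insert_everywhere(t, x):
    yield (t, x)
    if isinstance(t, tuple):
        a, b = t
        for na in _insert_everywhere(a, x):
            yield (na, b)
        for nb in _insert_everywhere(b, x):
            yield (a, nb)


def enumerate_topologies(taxa):
    """All unrooted binary topologies, as rooted tuples anchored on the
    first taxon ((2n-5)!! of them)."""
    taxa = list(taxa)
    if len(taxa) < 3:
        yield tuple(taxa) if len(taxa) > 1 else taxa[0]
        return
    for rest in _rooted_topologies(taxa[1:]):
        yield (taxa[0], rest)


def _clusters(tree, out):
    if not isinstance(tree, tuple):
        return frozenset([tree])
    acc = frozenset()
    for child in tree:
        acc |= _clusters(child, out)
    out.add(acc)
    return acc


def _respects_constraint(tree, constraint):
    """Each group of >=2 taxa must form one side of a split of the tree."""
    leaves = frozenset(_tree_leaves(tree))
    clusters = set()
    _clusters(tree, clusters)
    splits = {c for c in clusters} | {leaves - c for c in clusters}
    by_group = {}
    for taxon, grp in constraint.items():
        by_group.setdefault(grp, set()).add(taxon)
    return all(frozenset(members) in splits
               for members in by_group.values() if len(members) > 1)


def demo_toys() -> list[CharacterMatrix]:
    """Bundled small haplotype toys (<= 5 haplotypes, <= 8 sites).

    Desk-scale inputs for exercising the median-joining construction against
    the exact Steiner reference: the classic three-haplotype triangle (one
    median), chains, a star, a recurrent-mutation rectangle, and a mixed
    five-haplotype case.
    """
    def mk(name_rows, n_sites):
        taxa = [f"{i}" for i in range(len(name_rows))]
        states = np.array(name_rows, dtype=object)
        return CharacterMatrix(taxa=taxa, states=states,
                               positions=list(range(1, n_sites + 1)))

    return [
        mk([[1, 1, 0], [0, 1, 1], [1, 0, 1]], 3),                  # triangle
        mk([[0, 0], [1, 0]], 2),                                   # pair
        mk([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]], 3),       # chain
        mk([[0, 0, 0, 0], [1, 0, 0, 0], [0, 1, 0, 0],
            [0, 0, 1, 0], [0, 0, 0, 1]], 4),                       # star
        mk([[0, 0], [0, 1], [1, 0], [1, 1]], 2),                   # rectangle
        mk([[0, 0, 0, 0, 0, 0], [1, 1, 0, 0, 0, 0],
            [0, 0, 1, 1, 0, 0], [1, 1, 1, 1, 0, 0],
            [0, 0, 0, 0, 1, 1]], 6),                               # mixed
    ]


def mp_search(matrix: CharacterMatrix, max_taxa: int = 9,
              constraint: Optional[dict] = None):
    """Exhaustive maximum-parsimony search over unrooted topologies.

    Returns ``(best_trees, best_length)`` with every minimum-length topology
    included.  ``constraint`` maps taxa to named groups (e.g. haplogroup
    assignments) that must be monophyletic, restricting the search.
    """
    if matrix.n_taxa > max_taxa:
        raise NetworkSizeError(
            f"{matrix.n_taxa} taxa exceeds the exhaustive bound {max_taxa}; "
            "use the constrained mode or a smaller clade")
    best, best_len = [], np.inf
    for tree in enumerate_topologies(matrix.taxa):
        if constraint and not _respects_constraint(tree, constraint):
            continue
        length = fitch_length(tree, matrix)
        if length < best_len - 1e-9:
            best, best_len = [tree], length
        elif length <= best_len + 1e-9:
            best.append(tree)
    return best, float(best_len)
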