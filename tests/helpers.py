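"""Independent oracles and small builders used across the test suite.

Everything here is deliberately written from first principles (pure
Python, no reuse of the package's own code paths) so that agreement with
the implementation is meaningful.
"""

from __future__ import annotations

import math
import random

from ednascreen.io_formats import ReferenceRecord


# ---------------------------------------------------------------------------
# brute-force semi-global alignment oracle


def semiglobal_edit_distance(seq_a: str, seq_b: str) -> int:
    """Minimum substitutions+gaps placing the shorter sequence within the
    longer without end penalties. Full dynamic programming over all
    placements; ambiguous bases never match."""
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) == len(b) and a != b:
        return min(_semiglobal(a, b), _semiglobal(b, a))
    contained, container = (a, b) if len(a) <= len(b) else (b, a)
    return _semiglobal(contained, container)


def _semiglobal(contained: str, container: str) -> int:
    m, n = len(contained), len(container)
    prev = [0] * (n + 1)  # free leading gap in the container
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        ci = contained[i - 1]
        for j in range(1, n + 1):
            cj = container[j - 1]
            cost = 0 if (ci == cj and ci in "ACGT") else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)  # free trailing gap in the container


# ---------------------------------------------------------------------------
# Spearman oracle: average ranks + product-moment formula


def average_ranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # 1-based average rank of the tie block
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return math.nan
    return sxy / math.sqrt(sxx * syy)


def spearman_oracle(x, y) -> float:
    return pearson(average_ranks(x), average_ranks(y))


# ---------------------------------------------------------------------------
# random additive trees (for neighbor-joining recovery checks)


def random_additive_tree(n_leaves: int, rng: random.Random):
    """Random unrooted binary tree with positive branch lengths.

    Returns (adjacency, leaves): adjacency maps node -> {neighbour:
    length}; leaves are named L0..L{n-1}.
    """
    def new_len() -> float:
        return round(rng.uniform(0.05, 1.0), 4)

    adj: dict[str, dict[str, float]] = {}

    def add_edge(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def drop_edge(u, v):
        del adj[u][v]
        del adj[v][u]

    add_edge("L0", "X0", new_len())
    add_edge("L1", "X0", new_len())
    add_edge("L2", "X0", new_len())
    internal = 1
    for i in range(3, n_leaves):
        edges = sorted((u, v) for u in adj for v in adj[u] if u < v)
        u, v = edges[rng.randrange(len(edges))]
        w = adj[u][v]
        mid = f"X{internal}"
        internal += 1
        drop_edge(u, v)
        split = rng.uniform(0.2, 0.8) * w
        add_edge(u, mid, round(split, 6))
        add_edge(mid, v, round(w - split, 6))
        add_edge(mid, f"L{i}", new_len())
    leaves = [f"L{i}" for i in range(n_leaves)]
    return adj, leaves


def tree_distances(adj, leaves) -> dict[tuple[str, str], float]:
    dist = {}
    for src in leaves:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for dst in leaves:
            dist[(src, dst)] = seen[dst]
    return dist


def splits_of_adjacency(adj, leaves) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree given as adjacency,
    each normalised to the side not containing the first leaf."""
    anchor = leaves[0]
    splits = set()
    for u in adj:
        for v in adj[u]:
            if u > v:
                continue
            side = _leaves_beyond(adj, u, v, set(leaves))
            if anchor in side:
                side = set(leaves) - side
            if 1 < len(side) < len(leaves) - 1:
                splits.add(frozenset(side))
    return splits


def _leaves_beyond(adj, u, v, leaves) -> set:
    """Leaves on v's side of edge (u, v)."""
    seen = {u, v}
    stack = [v]
    found = set()
    while stack:
        x = stack.pop()
        if x in leaves:
            found.add(x)
        for y in adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return found


def splits_of_newick(newick: str, leaf_names) -> set[frozenset]:
    """Bipartitions of a Newick tree, normalised like
    :func:`splits_of_adjacency` (anchored at the first leaf name)."""
    import io

    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    leaves = set(leaf_names)
    anchor = sorted(leaves)[0] if leaf_names else None
    anchor = leaf_names[0]
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if anchor in side:
            side = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset(side))
    return splits


# ---------------------------------------------------------------------------
# builders


def make_ref(ref_id: str, sequence: str, species: str,
             genus: str | None = None, family: str = "FamA",
             order: str = "Lepidoptera") -> ReferenceRecord:
    genus = genus or species.split()[0]
    return ReferenceRecord(
        ref_id=ref_id, sequence=sequence,
        lineage={"order": order, "family": family, "genus": genus,
                 "species": species},
        species=species)


def random_dna(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def mutate_at(sequence: str, positions, rng: random.Random) -> str:
    out = list(sequence)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)
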