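"""Independent brute-force oracles.

Every function here recomputes a quantity by the most literal route
available — explicit path walks, term-by-term summation, exhaustive
enumeration, power iteration — and never calls the implementation it is
used to check.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


# ---------------------------------------------------------------------------
# trees (as parent/length dicts, built without the package's helpers)


def tree_to_parent_map(tree):
    """skbio TreeNode -> ({node_id: parent_id}, {node_id: length}, {tip_name: node_id})."""
    parent: dict[int, int | None] = {}
    length: dict[int, float] = {}
    tips: dict[str, int] = {}
    for node in tree.traverse(include_self=True):
        parent[id(node)] = id(node.parent) if node.parent is not None else None
        length[id(node)] = float(node.length) if node.length is not None else 0.0
        if node.is_tip():
            tips[node.name] = id(node)
    return parent, length, tips


def path_to_root(node_id, parent):
    path = [node_id]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path


def cophenetic_oracle(tree, taxa):
    """Patristic distances by explicit tip-to-tip path summation."""
    parent, length, tips = tree_to_parent_map(tree)
    n = len(taxa)
    out = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        pi = path_to_root(tips[taxa[i]], parent)
        pj = set(path_to_root(tips[taxa[j]], parent))
        # walk up from i until the first shared ancestor, then from j up to it
        shared = next(a for a in pi if a in pj)
        d = 0.0
        a = tips[taxa[i]]
        while a != shared:
            d += length[a]
            a = parent[a]
        b = tips[taxa[j]]
        while b != shared:
            d += length[b]
            b = parent[b]
        out[i, j] = out[j, i] = d
    return out


def branch_tip_sets(tree):
    """Every branch of the tree as (length, frozenset of descendant tip names)."""
    out = []
    below: dict[int, frozenset] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            tips = frozenset([node.name])
        else:
            tips = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = tips
        if node.parent is not None:
            out.append((float(node.length), tips))
    return out


def weighted_unifrac_oracle(tree, taxa, pa, pb, normalized=True):
    """Branch-enumeration weighted UniFrac between two proportion vectors."""
    ab = dict(zip(taxa, pa))
    bb = dict(zip(taxa, pb))
    num = den = 0.0
    for length, tip_set in branch_tip_sets(tree):
        a_i = sum(ab.get(t, 0.0) for t in tip_set)
        b_i = sum(bb.get(t, 0.0) for t in tip_set)
        num += length * abs(a_i - b_i)
        den += length * (a_i + b_i)
    if not normalized:
        return num
    return num / den if den > 0 else 0.0


def beta_mntd_oracle(pa, pb, D):
    """Term-by-term expansion of the abundance-weighted βMNTD formula."""
    pa = np.asarray(pa, float) / np.sum(pa)
    pb = np.asarray(pb, float) / np.sum(pb)
    sup_a = [i for i in range(len(pa)) if pa[i] > 0]
    sup_b = [j for j in range(len(pb)) if pb[j] > 0]
    term_a = sum(pa[i] * min(D[i][j] for j in sup_b) for i in sup_a)
    term_b = sum(pb[j] * min(D[j][i] for i in sup_a) for j in sup_b)
    return 0.5 * (term_a + term_b)


# ---------------------------------------------------------------------------
# graphs (adjacency dicts: node -> set of neighbours)


def bfs_path_lengths(adj, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def average_path_length_oracle(adj):
    """Mean BFS shortest-path length over reachable ordered pairs (>0)."""
    lengths = []
    for s in adj:
        for t, d in bfs_path_lengths(adj, s).items():
            if d > 0:
                lengths.append(d)
    return float(np.mean(lengths)) if lengths else float("nan")


def _set_partitions(items):
    """All set partitions (Bell number enumeration) of a list."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity_value(adj_w, partition):
    """Weighted Newman modularity of a partition (list of node lists)."""
    m2 = sum(sum(nbrs.values()) for nbrs in adj_w.values())  # = 2m
    if m2 == 0:
        return float("nan")
    comm = {}
    for ci, nodes in enumerate(partition):
        for n in nodes:
            comm[n] = ci
    q = 0.0
    for u in adj_w:
        for v in adj_w:
            if comm[u] != comm[v]:
                continue
            a_uv = adj_w[u].get(v, 0.0)
            k_u = sum(adj_w[u].values())
            k_v = sum(adj_w[v].values())
            q += a_uv - k_u * k_v / m2
    return q / m2


def best_partition_oracle(adj_w):
    """Exhaustive modularity maximization over all set partitions."""
    nodes = sorted(adj_w)
    best_q, best_p = -np.inf, None
    for part in _set_partitions(nodes):
        q = modularity_value(adj_w, part)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, best_p


def eigenvector_centrality_oracle(adj_w, tol=1e-12, max_iter=100000):
    """Power iteration on the (absolute-)weight adjacency to convergence.

    Iterates on A + cI (c = max row sum + 1): the diagonal shift leaves the
    eigenvectors unchanged but makes the dominant eigenvalue strictly
    largest in magnitude, so the iteration converges even on bipartite
    graphs where plain power iteration oscillates.
    """
    nodes = sorted(adj_w)
    index = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, nbrs in adj_w.items():
        for v, w in nbrs.items():
            A[index[u], index[v]] = abs(w)
    shift = A.sum(axis=1).max() + 1.0
    M = A + shift * np.eye(len(nodes))
    x = np.ones(len(nodes))
    for _ in range(max_iter):
        nxt = M @ x
        nxt /= np.linalg.norm(nxt)
        if np.linalg.norm(nxt - x) < tol:
            x = nxt
            break
        x = nxt
    return dict(zip(nodes, np.abs(x)))


# ---------------------------------------------------------------------------
# statistics


def anosim_r_oracle(dist, labels):
    """ANOSIM R from first principles (mean rank difference over N(N-1)/4)."""
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    values = [dist[i][j] for i, j in pairs]
    order = sorted(range(len(values)), key=lambda k: values[k])
    ranks = [0.0] * len(values)
    k = 0
    while k < len(order):  # average ranks for ties
        j = k
        while j + 1 < len(order) and values[order[j + 1]] == values[order[k]]:
            j += 1
        avg = (k + j) / 2.0 + 1.0
        for idx in order[k : j + 1]:
            ranks[idx] = avg
        k = j + 1
    within = [r for r, (i, j) in zip(ranks, pairs) if labels[i] == labels[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if labels[i] != labels[j]]
    return (np.mean(between) - np.mean(within)) / (n * (n - 1) / 4.0)


def anosim_exhaustive_p(dist, labels):
    """Exact permutation p-value by full enumeration of label orderings."""
    r_obs = anosim_r_oracle(dist, labels)
    count = total = 0
    for perm in set(permutations(labels)):
        total += 1
        if anosim_r_oracle(dist, list(perm)) >= r_obs - 1e-12:
            count += 1
    return r_obs, count / total


def permanova_ss_oracle(dist, labels):
    """Hand SS partition: returns (R2, pseudo_F)."""
    n = len(labels)
    ss_total = sum(dist[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    groups = sorted(set(labels))
    ss_within = 0.0
    for g in groups:
        members = [i for i in range(n) if labels[i] == g]
        ss_g = sum(dist[i][j] ** 2 for i in members for j in members if i < j)
        ss_within += ss_g / len(members)
    ss_between = ss_total - ss_within
    a = len(groups)
    f = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else np.inf
    return ss_between / ss_total, f


def ward_d2_heights_oracle(points):
    """Agglomerative ward.D2 merge heights via the Lance–Williams update.

    Starts from squared Euclidean distances; at each step merges the pair
    with the smallest current distance and updates by the Ward formula
    d²(ij,k) = ((n_i+n_k)d²(i,k) + (n_j+n_k)d²(j,k) − n_k d²(i,j)) /
    (n_i+n_j+n_k); reported heights are sqrt of the merge distances (the
    ward.D2 convention).
    """
    points = np.asarray(points, float)
    clusters = {i: 1 for i in range(len(points))}
    d2 = {}
    for i, j in combinations(range(len(points)), 2):
        d2[(i, j)] = float(((points[i] - points[j]) ** 2).sum())
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        (i, j), dij = min(d2.items(), key=lambda kv: kv[1])
        heights.append(np.sqrt(dij))
        ni, nj = clusters[i], clusters[j]
        merged = {}
        for k in clusters:
            if k in (i, j):
                continue
            nk = clusters[k]
            dik = d2[tuple(sorted((i, k)))]
            djk = d2[tuple(sorted((j, k)))]
            merged[k] = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
        del clusters[i], clusters[j]
        d2 = {key: v for key, v in d2.items() if i not in key and j not in key}
        for k, v in merged.items():
            d2[tuple(sorted((k, next_id)))] = v
        clusters[next_id] = ni + nj
        next_id += 1
    return heights
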