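"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by the most literal possible route
(double loops, explicit branch/pair enumeration, textbook formulas) so the
library implementations are checked against code that shares nothing with
them beyond numpy primitives.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def avd_bruteforce(values: np.ndarray, ddof: int = 1) -> float:
    """AVD by explicit double loop over features and samples."""
    n_feat, k = values.shape
    total = 0.0
    n_eff = 0
    for i in range(n_feat):
        row = values[i].astype(float)
        mean = sum(row) / k
        var = sum((v - mean) ** 2 for v in row) / (k - ddof)
        sd = var**0.5
        if sd <= 0:
            continue
        n_eff += 1
        for v in row:
            total += abs(v - mean) / sd
    if n_eff == 0:
        raise ValueError("all features constant")
    return total / (k * n_eff)


def spearman_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho as Pearson correlation of average ranks."""

    def ranks(v):
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(np.asarray(x)), ranks(np.asarray(y))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def bh_adjust_bruteforce(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up by the textbook procedure."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adj[i] = running
    return adj


def patristic_matrix(tree) -> tuple[list[str], np.ndarray]:
    """Tip-tip distances by explicit root-path comparison."""

    def path_to_root(tip):
        path = []
        node = tip
        while node.parent is not None:
            path.append(node)
            node = node.parent
        return path

    tips = list(tree.tips())
    names = [t.name for t in tips]
    n = len(tips)
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        pi = path_to_root(tips[i])
        pj = path_to_root(tips[j])
        seti = {id(n_) for n_ in pi}
        shared = [n_ for n_ in pj if id(n_) in seti]
        mrca_path_j = []
        for n_ in pj:
            if id(n_) in seti:
                break
            mrca_path_j.append(n_)
        # distance = sum of branches from each tip up to (excluding) the MRCA
        first_shared = shared[0] if shared else None
        d = 0.0
        for n_ in pi:
            if first_shared is not None and id(n_) == id(first_shared):
                break
            d += n_.length
        for n_ in mrca_path_j:
            d += n_.length
        D[i, j] = D[j, i] = d
    return names, D


def faith_pd_bruteforce(tree, present: set[str]) -> float:
    """Sum of branch lengths on the union of root-to-tip paths of present tips."""
    used = set()
    total = 0.0
    for tip in tree.tips():
        if tip.name not in present:
            continue
        node = tip
        while node.parent is not None:
            if id(node) not in used:
                used.add(id(node))
                total += node.length
            node = node.parent
    return total


def weighted_unifrac_bruteforce(tree, abund_a: dict, abund_b: dict,
                                normalized: bool = True) -> float:
    """Per-branch |p_A - p_B| x length sum over every branch of the tree."""
    ta = sum(abund_a.values())
    tb = sum(abund_b.values())
    num = 0.0
    den = 0.0
    for node in tree.traverse(include_self=False):
        tips_below = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        pa = sum(abund_a.get(t, 0.0) for t in tips_below) / ta
        pb = sum(abund_b.get(t, 0.0) for t in tips_below) / tb
        num += node.length * abs(pa - pb)
        den += node.length * (pa + pb)
    return num / den if normalized else num


def bmntd_bruteforce(tree, abund_a: dict, abund_b: dict) -> float:
    """Abundance-weighted betaMNTD via the explicit patristic matrix."""
    names, D = patristic_matrix(tree)
    idx = {n: i for i, n in enumerate(names)}

    def one_way(src: dict, dst: dict) -> float:
        total_src = sum(src.values())
        out = 0.0
        for taxon, w in src.items():
            if w <= 0:
                continue
            nearest = min(D[idx[taxon], idx[o]] for o, v in dst.items() if v > 0)
            out += (w / total_src) * nearest
        return out

    return 0.5 * (one_way(abund_a, abund_b) + one_way(abund_b, abund_a))


def topology_bruteforce(edges: list[tuple]) -> dict:
    """avgK, avgCC, APD and GD via adjacency sets, triangle counts and BFS."""
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    nodes = sorted(adj)
    n = len(nodes)
    m = len(edges)
    avg_k = 2 * m / n
    cc_sum = 0.0
    for v in nodes:
        nb = list(adj[v])
        k = len(nb)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nb, 2) if b in adj[a])
        cc_sum += 2 * links / (k * (k - 1))
    avg_cc = cc_sum / n
    # BFS shortest paths over connected pairs
    total = 0
    pairs = 0
    for src in nodes:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        for tgt, d in dist.items():
            if tgt != src:
                total += d
                pairs += 1
    apd = total / pairs if pairs else float("nan")
    gd = 2 * m / (n * (n - 1))
    return {"avg_k": avg_k, "avg_cc": avg_cc, "apd": apd, "graph_density": gd}


def modularity_bruteforce(edges: list[tuple], partition: dict) -> float:
    """Newman-Girvan Q = sum_c (e_cc - a_c^2) over the module partition."""
    m = len(edges)
    communities = set(partition.values())
    q = 0.0
    for c in communities:
        e_cc = sum(1 for u, v in edges if partition[u] == c and partition[v] == c) / m
        a_c = sum(1 for u, v in edges for x in (u, v) if partition[x] == c) / (2 * m)
        q += e_cc - a_c**2
    return q
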