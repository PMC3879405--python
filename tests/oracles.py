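"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: exhaustive path enumeration,
direct formula evaluation, multiset-permutation enumeration.  None of it
shares code with the package.
"""

from __future__ import annotations

import itertools
from collections import deque


def all_geodesics(adj: dict, s, t) -> list[tuple]:
    """All shortest s-t paths by breadth-first enumeration."""
    best: dict = {s: 0}
    paths = {s: [(s,)]}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in best:
                best[v] = best[u] + 1
                paths[v] = [p + (v,) for p in paths[u]]
                queue.append(v)
            elif best[v] == best[u] + 1:
                paths[v].extend(p + (v,) for p in paths[u])
    return paths.get(t, [])


def brute_betweenness(adj: dict) -> dict:
    """Normalized betweenness by explicit geodesic enumeration."""
    nodes = sorted(adj)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_geodesics(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: bc[v] / norm for v in nodes}


def brute_stress(adj: dict) -> dict:
    """Stress centrality by explicit geodesic enumeration."""
    nodes = sorted(adj)
    sc = {v: 0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        for p in all_geodesics(adj, s, t):
            for v in p[1:-1]:
                sc[v] += 1
    return sc


def _components(nodes: set, adj: dict) -> list[set]:
    remaining = set(nodes)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        stack = [seed]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v in remaining:
                    remaining.discard(v)
                    comp.add(v)
                    stack.append(v)
        comps.append(comp)
    return comps


def brute_mnc_dmnc(adj: dict, node, epsilon: float = 1.7) -> tuple[int, float]:
    """MNC and DMNC by exhaustive neighborhood-component enumeration."""
    nbrs = set(adj[node])
    sub = {v: [u for u in adj[v] if u in nbrs] for v in nbrs}
    if not nbrs:
        return 0, 0.0

    def n_edges(comp: set) -> int:
        return sum(1 for u in comp for v in sub[u] if u < v)

    comps = _components(nbrs, sub)
    best = max(comps, key=lambda c: (len(c), n_edges(c), sorted(map(str, c))))
    size = len(best)
    if size < 2:
        return size, 0.0
    return size, n_edges(best) / size**epsilon


def brute_modularity(adj: dict, labels: dict) -> float:
    """Q from the adjacency-matrix definition (1/2m) sum (A - kk'/2m) delta."""
    nodes = sorted(adj)
    m = sum(len(adj[v]) for v in nodes) / 2
    if m == 0:
        return 0.0
    k = {v: len(adj[v]) for v in nodes}
    q = 0.0
    for u in nodes:
        for v in nodes:
            if labels[u] != labels[v]:
                continue
            a = 1.0 if v in adj[u] else 0.0
            q += a - k[u] * k[v] / (2 * m)
    return q / (2 * m)


def chisq_oracle(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square via sum (O - E)^2 / E on the 2x2 table."""
    n = a + b + c + d
    obs = [[a, b], [c, d]]
    rows = [a + b, c + d]
    cols = [a + c, b + d]
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            if e > 0:
                chi2 += (obs[i][j] - e) ** 2 / e
    return chi2


def naive_late_motifs(seq: str) -> list[int]:
    """Sliding-window DTAAG scan, no regex."""
    out = []
    for i in range(len(seq) - 4):
        if seq[i] in "AGT" and seq[i + 1 : i + 5] == "TAAG":
            out.append(i + 1)
    return out


def naive_early_pairs(seq: str) -> list[tuple[int, int]]:
    """Sliding-window TATA/TATAWWW + downstream CANT scan, no regex."""
    boxes = []
    for i in range(len(seq) - 3):
        if seq[i : i + 4] == "TATA":
            if i + 7 <= len(seq) and all(b in "AT" for b in seq[i + 4 : i + 7]):
                boxes.append((i + 1, i + 7))
            boxes.append((i + 1, i + 4))
    cants = [
        i + 1
        for i in range(len(seq) - 3)
        if seq[i] == "C" and seq[i + 1] == "A" and seq[i + 3] == "T"
        and seq[i + 2] in "ACGTN"
    ]
    pairs = set()
    for start, end in boxes:
        for c in cants:
            if c > end:
                pairs.add((start, c))
    return sorted(pairs)


def run_probability_exhaustive_value(
    values: list,
    value,
    run_length: int,
    circular: bool = True,
    strands: list | None = None,
) -> float:
    """P(>=1 run of `value` of length >= run_length) over all arrangements."""
    items = list(zip(values, strands)) if strands else [(v, "+") for v in values]
    arrangements = set(itertools.permutations(items))
    hits = 0
    for arr in arrangements:
        vals = [a[0] for a in arr]
        strs = [a[1] for a in arr]
        n = len(vals)
        if run_length <= 1:
            found = value in vals
        else:
            found = False
            positions = range(n) if circular else range(n - run_length + 1)
            for start in positions:
                idxs = [(start + k) % n for k in range(run_length)]
                window_vals = [vals[i] for i in idxs]
                window_strs = {strs[i] for i in idxs}
                if all(v == value for v in window_vals) and (
                    strands is None or len(window_strs) == 1
                ):
                    found = True
                    break
        hits += found
    return hits / len(arrangements)
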