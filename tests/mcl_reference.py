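"""Independent pure-Python MCL reference used as a test oracle.

Deliberately coded without numpy and run on the full matrix at once (no
per-component decomposition) so that it shares no code path with the
package implementation: explicit list-of-lists matrix algebra, the same
procedure (self-loops at the max incident weight, expansion, inflation,
column renormalisation, pruning) and the same attractor interpretation.
"""

from __future__ import annotations


def _normalise(m: list[list[float]]) -> None:
    n = len(m)
    for j in range(n):
        s = sum(m[i][j] for i in range(n))
        if s > 0:
            for i in range(n):
                m[i][j] /= s


def _matmul(a: list[list[float]], b: list[list[float]]) -> list[list[float]]:
    n = len(a)
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        ai = a[i]
        oi = out[i]
        for k in range(n):
            aik = ai[k]
            if aik == 0.0:
                continue
            bk = b[k]
            for j in range(n):
                oi[j] += aik * bk[j]
    return out


def mcl_reference_partition(
    nodes,
    weighted_edges,
    inflation: float = 2.2,
    expansion: int = 2,
    prune: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 200,
):
    """Run MCL on (nodes, edges) and return the partition as a set of frozensets."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = [[0.0] * n for _ in range(n)]
    for u, v, w in weighted_edges:
        m[idx[u]][idx[v]] = w
        m[idx[v]][idx[u]] = w
    for i in range(n):
        col_max = max(m[j][i] for j in range(n))
        m[i][i] = col_max if col_max > 0 else 1.0
    _normalise(m)

    for _ in range(max_iter):
        prev = [row[:] for row in m]
        m = prev
        for _ in range(expansion - 1):
            m = _matmul(m, prev)
        for i in range(n):
            for j in range(n):
                m[i][j] = m[i][j] ** inflation
        _normalise(m)
        for i in range(n):
            for j in range(n):
                if m[i][j] < prune:
                    m[i][j] = 0.0
        _normalise(m)
        change = max(
            abs(m[i][j] - prev[i][j]) for i in range(n) for j in range(n)
        )
        if change < tol:
            break
    else:
        raise RuntimeError("reference MCL did not converge")

    attractors = [i for i in range(n) if m[i][i] > 0.0]
    # merge attractor systems sharing mass
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for a in attractors:
        for b in attractors:
            if a != b and (m[a][b] > 0.0 or m[b][a] > 0.0):
                union(a, b)

    clusters: dict[int, set[int]] = {}
    for a in attractors:
        clusters.setdefault(find(a), set()).add(a)
    attracted = set(attractors)
    singleton_roots = []
    for j in range(n):
        if j in attracted:
            continue
        masses = [(m[a][j], a) for a in attractors if m[a][j] > 0.0]
        if masses:
            best = max(w for w, _ in masses)
            best_attrs = [a for w, a in masses if w == best]
            # ties: join the system containing the smallest node index
            target = min(best_attrs, key=lambda a: min(clusters[find(a)]))
            clusters[find(target)].add(j)
        else:
            singleton_roots.append(j)
    parts = [frozenset(nodes[i] for i in c) for c in clusters.values()]
    parts += [frozenset({nodes[j]}) for j in singleton_roots]
    return set(parts)
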