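"""Independent reference implementations used only to check the package."""

import numpy as np


def brute_force_local_efficiency(A: np.ndarray, i: int) -> float:
    """Textbook local efficiency: BFS shortest paths within the subgraph
    induced by node i's neighbors, averaged inverse distance over ordered
    neighbor pairs (unreachable pairs contribute 0)."""
    nbrs = [j for j in range(A.shape[0]) if A[i, j]]
    k = len(nbrs)
    if k < 2:
        return 0.0
    total = 0.0
    for a in nbrs:
        dist = {a: 0}
        frontier = [a]
        while frontier:
            nxt = []
            for u in frontier:
                for v in nbrs:
                    if A[u, v] and v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for b in nbrs:
            if b != a and b in dist:
                total += 1.0 / dist[b]
    return total / (k * (k - 1))
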