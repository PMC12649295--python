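"""Independent oracles used by the test suite.

These deliberately re-derive results with the simplest possible algorithms
(quadratic DP, exhaustive enumeration) and stay independent of the package
code paths they check.
"""

from __future__ import annotations


def gotoh_local(a: str, b: str, match: int = 2, mismatch: int = -3,
                gap_open: int = 5, gap_extend: int = 2):
    """Quadratic affine-gap local alignment (Gotoh).

    Gap scoring convention: the first gap position costs ``gap_open``, each
    further position ``gap_extend``.  Returns (best score, identities,
    alignment columns) of one traceback of a best-scoring local alignment.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a (move along b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b (move along a)
    best, best_pos = 0.0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            sub = match if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGTU") else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best, best_pos = H[i][j], (i, j)
    if best <= 0:
        return 0.0, 0, 0
    # traceback one optimal path
    i, j = best_pos
    identities = columns = 0
    state = "H"
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            sub = match if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGTU") else mismatch
            if H[i][j] == H[i - 1][j - 1] + sub:
                identities += a[i - 1] == b[j - 1] and a[i - 1] in "ACGTU"
                columns += 1
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i][j] == H[i][j - 1] - gap_open:
                state = "H"
            j -= 1
        else:
            columns += 1
            if F[i][j] == H[i - 1][j] - gap_open:
                state = "H"
            i -= 1
    return best, identities, columns


def exhaustive_fmeasure(classes: dict[str, set], clusters: dict[str, set]) -> float:
    """Clustering F-measure by brute-force set intersection."""
    n = sum(len(members) for members in classes.values())
    total = 0.0
    for class_members in classes.values():
        n_k = len(class_members)
        best = 0.0
        for cluster_members in clusters.values():
            n_kj = len(class_members & cluster_members)
            if n_kj == 0:
                continue
            n_j = len(cluster_members)
            p, r = n_kj / n_j, n_kj / n_k
            best = max(best, 2 * p * r / (p + r))
        total += n_k / n * best
    return total


def brute_force_components(ids: set, edges: list[tuple[str, str]]) -> set[frozenset]:
    """Connected components by repeated closure (no union-find, no graphs)."""
    components: list[set] = [{i} for i in ids]
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            ca = next(c for c in components if a in c)
            cb = next(c for c in components if b in c)
            if ca is not cb:
                ca |= cb
                components.remove(cb)
                changed = True
    return {frozenset(c) for c in components}
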