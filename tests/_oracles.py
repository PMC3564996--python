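"""Independent brute-force oracles used to validate the implementation.

Each oracle is deliberately written with a different algorithm than the
code under test: a full (unbanded) dynamic-programming matrix for the
banded aligner, plain BFS for connected components, and literal set
partition enumeration for the minimum haplotype count.
"""

from __future__ import annotations

import numpy as np

_GAP = -3
_NEG = -(10**9)


def _codes(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def full_overlap_align(a: str, b: str, offset: int):
    """Unbanded overlap alignment with the same scoring and end rules.

    Returns ``(matches, aligned_len, score)``.  Full (n+1) x (m+1) matrix,
    row-swept with numpy; traceback recomputes predecessors from the stored
    matrix with the preference order diagonal > up > left.
    """
    qs, ss = max(0, offset), max(0, -offset)
    qa, sb = _codes(a[qs:]), _codes(b[ss:])
    n, m = qa.size, sb.size
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    H[0, :] = _GAP * np.arange(m + 1)
    H[:, 0] = _GAP * np.arange(n + 1)
    j_arr = np.arange(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        sub = np.where((sb == qa[i - 1]) & (qa[i - 1] < 4), 1, -2)
        diag = H[i - 1, :-1] + sub
        up = H[i - 1, 1:] + _GAP
        v = np.maximum(diag, up)
        acc = np.empty(m + 1, dtype=np.int64)
        acc[0] = H[i, 0]
        acc[1:] = v
        H[i] = np.maximum.accumulate(acc + (-_GAP) * j_arr) + _GAP * j_arr
    # free end: best on the last row (ascending j), then the last column
    # (ascending i), strict improvement only — mirrors the banded scan order
    best, bi, bj = _NEG, n, 0
    for j in range(m + 1):
        if H[n, j] > best:
            best, bi, bj = H[n, j], n, j
    for i in range(n + 1):
        if H[i, m] > best:
            best, bi, bj = H[i, m], i, m
    matches = 0
    aligned = 0
    i, j = bi, bj
    while i > 0 or j > 0:
        aligned += 1
        if i > 0 and j > 0:
            sub = 1 if (qa[i - 1] == sb[j - 1] and qa[i - 1] < 4) else -2
            if H[i, j] == H[i - 1, j - 1] + sub:
                matches += sub == 1
                i -= 1
                j -= 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + _GAP:
            i -= 1
            continue
        j -= 1
    return matches, aligned, int(best)


def bfs_components(ids, pairs):
    """Connected components by plain breadth-first search."""
    adj = {i: set() for i in ids}
    for a, b in pairs:
        adj[a].add(b)
        adj[b].add(a)
    seen = set()
    components = []
    for start in ids:
        if start in seen:
            continue
        queue = [start]
        seen.add(start)
        comp = {start}
        while queue:
            node = queue.pop()
            for other in adj[node]:
                if other not in seen:
                    seen.add(other)
                    comp.add(other)
                    queue.append(other)
        components.append(frozenset(comp))
    return set(components)


def min_partition_haplotypes(vectors: list[list]) -> int:
    """Minimum number of pairwise conflict-free groups, by enumerating
    every set partition (add-to-group-or-open-new-group recursion)."""
    n = len(vectors)
    if n == 0:
        return 0
    compatible = [
        [
            all(
                x is None or y is None or x == y
                for x, y in zip(vectors[i], vectors[j])
            )
            for j in range(n)
        ]
        for i in range(n)
    ]
    best = [n]

    def recurse(item: int, groups: list[list[int]]) -> None:
        if item == n:
            best[0] = min(best[0], len(groups))
            return
        for group in groups:
            if all(compatible[item][j] for j in group):
                group.append(item)
                recurse(item + 1, groups)
                group.pop()
        groups.append([item])
        recurse(item + 1, groups)
        groups.pop()

    recurse(0, [])
    return best[0]


def brute_force_overlap(matrix, ind_a: str, ind_b: str) -> float:
    """Pairwise SNP-position overlap by a double loop over sites."""
    n = len(matrix.sites)
    if n == 0:
        return 0.0
    both = 0
    for j in range(n):
        if matrix.get(ind_a, j) is not None and matrix.get(ind_b, j) is not None:
            both += 1
    return both / n


def mutate_with_divergence(seq: str, divergence: float, rng, n_indels: int = 0,
                           max_indel: int = 3) -> str:
    """Substitute ~divergence of sites and optionally add short indels."""
    arr = list(seq)
    for pos in np.flatnonzero(rng.random(len(arr)) < divergence):
        arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]
    for _ in range(n_indels):
        size = int(rng.integers(1, max_indel + 1))
        pos = int(rng.integers(10, max(11, len(arr) - 10 - size)))
        if rng.random() < 0.5:
            del arr[pos : pos + size]
        else:
            insert = [str(b) for b in rng.choice(list("ACGT"), size)]
            arr[pos:pos] = insert
    return "".join(arr)
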