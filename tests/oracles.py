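"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths (regex scanning,
Biopython alignment, scikit-bio NJ): explicit loops and naive dynamic
programming only.
"""

from __future__ import annotations

import numpy as np

PYR = set("CUT")


def brute_force_cu_motifs(seq: str, min_len: int = 3) -> list[tuple[int, int]]:
    """Maximal pyrimidine runs with >=1 C and >=1 U, by explicit position walk."""
    seq = seq.upper().replace("T", "U")
    out = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] in "CU":
            j = i
            while j < n and seq[j] in "CU":
                j += 1
            run = seq[i:j]
            if len(run) >= min_len and "C" in run and "U" in run:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


def brute_force_regions(
    spans: list[tuple[int, int]], window: int, min_motifs: int, span_mode: str = "start_to_end"
) -> list[tuple[int, int]]:
    """All maximal consecutive motif-index runs whose every min_motifs-sized
    sub-window fits in the span window, by exhaustive enumeration."""

    n = len(spans)

    def window_ok(i: int) -> bool:
        j = i + min_motifs - 1
        if span_mode == "start_to_start":
            return spans[j][0] - spans[i][0] <= window
        return spans[j][1] - spans[i][0] <= window

    def run_ok(i: int, j: int) -> bool:  # motifs i..j inclusive, j-i+1 >= min_motifs
        return all(window_ok(k) for k in range(i, j - min_motifs + 2))

    out = []
    for i in range(n):
        for j in range(i + min_motifs - 1, n):
            if not run_ok(i, j):
                continue
            extend_left = i > 0 and run_ok(i - 1, j)
            extend_right = j < n - 1 and run_ok(i, j + 1)
            if not extend_left and not extend_right:
                out.append((i, j))
    return out


def gotoh_local_score(a: str, b: str, matrix, gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """Naive affine-gap Smith-Waterman score (a gap of length k costs open + k*extend).

    Cell-by-cell three-state DP; no vectorization, no traceback.
    """
    la, lb = len(a), len(b)
    NEG = -1e18
    M = [[0.0] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (b consumed)
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            X[i][j] = max(M[i - 1][j] - (gap_open + gap_extend), X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - (gap_open + gap_extend), Y[i][j - 1] - gap_extend)
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]))
            best = max(best, M[i][j])
    return best


def conservation_tally(
    columns: list[dict[str, str]], refs: tuple[str, str], gap: str = "-"
) -> list[dict[str, str]]:
    """Per-column category for each non-reference row, computed directly.

    ``columns``: one dict per alignment column mapping row id -> residue.
    """
    out = []
    for col in columns:
        r1, r2 = col[refs[0]], col[refs[1]]
        others = {k: v for k, v in col.items() if k not in refs}
        counts: dict[str, int] = {}
        for v in others.values():
            if v != gap:
                counts[v] = counts.get(v, 0) + 1
        cats = {}
        for k, v in others.items():
            if v == gap:
                cats[k] = "nonconserved"
            elif r1 == r2 and r1 != gap and v == r1:
                cats[k] = "reference-identical"
            elif r1 != r2 and v in (r1, r2):
                cats[k] = "reference-identical"
            elif counts.get(v, 0) >= 2:
                cats[k] = "shared-in-≥2"
            else:
                cats[k] = "nonconserved"
        out.append(cats)
    return out


def leaf_path_lengths(newick_adj: dict, start) -> dict:
    """All path lengths from ``start`` in an undirected weighted adjacency dict."""
    dist = {start: 0.0}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, w in newick_adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                stack.append(v)
    return dist


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGU") -> str:
    return "".join(rng.choice(list(alphabet), size=n))
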