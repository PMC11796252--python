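"""Independent brute-force oracles used to cross-check the implementation.

Each oracle deliberately uses a different algorithmic route than the code it
checks: local alignment via the Waterman-Smith-Beyer all-gap-length scan,
profile scoring via exhaustive path enumeration, ARI via explicit pair
counting, and k-selection via a direct re-derivation of mutual top-k lists.
"""

from __future__ import annotations

import math


def sw_score_oracle(a: str, b: str, sub: dict[tuple[str, str], float], gap_open: float, gap_extend: float) -> float:
    """Optimal local alignment score, scanning every gap length explicitly.

    A gap of length L costs ``gap_open + L * gap_extend``.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cand = [0.0, H[i - 1][j - 1] + sub[(a[i - 1], b[j - 1])]]
            for k in range(1, i + 1):
                cand.append(H[i - k][j] - (gap_open + k * gap_extend))
            for k in range(1, j + 1):
                cand.append(H[i][j - k] - (gap_open + k * gap_extend))
            H[i][j] = max(cand)
            best = max(best, H[i][j])
    return best


def profile_score_oracle(profile, seq: str) -> float:
    """Best log-odds path score by exhaustive enumeration of state paths."""
    from pepfam.families import _RES_INDEX

    K = profile.n_match_states
    L = len(seq)
    t = {label: math.log2(p) for label, p in profile.transitions.items()}
    best = [-math.inf]

    def emit(k: int, pos: int) -> float:
        r = _RES_INDEX.get(seq[pos])
        return 0.0 if r is None else float(profile.match_logodds[k - 1, r])

    def walk(state: str, k: int, pos: int, score: float) -> None:
        if k == K and state in ("M", "D"):
            best[0] = max(best[0], score)  # trailing query residues are free
            return
        if state == "M":
            if pos < L:
                walk("M", k + 1, pos + 1, score + t["MM"] + emit(k + 1, pos))
                if k < K:
                    walk("I", k, pos + 1, score + t["MI"])
            walk("D", k + 1, pos, score + t["MD"])
        elif state == "I":
            if pos < L:
                walk("I", k, pos + 1, score + t["II"])
                walk("M", k + 1, pos + 1, score + t["IM"] + emit(k + 1, pos))
        else:  # D
            if pos < L:
                walk("M", k + 1, pos + 1, score + t["DM"] + emit(k + 1, pos))
            walk("D", k + 1, pos, score + t["DD"])

    for i in range(L):
        walk("M", 1, i + 1, emit(1, i))
    for i in range(L + 1):
        walk("D", 1, i, 0.0)
    return best[0]


def ari_pair_oracle(labels_a, labels_b) -> float:
    """ARI from the four explicit pair-agreement counts."""
    n = len(labels_a)
    n11 = n00 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa = labels_a[i] == labels_a[j]
            sb = labels_b[i] == labels_b[j]
            if sa and sb:
                n11 += 1
            elif sa:
                n10 += 1
            elif sb:
                n01 += 1
            else:
                n00 += 1
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return 1.0
    return 2.0 * (n11 * n00 - n10 * n01) / denom


def select_k_oracle(g) -> int:
    """Smallest non-isolating mutual-top-k, re-derived from scratch."""
    max_degree = max(dict(g.degree()).values())
    for k in range(1, max_degree + 1):
        tops = {}
        for node in g:
            ranked = sorted(g[node].items(), key=lambda kv: (-kv[1]["weight"], kv[0]))
            tops[node] = {nbr for nbr, _ in ranked[:k]}
        degree = {node: 0 for node in g}
        for a, b in g.edges():
            if b in tops[a] and a in tops[b]:
                degree[a] += 1
                degree[b] += 1
        if min(degree.values()) >= 1:
            return k
    return max_degree
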