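"""Independent brute-force oracles used by the property tests.

Each oracle re-implements a primitive from first principles, structured
differently from the package implementation, so agreement on random
instances is meaningful evidence of correctness.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "U"), ("U", "G")}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg by the textbook definition


def bh_oracle(p):
    """q_(i) = min_{j >= i} p_(j) * n / j over the sorted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Seed-site taxonomy by independent per-class window tests


def seed_sites_oracle(mir: str, tgt: str):
    """Each seed class tested independently with an explicit window
    comparison; overlapping classes reduced to the most specific per
    6mer-core occurrence.  Returns a list of (start, end, class)."""
    comp27 = revcomp(mir[1:7])   # target window opposite miRNA positions 2-7
    comp28 = revcomp(mir[1:8])   # opposite positions 2-8
    out = []
    for i in range(len(tgt) - 5):
        if tgt[i:i + 6] != comp27:
            continue
        is_m8 = i >= 1 and tgt[i - 1:i + 6] == comp28
        is_a1 = i + 6 < len(tgt) and tgt[i + 6] == "A"
        if is_m8 and is_a1:
            out.append((i - 1, i + 7, "8mer"))
        elif is_m8:
            out.append((i - 1, i + 6, "7mer-m8"))
        elif is_a1:
            out.append((i, i + 7, "7mer-A1"))
        else:
            out.append((i, i + 6, "6mer"))
    return out


# ---------------------------------------------------------------------------
# Local alignment with affine gaps, by explicit gap-length enumeration
# (O(M*N*(M+N)) formulation, structurally distinct from the Gotoh recurrence)


def _sub(m: str, t: str, i: int, seed_weight: float) -> float:
    if (m, t) in _WC:
        s = 5.0
    elif (m, t) in _WOBBLE:
        s = 1.0
    else:
        s = -3.0
    if 1 <= i <= 7:
        s *= seed_weight
    return s


def _gap(k: int) -> float:
    return -9.0 - 4.0 * (k - 1)


def align_oracle(mir: str, window: str, seed_weight: float = 2.0) -> float:
    """Optimal local score of mir vs the reversed window.

    H[i][j] = best local alignment ending in a substitution at (i, j); a
    gap of length k between two substitutions costs -9 - 4*(k-1) and every
    gap length is enumerated explicitly (no three-state recurrence)."""
    rev = window[::-1]
    M, N = len(mir), len(rev)
    H = np.zeros((M + 1, N + 1))
    best = 0.0
    for i in range(1, M + 1):
        for j in range(1, N + 1):
            s = _sub(mir[i - 1], rev[j - 1], i - 1, seed_weight)
            pred = max(0.0, H[i - 1][j - 1])
            for k in range(1, i - 1):
                pred = max(pred, H[i - 1 - k][j - 1] + _gap(k))
            for k in range(1, j - 1):
                pred = max(pred, H[i - 1][j - 1 - k] + _gap(k))
            H[i][j] = max(0.0, pred + s)
            best = max(best, H[i][j])
    return best


def align_enum_oracle(mir: str, window: str, seed_weight: float = 2.0) -> float:
    """Full recursive enumeration of every local alignment path (tiny
    inputs only).  Moves: substitution, gap in target, gap in miRNA; a path
    must start and end with a substitution."""
    rev = window[::-1]
    M, N = len(mir), len(rev)
    best = 0.0

    def walk(i, j, score, last_was_sub):
        nonlocal best
        if last_was_sub:
            best = max(best, score)
        if i == M or j == N:
            return
        # substitution
        walk(i + 1, j + 1, score + _sub(mir[i], rev[j], i, seed_weight), True)
        # open a gap of length k in either row (only mid-path)
        if last_was_sub or score > 0:
            for k in range(1, M - i):
                walk(i + k, j, score - 9.0 - 4.0 * (k - 1), False)
            for k in range(1, N - j):
                walk(i, j + k, score - 9.0 - 4.0 * (k - 1), False)

    for i in range(M):
        for j in range(N):
            walk(i, j, 0.0, False)
    return best


# ---------------------------------------------------------------------------
# Duplex free energy: re-walk the pairing string and sum table entries


def dg_oracle(mir_aln: str, tgt_aln: str, pairing: str, stacks, initiation: float,
              terminal: float) -> float:
    paired = [k for k, c in enumerate(pairing) if c in "|:"]
    if not paired:
        return 0.0
    dg = initiation
    for a, b in zip(paired, paired[1:]):
        if b == a + 1:
            dg += stacks[(mir_aln[a] + mir_aln[b], tgt_aln[a] + tgt_aln[b])]
    # helix ends: first/last index of every maximal consecutive run; a run
    # of length 1 has coincident ends and is penalized once
    for k in paired:
        if (k - 1) not in paired or (k + 1) not in paired:
            pair = (mir_aln[k], tgt_aln[k])
            if pair in _WOBBLE or pair in {("A", "U"), ("U", "A")}:
                dg += terminal
    return dg


# ---------------------------------------------------------------------------
# Relative degree from the raw adjacency matrix


def relative_degree_oracle(edges, nodes):
    """Degree counting straight off an edge list."""
    deg = {v: 0 for v in nodes}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    mx = max(deg.values())
    return {v: d / mx for v, d in deg.items()}


# ---------------------------------------------------------------------------
# AUC as the explicit all-pairs concordance count


def auc_oracle(scores, y01):
    scores = np.asarray(scores, dtype=float)
    y01 = np.asarray(y01)
    pos = scores[y01 == 1]
    neg = scores[y01 == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))
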