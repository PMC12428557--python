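"""Independent brute-force oracles used to pin implementation behavior.

Every function here deliberately avoids the code paths it checks: duplex
energies by exhaustive chain enumeration, stop codons by all-offset triplet
scans, rank-sum p by enumerating group assignments, hypergeometric tails by
direct summation.
"""

from itertools import combinations
from math import comb

from splicedown.duplex import _PAIR_CODE, step_cost

STOPS = ("TAG", "TAA", "TGA")


def oracle_duplex_mfe(mirna: str, target: str, model) -> float:
    """Exhaustive enumeration over every loop-bounded co-linear pairing."""
    r = target[::-1]
    L, T = len(mirna), len(r)
    valid = [[(mirna[i] + r[j]) in _PAIR_CODE for j in range(T)] for i in range(L)]
    best = [float("inf")]
    mb, mi = model.max_bulge, model.max_interior

    def extend(i, j, energy):
        if energy < best[0]:
            best[0] = energy
        for i2 in range(i + 1, L):
            a = i2 - i - 1
            if a > mb:
                break
            for j2 in range(j + 1, T):
                b = j2 - j - 1
                if b > mb:
                    break
                if not valid[i2][j2]:
                    continue
                if a > 0 and b > 0 and (a > mi or b > mi):
                    continue
                extend(i2, j2, energy + step_cost(
                    model, mirna[i] + r[j], mirna[i2] + r[j2], a, b))

    for i in range(L):
        for j in range(T):
            if valid[i][j]:
                extend(i, j, model.duplex_init)
    v = best[0]
    return 0.0 if v == float("inf") or v >= 0 else v


def oracle_all_stop_offsets(seq: str):
    """0-based offsets of every stop triplet at every offset (any frame)."""
    seq = seq.upper().replace("U", "T")
    return [k for k in range(len(seq) - 2) if seq[k:k + 3] in STOPS]


def oracle_inframe_stops(seq: str, frame: int):
    """1-based first-nucleotide positions of in-frame stop codons."""
    seq = seq.upper().replace("U", "T")
    return [k + 1 for k in range(frame - 1, len(seq) - 2, 3)
            if seq[k:k + 3] in STOPS]


def oracle_motif_positions(seq: str, pattern: str, table):
    """Naive regex-free sliding comparison under an IUPAC table."""
    seq = seq.upper().replace("T", "U")
    pattern = pattern.upper().replace("T", "U")
    hits = []
    for s in range(len(seq) - len(pattern) + 1):
        if all(seq[s + k] in table[pattern[k]] for k in range(len(pattern))):
            hits.append(s)
    return hits


def _midranks(values):
    order = sorted(range(len(values)), key=lambda k: values[k])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        for k in range(i, j + 1):
            ranks[order[k]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def oracle_ranksum_p(x, y):
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n = len(x)
    ranks = _midranks(pooled)
    observed = sum(ranks[:n])
    lo = hi = total = 0
    for combo in combinations(range(len(pooled)), n):
        w = sum(ranks[k] for k in combo)
        total += 1
        if w <= observed + 1e-9:
            lo += 1
        if w >= observed - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def oracle_hypergeom_upper_tail(k, N, K, n):
    """P(X >= k) by direct summation of hypergeometric point masses."""
    total = 0.0
    for kk in range(k, min(K, n) + 1):
        total += comb(K, kk) * comb(N - K, n - kk) / comb(N, n)
    return min(total, 1.0)


def oracle_bh(pvalues):
    """Benjamini-Hochberg adjusted values by the textbook formula."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvalues[i] * m / rank_from_end)
        adj[i] = val
        prev = val
    return adj
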