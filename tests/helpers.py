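"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid numpy vectorization and the package's own code
paths: distributions are estimated with explicit Python loops and the 16
nucleotide pairs are enumerated one by one.
"""

import math

BASES = "ACGT"


def brute_marginal(seq: str) -> dict[str, float]:
    seq = seq.upper()
    counts = {b: 0 for b in BASES}
    total = 0
    for c in seq:
        if c in counts:
            counts[c] += 1
            total += 1
    return {b: counts[b] / total for b in BASES}


def brute_joint(seq: str, k: int) -> dict[tuple[str, str], float]:
    seq = seq.upper()
    counts = {(x, y): 0 for x in BASES for y in BASES}
    total = 0
    for i in range(len(seq) - k):
        x, y = seq[i], seq[i + k]
        if x in BASES and y in BASES:
            counts[(x, y)] += 1
            total += 1
    return {pair: c / total for pair, c in counts.items()}


def brute_ami(seq: str, max_lag: int) -> list[float]:
    p0 = brute_marginal(seq)
    out = []
    for k in range(1, max_lag + 1):
        pk = brute_joint(seq, k)
        total = 0.0
        for x in BASES:
            for y in BASES:
                p = pk[(x, y)]
                if p > 0:
                    total += p * math.log2(p / (p0[x] * p0[y]))
        out.append(total)
    return out


def brute_eami(seq: str, max_lag: int) -> list[float]:
    out = []
    for k in range(1, max_lag + 1):
        pk = brute_joint(seq, k)
        for x in BASES:
            for y in BASES:
                out.append(pk[(x, y)])
    return out


def brute_eaami(seq: str, max_lag: int) -> list[float]:
    p0 = brute_marginal(seq)
    out = []
    for k in range(1, max_lag + 1):
        pk = brute_joint(seq, k)
        for x in BASES:
            for y in BASES:
                p = pk[(x, y)]
                out.append(p * math.log2(p / (p0[x] * p0[y])) if p > 0 else 0.0)
    return out


def pairwise_auc(scores, labels) -> float:
    """Mann-Whitney AUC by exhaustive coding/noncoding pair enumeration."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
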