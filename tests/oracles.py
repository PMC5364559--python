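"""Naive reference implementations used to cross-check the encoders.

Everything here is deliberately written with plain Python loops, dicts and
the statistics module -- no numpy vectorization, no imports from the
package's encoding code paths -- so agreement with the package is a real
dual-route check.  The three PAAC property tables are duplicated here on
purpose for the same reason.
"""

from itertools import combinations
from statistics import mean, pstdev

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


def standardize_table(table):
    vals = [table[aa] for aa in ALPHABET]
    m, s = mean(vals), pstdev(vals)
    return {aa: (table[aa] - m) / s for aa in ALPHABET}


def naive_aac(seq):
    return [seq.count(aa) / len(seq) for aa in ALPHABET]


def naive_dpc(seq):
    out = []
    for a in ALPHABET:
        for b in ALPHABET:
            pair = a + b
            n = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == pair)
            out.append(n / (len(seq) - 1))
    return out


def naive_theta(seq, j, prop_tables=None):
    tables = [
        standardize_table(t)
        for t in (prop_tables or (HYDROPHOBICITY, HYDROPHILICITY, SIDE_CHAIN_MASS))
    ]
    total = 0.0
    for i in range(len(seq) - j):
        a, b = seq[i], seq[i + j]
        total += mean((t[a] - t[b]) ** 2 for t in tables)
    return total / (len(seq) - j)


def naive_paac(seq, lam=1, weight=0.05):
    freqs = naive_aac(seq)
    thetas = [naive_theta(seq, j) for j in range(1, lam + 1)]
    denom = sum(freqs) + weight * sum(thetas)
    return [f / denom for f in freqs] + [weight * t / denom for t in thetas]


def naive_ctd(seq, groupings):
    """groupings: sequence of (name, {residue: group}) pairs."""
    import math

    L = len(seq)
    out = []
    for _, group_of in groupings:
        g = [group_of[aa] for aa in seq]
        for k in (1, 2, 3):
            out.append(sum(1 for x in g if x == k) / L)
        for p, q in combinations((1, 2, 3), 2):
            n = sum(
                1
                for i in range(L - 1)
                if (g[i] == p and g[i + 1] == q) or (g[i] == q and g[i + 1] == p)
            )
            out.append(n / (L - 1))
        for k in (1, 2, 3):
            positions = [i + 1 for i, x in enumerate(g) if x == k]
            if not positions:
                out.extend([0.0] * 5)
                continue
            n = len(positions)
            for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                rank = max(math.ceil(frac * n), 1)
                out.append(100.0 * positions[rank - 1] / L)
    return out


def naive_acf(seq, index_values, order):
    """index_values: ordered (id, {residue: value}) pairs; raw, unstandardized."""
    out = []
    for _, table in index_values:
        z = standardize_table(table)
        for d in range(1, order + 1):
            total = sum(z[seq[i]] * z[seq[i + d]] for i in range(len(seq) - d))
            out.append(total / (len(seq) - d))
    return out


def naive_auc(scores, labels):
    """All positive-negative pairs, ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
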