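"""Brute-force reference implementations used to validate the statistics.

These deliberately use the most direct (enumerative) formulation of each
quantity and share no code with the package implementations.
"""

import itertools
from collections import Counter

import numpy as np


def pi_bruteforce(hm):
    """All-pairs Hamming mean."""
    n = hm.n_haplotypes
    diffs = [
        (hm.alleles[i] != hm.alleles[j]).sum()
        for i, j in itertools.combinations(range(n), 2)
    ]
    return sum(diffs) / len(diffs)


def tajimas_d_oracle(hm):
    """Constant-by-constant re-evaluation of the D formula."""
    n = hm.n_haplotypes
    s = sum(1 for j in range(hm.n_sites) if 0 < hm.alleles[:, j].sum() < n)
    if s == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    pi = pi_bruteforce(hm)
    return (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def ehh_bruteforce(hm, core, allele, x):
    """Pairwise identity over the closed site interval [min(core,x), max]."""
    carriers = np.flatnonzero(hm.alleles[:, core] == allele)
    lo, hi = min(core, x), max(core, x)
    same = 0
    pairs = 0
    for i, j in itertools.combinations(carriers, 2):
        pairs += 1
        if (hm.alleles[i, lo : hi + 1] == hm.alleles[j, lo : hi + 1]).all():
            same += 1
    return same / pairs


def ihh_bruteforce(distances, ehh_values):
    """Direct summed trapezoid over one side's grid."""
    d = np.abs(np.asarray(distances, dtype=float))
    e = np.asarray(ehh_values, dtype=float)
    return sum(
        (d[k + 1] - d[k]) * (e[k] + e[k + 1]) / 2 for k in range(len(d) - 1)
    )


def h_stats_bruteforce(hm, start, stop):
    """H1, H12, H2 from direct haplotype-string counting."""
    strings = Counter("".join(map(str, row)) for row in hm.alleles[:, start:stop])
    p = np.array(sorted(strings.values(), reverse=True), dtype=float)
    p = p / p.sum()
    h1 = (p**2).sum()
    h12 = (p[0] + (p[1] if len(p) > 1 else 0)) ** 2 + (p[2:] ** 2).sum()
    return h1, h12, h1 - p[0] ** 2


def harmonic(n):
    return sum(1.0 / i for i in range(1, n))
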