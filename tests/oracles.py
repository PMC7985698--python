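"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the scanner oracle
expands a degenerate motif into all concrete sequences and slides a window;
the Fisher oracle enumerates every 2x2 table with the observed margins using
exact rational arithmetic on factorials.
"""

from __future__ import annotations

import bisect
from fractions import Fraction
from functools import lru_cache

from creascan.motifs import DegenerateMotif, expand_iupac, reverse_complement_motif


def naive_scan(sequence: str, motif: DegenerateMotif) -> list[tuple[int, str]]:
    """Expand-and-slide scanner: all (start, strand) hits on both strands."""
    seq = sequence.upper()
    length = motif.length
    forward = expand_iupac(motif)
    reverse = expand_iupac(reverse_complement_motif(motif))
    hits = []
    for i in range(len(seq) - length + 1):
        window = seq[i : i + length]
        if window in forward:
            hits.append((i, "+"))
        if window in reverse:
            hits.append((i, "-"))
    hits.sort()
    return hits


@lru_cache(maxsize=None)
def _fact(n: int) -> int:
    import math

    return math.factorial(n)


_REL_TOL = Fraction(10_000_001, 10_000_000)


def _table_prob(N: int, row1: int, col1: int, x: int) -> Fraction:
    # P(table | margins) via the factorial form of the hypergeometric law.
    return Fraction(
        _fact(row1) * _fact(N - row1) * _fact(col1) * _fact(N - col1),
        _fact(N)
        * _fact(x)
        * _fact(row1 - x)
        * _fact(col1 - x)
        * _fact(N - row1 - col1 + x),
    )


def fisher_two_sided_margin(N: int, row1: int, col1: int) -> dict[int, Fraction]:
    """Exact two-sided p for every admissible cell a, given fixed margins."""
    lo = max(0, row1 + col1 - N)
    hi = min(row1, col1)
    support = list(range(lo, hi + 1))
    probs = [_table_prob(N, row1, col1, x) for x in support]
    order = sorted(range(len(probs)), key=probs.__getitem__)
    sorted_probs = [probs[i] for i in order]
    prefix: list[Fraction] = []
    running = Fraction(0)
    for prob in sorted_probs:
        running += prob
        prefix.append(running)
    out: dict[int, Fraction] = {}
    for idx, a in enumerate(support):
        threshold = probs[idx] * _REL_TOL
        pos = bisect.bisect_right(sorted_probs, threshold)
        out[a] = min(prefix[pos - 1], Fraction(1)) if pos else Fraction(0)
    return out


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p for one table, by full-margin enumeration."""
    return fisher_two_sided_margin(a + b + c + d, a + b, a + c)[a]


def upset_brute_force(hits: dict[str, frozenset[str]]) -> dict[frozenset[str], int]:
    """Exact intersection counts by direct subset enumeration."""
    import itertools

    species = sorted(hits)
    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(species) + 1):
        for combo in itertools.combinations(species, r):
            inside = set.intersection(*(set(hits[s]) for s in combo))
            for other in species:
                if other not in combo:
                    inside -= hits[other]
            if inside:
                counts[frozenset(combo)] = len(inside)
    return counts
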