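"""Degenerate IUPAC motif parsing, double-strand scanning and pair detection.

The central object is the :class:`DegenerateMotif`: a named IUPAC pattern such
as the CreA repressor site 5'-SYGGRG-3' or the AmyR site 5'-CGGN{8}CGG-3'
(a gapped dyad; ``N{k}`` expands to k don't-care positions).  Scanning reports
every offset on either strand of a promoter where the window satisfies the
pattern, including overlapping hits.  A pattern position N matches any base
(including an ambiguous N in the sequence); every informative pattern position
requires a concrete A/C/G/T in the sequence, so runs of N in a genome can
never fake a binding site.

Adjacent same-motif pairs — the proxy for functional tandem repressor sites —
are counted as unordered pairs of distinct matches whose start coordinates lie
within a window (100 bp by default, inclusive), regardless of strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

MIN_MOTIF_LENGTH = 4


class MotifError(ValueError):
    """Raised for invalid motif definitions."""


@dataclass(frozen=True)
class DegenerateMotif:
    """A named IUPAC pattern; ``pattern`` is fully expanded (no gap syntax)."""

    name: str
    pattern: str

    @property
    def length(self) -> int:
        return len(self.pattern)


def parse_motif(name: str, raw_pattern: str) -> DegenerateMotif:
    """Parse a motif given as IUPAC letters, bracket classes or N{k} gaps.

    Bracket classes are normalized to the unique IUPAC code ([AG] -> R,
    [AGT] -> D, ...); ``N{k}`` (or any letter followed by {k}) is expanded to
    k copies.  The expanded pattern must be at least 4 positions long.
    """
    pattern: list[str] = []
    i = 0
    raw = raw_pattern.strip().upper()
    while i < len(raw):
        ch = raw[i]
        if ch == "[":
            j = raw.find("]", i)
            if j < 0:
                raise MotifError(f"motif {name!r}: unterminated bracket class")
            members = raw[i + 1 : j]
            if not members:
                raise MotifError(f"motif {name!r}: empty bracket class")
            if any(m not in "ACGT" for m in members):
                raise MotifError(
                    f"motif {name!r}: bracket class {members!r} must contain "
                    "only A/C/G/T"
                )
            code = _SET_TO_CODE[frozenset(members)]
            pattern.append(code)
            i = j + 1
        elif ch in IUPAC_SETS:
            code = ch
            i += 1
            if i < len(raw) and raw[i] == "{":
                j = raw.find("}", i)
                if j < 0:
                    raise MotifError(f"motif {name!r}: unterminated gap {{k}}")
                try:
                    k = int(raw[i + 1 : j])
                except ValueError:
                    raise MotifError(
                        f"motif {name!r}: non-integer gap length"
                    ) from None
                if k <= 0:
                    raise MotifError(f"motif {name!r}: gap length must be > 0")
                pattern.extend(code * k)
                i = j + 1
            else:
                pattern.append(code)
        else:
            raise MotifError(
                f"motif {name!r}: character {ch!r} outside IUPAC alphabet"
            )
    expanded = "".join(pattern)
    if len(expanded) < MIN_MOTIF_LENGTH:
        raise MotifError(
            f"motif {name!r}: expanded length {len(expanded)} < "
            f"{MIN_MOTIF_LENGTH}"
        )
    return DegenerateMotif(name=name, pattern=expanded)


def reverse_complement_motif(motif: DegenerateMotif) -> DegenerateMotif:
    """Reversed, IUPAC-complemented motif (same name)."""
    rc = "".join(IUPAC_COMPLEMENT[c] for c in reversed(motif.pattern))
    return DegenerateMotif(name=motif.name, pattern=rc)


def expand_iupac(
    motif: DegenerateMotif, limit: int = 65536
) -> frozenset[str]:
    """All concrete A/C/G/T strings matching the pattern.

    Refuses patterns whose expansion exceeds ``limit`` sequences.
    """
    count = 1
    for ch in motif.pattern:
        count *= len(IUPAC_SETS[ch])
    if count > limit:
        raise MotifError(
            f"motif {motif.name!r}: expansion size {count} exceeds limit "
            f"{limit}"
        )
    expansions = [""]
    for ch in motif.pattern:
        expansions = [
            prefix + base
            for prefix in expansions
            for base in sorted(IUPAC_SETS[ch])
        ]
    return frozenset(expansions)


@lru_cache(maxsize=512)
def _compile_pattern(pattern: str) -> re.Pattern[str]:
    # Lookahead so overlapping matches are all reported.
    parts = []
    for ch in pattern:
        if ch == "N":
            parts.append("[ACGTN]")
        else:
            allowed = "".join(sorted(IUPAC_SETS[ch]))
            parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return re.compile("(?=" + "".join(parts) + ")")


@dataclass(frozen=True)
class MotifMatch:
    """One motif hit, in promoter-local 0-based coordinates.

    ``site`` is the matched substring as written on the promoter (+) string,
    regardless of the matched strand.
    """

    gene_id: str
    motif_name: str
    start: int
    strand: str
    site: str


def scan_sequence(
    gene_id: str,
    promoter: str,
    motif: DegenerateMotif,
    both_strands: bool = True,
) -> list[MotifMatch]:
    """All matches of ``motif`` in ``promoter``, both strands by default.

    A minus-strand hit at offset i means the window promoter[i:i+len] matches
    the reverse complement of the pattern.  Output is sorted by
    (start, strand); a promoter shorter than the motif yields no matches.
    """
    seq = promoter.upper()
    length = motif.length
    if len(seq) < length:
        return []
    matches: list[MotifMatch] = []
    for m in _compile_pattern(motif.pattern).finditer(seq):
        i = m.start()
        matches.append(MotifMatch(gene_id, motif.name, i, "+", seq[i : i + length]))
    if both_strands:
        rc = reverse_complement_motif(motif)
        for m in _compile_pattern(rc.pattern).finditer(seq):
            i = m.start()
            matches.append(
                MotifMatch(gene_id, motif.name, i, "-", seq[i : i + length])
            )
    matches.sort(key=lambda match: (match.start, match.strand))
    return matches


def find_adjacent_pairs(
    matches: Sequence[MotifMatch], window: int = 100
) -> tuple[int, bool]:
    """Count unordered pairs of distinct matches within ``window`` bp.

    Distance is start-to-start, inclusive at the boundary; strand combination
    is unrestricted.  All matches must belong to one (gene, motif).
    Returns (pair_count, has_adjacent_pair).
    """
    import bisect

    if window < 0:
        raise ValueError("window must be non-negative")
    if not matches:
        return 0, False
    keys = {(m.gene_id, m.motif_name) for m in matches}
    if len(keys) > 1:
        raise ValueError(
            f"matches span multiple (gene, motif) groups: {sorted(keys)}"
        )
    distinct = sorted({(m.start, m.strand) for m in matches})
    starts = [s for s, _ in distinct]
    pair_count = 0
    for j, sj in enumerate(starts):
        i = bisect.bisect_left(starts, sj - window)
        pair_count += j - i
    return pair_count, pair_count >= 1


PRESENCE_COLUMNS = [
    "gene_id",
    "motif",
    "match_count",
    "has_single",
    "pair_count",
    "has_adjacent_pair",
    "window",
]


def build_presence_table(
    promoters,
    motifs: Sequence[DegenerateMotif],
    window: int = 100,
) -> pd.DataFrame:
    """Per-(gene, motif) match counts and single/pair presence flags.

    ``promoters`` is a {gene_id: sequence} mapping or an iterable of
    PromoterRecord.  Rows are ordered by (gene_id, motif).
    """
    if isinstance(promoters, Mapping):
        seqs = dict(promoters)
    else:
        seqs = {}
        for rec in promoters:
            if rec.gene_id in seqs:
                raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
            seqs[rec.gene_id] = rec.sequence
    rows = []
    for gene_id in sorted(seqs):
        for motif in sorted(motifs, key=lambda m: m.name):
            matches = scan_sequence(gene_id, seqs[gene_id], motif)
            pair_count, has_pair = find_adjacent_pairs(matches, window=window)
            rows.append(
                {
                    "gene_id": gene_id,
                    "motif": motif.name,
                    "match_count": len(matches),
                    "has_single": len(matches) >= 1,
                    "pair_count": pair_count,
                    "has_adjacent_pair": has_pair,
                    "window": window,
                }
            )
    return pd.DataFrame(rows, columns=PRESENCE_COLUMNS)


def genes_with_feature(
    presence: pd.DataFrame, motif_name: str, feature_kind: str
) -> frozenset[str]:
    """Genes whose promoter has the feature for one motif.

    ``feature_kind`` is "single" (at least one match) or "adjacent_pair"
    (at least one pair within the table's window).
    """
    if feature_kind == "single":
        column = "has_single"
    elif feature_kind == "adjacent_pair":
        column = "has_adjacent_pair"
    else:
        raise ValueError(f"unknown feature_kind {feature_kind!r}")
    sub = presence[presence["motif"] == motif_name]
    if sub.empty:
        raise KeyError(f"motif {motif_name!r} absent from presence table")
    return frozenset(sub.loc[sub[column], "gene_id"])


def matches_to_frame(matches: Iterable[MotifMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": m.gene_id,
                "motif": m.motif_name,
                "start": m.start,
                "strand": m.strand,
                "site": m.site,
            }
            for m in matches
        ],
        columns=["gene_id", "motif", "start", "strand", "site"],
    )


def read_motifs_tsv(path: str | Path) -> list[DegenerateMotif]:
    """Read motif definitions from a two-column (name, pattern) TSV."""
    table = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in table.columns]
    if cols[:2] != ["name", "pattern"]:
        raise MotifError(
            f"{path}: expected columns (name, pattern), got {list(table.columns)}"
        )
    return [
        parse_motif(str(row.iloc[0]), str(row.iloc[1]))
        for _, row in table.iterrows()
    ]


def read_presence_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(PRESENCE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing presence columns {sorted(missing)}")
    return table


# The CreA repressor site, its two sub-motifs, and the activator sites used
# for co-occurrence analysis (XlnR, AraR, RhaR, GaaR, AmyR).
MOTIF_DEFINITIONS: list[tuple[str, str]] = [
    ("SYGGRG", "SYGGRG"),
    ("SYGGGG", "SYGGGG"),
    ("SYGGAG", "SYGGAG"),
    ("XlnR", "GGCTA[AG]"),
    ("AraR", "CGG[AGT]TAA[AT]"),
    ("RhaR", "TG[CAG][GTA]GGG"),
    ("GaaR", "CC[ACGT]CCAA"),
    ("AmyR", "CGGN{8}CGG"),
]

ACTIVATOR_NAMES = ["XlnR", "AraR", "RhaR", "GaaR", "AmyR"]


def default_motifs() -> list[DegenerateMotif]:
    """The eight built-in motifs (CreA site, sub-motifs, five activators)."""
    return [parse_motif(name, raw) for name, raw in MOTIF_DEFINITIONS]
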