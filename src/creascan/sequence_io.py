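"""Sequence and annotation I/O, and strand-aware promoter extraction.

Promoters are the fixed-length windows immediately upstream of the annotated
gene start (1000 bp by default, following the convention used for fungal
regulatory-motif surveys).  All internal coordinates are 0-based, half-open;
GFF3 input (1-based, inclusive) is converted on read.  Promoter sequences are
written 5'->3' on the gene's own strand, so the base adjacent to the coding
start is always the last character.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# IUPAC ambiguity codes other than N are degraded to N on genome read.
_AMBIGUOUS = set("RYSWKMBDHV")
_VALID_BASES = set("ACGTN")


class FastaFormatError(ValueError):
    """Raised for malformed or degenerate FASTA input."""


class AnnotationError(ValueError):
    """Raised for malformed annotation records."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One gene's coordinates: 0-based, half-open interval on a contig."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise AnnotationError(
                f"gene {self.gene_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )


@dataclass
class PromoterRecord:
    """Upstream sequence of one gene, 5'->3' on the gene's strand.

    ``source`` records the genomic provenance as (contig, start, end, strand)
    in 0-based half-open genome coordinates.  ``truncated`` is set when the
    contig edge cut the window short (actual_length < target_length).
    """

    gene_id: str
    sequence: str
    target_length: int
    actual_length: int
    source: tuple[str, int, int, str]
    truncated: bool = False


def _normalize_sequence(seq_id: str, raw: str) -> str:
    seq = raw.upper()
    bad = set(seq) - _VALID_BASES
    if bad & _AMBIGUOUS:
        logger.warning(
            "record %s: ambiguity codes %s converted to N",
            seq_id,
            "".join(sorted(bad & _AMBIGUOUS)),
        )
        seq = seq.translate(str.maketrans({c: "N" for c in _AMBIGUOUS}))
        bad = set(seq) - _VALID_BASES
    if bad:
        raise FastaFormatError(
            f"record {seq_id!r}: invalid characters {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {id: uppercase sequence}.

    The id is the header token before the first whitespace.  Zero-length
    records, duplicate ids, and files that do not start with a header are
    rejected.
    """
    path = Path(path)
    text_head = ""
    with open(path) as handle:
        for line in handle:
            if line.strip():
                text_head = line
                break
    if not text_head:
        raise FastaFormatError(f"{path}: empty FASTA file (line 1)")
    if not text_head.startswith(">"):
        raise FastaFormatError(
            f"{path}: malformed header, first record line does not start "
            f"with '>': {text_head.strip()!r}"
        )
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if len(record.seq) == 0:
            raise FastaFormatError(
                f"{path}: zero-length record {record.id!r}"
            )
        if record.id in sequences:
            raise FastaFormatError(
                f"{path}: duplicate sequence id {record.id!r}"
            )
        sequences[record.id] = _normalize_sequence(record.id, str(record.seq))
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write {id: sequence} as wrapped FASTA."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-"}


def _parse_strand(symbol: str, line_no: int) -> str:
    try:
        return _STRAND_ALIASES[symbol]
    except KeyError:
        raise AnnotationError(
            f"line {line_no}: unknown strand symbol {symbol!r}"
        ) from None


def _gff3_genes(path: Path, feature_type: str) -> Iterable[GeneModel]:
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"line {line_no}: expected 9 GFF3 columns, got {len(fields)}"
                )
            if fields[2] != feature_type:
                continue
            contig = fields[0]
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"line {line_no}: non-integer coordinates"
                ) from None
            strand = _parse_strand(fields[6], line_no)
            gene_id = None
            for item in fields[8].split(";"):
                key, _, value = item.strip().partition("=")
                if key == "ID":
                    gene_id = value
                    break
            if not gene_id:
                raise AnnotationError(f"line {line_no}: missing ID attribute")
            if end1 < start1:
                raise AnnotationError(
                    f"line {line_no}: end < start for gene {gene_id!r}"
                )
            # 1-based inclusive -> 0-based half-open
            yield GeneModel(gene_id, contig, start1 - 1, end1, strand)


def _tsv_genes(path: Path) -> Iterable[GeneModel]:
    with open(path) as handle:
        header_line = handle.readline()
        sep = "\t" if "\t" in header_line else ","
        header = [h.strip() for h in header_line.rstrip("\n").split(sep)]
        expected = ["gene_id", "contig", "start", "end", "strand"]
        if [h.lower() for h in header[:5]] != expected:
            raise AnnotationError(
                f"line 1: expected header {expected}, got {header}"
            )
        for line_no, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(sep)
            if len(fields) < 5:
                raise AnnotationError(
                    f"line {line_no}: expected 5 columns, got {len(fields)}"
                )
            gene_id, contig = fields[0].strip(), fields[1].strip()
            try:
                start, end = int(fields[2]), int(fields[3])
            except ValueError:
                raise AnnotationError(
                    f"line {line_no}: non-integer coordinates"
                ) from None
            strand = _parse_strand(fields[4].strip(), line_no)
            if end <= start:
                raise AnnotationError(
                    f"line {line_no}: end <= start for gene {gene_id!r}"
                )
            yield GeneModel(gene_id, contig, start, end, strand)


def read_annotation(
    path: str | Path, dialect: str = "gff3", feature_type: str = "gene"
) -> list[GeneModel]:
    """Read gene coordinates from a GFF3 subset or a tabular annotation.

    GFF3: only lines whose feature type matches ``feature_type`` are used and
    1-based inclusive coordinates are converted to 0-based half-open.  The
    tabular dialect (gene_id, contig, start, end, strand with a header row,
    tab- or comma-separated) is taken as already 0-based half-open.
    """
    path = Path(path)
    if dialect == "gff3":
        genes = list(_gff3_genes(path, feature_type))
    elif dialect == "tsv":
        genes = list(_tsv_genes(path))
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    seen: set[str] = set()
    for gene in genes:
        if gene.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {gene.gene_id!r}")
        seen.add(gene.gene_id)
    return genes


def extract_promoters(
    genome: Mapping[str, str],
    genes: Iterable[GeneModel],
    length: int = 1000,
) -> list[PromoterRecord]:
    """Extract the upstream window of each gene, strand-aware.

    Plus-strand genes take genome[start-length, start); minus-strand genes
    take the reverse complement of genome[end, end+length).  Windows clipped
    by a contig edge are kept with ``truncated=True``; genes whose window is
    empty (gene flush against the edge) are skipped with a warning.
    """
    if length <= 0:
        raise ValueError("promoter length must be positive")
    promoters: list[PromoterRecord] = []
    for gene in genes:
        if gene.contig not in genome:
            raise KeyError(
                f"gene {gene.gene_id!r}: contig {gene.contig!r} not in genome"
            )
        contig_seq = genome[gene.contig]
        if gene.strand == "+":
            lo = max(0, gene.start - length)
            hi = gene.start
            seq = contig_seq[lo:hi]
        else:
            lo = gene.end
            hi = min(len(contig_seq), gene.end + length)
            seq = reverse_complement(contig_seq[lo:hi])
        if not seq:
            logger.warning(
                "gene %s: zero-length promoter at contig edge, skipped",
                gene.gene_id,
            )
            continue
        promoters.append(
            PromoterRecord(
                gene_id=gene.gene_id,
                sequence=seq,
                target_length=length,
                actual_length=len(seq),
                source=(gene.contig, lo, hi, gene.strand),
                truncated=len(seq) < length,
            )
        )
    return promoters


def write_promoters_fasta(
    promoters: Iterable[PromoterRecord], path: str | Path, width: int = 60
) -> None:
    """Write promoters as FASTA with provenance in the description."""
    with open(path, "w") as handle:
        for rec in promoters:
            contig, lo, hi, strand = rec.source
            handle.write(
                f">{rec.gene_id} promoter:{contig}:{lo}-{hi}({strand})\n"
            )
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-gene-per-line text file, ignoring blanks."""
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]
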