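"""Genome I/O and coordinate conventions.

All internal coordinates are 0-based half-open. Both supported annotation
dialects (GFF3 and a simple TSV) are 1-based inclusive; conversion happens
only at the I/O boundary. On circular replicons an origin-spanning feature
is encoded as ``end <= start`` (never as ``end > L``): the footprint runs
from ``start`` to the sequence end and wraps to ``end``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


@dataclass(frozen=True)
class GenomeRecord:
    """A single replicon: sequence plus circularity flag."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-nucleotide characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene.

    ``start``/``end`` are 0-based half-open; on a circular genome
    ``end <= start`` encodes an origin-spanning gene.
    """

    gene_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if self.start < 0 or self.end < 0:
            raise FormatError(f"gene {self.gene_id!r}: negative coordinate")

    def length(self, L: int) -> int:
        """Gene length in nt on a replicon of length L (wrap-aware)."""
        if self.end > self.start:
            return self.end - self.start
        return L - self.start + self.end

    def positions(self, L: int) -> Iterable[int]:
        """Genomic positions covered by the gene, in reading order on +."""
        if self.end > self.start:
            return range(self.start, self.end)
        return [*range(self.start, L), *range(0, self.end)]


def normalize_seq(raw: str) -> str:
    """Uppercase and map U->T; validation happens in GenomeRecord."""
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path, circular_default: bool = False) -> list[GenomeRecord]:
    """Read a (multi-)FASTA into GenomeRecords.

    Circularity is taken from a ``circular=true`` token in the header if
    present, otherwise from ``circular_default``.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        circular = circular_default
        for token in rec.description.split():
            if token.lower() in ("circular=true", "circular=false"):
                circular = token.lower().endswith("true")
        records.append(GenomeRecord(rec.id, normalize_seq(str(rec.seq)), circular))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Sequence[GenomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} circular={'true' if rec.circular else 'false'}\n")
            for i in range(0, rec.length, 70):
                fh.write(rec.seq[i : i + 70] + "\n")


def _check_coord(value: int, L: int | None, gene_id: str) -> None:
    if value < 1 or (L is not None and value > L):
        raise FormatError(f"gene {gene_id!r}: coordinate {value} outside [1, {L}]")


def _to_internal(start1: int, end1: int, gene_id: str, L: int | None) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open; start1 > end1 encodes a wrap."""
    _check_coord(start1, L, gene_id)
    _check_coord(end1, L, gene_id)
    if end1 >= start1:
        return start1 - 1, end1
    # origin-spanning: [start1, L] + [1, end1] -> internal end <= start
    if L is not None and end1 == L:  # pragma: no cover - defensive
        raise FormatError(f"gene {gene_id!r}: degenerate wrap")
    return start1 - 1, end1


def read_annotations(
    path: str | Path, dialect: str = "gff3", L: int | None = None
) -> list[GeneModel]:
    """Read gene annotations in GFF3 (CDS/gene rows) or TSV dialect.

    TSV columns: gene_id, start, end, strand (tab-separated, 1-based
    inclusive, optional header line starting with ``gene_id`` or ``#``).
    Returned list is sorted by start. ``L`` enables bound checking.
    """
    if dialect not in ("gff3", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "gff3":
                if len(fields) != 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
                if fields[2] not in ("CDS", "gene"):
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID")
                if gene_id is None:
                    raise FormatError(f"{path}:{lineno}: missing ID attribute")
                start1, end1, strand = int(fields[3]), int(fields[4]), fields[6]
            else:
                if fields[0] in ("gene_id",):
                    continue
                if len(fields) != 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 TSV columns")
                gene_id, strand = fields[0], fields[3]
                start1, end1 = int(fields[1]), int(fields[2])
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            start, end = _to_internal(start1, end1, gene_id, L)
            genes.append(GeneModel(gene_id, start, end, strand))
    genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return genes


def write_annotations(
    genes: Sequence[GeneModel],
    path: str | Path,
    dialect: str = "gff3",
    seqid: str = "genome",
    L: int | None = None,
) -> None:
    """Write annotations back out in 1-based inclusive coordinates."""
    if dialect not in ("gff3", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
        else:
            fh.write("gene_id\tstart\tend\tstrand\n")
        for g in genes:
            start1 = g.start + 1
            end1 = g.end if g.end > g.start else g.end  # wrap keeps end1 == g.end
            if dialect == "gff3":
                fh.write(
                    f"{seqid}\thairpinrule\tCDS\t{start1}\t{end1}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}\n"
                )
            else:
                fh.write(f"{g.gene_id}\t{start1}\t{end1}\t{g.strand}\n")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; involution, N<->N."""
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"non-alphabet characters {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def write_sites_bed(sites, genome: GenomeRecord, path: str | Path) -> None:
    """BED6 output of palindrome site footprints.

    Origin-spanning footprints on a circular genome are split into two BED
    lines sharing the site name. Score column carries the stem length.
    """
    L = genome.length
    with open(path, "w") as fh:
        fh.write("# BED6: chrom start end name score strand\n")
        for site in sites:
            start, end = site.span
            if end > start:
                segments = [(start, end)]
            else:  # wraps the origin
                segments = [(start, L), (0, end)]
            for seg_start, seg_end in segments:
                fh.write(
                    f"{genome.id}\t{seg_start}\t{seg_end}\t{site.site_id}\t"
                    f"{site.stem_len}\t.\n"
                )
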