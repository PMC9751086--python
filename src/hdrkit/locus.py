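"""Coordinate system, sequence containers and variant representation.

Everything positional in this package flows through two conventions:

* internal coordinates are 0-based, half-open (``GenomicInterval``);
* anything facing VCF or HGVS-like ``c.`` notation is 1-based
  (``PointVariant.position``, ``c_to_genomic``).

A ``CodingMap`` translates coding-sequence (``c.``) positions of a gene to
genomic coordinates and back, so that edits specified as e.g. ``c.1935C>A``
can be realised on a reference contig regardless of gene strand or exon
structure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "PointVariant",
    "CodingMap",
    "ReferenceLocus",
    "revcomp",
    "complement_base",
    "translate",
    "c_to_genomic",
    "genomic_to_c",
    "codon_of",
    "read_fasta",
    "write_fasta",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def translate(cds: str) -> str:
    """Translate a nucleotide string with the standard nuclear codon table."""
    return str(Seq(cds).translate())


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos0: int) -> bool:
        """Whether a 0-based position lies inside the interval."""
        return self.start <= pos0 < self.end

    def spans(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


_HGVS_C_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")


@dataclass(frozen=True)
class PointVariant:
    """A single-nucleotide substitution, 1-based, on the plus strand.

    ``label`` optionally carries the HGVS-like coding-coordinate name
    (e.g. ``"c.1935C>A"``); it is annotation only and never used for
    positional arithmetic.
    """

    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("PointVariant is single-nucleotide only")
        if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
            raise ValueError(f"bases must be ACGT, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")

    @property
    def pos0(self) -> int:
        return self.position - 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref, self.alt)

    @staticmethod
    def parse_c_label(label: str) -> tuple[int, str, str]:
        """Parse the supported ``c.<pos><ref>><alt>`` subset of HGVS."""
        m = _HGVS_C_RE.match(label)
        if m is None:
            raise ValueError(f"cannot parse coding variant label {label!r}")
        return int(m.group(1)), m.group(2), m.group(3)


class CodingMap:
    """Ordered CDS segments mapping coding (c.) positions to the genome.

    Parameters
    ----------
    segments
        Iterable of ``(GenomicInterval, first_c)`` pairs where ``first_c``
        is the coding position of the gene-strand first base of that
        segment.  Segments must be given in gene order (increasing c.).
    gene_strand
        ``"+"`` or ``"-"``; on minus-strand genes increasing c. runs along
        decreasing genomic coordinate.
    """

    def __init__(
        self,
        segments: Iterable[tuple[GenomicInterval, int]],
        gene_strand: str = "+",
        gene: str = "gene",
    ) -> None:
        if gene_strand not in ("+", "-"):
            raise ValueError("gene_strand must be '+' or '-'")
        self.gene_strand = gene_strand
        self.gene = gene
        self.segments: list[tuple[GenomicInterval, int]] = list(segments)
        if not self.segments:
            raise ValueError("CodingMap needs at least one CDS segment")
        last_end = None
        for iv, first_c in self.segments:
            if last_end is not None and first_c != last_end + 1:
                raise ValueError(
                    "c. positions must be contiguous and strictly increasing "
                    f"along the gene strand; segment starting c.{first_c} "
                    f"follows c.{last_end}"
                )
            last_end = first_c + len(iv) - 1
        for (a, _), (b, _) in zip(self.segments, self.segments[1:]):
            if a.contig == b.contig and a.start < b.end and b.start < a.end:
                raise ValueError("CDS segments overlap")

    @property
    def c_min(self) -> int:
        return self.segments[0][1]

    @property
    def c_max(self) -> int:
        iv, first_c = self.segments[-1]
        return first_c + len(iv) - 1

    def __len__(self) -> int:
        return self.c_max - self.c_min + 1

    def c_to_genomic(self, c_pos: int) -> tuple[str, int]:
        """Map a coding position to ``(contig, 1-based genomic position)``."""
        for iv, first_c in self.segments:
            offset = c_pos - first_c
            if 0 <= offset < len(iv):
                if self.gene_strand == "+":
                    return iv.contig, iv.start + 1 + offset
                return iv.contig, iv.end - offset
        raise ValueError(
            f"c.{c_pos} outside mapped coding range "
            f"c.{self.c_min}..c.{self.c_max}"
        )

    def genomic_to_c(self, contig: str, position: int) -> int:
        """Inverse of :meth:`c_to_genomic` (1-based genomic input)."""
        pos0 = position - 1
        for iv, first_c in self.segments:
            if iv.contig == contig and iv.contains(pos0):
                if self.gene_strand == "+":
                    return first_c + (pos0 - iv.start)
                return first_c + (iv.end - 1 - pos0)
        raise ValueError(f"{contig}:{position} is not inside any CDS segment")

    def iter_c_positions(self) -> Iterator[int]:
        return iter(range(self.c_min, self.c_max + 1))

    # ------------------------------------------------------------------
    # Serialization: BED-like TSV, 0-based half-open, with a header line
    # naming the gene and its strand.  Columns: contig, start, end, first_c.
    # ------------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#cds_map\tgene={self.gene}\tstrand={self.gene_strand}\n")
            for iv, first_c in self.segments:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{first_c}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodingMap":
        segments: list[tuple[GenomicInterval, int]] = []
        gene_strand = "+"
        gene = "gene"
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    for token in line.split("\t"):
                        if token.startswith("strand="):
                            gene_strand = token.split("=", 1)[1]
                        elif token.startswith("gene="):
                            gene = token.split("=", 1)[1]
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise ValueError(
                        f"{path}:{lineno}: expected 4 tab-separated fields"
                    )
                contig, start, end, first_c = fields
                segments.append(
                    (
                        GenomicInterval(contig, int(start), int(end)),
                        int(first_c),
                    )
                )
        return cls(segments, gene_strand=gene_strand, gene=gene)


def c_to_genomic(cmap: CodingMap, c_pos: int) -> tuple[str, int]:
    """Functional alias for :meth:`CodingMap.c_to_genomic`."""
    return cmap.c_to_genomic(c_pos)


def genomic_to_c(cmap: CodingMap, contig: str, position: int) -> int:
    return cmap.genomic_to_c(contig, position)


def _cds_sequence(cmap: CodingMap, genome: Mapping[str, str]) -> str:
    parts = []
    for iv, _ in cmap.segments:
        seg = genome[iv.contig][iv.start : iv.end]
        parts.append(seg if cmap.gene_strand == "+" else revcomp(seg))
    return "".join(parts)


def codon_of(
    cmap: CodingMap, c_pos: int, genome: Mapping[str, str]
) -> tuple[str, int]:
    """Return ``(codon, offset_in_codon)`` for a coding position.

    The codon is read on the gene strand; ``offset`` is ``(c_pos - 1) % 3``.
    Raises if the codon is incomplete (runs off the mapped CDS range).
    """
    cmap.c_to_genomic(c_pos)  # range check with a helpful message
    offset = (c_pos - 1) % 3
    first = c_pos - offset
    if first < cmap.c_min or first + 2 > cmap.c_max:
        raise ValueError(
            f"codon containing c.{c_pos} is incomplete within the mapped CDS"
        )
    bases = []
    for c in (first, first + 1, first + 2):
        contig, pos = cmap.c_to_genomic(c)
        base = genome[contig][pos - 1]
        bases.append(base if cmap.gene_strand == "+" else complement_base(base))
    return "".join(bases), offset


class ReferenceLocus:
    """Reference contigs plus the coding map and intended target edit.

    The container all pipeline stages share: sequences are plain uppercase
    strings keyed by contig name; the coding map anchors ``c.`` notation;
    ``target_edit`` is the knock-in substitution the experiment installs.
    """

    def __init__(
        self,
        contigs: Mapping[str, str],
        coding_map: CodingMap,
        target_edit: PointVariant,
    ) -> None:
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}
        self.coding_map = coding_map
        self.target_edit = target_edit
        self._validate()

    def _validate(self) -> None:
        for iv, _ in self.coding_map.segments:
            if iv.contig not in self.contigs:
                raise ValueError(f"CDS contig {iv.contig!r} not in reference")
            if iv.end > len(self.contigs[iv.contig]):
                raise ValueError(f"CDS segment {iv} exceeds contig length")
        te = self.target_edit
        ref = self.base_at(te.contig, te.position)
        if ref != te.ref:
            raise ValueError(
                f"target edit ref {te.ref} does not match reference base "
                f"{ref} at {te.contig}:{te.position}"
            )
        # target must be codable
        self.coding_map.genomic_to_c(te.contig, te.position)
        protein = translate(self.cds_sequence())
        if "*" in protein[:-1]:
            raise ValueError("CDS translation contains an internal stop codon")

    def base_at(self, contig: str, position: int) -> str:
        """1-based single-base access."""
        return self.contigs[contig][position - 1]

    def fetch(self, interval: GenomicInterval) -> str:
        seq = self.contigs[interval.contig][interval.start : interval.end]
        return seq if interval.strand == "+" else revcomp(seq)

    def cds_sequence(self, genome: Mapping[str, str] | None = None) -> str:
        return _cds_sequence(self.coding_map, genome or self.contigs)

    def codon_of(self, c_pos: int) -> tuple[str, int]:
        return codon_of(self.coding_map, c_pos, self.contigs)

    def apply_variant(self, variant: PointVariant) -> None:
        """Install a substitution in place (ref base is checked first)."""
        seq = self.contigs[variant.contig]
        if seq[variant.pos0] != variant.ref:
            raise ValueError(
                f"reference base at {variant.contig}:{variant.position} is "
                f"{seq[variant.pos0]}, not {variant.ref}"
            )
        self.contigs[variant.contig] = (
            seq[: variant.pos0] + variant.alt + seq[variant.position :]
        )

    def revert_variant(self, variant: PointVariant) -> None:
        """Undo :meth:`apply_variant`."""
        seq = self.contigs[variant.contig]
        if seq[variant.pos0] != variant.alt:
            raise ValueError("variant is not currently applied")
        self.contigs[variant.contig] = (
            seq[: variant.pos0] + variant.ref + seq[variant.position :]
        )

    def variant_from_c_label(self, label: str) -> PointVariant:
        """Build a genomic PointVariant from a ``c.<pos><ref>><alt>`` label.

        ref/alt in the label are gene-strand bases; the returned variant is
        plus-strand genomic.
        """
        c_pos, ref, alt = PointVariant.parse_c_label(label)
        contig, position = self.coding_map.c_to_genomic(c_pos)
        if self.coding_map.gene_strand == "-":
            ref, alt = complement_base(ref), complement_base(alt)
        return PointVariant(contig, position, ref, alt, label=label)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        record.id: str(record.seq).upper()
        for record in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(contigs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
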