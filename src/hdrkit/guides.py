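"""SpCas9 guide enumeration and dual-overlapping-guide geometry.

A guide is a 20-nt protospacer followed (3') by an NGG PAM.  The blunt
double-strand break is placed 3 bp 5' of the PAM, i.e. between protospacer
positions 17 and 18; the seed is the 5 PAM-proximal protospacer
nucleotides, where mismatches most strongly block re-cutting.  Both facts
drive donor design downstream: shield mutations are installed in the PAM
or seed so the repaired allele resists further cleavage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .locus import GenomicInterval, PointVariant, revcomp

__all__ = [
    "PROTOSPACER_LEN",
    "GuideSpec",
    "DualOverlapReport",
    "find_guides",
    "guide_from_protospacer",
    "dual_overlap_report",
    "read_guides_tsv",
    "write_guides_tsv",
]

logger = logging.getLogger(__name__)

PROTOSPACER_LEN = 20
_PAM_LEN = 3
_CUT_OFFSET = 3  # nt 5' of the PAM
_SEED_LEN = 5


def _is_ngg(pam: str) -> bool:
    return len(pam) == 3 and pam[1] == "G" and pam[2] == "G"


@dataclass(frozen=True)
class GuideSpec:
    """A located SpCas9 guide.

    ``protospacer`` is stored in guide orientation (5'->3' as synthesised);
    on minus-strand guides it is therefore the reverse complement of the
    plus-strand reference slice.  ``cut_site`` is a 0-based inter-base
    genomic coordinate.  ``seed`` is the genomic footprint of the 5
    PAM-proximal protospacer nucleotides.
    """

    name: str
    protospacer: str
    strand: str
    contig: str
    pam: str
    pam_interval: GenomicInterval
    protospacer_interval: GenomicInterval
    cut_site: int
    seed: GenomicInterval

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if not _is_ngg(self.pam):
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    def revalidate(self, genome: Mapping[str, str]) -> bool:
        """Re-extract protospacer and PAM from the genome and compare."""
        seq = genome[self.contig]
        ps = seq[self.protospacer_interval.start : self.protospacer_interval.end]
        pam = seq[self.pam_interval.start : self.pam_interval.end]
        if self.strand == "-":
            ps, pam = revcomp(ps), revcomp(pam)
        return ps == self.protospacer and pam == self.pam


def _build_guide(
    contig: str, seq: str, start: int, strand: str, name: str
) -> GuideSpec:
    """Build a GuideSpec from the protospacer's plus-strand start offset."""
    ps_iv = GenomicInterval(contig, start, start + PROTOSPACER_LEN, strand)
    if strand == "+":
        pam_iv = GenomicInterval(contig, ps_iv.end, ps_iv.end + _PAM_LEN, "+")
        protospacer = seq[ps_iv.start : ps_iv.end]
        pam = seq[pam_iv.start : pam_iv.end]
        cut = ps_iv.end - _CUT_OFFSET
        seed = GenomicInterval(contig, ps_iv.end - _SEED_LEN, ps_iv.end, "+")
    else:
        pam_iv = GenomicInterval(contig, ps_iv.start - _PAM_LEN, ps_iv.start, "-")
        protospacer = revcomp(seq[ps_iv.start : ps_iv.end])
        pam = revcomp(seq[pam_iv.start : pam_iv.end])
        cut = ps_iv.start + _CUT_OFFSET
        seed = GenomicInterval(
            contig, ps_iv.start, ps_iv.start + _SEED_LEN, "-"
        )
    return GuideSpec(
        name=name,
        protospacer=protospacer,
        strand=strand,
        contig=contig,
        pam=pam,
        pam_interval=pam_iv,
        protospacer_interval=ps_iv,
        cut_site=cut,
        seed=seed,
    )


def find_guides(
    genome: Mapping[str, str], region: GenomicInterval
) -> list[GuideSpec]:
    """Enumerate every NGG guide lying wholly inside ``region``.

    Both strands are scanned; the result is ordered by plus-strand
    protospacer start, plus strand before minus at ties.  A region too
    short to hold protospacer + PAM yields an empty list (logged, not an
    error).
    """
    if len(region) < PROTOSPACER_LEN + _PAM_LEN:
        logger.info(
            "region %s:%d-%d shorter than %d nt; no guides possible",
            region.contig,
            region.start,
            region.end,
            PROTOSPACER_LEN + _PAM_LEN,
        )
        return []
    seq = genome[region.contig]
    guides: list[GuideSpec] = []
    # plus strand: protospacer [i, i+20), PAM [i+20, i+23)
    for i in range(region.start, region.end - PROTOSPACER_LEN - _PAM_LEN + 1):
        pam = seq[i + PROTOSPACER_LEN : i + PROTOSPACER_LEN + _PAM_LEN]
        if _is_ngg(pam):
            guides.append(
                _build_guide(region.contig, seq, i, "+", f"guide_{i}_plus")
            )
    # minus strand: plus-strand CCN at [j, j+3), protospacer [j+3, j+23)
    for j in range(region.start, region.end - PROTOSPACER_LEN - _PAM_LEN + 1):
        pam_plus = seq[j : j + _PAM_LEN]
        if pam_plus[0] == "C" and pam_plus[1] == "C":
            guides.append(
                _build_guide(
                    region.contig, seq, j + _PAM_LEN, "-", f"guide_{j + 3}_minus"
                )
            )
    guides.sort(key=lambda g: (g.protospacer_interval.start, g.strand))
    return guides


def guide_from_protospacer(
    genome: Mapping[str, str],
    contig: str,
    protospacer: str,
    strand: str,
    name: str | None = None,
) -> GuideSpec:
    """Locate a known protospacer on the reference and build its GuideSpec.

    The protospacer is given in guide orientation.  Raises if the sequence
    is absent, ambiguous, or lacks an NGG PAM at the located site.
    """
    seq = genome[contig]
    query = protospacer if strand == "+" else revcomp(protospacer)
    first = seq.find(query)
    if first == -1:
        raise ValueError(f"protospacer {protospacer} not found on {contig}")
    if seq.find(query, first + 1) != -1:
        raise ValueError(f"protospacer {protospacer} occurs more than once")
    guide = _build_guide(
        contig, seq, first, strand, name or f"guide_{first}_{strand}"
    )
    if not _is_ngg(guide.pam):
        raise ValueError(
            f"located protospacer has PAM {guide.pam}, which is not NGG"
        )
    return guide


@dataclass(frozen=True)
class DualOverlapReport:
    """Geometry of a guide pair relative to the intended edit.

    ``cut_distances`` are signed, in nt, from each cut site to the 5' edge
    of the target base (negative = cut upstream of the target in genome
    coordinates).  ``flanking`` is true when the two cut sites fall on
    opposite sides of, or exactly at, the target.
    """

    overlap: bool
    opposite_strands: bool
    cut_distances: tuple[int, int]
    flanking: bool


def dual_overlap_report(
    g1: GuideSpec, g2: GuideSpec, target: PointVariant
) -> DualOverlapReport:
    if g1.contig != g2.contig:
        raise ValueError(
            f"guides on different contigs: {g1.contig} vs {g2.contig}"
        )
    if target.contig != g1.contig:
        raise ValueError("target not on the guides' contig")
    overlap = g1.protospacer_interval.overlaps(g2.protospacer_interval)
    opposite = g1.strand != g2.strand
    t0 = target.pos0
    d1 = g1.cut_site - t0
    d2 = g2.cut_site - t0
    flanking = d1 == 0 or d2 == 0 or (d1 < 0) != (d2 < 0)
    return DualOverlapReport(
        overlap=overlap,
        opposite_strands=opposite,
        cut_distances=(d1, d2),
        flanking=flanking,
    )


_GUIDE_COLUMNS = ["name", "protospacer", "strand", "contig", "pam_start"]


def write_guides_tsv(guides: Sequence[GuideSpec], path: str | Path) -> None:
    """Guides as a small TSV: name, sequence, strand, contig, 0-based PAM start."""
    with open(path, "w") as fh:
        fh.write("\t".join(_GUIDE_COLUMNS) + "\n")
        for g in guides:
            fh.write(
                f"{g.name}\t{g.protospacer}\t{g.strand}\t{g.contig}\t"
                f"{g.pam_interval.start}\n"
            )


def read_guides_tsv(
    path: str | Path, genome: Mapping[str, str]
) -> list[GuideSpec]:
    guides = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GUIDE_COLUMNS:
            raise ValueError(f"unexpected guide table header in {path}")
        for line in fh:
            if not line.strip():
                continue
            name, protospacer, strand, contig, _pam_start = line.rstrip(
                "\n"
            ).split("\t")
            guides.append(
                guide_from_protospacer(genome, contig, protospacer, strand, name)
            )
    return guides
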