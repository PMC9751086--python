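"""Four-category classification of on-target reads from mosaic founders.

CRISPR zygote editing yields founders whose cells are mosaics of repair
outcomes.  Each aligned read fully spanning the edited window is assigned
to exactly one of four categories:

* ``intended_KI`` — the read carries the intended edit together with the
  donor's shield mutations and nothing else: a faithful HDR product;
* ``indel`` — the read carries any insertion or deletion in the window
  (NHEJ-type repair); indels take precedence because a read physically
  harbouring one is not a faithful HDR product even if it also carries
  the point edit;
* ``no_mutation`` — the read matches the reference across the window;
* ``nonspecific`` — any other substitution pattern.

Category fractions over all spanning reads quantify founder mosaicism.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

from .donor import DonorSpec
from .locus import GenomicInterval, PointVariant

__all__ = [
    "Category",
    "IndelEvent",
    "ReadObservation",
    "OutcomeTally",
    "FounderCall",
    "CohortSummary",
    "classify_read",
    "observation_from_alignment",
    "summarize_locus",
    "cohort_summary",
    "percent_half_up",
]


class Category(str, enum.Enum):
    INTENDED_KI = "intended_KI"
    INDEL = "indel"
    NO_MUTATION = "no_mutation"
    NONSPECIFIC = "nonspecific"


@dataclass(frozen=True)
class IndelEvent:
    """A length-changing event: ``length`` > 0 insertion, < 0 deletion.

    ``position`` is the 0-based reference coordinate where the event
    anchors (first deleted base, or the base after which the insertion
    sits).  ``sequence`` holds inserted bases (empty for deletions).
    """

    position: int
    length: int
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.length == 0:
            raise ValueError("indel length must be nonzero")

    def overlaps(self, window: GenomicInterval) -> bool:
        if self.length < 0:  # deletion occupies [position, position - length)
            return self.position < window.end and window.start < (
                self.position - self.length
            )
        return window.start <= self.position < window.end


@dataclass
class ReadObservation:
    """Per-read decomposition into substitutions and indels."""

    read_id: str
    span: GenomicInterval
    substitutions: list[PointVariant] = field(default_factory=list)
    indels: list[IndelEvent] = field(default_factory=list)
    mapping_quality: int = 60


def observation_from_alignment(
    read: pysam.AlignedSegment, reference: str
) -> ReadObservation:
    """Decompose an aligned read against its reference contig sequence."""
    contig = read.reference_name
    span = GenomicInterval(contig, read.reference_start, read.reference_end)
    obs = ReadObservation(
        read_id=read.query_name,
        span=span,
        mapping_quality=read.mapping_quality,
    )
    qseq = read.query_sequence or ""
    qpos = 0
    rpos = read.reference_start
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):  # M / = / X
            for k in range(length):
                qb = qseq[qpos + k]
                rb = reference[rpos + k]
                if qb != rb and qb in "ACGT" and rb in "ACGT":
                    obs.substitutions.append(
                        PointVariant(contig, rpos + k + 1, rb, qb)
                    )
            qpos += length
            rpos += length
        elif op == 1:  # insertion relative to reference
            obs.indels.append(
                IndelEvent(rpos, length, qseq[qpos : qpos + length])
            )
            qpos += length
        elif op == 2:  # deletion
            obs.indels.append(IndelEvent(rpos, -length))
            rpos += length
        elif op in (4,):  # soft clip
            qpos += length
        elif op in (3,):  # N skip
            rpos += length
        # hard clips (5) and pads (6) consume nothing we track
    return obs


def classify_read(
    obs: ReadObservation,
    donor: DonorSpec,
    window: GenomicInterval,
    require_shields: bool = True,
) -> Category:
    """Assign one category to a window-spanning read.

    Precedence: indel > intended_KI > nonspecific > no_mutation.  A read
    counts as ``intended_KI`` only when it carries the intended edit, the
    shield alleles at every shield position it covers (unless
    ``require_shields`` is off), and no substitution beyond the donor's.
    A lone intended edit without its shields is ``nonspecific`` by
    default: it does not match either the reference or the donor
    haplotype.
    """
    if not obs.span.spans(window):
        raise ValueError(
            f"read {obs.read_id} does not span the window; pre-filter reads"
        )
    if any(ind.overlaps(window) for ind in obs.indels):
        return Category.INDEL
    subs = {
        v.position: v.alt
        for v in obs.substitutions
        if window.contains(v.pos0)
    }
    if not subs:
        return Category.NO_MUTATION
    donor_alleles = {
        pos: alt
        for pos, alt in donor.edited_alleles.items()
        if window.contains(pos - 1)
    }
    intended = donor.intended_edit
    has_intended = subs.get(intended.position) == intended.alt
    extras = any(
        donor_alleles.get(pos) != alt for pos, alt in subs.items()
    )
    if has_intended and not extras:
        if not require_shields:
            return Category.INTENDED_KI
        covered_shields = [
            s.variant
            for s in donor.shield_edits
            if window.contains(s.variant.pos0)
            and obs.span.contains(s.variant.pos0)
        ]
        if all(subs.get(v.position) == v.alt for v in covered_shields):
            return Category.INTENDED_KI
    return Category.NONSPECIFIC


@dataclass
class OutcomeTally:
    """Counts and fractions over the four outcome categories."""

    counts: dict[Category, int]

    @classmethod
    def empty(cls) -> "OutcomeTally":
        return cls({c: 0 for c in Category})

    def add(self, category: Category) -> None:
        self.counts[category] = self.counts.get(category, 0) + 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[Category, float] | None:
        """None when no read was tallied (explicitly undefined)."""
        if self.total == 0:
            return None
        return {c: n / self.total for c, n in self.counts.items()}

    def to_tsv(self, path: str | Path) -> None:
        frac = self.fractions
        with open(path, "w") as fh:
            fh.write("category\tcount\tfraction\n")
            for c in Category:
                f = "NA" if frac is None else f"{frac[c]:.6f}"
                fh.write(f"{c.value}\t{self.counts.get(c, 0)}\t{f}\n")


def _spanning_primary_reads(
    alignment: pysam.AlignmentFile,
    window: GenomicInterval,
    min_quality: int,
) -> Iterator[pysam.AlignedSegment]:
    for read in alignment.fetch(until_eof=True):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.is_duplicate:
            continue
        if read.mapping_quality < min_quality:
            continue
        if read.reference_name != window.contig:
            continue
        if read.reference_start <= window.start and (
            read.reference_end or 0
        ) >= window.end:
            yield read


def summarize_locus(
    alignment_path: str | Path,
    donor: DonorSpec,
    window: GenomicInterval | None,
    reference: str,
    min_quality: int = 20,
    require_shields: bool = True,
) -> OutcomeTally:
    """Tally categories over all spanning primary reads of a SAM/BAM file.

    ``window`` defaults to the donor footprint (oligo span).  Reads that
    are unmapped, secondary, supplementary, duplicate, below
    ``min_quality``, or not fully spanning the window are excluded.
    """
    window = window or donor.footprint
    tally = OutcomeTally.empty()
    save = pysam.set_verbosity(0)  # silence missing-index warning on SAM
    try:
        with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
            for read in _spanning_primary_reads(af, window, min_quality):
                obs = observation_from_alignment(read, reference)
                tally.add(
                    classify_read(
                        obs, donor, window, require_shields=require_shields
                    )
                )
    finally:
        pysam.set_verbosity(save)
    return tally


# ----------------------------------------------------------------------
# Cohort arithmetic
# ----------------------------------------------------------------------


def percent_half_up(numerator: int, denominator: int, digits: int = 1) -> float:
    """Percentage rounded half-up to ``digits`` decimals (e.g. 35/39 -> 89.7)."""
    if denominator == 0:
        raise ValueError("denominator must be positive")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    exp = Decimal(1).scaleb(-digits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FounderCall:
    """Per-founder genotype flags feeding the cohort summary."""

    founder_id: str
    any_mutation: bool
    intended_ki: bool


@dataclass(frozen=True)
class CohortSummary:
    n_founders: int
    n_any_mutation: int
    n_intended_ki: int
    pct_any_mutation: float
    pct_intended_ki: float


def cohort_summary(founders: Iterable[FounderCall]) -> CohortSummary:
    """Percent of founders carrying any mutation, and the intended knock-in."""
    founders = list(founders)
    if not founders:
        raise ValueError("empty founder cohort")
    n = len(founders)
    n_any = sum(1 for f in founders if f.any_mutation)
    n_ki = sum(1 for f in founders if f.intended_ki)
    return CohortSummary(
        n_founders=n,
        n_any_mutation=n_any,
        n_intended_ki=n_ki,
        pct_any_mutation=percent_half_up(n_any, n),
        pct_intended_ki=percent_half_up(n_ki, n),
    )
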