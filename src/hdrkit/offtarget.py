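"""Off-target analyses over whole-genome variant calls.

Three stages, all site-level:

1. **Background subtraction** — founder SNVs minus the wild-type control
   calls, the known-polymorphism catalog, and anything on unplaced
   contigs, leaving the *de novo* set attributable to editing.
2. **Predicted-site window check** — counting de novo SNVs within a
   window (default 500 bp, boundary inclusive) of each computationally
   predicted off-target cut site.
3. **Ectopic HDR signature scan** — searching the de novo set for the
   donor's fingerprint: a central transversion with at least one
   companion variant at one of the donor-derived upstream offsets
   carrying the required alternate base.  The scan is repeated on the
   reverse complement: a plus-strand C>A with upstream companions mirrors
   a G>T with complemented companions the same distances *downstream* in
   genome coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .donor import SignaturePattern
from .locus import GenomicInterval, PointVariant, complement_base

__all__ = [
    "DeNovoSet",
    "SignatureHit",
    "SiteReport",
    "read_vcf_snvs",
    "read_known_snps",
    "read_bed",
    "subtract_background",
    "predicted_site_check",
    "scan_signatures",
    "write_hits_tsv",
    "write_site_reports_tsv",
]


def read_vcf_snvs(path: str | Path, pass_only: bool = False) -> list[PointVariant]:
    """All biallelic-decomposed SNV records of a VCF (site-level).

    Multi-allelic records are split; non-SNV alleles are dropped.  With
    ``pass_only`` records failing FILTER are skipped; by default genotype
    and filter fields are ignored, matching a site-level subtraction.
    """
    out: list[PointVariant] = []
    save = pysam.set_verbosity(0)
    try:
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                if pass_only and rec.filter.keys() not in ([], ["PASS"]):
                    continue
                if rec.ref is None or len(rec.ref) != 1 or rec.ref not in "ACGT":
                    continue
                for alt in rec.alts or ():
                    if len(alt) == 1 and alt in "ACGT":
                        out.append(
                            PointVariant(rec.chrom, rec.pos, rec.ref, alt)
                        )
    finally:
        pysam.set_verbosity(save)
    return out


def read_known_snps(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Known-SNP catalog as exact (contig, pos, ref, alt) tuples.

    Accepts a VCF or a dbSNP-style 4-column TSV (contig, 1-based position,
    ref, alt); header/comment lines start with ``#``.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz"):
        return {v.key for v in read_vcf_snvs(path)}
    known: set[tuple[str, int, str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >=4 tab-separated fields"
                )
            known.add((fields[0], int(fields[1]), fields[2], fields[3]))
    return known


@dataclass
class DeNovoSet:
    """SNVs private to the founder, with subtraction provenance counters."""

    variants: list[PointVariant]
    counters: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    _index: dict[tuple[str, int], list[PointVariant]] | None = None

    def __post_init__(self) -> None:
        self.variants = sorted(
            self.variants, key=lambda v: (v.contig, v.position, v.alt)
        )

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def __contains__(self, variant: PointVariant) -> bool:
        return any(v.key == variant.key for v in self.at(variant.contig, variant.position))

    def at(self, contig: str, position: int) -> list[PointVariant]:
        if self._index is None:
            self._index = {}
            for v in self.variants:
                self._index.setdefault((v.contig, v.position), []).append(v)
        return self._index.get((contig, position), [])


def subtract_background(
    founder_vcf: str | Path,
    control_vcf: str | Path,
    known_snps: str | Path | Iterable[tuple[str, int, str, str]] | None = None,
    contig_allowlist: Sequence[str] | None = None,
    pass_only: bool = False,
) -> DeNovoSet:
    """Founder SNVs minus control calls, known SNPs, and unplaced contigs.

    Removal requires an exact (contig, pos, ref, alt) match; a control or
    known record sharing position and alt but a different ref leaves the
    founder variant retained, with a warning.  Contigs outside the
    allowlist (when given) are dropped first and counted separately.
    """
    founder = read_vcf_snvs(founder_vcf, pass_only=pass_only)
    control = read_vcf_snvs(control_vcf, pass_only=pass_only)
    if founder and control:
        founder_contigs = {v.contig for v in founder}
        control_contigs = {v.contig for v in control}
        if not (founder_contigs & control_contigs):
            example = sorted(control_contigs)[0]
            raise ValueError(
                "contig names do not match between founder and control "
                f"calls (e.g. control contig {example!r} absent from the "
                "founder file)"
            )
    control_keys = {v.key for v in control}
    control_loose = {(v.contig, v.position, v.alt) for v in control}
    if known_snps is None:
        known: set[tuple[str, int, str, str]] = set()
    elif isinstance(known_snps, (str, Path)):
        known = read_known_snps(known_snps)
    else:
        known = set(known_snps)
    known_loose = {(c, p, a) for c, p, _r, a in known}
    allow = set(contig_allowlist) if contig_allowlist is not None else None

    counters = {
        "input": len(founder),
        "removed_unplaced": 0,
        "removed_control": 0,
        "removed_known": 0,
        "retained": 0,
    }
    notes: list[str] = []
    retained: list[PointVariant] = []
    for v in founder:
        if allow is not None and v.contig not in allow:
            counters["removed_unplaced"] += 1
            continue
        if v.key in control_keys:
            counters["removed_control"] += 1
            continue
        if v.key in known:
            counters["removed_known"] += 1
            continue
        loose = (v.contig, v.position, v.alt)
        if loose in control_loose or loose in known_loose:
            notes.append(
                f"{v.contig}:{v.position} {v.ref}>{v.alt} retained: a "
                "background record at this position has the same alt but a "
                "different ref (exact-tuple matching)"
            )
        counters["retained"] += 1
        retained.append(v)
    for msg in notes:
        warnings.warn(msg, stacklevel=2)
    return DeNovoSet(retained, counters=counters, warnings=notes)


# ----------------------------------------------------------------------
# Predicted off-target sites
# ----------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Minimal BED3+ reader (0-based half-open) with line-number errors."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: BED line needs >=3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            intervals.append(GenomicInterval(fields[0], start, end))
    return intervals


@dataclass(frozen=True)
class SiteReport:
    site: GenomicInterval
    count: int
    variants: tuple[PointVariant, ...]


def _distance_to_interval(pos0: int, iv: GenomicInterval) -> int:
    if iv.contains(pos0):
        return 0
    if pos0 < iv.start:
        return iv.start - pos0
    return pos0 - (iv.end - 1)


def predicted_site_check(
    sites: Sequence[GenomicInterval] | str | Path,
    denovo: DeNovoSet,
    window_nt: int = 500,
) -> list[SiteReport]:
    """Count de novo SNVs within ``window_nt`` of each predicted site.

    Distance is 0 inside the interval; the boundary is inclusive, so a
    variant exactly ``window_nt`` away is counted and one at
    ``window_nt + 1`` is not.
    """
    if isinstance(sites, (str, Path)):
        sites = read_bed(sites)
    reports = []
    for iv in sites:
        nearby = tuple(
            v
            for v in denovo
            if v.contig == iv.contig
            and _distance_to_interval(v.pos0, iv) <= window_nt
        )
        reports.append(SiteReport(site=iv, count=len(nearby), variants=nearby))
    return reports


# ----------------------------------------------------------------------
# Ectopic HDR signature scan
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class SignatureHit:
    central: PointVariant
    companions: tuple[tuple[int, PointVariant], ...]
    strand: str
    pattern_id: str

    def __post_init__(self) -> None:
        if not self.companions:
            raise ValueError("a SignatureHit needs >=1 matched companion")


def scan_signatures(
    denovo: DeNovoSet, pattern: SignaturePattern
) -> list[SignatureHit]:
    """Find de novo variant clusters matching the donor signature.

    Plus-strand pass: a variant matching the pattern's central ref>alt
    with at least one de novo companion ``offset`` nt before it (lower
    coordinate) whose alt equals the required base — any reference base
    qualifies.  Minus-strand pass: the complemented central (G>T for C>A)
    with complemented companion alts the same offsets *after* it.  One
    matching companion suffices; all that match are recorded.
    """
    c_ref, c_alt = pattern.central
    passes = [
        ("+", c_ref, c_alt, -1, {o: a for o, a in pattern.companions}),
        (
            "-",
            complement_base(c_ref),
            complement_base(c_alt),
            +1,
            {o: complement_base(a) for o, a in pattern.companions},
        ),
    ]
    hits: list[SignatureHit] = []
    for strand, ref, alt, direction, rules in passes:
        for v in denovo:
            if v.ref != ref or v.alt != alt:
                continue
            matched: list[tuple[int, PointVariant]] = []
            for offset, required_alt in sorted(rules.items()):
                pos = v.position + direction * offset
                if pos < 1:
                    continue
                for u in denovo.at(v.contig, pos):
                    if u.alt == required_alt:
                        matched.append((offset, u))
            if matched:
                hits.append(
                    SignatureHit(
                        central=v,
                        companions=tuple(matched),
                        strand=strand,
                        pattern_id=pattern.pattern_id,
                    )
                )
    hits.sort(key=lambda h: (h.central.contig, h.central.position, h.strand))
    return hits


# ----------------------------------------------------------------------
# Reports
# ----------------------------------------------------------------------


def write_hits_tsv(hits: Sequence[SignatureHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tposition\tref\talt\tstrand\tcompanions\tpattern\n")
        for h in hits:
            comp = ",".join(
                f"{off}:{u.position}{u.ref}>{u.alt}" for off, u in h.companions
            )
            v = h.central
            fh.write(
                f"{v.contig}\t{v.position}\t{v.ref}\t{v.alt}\t{h.strand}\t"
                f"{comp}\t{h.pattern_id}\n"
            )


def write_site_reports_tsv(
    reports: Sequence[SiteReport], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tsnv_count\tsnvs\n")
        for r in reports:
            snvs = ",".join(
                f"{v.position}{v.ref}>{v.alt}" for v in r.variants
            )
            fh.write(
                f"{r.site.contig}\t{r.site.start}\t{r.site.end}\t{r.count}\t"
                f"{snvs or '.'}\n"
            )
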