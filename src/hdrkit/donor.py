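"""ssODN donor construction, validation and HDR-signature derivation.

A knock-in donor is a single-stranded oligo carrying the intended edit
flanked by homology arms (default 50 bp), plus *shield* mutations:
synonymous substitutions installed in each guide's PAM or seed region so
that SpCas9 cannot re-cut the repaired allele.  Because the shields travel
with the intended edit on one template, any ectopic insertion of the donor
elsewhere in the genome leaves the same constellation of substitutions —
the central edit plus companions at fixed upstream offsets.  That
constellation, the :class:`SignaturePattern`, is derived here and consumed
by the genome-wide scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Data import CodonTable

from .guides import GuideSpec
from .locus import (
    GenomicInterval,
    PointVariant,
    ReferenceLocus,
    complement_base,
    revcomp,
    translate,
)

__all__ = [
    "SHIELD_TAGS",
    "ShieldEdit",
    "DonorSpec",
    "DonorPolicy",
    "SignaturePattern",
    "ValidationReport",
    "synonymous_options",
    "build_ssodn",
    "validate_donor",
    "derive_signature_pattern",
]

SHIELD_TAGS = ("PAM", "seed")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = "ACGT"


def _codon_to_aa(codon: str) -> str:
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


def synonymous_options(codon: str, position_in_codon: int) -> list[str]:
    """Alternate bases at one codon position that preserve the amino acid.

    Standard nuclear codon table.  Returns bases in alphabetical order;
    empty when the position brooks no synonymous change (e.g. Met, Trp).
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"codon must be 3 unambiguous DNA bases, got {codon!r}")
    if position_in_codon not in (0, 1, 2):
        raise ValueError("position_in_codon must be 0, 1 or 2")
    aa = _codon_to_aa(codon)
    options = []
    for base in _BASES:
        if base == codon[position_in_codon]:
            continue
        edited = (
            codon[:position_in_codon] + base + codon[position_in_codon + 1 :]
        )
        if _codon_to_aa(edited) == aa:
            options.append(base)
    return options


@dataclass(frozen=True)
class ShieldEdit:
    """A synonymous protective substitution, tagged by what it disrupts."""

    variant: PointVariant
    tag: str  # "PAM" or "seed"
    guide: str  # owning guide name

    def __post_init__(self) -> None:
        if self.tag not in SHIELD_TAGS:
            raise ValueError(f"shield tag must be one of {SHIELD_TAGS}")


@dataclass(frozen=True)
class SignaturePattern:
    """Central transversion plus companion rules at fixed upstream offsets.

    ``central`` is the intended edit's ref>alt read on the gene strand;
    each companion is ``(offset_upstream_nt, required_alt_base)``.  The
    pattern is strand-symmetric by construction: a scan applies it to the
    plus strand and again to the reverse complement.
    """

    central: tuple[str, str]
    companions: tuple[tuple[int, str], ...]
    pattern_id: str = "donor-derived"
    strand_symmetric: bool = True

    def __post_init__(self) -> None:
        if not self.companions:
            raise ValueError("SignaturePattern needs at least one companion")
        offsets = [off for off, _ in self.companions]
        if any(off <= 0 for off in offsets):
            raise ValueError("companion offsets must be positive")
        if len(set(offsets)) != len(offsets):
            raise ValueError("companion offsets must be unique")

    @property
    def max_offset(self) -> int:
        return max(off for off, _ in self.companions)


@dataclass(frozen=True)
class DonorSpec:
    """A fully specified ssODN donor.

    ``core_interval`` is the minimal genomic span covering every edit;
    homology arms of ``arm_length`` nt extend it on both sides, and
    ``ssodn`` is the oligo in ``orientation`` (minus-orientation donors
    store the reverse complement of the plus-strand edited window).
    """

    contig: str
    intended_edit: PointVariant
    shield_edits: tuple[ShieldEdit, ...]
    arm_length: int
    ssodn: str
    orientation: str
    gene_strand: str
    core_interval: GenomicInterval

    @property
    def footprint(self) -> GenomicInterval:
        """Genomic span of the whole oligo (arms included)."""
        return GenomicInterval(
            self.contig,
            self.core_interval.start - self.arm_length,
            self.core_interval.end + self.arm_length,
        )

    @property
    def all_edits(self) -> tuple[PointVariant, ...]:
        return (self.intended_edit,) + tuple(
            s.variant for s in self.shield_edits
        )

    @property
    def edited_alleles(self) -> dict[int, str]:
        """1-based position -> donor alt base (plus strand)."""
        return {v.position: v.alt for v in self.all_edits}

    def plus_strand_ssodn(self) -> str:
        return self.ssodn if self.orientation == "+" else revcomp(self.ssodn)

    # ------------------------------------------------------------------
    # Construction
    # ------------------------------------------------------------------

    @classmethod
    def from_edits(
        cls,
        locus: ReferenceLocus,
        intended_edit: PointVariant,
        shields: Sequence[ShieldEdit],
        arm_length: int = 50,
        orientation: str = "+",
    ) -> "DonorSpec":
        """Assemble the oligo from the reference window plus the edits."""
        contig = intended_edit.contig
        positions = [intended_edit.pos0] + [s.variant.pos0 for s in shields]
        core = GenomicInterval(contig, min(positions), max(positions) + 1)
        window = GenomicInterval(
            contig, core.start - arm_length, core.end + arm_length
        )
        seq = list(locus.fetch(window))
        for v in (intended_edit, *[s.variant for s in shields]):
            i = v.pos0 - window.start
            if seq[i] != v.ref:
                raise ValueError(
                    f"edit {v.ref}>{v.alt} at {contig}:{v.position} does not "
                    f"match reference base {seq[i]}"
                )
            seq[i] = v.alt
        oligo = "".join(seq)
        if orientation == "-":
            oligo = revcomp(oligo)
        return cls(
            contig=contig,
            intended_edit=intended_edit,
            shield_edits=tuple(shields),
            arm_length=arm_length,
            ssodn=oligo,
            orientation=orientation,
            gene_strand=locus.coding_map.gene_strand,
            core_interval=core,
        )

    # ------------------------------------------------------------------
    # Serialization: oligo FASTA + edits TSV
    # ------------------------------------------------------------------

    def to_files(self, fasta_path: str | Path, edits_path: str | Path) -> None:
        with open(fasta_path, "w") as fh:
            fh.write(f">ssodn {self.contig} orientation={self.orientation}\n")
            fh.write(self.ssodn + "\n")
        with open(edits_path, "w") as fh:
            fh.write(
                f"#donor\tcontig={self.contig}\tarm_length={self.arm_length}\t"
                f"orientation={self.orientation}\t"
                f"gene_strand={self.gene_strand}\n"
            )
            fh.write("position\tref\talt\ttag\tguide\tlabel\n")
            v = self.intended_edit
            fh.write(
                f"{v.position}\t{v.ref}\t{v.alt}\tintended\t.\t{v.label or '.'}\n"
            )
            for s in self.shield_edits:
                v = s.variant
                fh.write(
                    f"{v.position}\t{v.ref}\t{v.alt}\t{s.tag}\t{s.guide}\t"
                    f"{v.label or '.'}\n"
                )

    @classmethod
    def from_files(
        cls,
        locus: ReferenceLocus,
        edits_path: str | Path,
    ) -> "DonorSpec":
        """Rebuild a donor from its edits table against a reference locus."""
        intended: PointVariant | None = None
        shields: list[ShieldEdit] = []
        contig = None
        arm_length = 50
        orientation = "+"
        with open(edits_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for token in line.split("\t"):
                        if token.startswith("contig="):
                            contig = token.split("=", 1)[1]
                        elif token.startswith("arm_length="):
                            arm_length = int(token.split("=", 1)[1])
                        elif token.startswith("orientation="):
                            orientation = token.split("=", 1)[1]
                    continue
                if not line or line.startswith("position\t"):
                    continue
                pos, ref, alt, tag, guide, label = line.split("\t")
                variant = PointVariant(
                    contig or locus.target_edit.contig,
                    int(pos),
                    ref,
                    alt,
                    label=None if label == "." else label,
                )
                if tag == "intended":
                    intended = variant
                else:
                    shields.append(ShieldEdit(variant, tag, guide))
        if intended is None:
            raise ValueError(f"no intended edit in {edits_path}")
        return cls.from_edits(
            locus, intended, shields, arm_length=arm_length,
            orientation=orientation,
        )


@dataclass(frozen=True)
class DonorPolicy:
    """Choice rules when several synonymous shields could protect a guide.

    The default installs, per guide, one PAM-disrupting edit when one
    exists (left-most position, then alphabetical alternate base),
    otherwise one seed edit — the minimal deterministic design.  Setting
    ``redundant_seed`` adds a seed edit alongside a PAM edit, belt and
    braces, which is how published dual-guide donors for this locus were
    laid out.
    """

    arm_length: int = 50
    prefer_pam: bool = True
    redundant_seed: bool = False
    orientation: str = "+"


def _pam_disrupted(guide: GuideSpec, alleles: Mapping[int, str],
                   genome: Mapping[str, str]) -> bool:
    """Whether the donor alleles break the guide's NGG PAM."""
    iv = guide.pam_interval
    seq = genome[guide.contig]
    bases = [
        alleles.get(pos0 + 1, seq[pos0]) for pos0 in range(iv.start, iv.end)
    ]
    pam = "".join(bases)
    if guide.strand == "-":
        pam = revcomp(pam)
    return not (pam[1] == "G" and pam[2] == "G")


def _seed_mismatch_count(guide: GuideSpec, alleles: Mapping[int, str]) -> int:
    return sum(
        1
        for pos0 in range(guide.seed.start, guide.seed.end)
        if pos0 + 1 in alleles
    )


def _candidate_shields(
    locus: ReferenceLocus, guide: GuideSpec, exclude_positions: set[int]
) -> list[tuple[str, int, str, bool]]:
    """Enumerate synonymous single-base shields for one guide.

    Returns tuples ``(tag, position_1based, alt_plus_strand, breaks_pam)``
    sorted left-most first, alternate bases alphabetically, PAM candidates
    that actually break NGG ahead of seed candidates.
    """
    cmap = locus.coding_map
    out: list[tuple[str, int, str, bool]] = []
    regions = [("PAM", guide.pam_interval), ("seed", guide.seed)]
    for tag, iv in regions:
        for pos0 in range(iv.start, iv.end):
            position = pos0 + 1
            if position in exclude_positions:
                continue
            try:
                c_pos = cmap.genomic_to_c(guide.contig, position)
            except ValueError:
                continue  # outside the CDS: no synonymy defined
            codon, offset = locus.codon_of(c_pos)
            for alt_gene in synonymous_options(codon, offset):
                alt_plus = (
                    alt_gene
                    if cmap.gene_strand == "+"
                    else complement_base(alt_gene)
                )
                breaks = False
                if tag == "PAM":
                    breaks = _pam_disrupted(
                        guide, {position: alt_plus}, locus.contigs
                    )
                    if not breaks:
                        continue  # a PAM edit that leaves NGG intact is useless
                out.append((tag, position, alt_plus, breaks))
    out.sort(key=lambda t: (t[0] != "PAM", t[1], t[2]))
    return out


class DonorDesignError(ValueError):
    """No synonymous option can disrupt a guide's PAM or seed."""


def build_ssodn(
    locus: ReferenceLocus,
    guides: Sequence[GuideSpec],
    policy: DonorPolicy | None = None,
) -> DonorSpec:
    """Design a donor: intended edit + one deterministic shield per guide.

    Shields are chosen per :class:`DonorPolicy`; the intended edit is the
    locus's target edit.  Raises :class:`DonorDesignError`, naming the
    guide, when no synonymous substitution can protect it.
    """
    policy = policy or DonorPolicy()
    intended = locus.target_edit
    for g in guides:
        if abs(g.cut_site - intended.pos0) > policy.arm_length:
            raise DonorDesignError(
                f"guide {g.name} cuts more than {policy.arm_length} nt from "
                "the intended edit; the donor cannot span both"
            )
    chosen: list[ShieldEdit] = []
    taken: set[int] = {intended.position}
    for g in guides:
        candidates = _candidate_shields(locus, g, taken)
        if not candidates:
            raise DonorDesignError(
                f"no synonymous shield available for guide {g.name} "
                "(PAM or seed)"
            )
        picks = [candidates[0]]
        if policy.redundant_seed and picks[0][0] == "PAM":
            seed_cands = [c for c in candidates if c[0] == "seed"]
            if seed_cands:
                picks.append(seed_cands[0])
        for tag, position, alt_plus, _breaks in picks:
            ref = locus.base_at(g.contig, position)
            chosen.append(
                ShieldEdit(
                    PointVariant(g.contig, position, ref, alt_plus), tag, g.name
                )
            )
            taken.add(position)
    return DonorSpec.from_edits(
        locus,
        intended,
        chosen,
        arm_length=policy.arm_length,
        orientation=policy.orientation,
    )


# ----------------------------------------------------------------------
# Validation
# ----------------------------------------------------------------------


@dataclass
class ValidationReport:
    items: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, name: str, passed: bool, detail: str = "") -> None:
        self.items.append((name, passed, detail))

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.items)

    def failures(self) -> list[tuple[str, str]]:
        return [(name, detail) for name, ok, detail in self.items if not ok]

    def __str__(self) -> str:
        lines = []
        for name, ok, detail in self.items:
            mark = "PASS" if ok else "FAIL"
            lines.append(f"[{mark}] {name}" + (f": {detail}" if detail else ""))
        lines.append(f"overall: {'PASS' if self.passed else 'FAIL'}")
        return "\n".join(lines)


def _protein_diff(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def validate_donor(
    donor: DonorSpec,
    locus: ReferenceLocus,
    guides: Sequence[GuideSpec],
) -> ValidationReport:
    """Itemized invariant check of a donor against a locus and its guides.

    Failures are report items, never exceptions, so externally designed
    oligos can be audited wholesale.
    """
    report = ValidationReport()
    fp = donor.footprint
    plus = donor.plus_strand_ssodn()

    # arm lengths + reference identity outside the edited core
    left_arm = plus[: donor.arm_length]
    right_arm = plus[len(plus) - donor.arm_length :]
    ref_left = locus.fetch(
        GenomicInterval(donor.contig, fp.start, donor.core_interval.start)
    )
    ref_right = locus.fetch(
        GenomicInterval(donor.contig, donor.core_interval.end, fp.end)
    )
    report.add(
        "arm_length",
        len(left_arm) == donor.arm_length == len(right_arm),
        f"arms {len(left_arm)}/{len(right_arm)} nt, expected {donor.arm_length}",
    )
    report.add(
        "arms_match_reference",
        left_arm == ref_left and right_arm == ref_right,
        "homology arms must be exact reference matches",
    )

    # oligo equals reference window + declared edits, nothing else
    expected = list(locus.fetch(fp))
    ok_positions = True
    for v in donor.all_edits:
        i = v.pos0 - fp.start
        if not (0 <= i < len(expected)):
            ok_positions = False
            continue
        if expected[i] != v.ref:
            ok_positions = False
        expected[i] = v.alt
    report.add("edits_within_span", ok_positions, "all edits inside the oligo")
    report.add(
        "ssodn_matches_edits",
        plus == "".join(expected),
        "oligo must equal the reference window with exactly the declared edits",
    )

    # intended edit present and is the single residue change
    intended_in = donor.edited_alleles.get(donor.intended_edit.position) == \
        donor.intended_edit.alt and plus[
            donor.intended_edit.pos0 - fp.start
        ] == donor.intended_edit.alt
    report.add(
        "intended_edit_present",
        intended_in,
        f"intended {donor.intended_edit.ref}>{donor.intended_edit.alt} at "
        f"{donor.contig}:{donor.intended_edit.position}",
    )

    # synonymy of every shield, and single-residue protein change overall
    ref_protein = translate(locus.cds_sequence())
    for v in donor.all_edits:
        locus.apply_variant(v)
    donor_protein = translate(locus.cds_sequence())
    for v in donor.all_edits:
        locus.revert_variant(v)
    diffs = _protein_diff(ref_protein, donor_protein)
    try:
        intended_c = locus.coding_map.genomic_to_c(
            donor.contig, donor.intended_edit.position
        )
        # residue index within the translated (possibly partial) CDS
        intended_residue = (intended_c - locus.coding_map.c_min) // 3
    except ValueError:
        intended_residue = None
    report.add(
        "single_residue_change",
        diffs == [intended_residue],
        f"protein differs at residues {diffs}, expected only "
        f"{intended_residue}",
    )
    for s in donor.shield_edits:
        locus.apply_variant(s.variant)
        shielded_protein = translate(locus.cds_sequence())
        locus.revert_variant(s.variant)
        report.add(
            f"shield_synonymous[{s.variant.contig}:{s.variant.position}"
            f"{s.variant.ref}>{s.variant.alt}]",
            shielded_protein == ref_protein,
            f"{s.tag} shield for {s.guide}",
        )

    # each targeted guide must be disrupted
    alleles = donor.edited_alleles
    for g in guides:
        disrupted = _pam_disrupted(g, alleles, locus.contigs) or \
            _seed_mismatch_count(g, alleles) >= 1
        report.add(
            f"guide_disrupted[{g.name}]",
            disrupted,
            "needs >=1 PAM-breaking or seed shield",
        )
    return report


# ----------------------------------------------------------------------
# Signature derivation
# ----------------------------------------------------------------------


def derive_signature_pattern(donor: DonorSpec) -> SignaturePattern:
    """Derive the ectopic-integration signature from a donor.

    The central rule is the intended edit's ref>alt on the gene strand;
    each shield contributes a companion at its distance upstream (5', gene
    strand) of the intended edit, requiring the shield's alternate base.
    Shields lying downstream are excluded from the pattern (returned
    pattern id notes how many were dropped) because upstream offsets are
    what an integrated donor stamps ahead of the central change in reading
    direction.
    """
    if not donor.shield_edits:
        raise ValueError("no companions derivable: donor has no shield edits")
    sign = 1 if donor.gene_strand == "+" else -1
    central_ref = donor.intended_edit.ref
    central_alt = donor.intended_edit.alt
    if donor.gene_strand == "-":
        central_ref = complement_base(central_ref)
        central_alt = complement_base(central_alt)
    companions: list[tuple[int, str]] = []
    downstream = 0
    for s in donor.shield_edits:
        offset = sign * (donor.intended_edit.position - s.variant.position)
        alt = s.variant.alt
        if donor.gene_strand == "-":
            alt = complement_base(alt)
        if offset <= 0:
            downstream += 1
            continue
        companions.append((offset, alt))
    if not companions:
        raise ValueError(
            "no companions derivable: all shields lie downstream of the "
            "intended edit on the gene strand"
        )
    companions.sort()
    pattern_id = "donor-derived"
    if downstream:
        pattern_id += f" ({downstream} downstream shield(s) excluded)"
    return SignaturePattern(
        central=(central_ref, central_alt),
        companions=tuple(companions),
        pattern_id=pattern_id,
    )
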