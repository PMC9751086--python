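"""Synthetic inputs for every pipeline stage.

The real experiment edited the mouse *Gaa* locus around coding position
c.1935.  No public sequencing accession exists for those animals, so this
module rebuilds the statistical structure of the data instead:

* a toy genome whose edited contig embeds a 32-nt core reconstructed by
  overlap-assembling the three published protospacers for the locus
  (their overlap fixes the sequence; the reading frame is anchored so the
  codon at c.1933-1935 is GAC, aspartate 645);
* mosaic founder read sets drawn from a mixture of outcome haplotypes
  (knock-in, indel, reference, stray substitution) with independent
  per-base sequencing error, emitted pre-aligned with per-read truth
  labels;
* founder/control VCF pairs with shared background SNVs, founder-private
  SNVs, a known-polymorphism catalog, optionally planted ectopic HDR
  signatures, and a predicted off-target site BED.

All generators are deterministic given (seed, config); truth tables are
sufficient to compute exact expected outputs downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .donor import DonorSpec, ShieldEdit, SignaturePattern
from .guides import GuideSpec, guide_from_protospacer
from .locus import (
    CodingMap,
    GenomicInterval,
    PointVariant,
    ReferenceLocus,
    complement_base,
    revcomp,
)

__all__ = [
    "GRNA_1",
    "GRNA_2",
    "GRNA_3",
    "LOCUS_CORE",
    "CORE_FIRST_C",
    "PUBLISHED_SHIELD_LABELS",
    "TARGET_EDIT_LABEL",
    "SimulationConfig",
    "PlantSpec",
    "assemble_core",
    "make_reference",
    "default_guides",
    "published_donor",
    "simulate_founder_reads",
    "simulate_vcf_pair",
]

# Published protospacers for the Gaa c.1935 locus (guide orientation).
# gRNA-1 and gRNA-2 are antisense to the gene; gRNA-3 is sense.
GRNA_1 = "CGCAGATGTCCGCCCCGACC"
GRNA_2 = "GCAGATGTCCGCCCCGACCA"
GRNA_3 = "GGGCGTGCCCCTGGTCGGGG"

# Coding position of the first core base; the intended edit c.1935 falls
# at core offset 24 and the codon GAC (Asp645) at offsets 22-24.
CORE_FIRST_C = 1911

TARGET_EDIT_LABEL = "c.1935C>A"
# Silent shields installed by the published dual-guide donor: PAM edits
# for gRNA-2 (c.1920) and gRNA-3 (c.1932), seed edits for gRNA-2 (c.1923)
# and gRNA-3 (c.1929).
PUBLISHED_SHIELD_LABELS = (
    "c.1920C>T",
    "c.1923G>C",
    "c.1929G>A",
    "c.1932G>A",
)

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def assemble_core(guides: Sequence[str] = (GRNA_3, GRNA_2, GRNA_1)) -> str:
    """Overlap-assemble the locus core from protospacer sequences.

    The sense-strand guide is extended by the reverse complements of the
    antisense guides wherever a suffix/prefix overlap of at least 8 nt
    exists; the published trio assembles into a unique 32-mer.
    """
    core = guides[0]
    fragments = [revcomp(g) for g in guides[1:]]
    changed = True
    while changed:
        changed = False
        for frag in fragments:
            if frag in core:
                continue
            for k in range(min(len(core), len(frag)), 7, -1):
                if core.endswith(frag[:k]):
                    core = core + frag[k:]
                    changed = True
                    break
                if frag.endswith(core[:k]):
                    core = frag + core[k:]
                    changed = True
                    break
    return core


LOCUS_CORE = assemble_core()

# CDS geometry on the synthetic contig: the in-frame segment starts 92 nt
# upstream of the core (30 whole codons + 2 nt completing the codon that
# ends on the first core base) and runs 104 nt past it, 228 nt in all.
_CDS_UPSTREAM = 92
_CDS_LEN = 228
_CDS_FIRST_C = CORE_FIRST_C - _CDS_UPSTREAM  # codon-aligned: c.1819


@dataclass(frozen=True)
class PlantSpec:
    """One planted ectopic HDR signature cluster.

    ``position`` is the 1-based central-variant position (None places it
    automatically); ``strand`` selects the plus-strand pattern or its
    reverse-complement image; ``offsets`` restricts which companions are
    written (None = all of the pattern's).
    """

    position: int | None = None
    strand: str = "+"
    offsets: tuple[int, ...] | None = None
    contig: str | None = None


@dataclass
class SimulationConfig:
    """The stated world every generator draws from.

    Defaults emulate the founder experiment's structure: a mosaic founder
    dominated by the knock-in haplotype (55% KI / 25% indel / 15%
    unedited / 5% stray substitution), short-read data at 0.1% per-base
    error with >50x spanning coverage, a clean off-target background
    (no planted signatures), and seven predicted off-target sites with no
    nearby variants.
    """

    seed: int = 0
    # reference geometry
    contig: str = "synth_locus"
    contig_length: int = 10_000
    locus_offset: int = 4_000
    # founder read mixture: (intended KI, indel, reference, stray)
    mixture: tuple[float, float, float, float] = (0.55, 0.25, 0.15, 0.05)
    n_reads: int = 200
    coverage: float | None = None  # when set, n_reads ~ Poisson(coverage)
    read_length: int = 150
    error_rate: float = 0.001
    indel_kind: str = "del"
    indel_length: int = 2
    # variant-call background
    bg_contig: str = "synth_bg"
    bg_length: int = 100_000
    shared_density: float = 2e-3
    private_density: float = 1e-3
    n_known: int = 5
    n_unplaced: int = 2
    unplaced_contig: str = "chrUn_synth"
    unplaced_length: int = 5_000
    planted: tuple[PlantSpec, ...] = ()
    avoid_signatures: bool = True
    include_on_target: bool = False
    # predicted off-target sites
    n_sites: int = 7
    site_width: int = 23
    site_window: int = 500

    def __post_init__(self) -> None:
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        if any(p < 0 for p in self.mixture):
            raise ValueError("mixture proportions must be non-negative")
        if self.error_rate < 0 or self.shared_density < 0 or (
            self.private_density < 0
        ):
            raise ValueError("rates and densities must be >= 0")
        if self.indel_kind not in ("del", "ins"):
            raise ValueError("indel_kind must be 'del' or 'ins'")
        lo = self.locus_offset
        if lo - _CDS_UPSTREAM < 0 or (
            lo - _CDS_UPSTREAM + _CDS_LEN > self.contig_length
        ):
            raise ValueError(
                "locus_offset places the coding segment outside the contig"
            )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _random_bases(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_reference(config: SimulationConfig) -> ReferenceLocus:
    """Synthetic contig embedding the reconstructed locus core, in frame.

    The core sits at ``locus_offset``; a 228-nt single-segment CDS around
    it is padded with stop-free codons so the full segment translates
    cleanly, and everything outside the CDS is uniform random sequence.
    Deterministic per seed.
    """
    rng = config.rng(0)
    core = LOCUS_CORE
    upstream_codons = "".join(
        rng.choice(_SENSE_CODONS, size=(_CDS_UPSTREAM - 2) // 3)
    )
    # two bases completing the codon whose third base is the first core
    # base (G): anything except TA-, which would create a TAG stop
    while True:
        junction = _random_bases(rng, 2)
        if junction + core[0] not in ("TAA", "TAG", "TGA"):
            break
    tail_junction = _random_bases(rng, 2)  # codon G?? can never be a stop
    downstream_codons = "".join(
        rng.choice(_SENSE_CODONS, size=(_CDS_LEN - _CDS_UPSTREAM - len(core) - 2) // 3)
    )
    cds = upstream_codons + junction + core + tail_junction + downstream_codons
    assert len(cds) == _CDS_LEN
    cds_start = config.locus_offset - _CDS_UPSTREAM
    prefix = _random_bases(rng, cds_start)
    suffix = _random_bases(
        rng, config.contig_length - cds_start - _CDS_LEN
    )
    seq = prefix + cds + suffix
    cmap = CodingMap(
        [
            (
                GenomicInterval(config.contig, cds_start, cds_start + _CDS_LEN),
                _CDS_FIRST_C,
            )
        ],
        gene_strand="+",
        gene="Gaa_synth",
    )
    target = PointVariant(
        config.contig,
        config.locus_offset + 24 + 1,
        "C",
        "A",
        label=TARGET_EDIT_LABEL,
    )
    return ReferenceLocus({config.contig: seq}, cmap, target)


def default_guides(locus: ReferenceLocus) -> list[GuideSpec]:
    """The dual overlapping guide pair used in vivo for this locus."""
    contig = locus.target_edit.contig
    return [
        guide_from_protospacer(locus.contigs, contig, GRNA_2, "-", "gRNA-2"),
        guide_from_protospacer(locus.contigs, contig, GRNA_3, "+", "gRNA-3"),
    ]


def _tag_for(guides: Sequence[GuideSpec], variant: PointVariant) -> tuple[str, str]:
    for g in guides:
        if g.pam_interval.contains(variant.pos0):
            return "PAM", g.name
    for g in guides:
        if g.seed.contains(variant.pos0):
            return "seed", g.name
    raise ValueError(
        f"shield at {variant.contig}:{variant.position} falls in no guide's "
        "PAM or seed"
    )


def published_donor(
    locus: ReferenceLocus,
    guides: Sequence[GuideSpec] | None = None,
    arm_length: int = 50,
) -> DonorSpec:
    """The donor as laid out for the in vivo experiment.

    Intended edit c.1935C>A plus four silent shields — one PAM and one
    seed edit per guide (c.1920/c.1923 for the antisense guide,
    c.1929/c.1932 for the sense guide).
    """
    guides = guides if guides is not None else default_guides(locus)
    intended = locus.variant_from_c_label(TARGET_EDIT_LABEL)
    shields = []
    for label in PUBLISHED_SHIELD_LABELS:
        v = locus.variant_from_c_label(label)
        tag, owner = _tag_for(guides, v)
        shields.append(ShieldEdit(v, tag, owner))
    return DonorSpec.from_edits(locus, intended, shields, arm_length=arm_length)


# ----------------------------------------------------------------------
# Founder read simulation
# ----------------------------------------------------------------------

_HAPLOTYPE_LABELS = ("intended_KI", "indel", "no_mutation", "nonspecific")


def _stray_variant(locus: ReferenceLocus, donor: DonorSpec) -> PointVariant:
    """A deterministic non-donor substitution inside the edited core."""
    for pos0 in range(donor.core_interval.start, donor.core_interval.end):
        position = pos0 + 1
        if position not in donor.edited_alleles:
            ref = locus.base_at(donor.contig, position)
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
            return PointVariant(donor.contig, position, ref, alt)
    raise ValueError("no free position for a stray substitution")


def simulate_founder_reads(
    config: SimulationConfig,
    donor: DonorSpec,
    locus: ReferenceLocus,
    guides: Sequence[GuideSpec],
    sam_path: str | Path,
    truth_path: str | Path | None = None,
) -> list[dict]:
    """Draw window-spanning reads from the outcome-haplotype mixture.

    Haplotypes: the full donor haplotype (intended edit + shields), an
    NHEJ indel at the first guide's cut site (default 2-nt deletion), the
    unedited reference, and a single stray substitution.  Reads are
    emitted pre-aligned to their known origin (alignment itself is not
    under test) with independent per-base substitution errors.  Returns
    the truth table (one dict per read) and writes SAM + optional TSV.
    """
    window = donor.footprint
    if config.read_length < len(window):
        raise ValueError(
            f"read_length {config.read_length} shorter than the donor "
            f"footprint ({len(window)} nt); reads cannot span the window"
        )
    rng = config.rng(1)
    contig = donor.contig
    refseq = locus.contigs[contig]

    ki_seq = list(refseq)
    for pos, alt in donor.edited_alleles.items():
        ki_seq[pos - 1] = alt
    ki_seq = "".join(ki_seq)

    cut = guides[0].cut_site
    if config.indel_kind == "del":
        indel_len = -config.indel_length
        indel_seq = refseq[:cut] + refseq[cut + config.indel_length :]
    else:
        indel_len = config.indel_length
        insert = _random_bases(rng, config.indel_length)
        indel_seq = refseq[:cut] + insert + refseq[cut:]

    stray = _stray_variant(locus, donor)
    stray_seq = (
        refseq[: stray.pos0] + stray.alt + refseq[stray.position :]
    )

    n_reads = (
        int(rng.poisson(config.coverage))
        if config.coverage is not None
        else config.n_reads
    )
    hap_idx = rng.choice(4, size=n_reads, p=list(config.mixture))

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": len(seq)}
                for name, seq in locus.contigs.items()
            ],
        }
    )
    truth: list[dict] = []
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for i, h in enumerate(hap_idx):
            label = _HAPLOTYPE_LABELS[h]
            rl = config.read_length
            if label == "indel" and indel_len < 0:
                ref_span = rl - indel_len  # deletion: reference span grows
            elif label == "indel":
                ref_span = rl - indel_len
            else:
                ref_span = rl
            lo = window.end - ref_span
            hi = window.start
            ref_start = int(rng.integers(lo, hi + 1)) if hi >= lo else lo

            if label == "intended_KI":
                seq = ki_seq[ref_start : ref_start + rl]
                cigar = [(0, rl)]
            elif label == "no_mutation":
                seq = refseq[ref_start : ref_start + rl]
                cigar = [(0, rl)]
            elif label == "nonspecific":
                seq = stray_seq[ref_start : ref_start + rl]
                cigar = [(0, rl)]
            elif indel_len < 0:  # deletion read
                d = -indel_len
                left = cut - ref_start
                seq = refseq[ref_start:cut] + refseq[
                    cut + d : ref_start + rl + d
                ]
                cigar = [(0, left), (2, d), (0, rl - left)]
            else:  # insertion read
                left = cut - ref_start
                seq = (
                    refseq[ref_start:cut]
                    + insert
                    + refseq[cut : ref_start + rl - indel_len]
                )
                cigar = [(0, left), (1, indel_len), (0, rl - left - indel_len)]

            seq_arr = np.array(list(seq))
            err_mask = rng.random(len(seq_arr)) < config.error_rate
            n_err = int(err_mask.sum())
            for j in np.flatnonzero(err_mask):
                current = seq_arr[j]
                others = [b for b in "ACGT" if b != current]
                seq_arr[j] = others[int(rng.integers(0, 3))]
            seq = "".join(seq_arr)

            read = pysam.AlignedSegment(header)
            read.query_name = f"read_{i:06d}"
            read.query_sequence = seq
            read.flag = 0
            read.reference_id = header.get_tid(contig)
            read.reference_start = ref_start
            read.mapping_quality = 60
            read.cigartuples = cigar
            read.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(read)
            truth.append(
                {
                    "read_id": read.query_name,
                    "haplotype": label,
                    "ref_start": ref_start,
                    "n_errors": n_err,
                }
            )
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("read_id\thaplotype\tref_start\tn_errors\n")
            for row in truth:
                fh.write(
                    f"{row['read_id']}\t{row['haplotype']}\t"
                    f"{row['ref_start']}\t{row['n_errors']}\n"
                )
    return truth


# ----------------------------------------------------------------------
# Founder/control VCF pair with optional planted signatures
# ----------------------------------------------------------------------


def _would_form_hit(
    candidate: PointVariant,
    by_pos: Mapping[tuple[str, int], list[PointVariant]],
    pattern: SignaturePattern,
) -> bool:
    """Would adding ``candidate`` to the founder-private set create a hit?

    Mirrors the scanner's two-pass rule: the candidate may complete a
    cluster either as a central variant or as a companion to an existing
    central.  Used by the generator to keep unplanted backgrounds
    signature-free.
    """
    c_ref, c_alt = pattern.central
    m_ref, m_alt = complement_base(c_ref), complement_base(c_alt)

    def present(pos: int, want_alt: str) -> bool:
        return any(
            v.alt == want_alt
            for v in by_pos.get((candidate.contig, pos), [])
        )

    def central_at(pos: int, ref: str, alt: str) -> bool:
        return any(
            v.ref == ref and v.alt == alt
            for v in by_pos.get((candidate.contig, pos), [])
        )

    for offset, req in pattern.companions:
        comp_req = complement_base(req)
        if candidate.ref == c_ref and candidate.alt == c_alt:
            if present(candidate.position - offset, req):
                return True
        if candidate.ref == m_ref and candidate.alt == m_alt:
            if present(candidate.position + offset, comp_req):
                return True
        if candidate.alt == req and central_at(
            candidate.position + offset, c_ref, c_alt
        ):
            return True
        if candidate.alt == comp_req and central_at(
            candidate.position - offset, m_ref, m_alt
        ):
            return True
    return False


def _write_vcf(
    path: Path,
    variants: Sequence[PointVariant],
    contig_lengths: Mapping[str, int],
) -> None:
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sorted(variants, key=lambda x: (x.contig, x.position, x.alt)):
            rec = vf.new_record(
                contig=v.contig,
                start=v.pos0,
                stop=v.position,
                alleles=(v.ref, v.alt),
            )
            vf.write(rec)


@dataclass
class SimulatedVcfPair:
    founder_vcf: Path
    control_vcf: Path
    known_snps: Path
    sites_bed: Path
    genome: dict[str, str]
    planted_centrals: list[tuple[str, int, str]]  # (contig, pos, strand)
    truth: dict


def simulate_vcf_pair(
    config: SimulationConfig,
    pattern: SignaturePattern,
    outdir: str | Path,
    locus: ReferenceLocus | None = None,
) -> SimulatedVcfPair:
    """Founder + control VCFs, known-SNP list and predicted-site BED.

    Shared background SNVs appear in both files; founder-private SNVs at
    ``private_density``; known-catalog SNVs appear in the founder file
    and the catalog only.  Each planted signature writes its central SNV
    and companions to the founder file alone, with the background contig
    sequence adjusted so reference bases are consistent.  With
    ``avoid_signatures`` the private background is rejection-sampled so
    it can never complete a signature cluster by chance.  Predicted sites
    occupy a reserved region that private SNVs avoid, mirroring a clean
    off-target outcome.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng(2)
    bg = list(_random_bases(rng, config.bg_length))
    unplaced_seq = _random_bases(rng, config.unplaced_length)

    max_off = pattern.max_offset

    # predicted off-target sites live in a reserved prefix of the contig
    sites: list[GenomicInterval] = []
    site_region_end = 0
    for i in range(config.n_sites):
        start = 1_000 + i * (config.site_width + 200)
        sites.append(
            GenomicInterval(config.bg_contig, start, start + config.site_width)
        )
        site_region_end = start + config.site_width
    snv_floor = site_region_end + config.site_window + 2  # keep sites clean

    def _safe_companion_ref(current: str, req: str) -> str:
        """Template base for a companion slot: must differ from the
        required alt, and must not let the companion itself read as a
        central variant (C>A or its reverse-complement image G>T)."""
        central_forming = {"A": "C", "T": "G"}  # alt -> forbidden ref
        bad = {req, central_forming.get(req, "")}
        if current not in bad:
            return current
        return next(b for b in "ACGT" if b not in bad)

    # planted signature clusters
    planted_variants: list[PointVariant] = []
    planted_centrals: list[tuple[str, int, str]] = []
    c_ref, c_alt = pattern.central
    auto_pos = config.bg_length // 2
    for plant in config.planted:
        contig = plant.contig or config.bg_contig
        if locus is not None and contig == locus.target_edit.contig:
            core_lo = config.locus_offset
            core_hi = config.locus_offset + len(LOCUS_CORE)
            if plant.position is not None and core_lo < plant.position <= core_hi:
                raise ValueError(
                    "planted signature collides with the locus core"
                )
        if contig != config.bg_contig:
            raise ValueError(
                "plants are only supported on the background contig"
            )
        pos = plant.position
        if pos is None:
            pos = auto_pos
            auto_pos += 1_000
        if not (snv_floor + max_off < pos <= config.bg_length - max_off):
            raise ValueError(f"planted position {pos} out of range")
        offsets = plant.offsets or tuple(o for o, _ in pattern.companions)
        required = dict(pattern.companions)
        if plant.strand == "+":
            bg[pos - 1] = c_ref
            planted_variants.append(
                PointVariant(contig, pos, c_ref, c_alt)
            )
            for off in offsets:
                req = required[off]
                comp_pos = pos - off
                ref = _safe_companion_ref(bg[comp_pos - 1], req)
                bg[comp_pos - 1] = ref
                planted_variants.append(PointVariant(contig, comp_pos, ref, req))
        else:
            bg[pos - 1] = complement_base(c_ref)
            planted_variants.append(
                PointVariant(
                    contig, pos, complement_base(c_ref), complement_base(c_alt)
                )
            )
            for off in offsets:
                req = complement_base(required[off])
                comp_pos = pos + off
                ref = _safe_companion_ref(bg[comp_pos - 1], req)
                bg[comp_pos - 1] = ref
                planted_variants.append(PointVariant(contig, comp_pos, ref, req))
        planted_centrals.append((contig, pos, plant.strand))

    bg_seq = "".join(bg)
    genome = {
        config.bg_contig: bg_seq,
        config.unplaced_contig: unplaced_seq,
    }
    if locus is not None:
        genome.update(locus.contigs)

    used: set[tuple[str, int]] = {
        (v.contig, v.position) for v in planted_variants
    }

    def draw_snv(contig: str, seq: str, lo: int, hi: int) -> PointVariant:
        while True:
            pos = int(rng.integers(lo, hi + 1))
            if (contig, pos) in used:
                continue
            ref = seq[pos - 1]
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
            return PointVariant(contig, pos, ref, alt)

    n_shared = round(config.bg_length * config.shared_density)
    n_private = round(config.bg_length * config.private_density)

    shared: list[PointVariant] = []
    for _ in range(n_shared):
        v = draw_snv(config.bg_contig, bg_seq, snv_floor, config.bg_length)
        used.add((v.contig, v.position))
        shared.append(v)

    known_only: list[PointVariant] = []
    for _ in range(config.n_known):
        v = draw_snv(config.bg_contig, bg_seq, snv_floor, config.bg_length)
        used.add((v.contig, v.position))
        known_only.append(v)

    by_pos: dict[tuple[str, int], list[PointVariant]] = {}
    for v in planted_variants:
        by_pos.setdefault((v.contig, v.position), []).append(v)
    private: list[PointVariant] = []
    attempts = 0
    while len(private) < n_private:
        attempts += 1
        if attempts > 50 * (n_private + 1):
            raise RuntimeError(
                "could not place signature-free private SNVs; lower the density"
            )
        v = draw_snv(config.bg_contig, bg_seq, snv_floor, config.bg_length)
        if config.avoid_signatures and _would_form_hit(v, by_pos, pattern):
            continue
        used.add((v.contig, v.position))
        by_pos.setdefault((v.contig, v.position), []).append(v)
        private.append(v)

    unplaced: list[PointVariant] = []
    for _ in range(config.n_unplaced):
        v = draw_snv(
            config.unplaced_contig, unplaced_seq, 1, config.unplaced_length
        )
        used.add((v.contig, v.position))
        unplaced.append(v)

    founder = shared + known_only + private + planted_variants + unplaced
    control = list(shared)
    if config.include_on_target and locus is not None:
        # the on-target HDR product itself, as seen by a variant caller
        donor = published_donor(locus)
        founder.extend(donor.all_edits)

    contig_lengths = {name: len(seq) for name, seq in genome.items()}
    founder_vcf = outdir / "founder.vcf"
    control_vcf = outdir / "control.vcf"
    _write_vcf(founder_vcf, founder, contig_lengths)
    _write_vcf(control_vcf, control, contig_lengths)

    known_path = outdir / "known_snps.tsv"
    with open(known_path, "w") as fh:
        fh.write("#contig\tposition\tref\talt\n")
        for v in sorted(known_only, key=lambda x: (x.contig, x.position)):
            fh.write(f"{v.contig}\t{v.position}\t{v.ref}\t{v.alt}\n")

    sites_bed = outdir / "predicted_sites.bed"
    with open(sites_bed, "w") as fh:
        for iv in sites:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")

    return SimulatedVcfPair(
        founder_vcf=founder_vcf,
        control_vcf=control_vcf,
        known_snps=known_path,
        sites_bed=sites_bed,
        genome=genome,
        planted_centrals=planted_centrals,
        truth={
            "n_shared": n_shared,
            "n_private": len(private),
            "n_known_only": len(known_only),
            "n_unplaced": len(unplaced),
            "n_planted": len(config.planted),
        },
    )
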