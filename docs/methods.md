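# Methods

## Coordinate conventions

Internal coordinates are 0-based half-open (`GenomicInterval`); anything
facing VCF or HGVS-like `c.` notation is 1-based. A `CodingMap` holds
ordered CDS segments as `(interval, first_c)` pairs; on minus-strand
genes increasing coding position runs along decreasing genomic
coordinate. Only the `c.<pos><ref>><alt>` subset of HGVS is parsed;
intronic/UTR notation and transcript databases are out of scope.

## Guide model

SpCas9 guides are 20-nt protospacers with an NGG PAM; NAG-tolerated PAMs
are excluded. The cut is modelled as blunt, 3 bp 5′ of the PAM (between
protospacer positions 17 and 18); no staggered-cut model is offered. The
seed is defined as the 5 PAM-proximal protospacer nucleotides.
`find_guides` enumerates exhaustively on both strands in deterministic
order; guide efficacy and genome-wide off-target site prediction are
deliberately not implemented — those are external services whose outputs
(rankings, BED files of predicted sites) the package accepts as inputs.
The dual-overlap report exposes signed cut-to-target distances and
leaves any proximity thresholding to the caller.

## Donor design

A donor consists of homology arms (default 50 nt, configurable), the
intended edit, and synonymous shield mutations in each guide's PAM or
seed. "Disrupted" means the edited PAM no longer matches NGG *or* at
least one seed position is edited; either suffices. When several
synonymous options exist the builder is deterministic: PAM-breaking
edits are preferred over seed edits, then left-most genomic position,
then alphabetical alternate base. The default installs the minimal one
shield per guide; `DonorPolicy(redundant_seed=True)` adds a seed edit
alongside each PAM edit, the belt-and-braces layout used by the
published donor for this locus (PAM edits at c.1920/c.1932, seed edits
at c.1923/c.1929). Validation is by construction *and* by
re-translation: every shield must leave the protein unchanged and the
whole donor must change exactly the intended residue.

## HDR signature pattern

Shield-to-intended-edit distances, measured in nucleotides along the
gene strand between variant positions, become the companion offsets of
the ectopic-integration signature (3, 6, 12, 15 for the c.1935 donor,
requiring alternates A, A, C, T). Companion rules are "any reference
base > fixed alternate". Shields downstream of the intended edit are
excluded from the pattern (and counted in the pattern id): the
published criteria are upstream-only, and an integrated donor stamps its
companions ahead of the central change in reading direction. One
matching companion suffices for a hit; all matching companions are
recorded; nearby de novo variants at non-pattern offsets neither
strengthen nor void a hit.

On the reverse-complement pass the central rule complements (G>T for
C>A) and companions complement and flip to the same offsets *downstream*
in genome coordinates. This is the only reading under which the
reverse-complement pass can add matches.

## Read classification

Reads must fully span the classification window (default: the donor
footprint, arms included) — this avoids censoring bias in category
fractions. Primary, non-duplicate alignments at mapping quality ≥ 20
(configurable) are decomposed into substitutions and indels; precedence
is indel > intended-KI > nonspecific > no-mutation. Intended-KI requires
the intended edit, the shield alleles at every covered shield position,
and no other substitution in the window; a lone intended edit without
shields is nonspecific by default (`require_shields=False` relaxes
this). Classification is read-level, not consensus-level. Base-quality
masking is off by default. Printed percentages round half-up to one
decimal (35/39 → 89.7, 15/39 → 38.5).

## Background subtraction and site windows

Subtraction is site-level and exact-tuple: a founder SNV is removed iff
an identical (contig, pos, ref, alt) exists in the control calls or the
known-SNP catalog, or its contig is outside the allowlist (the
"unplaced chromosome" filter). A same-position/same-alt record with a
different ref does not subtract; it retains the variant with a warning.
Genotype and FILTER fields are ignored by default (`pass_only`
available). Predicted-site windows are inclusive at exactly the window
size (default 500 nt, distance 0 inside the interval).

## Synthetic data: what it emulates and what it does not

The toy genome embeds a 32-nt core assembled by suffix/prefix overlap of
the three published protospacers; the assembly is over-determined and
self-checking — it yields NGG PAMs for all three guides and, with the
frame anchored so the core's first base is coding position 1911, the
codon GAC (Asp) at c.1933–1935 and synonymous status for all four
published shields. The 228-nt single-segment CDS around the core is
padded with stop-free codons; all other padding is uniform random
sequence. The genomic padding around the core is arbitrary (the real
flanking sequence is not reconstructable from printed data), so
coordinates on the synthetic contig are meaningful only relative to the
core.

Founder reads are drawn from four haplotypes — full donor, an NHEJ indel
at the first guide's cut site (default 2-nt deletion), reference, and a
single stray substitution — at a default 55/25/15/5 mixture emulating a
high-efficiency founder, with independent per-base substitution errors
(default 0.1%) and reads emitted pre-aligned to their origin. Alignment
is out of scope: classification, not mapping, is under test. Real data
differ in ways the generator does not model: correlated and
quality-dependent errors, PCR duplicates, soft-clipped breakpoints,
multi-nucleotide repair tracts. A green recovery test therefore
establishes classifier correctness given correct alignments, not
robustness to alignment artefacts.

The VCF generator writes shared background SNVs (both files), a
known-catalog subset (founder + catalog only), founder-private SNVs, and
optional planted signature clusters. Two construction details keep
plant/recover exact: private SNVs are rejection-sampled so they can
never complete a signature cluster by chance, and planted-companion
template bases are chosen so a companion variant cannot itself read as a
central variant (C>A or G>T) — otherwise intra-cluster geometry would
produce additional, formally legitimate hits. With `avoid_signatures`
disabled, chance hits occur at the closed-form rate
`L·d/6 · (1−(1−d/4)^k)` under a uniform background of density `d` with
`k` companion rules (verified by Monte-Carlo in the test suite).

## Numerical and degenerate-input conventions

- Regions shorter than 23 nt yield an empty guide list (logged), not an
  error; a zero-read window yields a tally with total 0 and explicitly
  undefined fractions; an empty founder cohort is an error.
- All randomness flows through `numpy.random.default_rng([seed, stream])`
  with fixed per-generator stream ids; identical (seed, config) gives
  byte-identical FASTA/SAM/VCF output.
- `coverage`, when set, draws the spanning-read count from a Poisson of
  that mean; otherwise `n_reads` is used directly.
- Ties in shield selection are broken deterministically (documented
  order above); serialized artifacts round-trip exactly.

## Known limitations

- Single-nucleotide edits only; multi-nucleotide intended edits and
  asymmetric homology arms are not modelled.
- The scanner is site-level: it does not inspect read evidence, phasing,
  or structural variants (ectopic full-length insertions large enough to
  be called as SVs belong to an SV caller, not this scan).
- Cohort summaries trust the per-founder flags they are given; deriving
  those flags from Sanger traces is out of scope.
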