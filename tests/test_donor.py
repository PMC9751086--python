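"""Donor construction, synonymy, validation, signature derivation."""

import pytest
from Bio.Seq import Seq

from hdrkit.donor import (
    DonorDesignError,
    DonorPolicy,
    DonorSpec,
    ShieldEdit,
    SignaturePattern,
    build_ssodn,
    derive_signature_pattern,
    synonymous_options,
    validate_donor,
)
from hdrkit.guides import find_guides
from hdrkit.locus import GenomicInterval, PointVariant, translate
from hdrkit.simulate import (
    SimulationConfig,
    default_guides,
    make_reference,
    published_donor,
)

ALL_CODONS = [
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
]


class TestSynonymousOptions:
    def test_single_codon_amino_acids_have_no_options(self):
        assert synonymous_options("ATG", 2) == []  # Met
        assert synonymous_options("TGG", 2) == []  # Trp

    def test_asp_codon_wobble(self):
        # GAC and GAT both code aspartate; no other third-base change does
        assert synonymous_options("GAC", 2) == ["T"]

    def test_full_enumeration_matches_translation_oracle(self):
        for codon in ALL_CODONS:
            aa = str(Seq(codon).translate())
            for pos in range(3):
                expected = sorted(
                    b
                    for b in "ACGT"
                    if b != codon[pos]
                    and str(
                        Seq(codon[:pos] + b + codon[pos + 1 :]).translate()
                    )
                    == aa
                )
                assert synonymous_options(codon, pos) == expected

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError):
            synonymous_options("ANG", 1)


class TestBuildSsodn:
    def test_published_pair_yields_valid_minimal_donor(self, locus, guides):
        donor = build_ssodn(locus, guides)
        assert len(donor.shield_edits) == 2  # one PAM shield per guide
        assert all(s.tag == "PAM" for s in donor.shield_edits)
        assert validate_donor(donor, locus, guides).passed

    def test_redundant_seed_policy_adds_seed_shields(self, locus, guides):
        donor = build_ssodn(locus, guides, DonorPolicy(redundant_seed=True))
        tags = sorted(s.tag for s in donor.shield_edits)
        assert tags == ["PAM", "PAM", "seed", "seed"]
        assert validate_donor(donor, locus, guides).passed

    def test_arm_arithmetic(self, locus, guides):
        donor = build_ssodn(locus, guides, DonorPolicy(arm_length=40))
        assert len(donor.ssodn) == 2 * 40 + len(donor.core_interval)

    def test_far_guide_rejected(self, locus, config):
        region = GenomicInterval(config.contig, 100, 400)
        far = find_guides(locus.contigs, region)[0]
        with pytest.raises(DonorDesignError, match=far.name):
            build_ssodn(locus, [far])

    @pytest.mark.parametrize("seed", range(5))
    def test_build_then_validate_round_trip(self, seed):
        """Any donor the builder produces passes its own validator."""
        cfg = SimulationConfig(seed=seed)
        loc = make_reference(cfg)
        near = GenomicInterval(
            cfg.contig, cfg.locus_offset - 30, cfg.locus_offset + 60
        )
        candidates = [
            g
            for g in find_guides(loc.contigs, near)
            if abs(g.cut_site - loc.target_edit.pos0) <= 50
        ]
        built = 0
        for g in candidates:
            try:
                donor = build_ssodn(loc, [g])
            except DonorDesignError:
                continue
            assert validate_donor(donor, loc, [g]).passed
            built += 1
        assert built >= 1  # the locus itself guarantees designable guides


class TestValidateDonor:
    def test_unedited_reference_window_fails_intended_edit(self, locus, guides):
        donor = published_donor(locus, guides)
        unedited = DonorSpec(
            contig=donor.contig,
            intended_edit=donor.intended_edit,
            shield_edits=donor.shield_edits,
            arm_length=donor.arm_length,
            ssodn=locus.fetch(donor.footprint),
            orientation="+",
            gene_strand=donor.gene_strand,
            core_interval=donor.core_interval,
        )
        report = validate_donor(unedited, locus, guides)
        assert not report.passed
        failed = {name for name, _ in report.failures()}
        assert any("intended_edit_present" in n for n in failed)

    def test_published_donor_passes_overall(self, locus, guides, donor):
        report = validate_donor(donor, locus, guides)
        assert report.passed, str(report)

    def test_nonsynonymous_shield_named_in_failure(self, locus, guides):
        # first-position change in the GAC codon (c.1933) is never silent
        bad_pos = locus.coding_map.c_to_genomic(1933)[1]
        bad = ShieldEdit(
            PointVariant(
                locus.target_edit.contig,
                bad_pos,
                locus.base_at(locus.target_edit.contig, bad_pos),
                "T",
            ),
            "seed",
            "gRNA-3",
        )
        donor = DonorSpec.from_edits(
            locus,
            locus.target_edit,
            [bad],
        )
        report = validate_donor(donor, locus, guides)
        failed = [name for name, _ in report.failures()]
        assert any(
            "shield_synonymous" in n and str(bad_pos) in n for n in failed
        )

    def test_donor_protein_differs_at_exactly_one_residue(self, locus, donor):
        ref_protein = translate(locus.cds_sequence())
        for v in donor.all_edits:
            locus.apply_variant(v)
        edited_protein = translate(locus.cds_sequence())
        diffs = [
            i for i, (a, b) in enumerate(zip(ref_protein, edited_protein))
            if a != b
        ]
        assert len(diffs) == 1


class TestSignaturePattern:
    def test_published_donor_pattern(self, donor):
        pattern = derive_signature_pattern(donor)
        assert pattern.central == ("C", "A")
        assert pattern.companions == ((3, "A"), (6, "A"), (12, "C"), (15, "T"))

    def test_offsets_equal_coding_position_differences(self, locus, donor):
        cmap = locus.coding_map
        intended_c = cmap.genomic_to_c(
            donor.contig, donor.intended_edit.position
        )
        expected = sorted(
            intended_c
            - cmap.genomic_to_c(donor.contig, s.variant.position)
            for s in donor.shield_edits
        )
        pattern = derive_signature_pattern(donor)
        assert [off for off, _ in pattern.companions] == expected

    def test_no_shields_is_an_error(self, locus):
        bare = DonorSpec.from_edits(locus, locus.target_edit, [])
        with pytest.raises(ValueError, match="no companions derivable"):
            derive_signature_pattern(bare)

    def test_invariant_under_oligo_orientation(self, locus, donor):
        flipped = DonorSpec.from_edits(
            locus,
            donor.intended_edit,
            list(donor.shield_edits),
            arm_length=donor.arm_length,
            orientation="-",
        )
        assert derive_signature_pattern(flipped) == derive_signature_pattern(
            donor
        )

    def test_downstream_shields_flagged_and_excluded(self, locus):
        contig = locus.target_edit.contig
        # a synonymous wobble downstream (3' of c.1935): c.1938 third base
        pos = locus.coding_map.c_to_genomic(1938)[1]
        ref = locus.base_at(contig, pos)
        codon, off = locus.codon_of(1938)
        options = synonymous_options(codon, off)
        if not options:  # depends on random padding codon; make one upstream
            pytest.skip("no synonymous wobble at c.1938 for this seed")
        down = ShieldEdit(
            PointVariant(contig, pos, ref, options[0]), "seed", "gRNA-3"
        )
        up = ShieldEdit(
            locus.variant_from_c_label("c.1920C>T"), "PAM", "gRNA-2"
        )
        donor = DonorSpec.from_edits(locus, locus.target_edit, [up, down])
        pattern = derive_signature_pattern(donor)
        assert pattern.companions == ((15, "T"),)
        assert "downstream" in pattern.pattern_id

    def test_pattern_invariants(self):
        with pytest.raises(ValueError):
            SignaturePattern(("C", "A"), ())
        with pytest.raises(ValueError):
            SignaturePattern(("C", "A"), ((3, "A"), (3, "T")))


def test_donor_file_round_trip(tmp_path, locus, donor):
    donor.to_files(tmp_path / "d.fa", tmp_path / "d.edits.tsv")
    loaded = DonorSpec.from_files(locus, tmp_path / "d.edits.tsv")
    assert loaded.ssodn == donor.ssodn
    assert loaded.all_edits == donor.all_edits
    assert [s.tag for s in loaded.shield_edits] == [
        s.tag for s in donor.shield_edits
    ]
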