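"""Background subtraction, predicted-site windows, signature scanning."""

import math

import numpy as np
import pytest

from hdrkit.donor import SignaturePattern
from hdrkit.locus import GenomicInterval, PointVariant, revcomp
from hdrkit.offtarget import (
    DeNovoSet,
    predicted_site_check,
    scan_signatures,
    subtract_background,
)
from hdrkit.simulate import PlantSpec, SimulationConfig, simulate_vcf_pair


def _write_vcf(path, variants):
    contigs = sorted({c for c, *_ in variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c},length=1000000>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for contig, pos, ref, alt in sorted(variants):
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


class TestSubtractBackground:
    def test_founder_equals_control_leaves_nothing(self, tmp_path):
        records = [("chr1", 100, "A", "G"), ("chr1", 200, "C", "T")]
        _write_vcf(tmp_path / "f.vcf", records)
        _write_vcf(tmp_path / "c.vcf", records)
        dn = subtract_background(tmp_path / "f.vcf", tmp_path / "c.vcf")
        assert len(dn) == 0
        assert dn.counters["removed_control"] == 2

    def test_set_arithmetic_with_known_and_unplaced(self, tmp_path):
        shared = [("chr1", i * 10, "A", "G") for i in range(1, 5)]
        unplaced = [("chrUn_x", 7, "C", "T"), ("chrUn_x", 9, "G", "A")]
        known = [("chr1", 500, "T", "C")]
        private = [
            ("chr1", 601, "C", "A"),
            ("chr1", 702, "G", "T"),
            ("chr2", 55, "A", "C"),
        ]
        _write_vcf(tmp_path / "f.vcf", shared + unplaced + known + private)
        _write_vcf(tmp_path / "c.vcf", shared)
        dn = subtract_background(
            tmp_path / "f.vcf",
            tmp_path / "c.vcf",
            known_snps=[("chr1", 500, "T", "C")],
            contig_allowlist=["chr1", "chr2"],
        )
        assert len(dn) == 3
        assert dn.counters == {
            "input": 10,
            "removed_unplaced": 2,
            "removed_control": 4,
            "removed_known": 1,
            "retained": 3,
        }
        assert sum(v for k, v in dn.counters.items() if k != "input") == (
            dn.counters["input"]
        )

    def test_same_alt_different_ref_retained_with_warning(self, tmp_path):
        _write_vcf(tmp_path / "f.vcf", [("chr1", 100, "A", "G")])
        _write_vcf(tmp_path / "c.vcf", [("chr1", 100, "C", "G")])
        with pytest.warns(UserWarning, match="different ref"):
            dn = subtract_background(tmp_path / "f.vcf", tmp_path / "c.vcf")
        assert len(dn) == 1

    def test_disjoint_contig_names_error(self, tmp_path):
        _write_vcf(tmp_path / "f.vcf", [("chr1", 100, "A", "G")])
        _write_vcf(tmp_path / "c.vcf", [("1", 100, "A", "G")])
        with pytest.raises(ValueError, match="'1'"):
            subtract_background(tmp_path / "f.vcf", tmp_path / "c.vcf")


class TestPredictedSiteCheck:
    SITE = GenomicInterval("chr1", 10_000, 10_023)

    def _denovo(self, positions):
        return DeNovoSet(
            [PointVariant("chr1", p, "A", "G") for p in positions]
        )

    def test_empty_set_gives_all_zero_counts(self):
        reports = predicted_site_check([self.SITE] * 3, DeNovoSet([]))
        assert [r.count for r in reports] == [0, 0, 0]

    def test_boundary_inclusive_at_exactly_500(self):
        # left edge: site starts at 0-based 10_000 -> first base is pos 10_001
        at_500 = self._denovo([10_001 - 500])
        at_501 = self._denovo([10_001 - 501])
        assert predicted_site_check([self.SITE], at_500)[0].count == 1
        assert predicted_site_check([self.SITE], at_501)[0].count == 0
        # right edge: last base is pos 10_023
        assert predicted_site_check([self.SITE], self._denovo([10_523]))[
            0
        ].count == 1
        assert predicted_site_check([self.SITE], self._denovo([10_524]))[
            0
        ].count == 0

    def test_inside_site_counts_at_distance_zero(self):
        assert predicted_site_check(
            [self.SITE], self._denovo([10_010]), window_nt=0
        )[0].count == 1

    def test_only_the_hit_site_is_flagged(self):
        sites = [
            GenomicInterval("chr1", 1_000 * k, 1_000 * k + 23)
            for k in range(1, 8)
        ]
        dn = self._denovo([3_010])  # inside site 3
        reports = predicted_site_check(sites, dn)
        assert [r.count for r in reports] == [0, 0, 1, 0, 0, 0, 0]

    def test_malformed_bed_reports_line_number(self, tmp_path):
        bad = tmp_path / "sites.bed"
        bad.write_text("chr1\t10\t50\nchr1\toops\t60\n")
        with pytest.raises(ValueError, match="line|:2"):
            predicted_site_check(bad, DeNovoSet([]))


PATTERN = SignaturePattern(
    central=("C", "A"),
    companions=((3, "A"), (6, "A"), (12, "C"), (15, "T")),
)


class TestScanSignatures:
    def test_empty_set_no_hits(self):
        assert scan_signatures(DeNovoSet([]), PATTERN) == []

    def test_single_plus_strand_cluster_one_companion_suffices(self):
        dn = DeNovoSet(
            [
                PointVariant("chr1", 5_000, "C", "A"),
                PointVariant("chr1", 4_997, "G", "A"),
            ]
        )
        hits = scan_signatures(dn, PATTERN)
        assert len(hits) == 1
        assert hits[0].strand == "+"
        assert hits[0].companions == ((3, dn.variants[0]),)

    def test_minus_strand_image_matches_downstream(self):
        # a minus-strand central reads as G>T on the plus strand; the
        # N>T @ -15 companion of the donor appears 15 nt *after* it in
        # genome coordinates with the complemented alternate (A)
        dn = DeNovoSet(
            [
                PointVariant("chr1", 5_000, "G", "T"),
                PointVariant("chr1", 5_015, "G", "A"),
            ]
        )
        hits = scan_signatures(dn, PATTERN)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].companions[0][0] == 15

    def test_lone_centrals_never_hit(self):
        dn = DeNovoSet(
            [PointVariant("chr1", p, "C", "A") for p in range(1000, 1200, 40)]
        )
        assert scan_signatures(dn, PATTERN) == []

    def test_companion_with_wrong_alt_does_not_hit(self):
        dn = DeNovoSet(
            [
                PointVariant("chr1", 5_000, "C", "A"),
                PointVariant("chr1", 4_997, "G", "C"),  # needs alt A at -3
            ]
        )
        assert scan_signatures(dn, PATTERN) == []

    def test_all_companions_recorded_when_multiple_match(self):
        dn = DeNovoSet(
            [
                PointVariant("chr1", 5_000, "C", "A"),
                PointVariant("chr1", 4_997, "G", "A"),
                PointVariant("chr1", 4_994, "G", "A"),
                PointVariant("chr1", 4_988, "G", "C"),
                # ref A so the offset-15 companion cannot itself read as a
                # minus-strand central (G>T)
                PointVariant("chr1", 4_985, "A", "T"),
            ]
        )
        hits = scan_signatures(dn, PATTERN)
        assert len(hits) == 1
        assert [off for off, _ in hits[0].companions] == [3, 6, 12, 15]

    def test_hits_are_subset_of_the_denovo_set(self):
        rng = np.random.default_rng(5)
        variants = []
        for pos in rng.choice(100_000, size=400, replace=False):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            variants.append(PointVariant("chr1", int(pos) + 20, ref, alt))
        dn = DeNovoSet(variants)
        for h in scan_signatures(dn, PATTERN):
            assert h.central in dn
            for off, u in h.companions:
                assert u in dn
                expected = dict(PATTERN.companions)[off]
                if h.strand == "+":
                    assert u.alt == expected
                    assert u.position == h.central.position - off
                else:
                    assert u.position == h.central.position + off

    def test_strand_symmetry_under_fixture_mirroring(self):
        contig_len = 10_000
        rng = np.random.default_rng(9)
        variants = [
            PointVariant("chr1", 5_000, "C", "A"),
            PointVariant("chr1", 4_997, "G", "A"),
            PointVariant("chr1", 2_000, "G", "T"),
            PointVariant("chr1", 2_012, "T", "G"),
        ]
        for pos in rng.choice(9_000, size=60, replace=False):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            variants.append(PointVariant("chr1", int(pos) + 100, ref, alt))
        mirrored = [
            PointVariant(
                "chr1",
                contig_len + 1 - v.position,
                revcomp(v.ref),
                revcomp(v.alt),
            )
            for v in variants
        ]
        n_fwd = len(scan_signatures(DeNovoSet(variants), PATTERN))
        n_rev = len(scan_signatures(DeNovoSet(mirrored), PATTERN))
        assert n_fwd == n_rev >= 2


class TestFalsePositiveRate:
    def test_uniform_background_matches_binomial_closed_form(self):
        """Expected chance-hit count under a uniform random SNV background.

        Each position mutates independently with probability d; ref bases
        are uniform, alts uniform over the three non-ref bases.  A central
        (C>A or G>T image) occurs at rate d/12 per strand; a companion
        slot matches at rate q = d/4; P(hit | central) = 1-(1-q)^4.
        """
        L, d = 50_000, 0.01
        n_seeds = 30
        k = len(PATTERN.companions)
        q = d / 4
        expected = (L * d / 6) * (1 - (1 - q) ** k)
        counts = []
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            mask = rng.random(L) < d
            positions = np.flatnonzero(mask) + 1
            refs = rng.choice(list("ACGT"), size=len(positions))
            variants = []
            for pos, ref in zip(positions, refs):
                alt = rng.choice([b for b in "ACGT" if b != ref])
                variants.append(PointVariant("chr1", int(pos), ref, str(alt)))
            counts.append(len(scan_signatures(DeNovoSet(variants), PATTERN)))
        mean = float(np.mean(counts))
        mc_se = math.sqrt(expected / n_seeds)  # Poisson-like variance
        assert abs(mean - expected) < 4 * mc_se


class TestPlantRecover:
    @pytest.mark.parametrize("seed", range(6))
    def test_planted_clusters_recovered_exactly(
        self, tmp_path, locus, pattern, seed
    ):
        cfg = SimulationConfig(
            seed=seed,
            planted=(PlantSpec(), PlantSpec(strand="-"), PlantSpec()),
        )
        pair = simulate_vcf_pair(cfg, pattern, tmp_path / str(seed), locus=locus)
        dn = subtract_background(
            pair.founder_vcf,
            pair.control_vcf,
            known_snps=pair.known_snps,
            contig_allowlist=[cfg.bg_contig, cfg.contig],
        )
        hits = scan_signatures(dn, pattern)
        assert {
            (h.central.contig, h.central.position, h.strand) for h in hits
        } == set(pair.planted_centrals)

    def test_clean_background_mirrors_negative_outcome(
        self, tmp_path, locus, pattern
    ):
        """Zero planted signatures and clean predicted sites: the scan and
        the site check both come back empty."""
        cfg = SimulationConfig(seed=40)
        pair = simulate_vcf_pair(cfg, pattern, tmp_path, locus=locus)
        dn = subtract_background(
            pair.founder_vcf,
            pair.control_vcf,
            known_snps=pair.known_snps,
            contig_allowlist=[cfg.bg_contig, cfg.contig],
        )
        assert scan_signatures(dn, pattern) == []
        reports = predicted_site_check(pair.sites_bed, dn)
        assert len(reports) == 7
        assert all(r.count == 0 for r in reports)
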