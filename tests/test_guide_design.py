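"""PAM scanning, TSS-window classification, stoichiometry, extension, pairing."""

import numpy as np
import pytest

from ifcascade.guide_design import (
    GuideCandidate,
    classify_tss_window,
    csy3_copies,
    extend_spacer,
    extract_candidates,
    rank_candidates,
    scan_pam_sites,
    select_pairs,
    truncate_spacer,
)
from ifcascade.sequence_io import GenomeSequences, TssRecord, revcomp
from ifcascade.synthetic_data import (
    generate_genome,
    plant_gene,
    plant_on_target,
    random_spacer,
)


class TestScanPamSites:
    def test_forward_site(self):
        assert scan_pam_sites("AACCGTGTGT", 6) == [("+", 4)]

    def test_reverse_complement_symmetry_of_example(self):
        # the same site seen from the other strand
        assert scan_pam_sites("ACACACGGTT", 6) == [("-", 0)]

    def test_no_pam_no_sites(self):
        assert scan_pam_sites("AAAAAA", 2) == []

    def test_n_in_window_excluded(self):
        assert scan_pam_sites("AACCGTNTGT", 6) == []

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            scan_pam_sites("ACGT", 0)
        with pytest.raises(ValueError):
            scan_pam_sites("", 4)

    def test_strand_symmetry_on_random_sequences(self, rng):
        # candidate sets on a sequence and its reverse complement are mirror images
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=5000))
            L = 32
            fwd = set(scan_pam_sites(seq, L))
            rc = set(scan_pam_sites(revcomp(seq), L))
            mapped = {("-" if s == "+" else "+", len(seq) - i - L) for s, i in rc}
            assert fwd == mapped


class TestClassifyTssWindow:
    @pytest.mark.parametrize(
        "offset,expected",
        [
            (-150, "optimal"),
            (-200, "optimal"),
            (-100, "optimal"),
            (-201, "in_range"),
            (-400, "in_range"),
            (-500, "in_range"),
            (-501, "out_of_range"),
            (-50, "out_of_range"),
            (50, "out_of_range"),
        ],
    )
    def test_boundaries(self, offset, expected):
        assert classify_tss_window(offset) == expected


class TestCsy3Copies:
    @pytest.mark.parametrize("length,copies", [(32, 6), (14, 3), (50, 9), (6, 1), (56, 10)])
    def test_documented_values(self, length, copies):
        assert csy3_copies(length) == copies

    def test_below_minimal_binding_unit(self):
        with pytest.raises(ValueError):
            csy3_copies(5)

    def test_closed_form_and_monotonicity(self):
        values = [csy3_copies(L) for L in range(6, 121)]
        assert values == [-(-L // 6) for L in range(6, 121)]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestExtractCandidates:
    def _dataset(self, offsets, strand="+", seed=11):
        ds = generate_genome(1, 12000, seed=seed)
        gene = plant_gene(ds, "chr1", 6000, strand, "g")
        spacers = {}
        for off in offsets:
            spacers[off] = plant_on_target(ds, gene, random_spacer(ds.rng), off).spacer_ref
        return ds, spacers

    def test_planted_offsets_recovered_with_window_class(self):
        ds, spacers = self._dataset([-150, -400])
        cands = extract_candidates(ds.genome(), ds.tss_records)
        by_off = {c.tss_offset: c for c in cands}
        assert by_off[-150].window_class == "optimal"
        assert by_off[-150].spacer == spacers[-150]
        assert by_off[-400].window_class == "in_range"

    def test_downstream_site_excluded(self):
        ds, _ = self._dataset([150])
        cands = extract_candidates(ds.genome(), ds.tss_records)
        assert all(c.tss_offset != 150 for c in cands)

    def test_minus_strand_gene(self):
        ds, spacers = self._dataset([-150], strand="-")
        cands = extract_candidates(ds.genome(), ds.tss_records)
        match = [c for c in cands if c.tss_offset == -150 and c.strand == "-"]
        assert len(match) == 1
        assert match[0].spacer == spacers[-150]
        assert match[0].window_class == "optimal"

    def test_planted_site_found_exactly_once(self):
        for seed in range(5):
            ds, spacers = self._dataset([-150, -300, -480], seed=seed)
            cands = extract_candidates(ds.genome(), ds.tss_records)
            for off, spacer in spacers.items():
                assert sum(c.spacer == spacer and c.tss_offset == off for c in cands) == 1

    def test_no_tss_is_error(self):
        ds, _ = self._dataset([-150])
        with pytest.raises(ValueError):
            extract_candidates(ds.genome(), [])

    def test_unknown_sequence_is_error(self):
        ds, _ = self._dataset([-150])
        bad = TssRecord("x", "chrZ", 10, "+")
        with pytest.raises(KeyError):
            extract_candidates(ds.genome(), [bad])


class TestExtendSpacer:
    def _candidate_and_genome(self, strand="+"):
        ds = generate_genome(1, 12000, seed=3)
        gene = plant_gene(ds, "chr1", 6000, strand, "g")
        plant_on_target(ds, gene, random_spacer(ds.rng), -150)
        genome = ds.genome()
        (cand,) = [c for c in extract_candidates(genome, ds.tss_records) if c.tss_offset == -150]
        return cand, genome

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_pam_proximal_32_preserved(self, strand):
        cand, genome = self._candidate_and_genome(strand)
        ext = extend_spacer(cand, 56, genome)
        assert len(ext.spacer) == 56
        assert ext.spacer[:32] == cand.spacer
        assert ext.csy3_copies == 10
        assert ext.tss_offset == cand.tss_offset

    def test_identity_extension(self):
        cand, genome = self._candidate_and_genome()
        assert extend_spacer(cand, 32, genome) == cand

    def test_non_multiple_of_six_rejected(self):
        cand, genome = self._candidate_and_genome()
        with pytest.raises(ValueError):
            extend_spacer(cand, 40, genome)

    def test_extension_beyond_sequence_bounds(self):
        genome = GenomeSequences({"c": "AACC" + "G" * 32})
        cand = GuideCandidate("g", "c", "+", 4, 36, "CC", "G" * 32, -150, "optimal", 6)
        with pytest.raises(ValueError, match="bounds"):
            extend_spacer(cand, 38, genome)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_extend_then_truncate_round_trip(self, strand):
        cand, genome = self._candidate_and_genome(strand)
        assert truncate_spacer(extend_spacer(cand, 50, genome), 32) == cand


class TestSelectPairs:
    def _cand(self, start, gene="g"):
        return GuideCandidate(gene, "c", "+", start, start + 32, "CC", "A" * 32, -150, "optimal", 6)

    def test_optimal_spacing(self):
        (pair,) = select_pairs([self._cand(100), self._cand(160)])
        assert pair.spacing == 60
        assert pair.spacing_class == "optimal"

    def test_acceptable_spacing(self):
        (pair,) = select_pairs([self._cand(100), self._cand(127)])
        assert pair.spacing == 27
        assert pair.spacing_class == "acceptable"

    def test_single_candidate_yields_empty(self):
        assert select_pairs([self._cand(100)]) == []

    def test_optimal_sorted_first_then_by_distance_from_midpoint(self):
        pairs = select_pairs([self._cand(0), self._cand(63), self._cand(200)])
        assert [p.spacing for p in pairs] == [63, 137, 200]
        assert [p.spacing_class for p in pairs] == ["optimal", "acceptable", "acceptable"]

    def test_mixed_genes_rejected(self):
        with pytest.raises(ValueError):
            select_pairs([self._cand(0, "a"), self._cand(60, "b")])


class TestRankCandidates:
    def _cand(self, off, wc, start=0):
        return GuideCandidate("g", "c", "+", start, start + 32, "CC", "A" * 32, off, wc, 6)

    def test_optimal_before_in_range(self):
        a, b = self._cand(-400, "in_range"), self._cand(-150, "optimal")
        assert rank_candidates([a, b]) == [b, a]

    def test_stability_on_identical_keys(self):
        a, b = self._cand(-150, "optimal"), self._cand(-150, "optimal")
        assert rank_candidates([a, b]) == [a, b]

    def test_empty(self):
        assert rank_candidates([]) == []

    def test_closer_to_window_center_first(self):
        far, near = self._cand(-110, "optimal", 10), self._cand(-149, "optimal", 60)
        assert rank_candidates([far, near]) == [near, far]
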