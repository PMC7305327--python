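"""Off-target enumeration vs oracle, promoter filtering, overlap search, reports."""

import numpy as np
import pytest

from ifcascade.mismatch_model import PositionMask, apply_mismatches
from ifcascade.offtarget_search import (
    OffTargetHit,
    RuleSet,
    brute_force_oracle,
    cascade_rule,
    enumerate_offtargets,
    find_overlap_sites,
    promoter_filter,
    render_site,
    report,
    spcas9_rule,
)
from ifcascade.sequence_io import (
    GenomeSequences,
    PromoterInterval,
    TssRecord,
    build_promoters,
    revcomp,
)
from ifcascade.synthetic_data import (
    generate_genome,
    plant_decoy,
    plant_gene,
    plant_on_target,
    random_spacer,
)


def _key(h: OffTargetHit):
    return (h.seq_name, h.strand, h.protospacer_start)


def _hitset(hits):
    return {(_key(h), h.mismatch_positions, h.effective_count) for h in hits}


class TestRuleSets:
    def test_cascade_and_cas9_share_the_machinery(self):
        cas = cascade_rule()
        cas9 = spcas9_rule()
        assert (cas.spacer_len, cas.pam_pattern, cas.pam_side) == (32, "CC", "5prime")
        assert set(cas.mask.masked) == {6, 12, 18} | set(range(24, 33))
        assert (cas9.spacer_len, cas9.pam_pattern, cas9.pam_side) == (20, "NGG", "3prime")
        assert cas9.mask.masked == frozenset()
        assert cas.max_mismatches == cas9.max_mismatches == 4

    def test_invalid_rule_parameters(self):
        with pytest.raises(ValueError):
            RuleSet("x", 32, "", "5prime", PositionMask.unmasked(32))
        with pytest.raises(ValueError):
            RuleSet("x", 32, "CC", "sideways", PositionMask.unmasked(32))


class TestEnumerate:
    def test_single_planted_site_exact_hit(self):
        ds = generate_genome(1, 5000, seed=1)
        q = random_spacer(ds.rng)
        plant_decoy(ds, q, [])
        hits = enumerate_offtargets(q, ds.genome(), cascade_rule())
        planted = [h for h in hits if h.effective_count == 0 and h.is_on_target]
        assert len(planted) == 1
        assert planted[0].mismatch_positions == ()

    def test_masked_only_decoy_scores_zero(self):
        ds = generate_genome(1, 5000, seed=2)
        q = random_spacer(ds.rng)
        t = plant_decoy(ds, q, [6, 12, 24, 25, 26])
        hits = enumerate_offtargets(q, ds.genome(), cascade_rule())
        match = [h for h in hits if _key(h) == (t.seq_name, t.strand, t.start)]
        assert len(match) == 1
        assert match[0].effective_count == 0
        assert match[0].mismatch_positions == (6, 12, 24, 25, 26)
        assert not match[0].is_on_target

    def test_five_seed_mismatches_absent(self):
        ds = generate_genome(1, 5000, seed=3)
        q = random_spacer(ds.rng)
        t = plant_decoy(ds, q, [1, 2, 3, 4, 5])
        hits = enumerate_offtargets(q, ds.genome(), cascade_rule())
        assert not any(_key(h) == (t.seq_name, t.strand, t.start) for h in hits)

    def test_query_length_and_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            enumerate_offtargets("ACGT", GenomeSequences({"c": "ACGT" * 20}), cascade_rule())
        with pytest.raises(ValueError):
            enumerate_offtargets("N" * 32, GenomeSequences({"c": "ACGT" * 20}), cascade_rule())

    def test_no_duplicate_hit_keys(self):
        ds = generate_genome(1, 10000, seed=4)
        q = random_spacer(ds.rng)
        for pos in ([], [6], [1]):
            plant_decoy(ds, q, pos)
        hits = enumerate_offtargets(q, ds.genome(), cascade_rule())
        keys = [_key(h) for h in hits]
        assert len(keys) == len(set(keys))

    def test_strand_symmetry(self):
        ds = generate_genome(1, 8000, seed=5)
        q = random_spacer(ds.rng)
        for pos in ([], [6, 12], [3]):
            plant_decoy(ds, q, pos)
        genome = ds.genome()
        n = len(genome["chr1"])
        flipped = GenomeSequences({"chr1": revcomp(genome["chr1"])})
        fwd = enumerate_offtargets(q, genome, cascade_rule())
        rev = enumerate_offtargets(q, flipped, cascade_rule())
        mapped = {
            (("chr1", "-" if h.strand == "+" else "+", n - h.protospacer_start - 32),
             h.mismatch_positions, h.effective_count)
            for h in rev
        }
        assert _hitset(fwd) == mapped

    def test_monotonicity_in_cap_and_mask(self):
        ds = generate_genome(1, 8000, seed=6)
        q = random_spacer(ds.rng)
        for pos in ([1], [1, 2], [1, 2, 3], [6, 12, 18]):
            plant_decoy(ds, q, pos)
        genome = ds.genome()
        lo = _hitset(enumerate_offtargets(q, genome, cascade_rule(max_mismatches=2)))
        hi = _hitset(enumerate_offtargets(q, genome, cascade_rule(max_mismatches=4)))
        assert lo <= hi
        small_mask = PositionMask(32, frozenset({6, 12}), frozenset())
        shrunk = enumerate_offtargets(q, genome, cascade_rule(mask=small_mask))
        # effective counts change with the mask; the set of matched loci may only shrink
        assert {(_key(h), h.mismatch_positions) for h in shrunk} <= {
            (_key(h), h.mismatch_positions) for h in enumerate_offtargets(q, genome, cascade_rule())
        }

    def test_pam_not_required_when_disabled(self):
        ds = generate_genome(1, 5000, seed=7)
        q = random_spacer(ds.rng)
        t = plant_decoy(ds, q, [6])
        genome = ds.genome()
        rule = cascade_rule()
        relaxed = RuleSet("relaxed", 32, "CC", "5prime", rule.mask, 4, require_pam_on_offtargets=False)
        strict_hits = _hitset(enumerate_offtargets(q, genome, rule))
        relaxed_hits = _hitset(enumerate_offtargets(q, genome, relaxed))
        assert strict_hits <= relaxed_hits


class TestOracleEquivalence:
    @pytest.mark.parametrize("rule_factory,qlen", [(cascade_rule, 32), (spcas9_rule, 20)])
    def test_enumerator_matches_oracle_with_planted_decoys(self, rule_factory, qlen):
        rule = rule_factory()
        for seed in range(10):
            ds = generate_genome(1, 2000, seed=seed)
            q = random_spacer(ds.rng, qlen)
            for pos in ([], [1, 2], [6, 12] if qlen == 32 else [5, 9]):
                plant_decoy(ds, q, pos, rule=rule)
            genome = ds.genome()
            assert enumerate_offtargets(q, genome, rule) == brute_force_oracle(q, genome, rule)

    def test_oracle_rejects_all_n_query(self):
        with pytest.raises(ValueError):
            brute_force_oracle("N" * 32, GenomeSequences({"c": "ACGT" * 20}), cascade_rule())


class TestPromoterFilter:
    def _hit(self, start, seq="chr1"):
        return OffTargetHit(seq, "+", start, "A" * 32, "CC", (), 0, False, start)

    def test_within_2kb_retained_beyond_removed(self):
        promoters = [PromoterInterval("g", "chr1", 8000, 12001, 10000)]
        near, far = self._hit(10000 - 1500), self._hit(10000 - 2500 - 31)
        kept = promoter_filter([near, far], promoters)
        assert [h.protospacer_start for h in kept] == [near.protospacer_start]
        assert kept[0].nearest_gene == "g"
        assert kept[0].tss_distance == -1500

    def test_equidistant_tie_broken_lexicographically(self):
        promoters = [
            PromoterInterval("b", "chr1", 0, 4001, 2000),
            PromoterInterval("a", "chr1", 2000, 6001, 4000),
        ]
        (hit,) = promoter_filter([self._hit(3000)], promoters)
        assert hit.nearest_gene == "a"

    def test_hit_on_other_sequence_dropped(self):
        promoters = [PromoterInterval("g", "chr1", 0, 4001, 2000)]
        assert promoter_filter([self._hit(2000, seq="chr2")], promoters) == []


class TestFindOverlapSites:
    def _engineered(self, with_decoys=True, with_overlap=True, seed=8):
        ds = generate_genome(1, 30000, seed=seed)
        target = plant_gene(ds, "chr1", 6000, "+", "geneA")
        other = plant_gene(ds, "chr1", 20000, "+", "geneB")
        rng = np.random.default_rng(seed + 50)
        spacer = random_spacer(rng)
        if with_overlap:
            # positions 21-23 of the protospacer form an NGG, so a 20-nt
            # Cas9 window (positions 1-20) overlaps the Cascade site
            spacer = spacer[:20] + "AGG" + spacer[23:]
        plant_on_target(ds, target, spacer, -150)
        cas9_spacer = spacer[:20]
        if with_decoys:
            plant_decoy(ds, spacer, [1, 2], near_gene=other, tss_offset=-300)
            plant_decoy(ds, cas9_spacer, [1, 2], near_gene=other, tss_offset=-600, rule=spcas9_rule())
        return ds

    def test_engineered_overlap_with_decoys_found(self):
        ds = self._engineered()
        regions = find_overlap_sites(ds.genome(), ds.tss_records, cascade_rule(), spcas9_rule())
        assert len(regions) >= 1
        r = regions[0]
        assert r.gene_id == "geneA"
        assert all(h.nearest_gene == "geneB" for h in r.cascade_offtargets)
        assert all(h.nearest_gene == "geneB" for h in r.cas9_offtargets)

    def test_without_decoys_no_region(self):
        ds = self._engineered(with_decoys=False)
        regions = find_overlap_sites(ds.genome(), ds.tss_records, cascade_rule(), spcas9_rule())
        assert regions == []


class TestReport:
    def _hits(self):
        ds = generate_genome(1, 5000, seed=9)
        q = random_spacer(ds.rng)
        plant_decoy(ds, q, [])
        plant_decoy(ds, q, [3, 6])
        return q, enumerate_offtargets(q, ds.genome(), cascade_rule())

    def test_tsv_rows_and_lowercase_mismatches(self, tmp_path):
        q, hits = self._hits()
        out = tmp_path / "hits.tsv"
        report(hits, out, "tsv")
        lines = out.read_text().splitlines()
        assert len(lines) == len(hits) + 1
        mism = next(h for h in hits if h.mismatch_positions)
        rendered = render_site(mism)
        assert [c.islower() for c in rendered] == [
            (i + 1) in mism.mismatch_positions for i in range(32)
        ]

    def test_bed_half_open_interval(self, tmp_path):
        _, hits = self._hits()
        out = tmp_path / "hits.bed"
        report(hits, out, "bed")
        for line, h in zip(out.read_text().splitlines(), hits):
            fields = line.split("\t")
            assert int(fields[2]) - int(fields[1]) == 32
            assert fields[5] == h.strand

    def test_rerun_byte_identical(self, tmp_path):
        _, hits = self._hits()
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        report(hits, a, "tsv")
        report(hits, b, "tsv")
        assert a.read_bytes() == b.read_bytes()
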