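"""Fragment conversion, coverage arithmetic, normalisation, aggregation
and read filtering."""

import numpy as np
import pandas as pd
import pytest

from dupdepth import (
    AnnotationSet,
    DomainAnnotation,
    GenomicInterval,
    Strategy,
    aggregate,
    copies_from_coverage,
    domain_coverage,
    estimate_genome_coverage,
    filter_reads,
    fit_gc_model,
    gene_copy_number,
    normalize_sample,
    reads_to_fragments,
)
from dupdepth.aligner import AlignmentRecord
from dupdepth.quantify import Fragment, binned_depth_and_gc, trim_low_quality_tail
from dupdepth.simulator import SimulatedRead


def _rec(rid, mate, start, end, strand="+", n_loci=1, chrom="chr1"):
    return AlignmentRecord(rid, GenomicInterval(chrom, start, end, strand), 0, n_loci, False, mate)


class TestReadsToFragments:
    def test_proper_pair_joined_to_span(self):
        recs = [_rec("p", 1, 100, 200), _rec("p", 2, 400, 500, "-")]
        [frag] = reads_to_fragments(recs, 350)
        assert (frag.interval.start, frag.interval.end) == (100, 500)
        assert frag.weight == 1.0

    def test_discordant_mate_extended_to_half_insert(self):
        recs = [_rec("d", 1, 1000, 1100), _rec("d", 2, 1000, 1100, chrom="chr2")]
        frags = reads_to_fragments(recs, 350)
        assert len(frags) == 2
        assert all(f.interval.length == 175 for f in frags)

    def test_extension_is_three_prime_directional(self):
        recs = [_rec("d", 1, 1000, 1100, "-"), _rec("d", 2, 5000, 5100, "+", chrom="chr2")]
        frags = reads_to_fragments(recs, 350)
        minus = next(f for f in frags if f.interval.strand == "-")
        assert (minus.interval.start, minus.interval.end) == (925, 1100)

    def test_single_end_reads_not_extended(self):
        recs = [_rec("s", 0, 1000, 1100)]
        [frag] = reads_to_fragments(recs, 350)
        assert frag.interval.length == 100

    def test_multi_locus_read_fractional_weights(self):
        recs = [_rec("m", 0, s, s + 100, n_loci=4) for s in (0, 1000, 2000, 3000)]
        frags = reads_to_fragments(recs, 350)
        assert len(frags) == 4
        assert all(f.weight == 0.25 for f in frags)

    def test_weight_conservation_under_ties(self):
        # 2x2 mate placements forming 2 proper combos: weights sum to 1
        recs = [
            _rec("t", 1, 100, 200), _rec("t", 1, 5000, 5100),
            _rec("t", 2, 400, 500, "-"), _rec("t", 2, 5300, 5400, "-"),
        ]
        frags = reads_to_fragments(recs, 350)
        assert len(frags) == 2
        assert sum(f.weight for f in frags) == pytest.approx(1.0)


class TestDomainCoverage:
    REGIONS = {"A": GenomicInterval("chr1", 1000, 2000)}

    def test_full_cover_weight_one_gives_1x(self):
        frags = [Fragment(GenomicInterval("chr1", 1000, 2000), 1.0)]
        cov = domain_coverage(frags, self.REGIONS)
        assert cov.loc["A", "coverage"] == 1.0

    def test_half_overlap_half_weight_adds_quarter(self):
        frags = [Fragment(GenomicInterval("chr1", 500, 1500), 0.5)]
        cov = domain_coverage(frags, self.REGIONS)
        assert cov.loc["A", "coverage"] == pytest.approx(0.25)

    def test_non_overlapping_fragment_ignored(self):
        frags = [Fragment(GenomicInterval("chr1", 100, 400), 1.0),
                 Fragment(GenomicInterval("chr2", 1000, 2000), 1.0)]
        cov = domain_coverage(frags, self.REGIONS)
        assert cov.loc["A", "coverage"] == 0.0


class TestCopiesFromCoverage:
    def test_division_by_expected_haploid(self):
        assert copies_from_coverage(15.0) == 1.0
        assert copies_from_coverage(45.0) == 3.0

    def test_frame_gets_copies_column(self):
        df = pd.DataFrame({"coverage": [30.0]}, index=["A"])
        out = copies_from_coverage(df)
        assert out.loc["A", "copies"] == 2.0

    def test_nonpositive_haploid_errors(self):
        with pytest.raises(ValueError):
            copies_from_coverage(10.0, expected_haploid=0)


class TestGCModel:
    def test_uniform_depth_factors_one(self):
        rng = np.random.default_rng(1)
        gc = rng.uniform(0.3, 0.6, 200)
        model = fit_gc_model(np.full(200, 30.0), gc)
        assert model.factor(0.45) == pytest.approx(1.0, abs=1e-6)

    def test_depth_above_mean_gets_reciprocal_factor(self):
        # bins at GC 0.6 run at 2x the 0.4-GC depth: factor = mean/fitted
        gc = np.concatenate([np.full(80, 0.4), np.full(80, 0.5), np.full(80, 0.6)])
        depth = np.concatenate([np.full(80, 20.0), np.full(80, 30.0), np.full(80, 40.0)])
        model = fit_gc_model(depth, gc, frac=0.3)
        assert model.factor(0.6) == pytest.approx(30.0 / 40.0, rel=0.05)
        assert model.factor(0.4) == pytest.approx(30.0 / 20.0, rel=0.05)

    def test_sinusoidal_bias_flattened(self):
        # a wiggly bias needs a short loess span to be captured
        rng = np.random.default_rng(2)
        gc = rng.uniform(0.3, 0.7, 400)
        depth = 30.0 * (1 + 0.5 * np.sin(8 * gc)) + rng.normal(0, 0.5, 400)
        model = fit_gc_model(depth, gc, frac=0.15)
        corrected = depth * model.factor(gc)
        r = np.corrcoef(gc, corrected)[0, 1]
        assert abs(r) < 0.1

    def test_degenerate_gc_range_identity_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            model = fit_gc_model(np.full(60, 30.0), np.full(60, 0.5))
        assert model.identity and model.factor(0.2) == 1.0

    def test_binned_depth_and_gc(self):
        ref = {"c": "G" * 1000 + "A" * 1000}
        frags = [Fragment(GenomicInterval("c", 0, 1000), 1.0)]
        df = binned_depth_and_gc(frags, ref, bin_width=1000)
        assert list(df["gc"]) == [1.0, 0.0]
        assert list(df["depth"]) == [1.0, 0.0]


class TestNormalizeSample:
    def test_background_normalisation(self):
        df = pd.DataFrame({"coverage": [60.0, 30.0]}, index=["roi", "bglike"])
        out = normalize_sample(df, background_mean=30.0)
        assert out.loc["roi", "normalized"] == 2.0
        assert out.loc["roi", "copies"] == 4.0
        assert out.loc["bglike", "normalized"] == pytest.approx(1.0)

    def test_zero_background_errors(self):
        df = pd.DataFrame({"coverage": [60.0]}, index=["roi"])
        with pytest.raises(ValueError, match="zero mean"):
            normalize_sample(df, background_mean=0.0)


def _ann(units):
    doms = []
    for i, (gene, clade) in enumerate(units):
        iv = GenomicInterval("chr1", 1000 * (i + 1), 1000 * (i + 1) + 500)
        doms.append(DomainAnnotation(gene=gene, clade=clade, index=1,
                                     exon_long=iv, quant_region=iv))
    from dupdepth import name_domains

    return name_domains(AnnotationSet(doms))


class TestAggregate:
    def test_conservation_across_levels(self):
        ann = _ann([("G1", "CON1"), ("G1", "CON1"), ("G2", "CON1"), ("G2", "HLS1")])
        copies = {d.name: c for d, c in zip(ann.domains, (1.0, 2.0, 3.0, 4.0))}
        table = aggregate(copies, ann)
        total = sum(copies.values())
        for level in ("domain", "gene-clade", "group-clade", "clade"):
            assert table[table.level == level]["copies"].sum() == pytest.approx(total)

    def test_group_sums_members(self):
        from dupdepth import GeneGroupSet

        ann = _ann([("G1", "CON1"), ("G2", "CON1"), ("G3", "CON1")])
        groups = GeneGroupSet({"CON1": {"G1": "G1+G2", "G2": "G1+G2", "G3": "G3"}})
        copies = {d.name: 2.0 for d in ann.domains}
        table = aggregate(copies, ann, groups)
        gc = table[table.level == "group-clade"].set_index("unit")["copies"]
        assert gc["G1+G2:CON1"] == 4.0 and gc["G3:CON1"] == 2.0

    def test_single_gene_group_equals_gene_value(self):
        ann = _ann([("G1", "CON1"), ("G1", "CON1")])
        table = aggregate({d.name: 1.5 for d in ann.domains}, ann)
        gene = table[table.level == "gene-clade"]["copies"].iloc[0]
        group = table[table.level == "group-clade"]["copies"].iloc[0]
        assert gene == group == 3.0

    def test_missing_group_errors(self):
        from dupdepth import GeneGroupSet

        ann = _ann([("G1", "CON1")])
        groups = GeneGroupSet({"CON1": {"OTHER": "OTHER"}})
        with pytest.raises(ValueError, match="no group"):
            aggregate({d.name: 1.0 for d in ann.domains}, ann, groups)

    def test_align_all_clade_normalisation(self):
        ann = _ann([("G1", "CON1"), ("G2", "CON1")])
        copies = {d.name: 2.0 for d in ann.domains}
        table = aggregate(copies, ann, strategy=Strategy.ALL_CROP36)
        clade = table[(table.level == "clade")].set_index("unit")["copies"]
        assert clade["CON1"] == pytest.approx(2.0)  # 4 total / 2 reference domains


class TestGeneCopyNumber:
    def test_background_depth_means_two_copies(self):
        frags = [Fragment(GenomicInterval("chr1", 0, 10_000), 1.0) for _ in range(30)]
        regions = {"G": [GenomicInterval("chr1", 2000, 3000)]}
        out = gene_copy_number(frags, regions, background_mean=30.0)
        assert out.loc["G", "copies"] == pytest.approx(2.0)

    def test_gene_without_unique_region_unmeasurable(self):
        out = gene_copy_number([], {"G": []}, background_mean=30.0)
        assert not out.loc["G", "measurable"]
        assert np.isnan(out.loc["G", "copies"])


class TestFilterReads:
    def _read(self, name, quals, mate=0, length=None):
        L = length or len(quals)
        seq = "A" * L
        qual = "".join(chr(33 + q) for q in quals)
        return SimulatedRead(name, seq, qual, mate)

    def test_trailing_low_quality_trimmed_then_dropped(self):
        r = self._read("r", [40] * 70 + [5] * 30)
        kept, stats = filter_reads([r])
        assert kept == [] and stats["n_dropped"] == 1

    def test_high_quality_read_unchanged(self):
        r = self._read("r", [40] * 100)
        kept, stats = filter_reads([r])
        assert kept[0].seq == r.seq and stats["n_trimmed"] == 0

    def test_trim_keeps_read_at_or_above_80(self):
        r = self._read("r", [40] * 85 + [5] * 15)
        kept, _ = filter_reads([r])
        assert len(kept) == 1 and len(kept[0].seq) == 85

    def test_pair_dropped_together(self):
        r1 = self._read("p", [40] * 100, mate=1)
        r2 = self._read("p", [40] * 50 + [5] * 50, mate=2)
        kept, stats = filter_reads([r1, r2])
        assert kept == [] and stats["n_dropped"] == 2

    def test_internal_low_quality_not_trimmed(self):
        r = self._read("r", [40] * 40 + [5] * 10 + [40] * 50)
        kept, _ = filter_reads([r])
        assert len(kept[0].seq) == 100

    def test_trim_helper_exact(self):
        r = self._read("r", [30, 30, 9, 8])
        assert len(trim_low_quality_tail(r).seq) == 2


class TestGenomeCoverage:
    def test_identity_case(self):
        cov, flagged = estimate_genome_coverage(1000, 350, 350_000)
        assert cov == pytest.approx(1.0) and flagged

    def test_low_coverage_flagged_for_removal(self):
        cov, flagged = estimate_genome_coverage(95_000_000, 100, 1_000_000_000)
        assert cov == pytest.approx(9.5) and flagged

    def test_adequate_coverage_not_flagged(self):
        cov, flagged = estimate_genome_coverage(150_000_000, 100, 1_000_000_000)
        assert cov == pytest.approx(15.0) and not flagged

    def test_nonpositive_inputs_error(self):
        with pytest.raises(ValueError):
            estimate_genome_coverage(0, 350, 1000)
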