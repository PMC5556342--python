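"""Ambiguity matrices, gene grouping, unique regions and RMSE."""

import numpy as np
import pandas as pd
import pytest

from dupdepth import (
    AnnotationSet,
    DomainAnnotation,
    GeneGroupSet,
    GenomicInterval,
    OracleAligner,
    SimSpec,
    Strategy,
    ambiguity_matrix,
    derive_groups,
    find_unique_regions,
    off_target,
    oracle_align,
    rmse,
    simulate_spike_in,
)
from dupdepth.aligner import AlignmentRecord
from dupdepth.ambiguity import AmbiguityMatrix, gene_unique_regions, unit_of


def _random_seq(n, seed):
    r = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[r.integers(0, 4, n)])


def _matrix(level, entries, units):
    mat = pd.DataFrame(0.0, index=units, columns=units)
    for (i, j), v in entries.items():
        mat.loc[i, j] = v
    return AmbiguityMatrix(level, mat, pd.Series(1.0, index=units))


@pytest.fixture(scope="module")
def twin_truth():
    """Two identical domains (duplicated with 800 bp of flanking context,
    so every overlapping fragment is ambiguous) plus one unique domain."""
    from dupdepth.fixtures import TruthSet

    segment = _random_seq(800 + 600 + 800, 9)  # flank + domain + flank
    uniq_seq = _random_seq(600, 10)
    spacer = lambda s: _random_seq(2000, s)
    seq = spacer(1) + segment + spacer(2) + segment + spacer(3) + uniq_seq + spacer(4)
    starts = [
        2000 + 800,
        2000 + 2200 + 2000 + 800,
        2000 + 2200 + 2000 + 2200 + 2000,
    ]
    doms = []
    for gene, s in zip(("GA", "GB", "GC"), starts):
        iv = GenomicInterval("chrZ", s, s + 600)
        doms.append(DomainAnnotation(gene=gene, clade="CON1", index=1,
                                     exon_long=iv, quant_region=iv))
    return TruthSet({"chrZ": seq}, AnnotationSet(doms), {d.name: 2 for d in doms})


class TestAmbiguityMatrix:
    def _simulate(self, truth, strategy, seed=3):
        oracle = OracleAligner(truth.reference)
        rng = np.random.default_rng(seed)
        recs = []
        for d in truth.annotations:
            reads = simulate_spike_in(d, truth.reference, SimSpec(copies=2), rng)
            recs += oracle_align(reads, oracle, strategy, seed=seed)
        return recs

    def test_unique_domain_diagonal_near_100(self, twin_truth):
        recs = self._simulate(twin_truth, Strategy.BEST)
        m = ambiguity_matrix(recs, twin_truth.annotations, "domain")
        assert m.percent.loc["GC_CON1_1", "GC_CON1_1"] > 99.0

    def test_identical_twins_split_50_50(self, twin_truth):
        recs = self._simulate(twin_truth, Strategy.BEST)
        m = ambiguity_matrix(recs, twin_truth.annotations, "domain")
        row = m.percent.loc["GA_CON1_1"]
        # symmetric ambiguity: binomial split around 50/50
        n = m.row_weights["GA_CON1_1"]
        se_pct = 100 * np.sqrt(0.25 / n)
        assert abs(row["GA_CON1_1"] - 50) < 4 * se_pct
        assert abs(row["GB_CON1_1"] - 50) < 4 * se_pct

    def test_best_ties_twins_exactly_half_weight(self, twin_truth):
        recs = self._simulate(twin_truth, Strategy.BEST_TIES)
        m = ambiguity_matrix(recs, twin_truth.annotations, "domain")
        row = m.percent.loc["GA_CON1_1"]
        # multi-read correction assigns exactly half a unit per side, so
        # the two columns are identical; a rare unmapped mate (a read
        # drawing 3+ errors) can shave both slightly below 50
        assert row["GA_CON1_1"] == pytest.approx(row["GB_CON1_1"], abs=1e-9)
        assert 47.0 < row["GA_CON1_1"] <= 50.0 + 1e-9

    def test_row_sums_at_most_100(self, twin_truth):
        recs = self._simulate(twin_truth, Strategy.BEST)
        for level in ("domain", "gene-clade", "clade"):
            m = ambiguity_matrix(recs, twin_truth.annotations, level)
            assert (m.percent.sum(axis=1) <= 100.0 + 1e-9).all()

    def test_no_reads_from_source_flagged_empty(self, twin_truth):
        oracle = OracleAligner(twin_truth.reference)
        d = twin_truth.annotations.domains[2]
        reads = simulate_spike_in(d, twin_truth.reference, SimSpec(copies=2),
                                  np.random.default_rng(0))
        recs = oracle_align(reads, oracle, Strategy.BEST, seed=0)
        m = ambiguity_matrix(recs, twin_truth.annotations, "domain")
        assert set(m.empty_sources) == {"GA_CON1_1", "GB_CON1_1"}

    def test_untagged_read_errors(self, twin_truth):
        rec = AlignmentRecord("plainname", GenomicInterval("chrZ", 0, 100), 0)
        with pytest.raises(ValueError):
            ambiguity_matrix([rec], twin_truth.annotations, "domain")


class TestOffTarget:
    def test_diagonal_matrix_zero_everywhere(self):
        m = _matrix("domain", {("A", "A"): 100.0, ("B", "B"): 100.0}, ["A", "B"])
        ot = off_target(m)
        assert (ot["off_target_pct"] == 0).all()

    def test_90_percent_on_target_gives_10(self):
        m = _matrix("domain", {("A", "A"): 90.0, ("A", "B"): 10.0, ("B", "B"): 100.0},
                    ["A", "B"])
        ot = off_target(m).set_index("unit")
        assert ot.loc["A", "off_target_pct"] == pytest.approx(10.0)

    def test_clade_summary_read_weighted(self):
        m = _matrix("domain", {("A", "A"): 90.0, ("B", "B"): 100.0}, ["A", "B"])
        m.row_weights["A"] = 300.0
        m.row_weights["B"] = 100.0
        ot = off_target(m, clade_of={"A": "CON1", "B": "CON1"})
        clade = ot[ot.scope == "clade"].iloc[0]
        assert clade["off_target_pct"] == pytest.approx((10 * 300 + 0 * 100) / 400)


class TestDeriveGroups:
    def _units(self, genes, clade="CON1"):
        return [f"{g}:{clade}" for g in genes]

    def test_zero_sharing_every_gene_alone(self):
        units = self._units(["A", "B", "C"])
        m = _matrix("gene-clade", {(u, u): 100.0 for u in units}, units)
        groups = derive_groups(m, 5.0)
        assert len(set(groups.groups["CON1"].values())) == 3

    def test_chain_sharing_one_component(self):
        units = self._units(["A", "B", "C"])
        m = _matrix("gene-clade", {
            (u, u): 80.0 for u in units
        } | {("A:CON1", "B:CON1"): 10.0, ("B:CON1", "C:CON1"): 10.0}, units)
        groups = derive_groups(m, 5.0)
        assert groups.group_of("A", "CON1") == groups.group_of("C", "CON1") == "A+B+C"

    def test_invariant_to_gene_ordering(self):
        units = self._units(["A", "B", "C"])
        entries = {(u, u): 80.0 for u in units}
        entries[("A:CON1", "C:CON1")] = 20.0
        m1 = _matrix("gene-clade", entries, units)
        m2 = _matrix("gene-clade", entries, list(reversed(units)))
        assert derive_groups(m1, 5.0).groups == derive_groups(m2, 5.0).groups

    def test_highly_similar_genes_grouped_by_simulation(self, twin_truth):
        oracle = OracleAligner(twin_truth.reference)
        rng = np.random.default_rng(4)
        recs = []
        for d in twin_truth.annotations:
            reads = simulate_spike_in(d, twin_truth.reference, SimSpec(copies=2), rng)
            recs += oracle_align(reads, oracle, Strategy.BEST, seed=4)
        m = ambiguity_matrix(recs, twin_truth.annotations, "gene-clade")
        groups = derive_groups(m, 5.0)
        assert groups.group_of("GA", "CON1") == groups.group_of("GB", "CON1") == "GA+GB"
        assert groups.group_of("GC", "CON1") == "GC"

    def test_wrong_level_rejected(self):
        m = _matrix("domain", {("A", "A"): 100.0}, ["A"])
        with pytest.raises(ValueError, match="gene-clade"):
            derive_groups(m)

    def test_tsv_shape(self):
        groups = GeneGroupSet({"CON1": {"A": "A+B", "B": "A+B"}})
        tsv = groups.to_tsv()
        assert tsv.splitlines()[0] == "clade\tgroup\tgene"
        assert len(tsv.strip().splitlines()) == 3


class TestUniqueRegions:
    def test_single_copy_chromosome_fully_unique(self):
        ref = {"c": _random_seq(2000, 30)}
        regions = find_unique_regions(ref, read_length=100, stride=20)
        assert len(regions["c"]) == 1
        iv = regions["c"][0]
        assert iv.start == 0 and iv.end >= 1900

    def test_exact_duplication_excluded_both_copies(self):
        base = _random_seq(3000, 31)
        dup = base[500:700]
        ref = {"c": base + dup + _random_seq(500, 32)}
        regions = find_unique_regions(ref["c"] and ref, read_length=100, stride=10)
        for iv in regions["c"]:
            # no unique interval may contain a read fully inside either copy
            for s, e in ((500, 700), (3000, 3200)):
                assert not (iv.start <= s and e <= iv.end and e - s >= 100)

    def test_one_mismatch_diverged_duplication_still_excluded(self):
        base = _random_seq(2500, 33)
        block = list(base[500:700])
        block[100] = {"A": "C", "C": "G", "G": "T", "T": "A"}[block[100]]
        ref = {"c": base + "".join(block) + _random_seq(400, 34)}
        regions = find_unique_regions(ref, read_length=100, max_mismatches=1, stride=5)
        starts_in_block = [
            p for p in range(520, 581, 5)
        ]  # reads fully inside the first copy
        for iv in regions["c"]:
            for p in starts_in_block:
                assert not (iv.start <= p and p + 100 <= iv.end)

    def test_gene_unique_regions_margin_subtracts_flanks(self):
        unique = {"c": [GenomicInterval("c", 0, 10_000)]}
        windows = {"G": GenomicInterval("c", 1000, 9000)}
        exclusions = [GenomicInterval("c", 4000, 5000)]
        out = gene_unique_regions(unique, windows, exclusions, margin=500)
        spans = [(iv.start, iv.end) for iv in out["G"]]
        assert spans == [(1000, 3500), (5500, 9000)]


class TestRmse:
    def test_perfect_measurement_zero(self):
        assert rmse({"a": 2.0, "b": 4.0}, {"a": 2.0, "b": 4.0}) == 0.0

    def test_three_four_five(self):
        assert rmse({"a": 3.0, "b": 4.0}, {"a": 0.0, "b": 0.0}) == pytest.approx(5.0)

    def test_mean_variant(self):
        assert rmse({"a": 3.0, "b": 4.0}, {"a": 0.0, "b": 0.0}, mean=True) == \
            pytest.approx(np.sqrt(12.5))

    def test_mismatched_units_error(self):
        with pytest.raises(ValueError, match="unit sets"):
            rmse({"a": 1.0}, {"b": 1.0})


class TestUnitOf:
    def test_levels(self):
        d = DomainAnnotation(gene="G1", clade="CON1", index=2,
                             exon_long=GenomicInterval("c", 0, 100))
        assert unit_of(d, "domain") == "G1_CON1_2"
        assert unit_of(d, "gene-clade") == "G1:CON1"
        assert unit_of(d, "clade") == "CON1"
        groups = GeneGroupSet({"CON1": {"G1": "G1+G2"}})
        assert unit_of(d, "group-clade", groups) == "G1+G2:CON1"
        with pytest.raises(ValueError):
            unit_of(d, "nope")
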