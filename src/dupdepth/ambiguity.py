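"""Read-alignment ambiguity, gene grouping, unique regions and evaluation.

Truth-tagged alignments are summarised as source x target percentage
matrices at four resolution levels (domain, gene-clade, group-clade,
clade).  Genes whose domains share reads above a threshold are merged
into groups (connected components of the sharing graph, per clade) —
the grouping that trades a little resolution for much lower error.
Spike-in experiments across read lengths, library types and alignment
strategies are scored by RMSE against the known copy numbers and by
percent off-target alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .aligner import AlignmentRecord, OracleAligner, Strategy, oracle_align
from .intervals import GenomicInterval, merge_intervals, subtract_intervals
from .quantify import domain_coverage, reads_to_fragments
from .simulator import InsertModel, SimSpec, TruthTag, simulate_spike_in

LEVELS = ("domain", "gene-clade", "group-clade", "clade")


@dataclass
class GeneGroupSet:
    """Per-clade partition of genes into read-sharing groups."""

    groups: dict[str, dict[str, str]]  # clade -> gene -> group name
    threshold: float = 5.0

    def group_of(self, gene: str, clade: str) -> str | None:
        return self.groups.get(clade, {}).get(gene)

    def members(self, clade: str, group: str) -> list[str]:
        return sorted(g for g, grp in self.groups.get(clade, {}).items() if grp == group)

    @classmethod
    def trivial(cls, annotations) -> "GeneGroupSet":
        """Every gene its own group, for every clade present."""
        groups: dict[str, dict[str, str]] = {}
        for d in annotations:
            groups.setdefault(d.clade, {})[d.gene] = d.gene
        return cls(groups, threshold=0.0)

    def to_tsv(self) -> str:
        lines = ["clade\tgroup\tgene"]
        for clade in sorted(self.groups):
            for gene in sorted(self.groups[clade]):
                lines.append(f"{clade}\t{self.groups[clade][gene]}\t{gene}")
        return "\n".join(lines) + "\n"


def unit_of(domain, level: str, groups: GeneGroupSet | None = None) -> str:
    """Measurement unit of a domain at a resolution level."""
    if level == "domain":
        return domain.name
    if level == "gene-clade":
        return f"{domain.gene}:{domain.clade}"
    if level == "group-clade":
        grp = groups.group_of(domain.gene, domain.clade) if groups else domain.gene
        if grp is None:
            raise ValueError(f"gene {domain.gene} has no group for clade {domain.clade}")
        return f"{grp}:{domain.clade}"
    if level == "clade":
        return domain.clade
    raise ValueError(f"unknown level {level!r}")


@dataclass
class AmbiguityMatrix:
    """Percentage of (weighted) reads from each source unit landing on
    each target unit; rows may sum below 100 (unaligned or off-annotation
    landings are excluded from the columns but kept in the denominator)."""

    level: str
    percent: pd.DataFrame            # index = source unit, columns = target unit
    row_weights: pd.Series           # aligned read-units per source
    empty_sources: list[str] = field(default_factory=list)

    def to_long(self) -> pd.DataFrame:
        long = self.percent.stack().rename("percent").reset_index()
        long.columns = ["source", "target", "percent"]
        return long


def ambiguity_matrix(
    records: list[AlignmentRecord],
    annotations,
    level: str = "domain",
    groups: GeneGroupSet | None = None,
    sample_mean_insert: float = 350.0,
) -> AmbiguityMatrix:
    """Build the source x target ambiguity matrix from truth-tagged
    alignments; multi-locus reads contribute 1/n_loci per landing.

    Alignments are first joined into fragments (proper pairs become one
    unit), so a mate protruding past the domain edge does not count as
    an off-target landing; a fragment lands on the region it overlaps
    most.
    """
    frags = reads_to_fragments(records, sample_mean_insert)
    regions = annotations.quant_regions()
    by_name = annotations.by_name()
    # sorted region arrays per chromosome for target lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in {iv.chrom for iv in regions.values()}:
        sub = sorted(
            ((n, iv) for n, iv in regions.items() if iv.chrom == chrom),
            key=lambda t: t[1].start,
        )
        by_chrom[chrom] = (
            np.array([iv.start for _, iv in sub]),
            np.array([iv.end for _, iv in sub]),
            [n for n, _ in sub],
        )

    def target_domain(iv: GenomicInterval) -> str | None:
        entry = by_chrom.get(iv.chrom)
        if entry is None:
            return None
        starts, ends, names = entry
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        best, best_ov = None, 0
        for i in range(lo, hi):
            ov = min(ends[i], iv.end) - max(starts[i], iv.start)
            if ov > best_ov:
                best, best_ov = names[i], ov
        return best

    landed: dict[tuple[str, str], float] = {}
    denom: dict[str, float] = {}
    for f in frags:
        tag = TruthTag.decode(f.read_id)  # raises on untagged reads
        src_dom = by_name.get(tag.domain)
        if src_dom is None:
            raise ValueError(f"truth tag names unknown domain {tag.domain!r}")
        src = unit_of(src_dom, level, groups)
        denom[src] = denom.get(src, 0.0) + f.weight
        tgt_name = target_domain(f.interval)
        if tgt_name is not None:
            tgt = unit_of(by_name[tgt_name], level, groups)
            landed[(src, tgt)] = landed.get((src, tgt), 0.0) + f.weight

    all_units = sorted({unit_of(d, level, groups) for d in annotations})
    mat = pd.DataFrame(0.0, index=all_units, columns=all_units)
    weights = pd.Series(0.0, index=all_units)
    for src, w in denom.items():
        weights[src] = w
    for (src, tgt), w in landed.items():
        if tgt in mat.columns:
            mat.loc[src, tgt] = 100.0 * w / denom[src]
    empty = [u for u in all_units if weights[u] == 0]
    return AmbiguityMatrix(level, mat, weights, empty)


def off_target(matrix: AmbiguityMatrix, clade_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Off-target percentage per source unit (100 minus on-target), with
    read-weighted per-clade summaries appended when ``clade_of`` maps
    source units to clades."""
    rows = []
    for src in matrix.percent.index:
        on = float(matrix.percent.loc[src, src]) if src in matrix.percent.columns else 0.0
        rows.append({"unit": src, "scope": "source", "off_target_pct": 100.0 - on,
                     "weight": float(matrix.row_weights[src])})
    df = pd.DataFrame(rows)
    if clade_of:
        summaries = []
        for clade in sorted(set(clade_of.values())):
            sub = df[[clade_of.get(u) == clade for u in df["unit"]]]
            w = sub["weight"].to_numpy()
            if w.sum() == 0:
                continue
            pct = float(np.average(sub["off_target_pct"], weights=w))
            summaries.append({"unit": clade, "scope": "clade",
                              "off_target_pct": pct, "weight": float(w.sum())})
        df = pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)
    return df


def derive_groups(
    gene_clade_matrix: AmbiguityMatrix, threshold: float = 5.0
) -> GeneGroupSet:
    """Group genes whose same-clade units share at least ``threshold``
    percent of reads (either direction); groups are connected components,
    computed independently per clade.  Invariant to gene ordering."""
    if gene_clade_matrix.level != "gene-clade":
        raise ValueError("derive_groups needs a gene-clade level matrix")
    mat = gene_clade_matrix.percent
    per_clade: dict[str, nx.Graph] = {}
    for unit in mat.index:
        gene, clade = unit.rsplit(":", 1)
        per_clade.setdefault(clade, nx.Graph()).add_node(gene)
    for src in mat.index:
        g1, c1 = src.rsplit(":", 1)
        for tgt in mat.columns:
            g2, c2 = tgt.rsplit(":", 1)
            if c1 != c2 or g1 == g2:
                continue
            if mat.loc[src, tgt] >= threshold or mat.loc[tgt, src] >= threshold:
                per_clade[c1].add_edge(g1, g2)
    groups: dict[str, dict[str, str]] = {}
    for clade, graph in per_clade.items():
        groups[clade] = {}
        for comp in nx.connected_components(graph):
            name = "+".join(sorted(comp))
            for gene in comp:
                groups[clade][gene] = name
    return GeneGroupSet(groups, threshold)


def find_unique_regions(
    reference: dict[str, str],
    read_length: int = 100,
    max_mismatches: int = 1,
    stride: int = 1,
    oracle: OracleAligner | None = None,
) -> dict[str, list[GenomicInterval]]:
    """Maximal intervals from which every read maps back uniquely within
    the mismatch cap (tiled read starts at the given stride)."""
    oracle = oracle or OracleAligner(reference)
    out: dict[str, list[GenomicInterval]] = {}
    for chrom, seq in reference.items():
        unique_starts = []
        for p in range(0, len(seq) - read_length + 1, stride):
            read = seq[p : p + read_length]
            placements = oracle.align(read, max_mismatches)
            if len(placements) == 1:
                unique_starts.append(p)
        intervals = []
        for p in unique_starts:
            intervals.append(GenomicInterval(chrom, p, p + read_length))
        out[chrom] = merge_intervals(intervals)
    return out


def gene_unique_regions(
    unique: dict[str, list[GenomicInterval]],
    gene_windows: dict[str, GenomicInterval],
    exclusions: list[GenomicInterval],
    margin: int = 0,
) -> dict[str, list[GenomicInterval]]:
    """Intersect genome-wide unique regions with per-gene windows and
    subtract coding-domain portions and flagged UTR exons.

    ``margin`` widens each exclusion on both sides — set it to about one
    fragment length so that reads straddling a domain boundary (whose
    depth tracks the domain's copy number, not the gene's) cannot leak
    into the gene-level estimate.
    """
    if margin:
        exclusions = [
            GenomicInterval(iv.chrom, max(0, iv.start - margin), iv.end + margin, iv.strand)
            for iv in exclusions
        ]
    out: dict[str, list[GenomicInterval]] = {}
    for gene, window in gene_windows.items():
        within = []
        for iv in unique.get(window.chrom, []):
            ov = iv.overlap(window)
            if ov > 0:
                within.append(
                    GenomicInterval(window.chrom, max(iv.start, window.start),
                                    min(iv.end, window.end))
                )
        out[gene] = subtract_intervals(within, exclusions)
    return out


def rmse(
    measured: dict[str, float] | pd.Series,
    expected: dict[str, float] | pd.Series,
    mean: bool = False,
) -> float:
    """Root of the summed squared copy errors (``mean=True`` averages the
    squared errors before the root instead of summing them)."""
    m = pd.Series(measured)
    e = pd.Series(expected)
    if set(m.index) != set(e.index):
        raise ValueError("measured and expected unit sets differ")
    sq = ((m - e.reindex(m.index)) ** 2).to_numpy()
    return float(np.sqrt(sq.mean() if mean else sq.sum()))


# --------------------------------------------------------------------------
# Spike-in evaluation (read length / strategy comparison)
# --------------------------------------------------------------------------

def _subseed(*parts) -> int:
    import zlib

    return zlib.crc32("|".join(str(p) for p in parts).encode()) % (2**31)


def spike_in_experiment(
    reference: dict[str, str],
    annotations,
    read_lengths: tuple[int, ...] = (36, 100, 150, 300),
    paired_modes: tuple[bool, ...] = (False, True),
    copies: tuple[int, ...] = tuple(range(1, 11)),
    replicates: int = 1,
    strategies: tuple[Strategy, ...] = (Strategy.BEST,),
    haploid_coverage: float = 15.0,
    seed: int = 0,
    groups: GeneGroupSet | None = None,
    insert: InsertModel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the spike-in grid and score it.

    For every strategy x read length x library type, each canonical
    domain is simulated at each copy count, aligned, and quantified; the
    measured copies of the domain's unit at each level are compared with
    the spiked value (the relative-ratio convention: a domain losing a
    constant fraction of reads off target scales linearly in copies).

    Returns ``(evaluation, off_target_summary)`` frames: RMSE (summed and
    mean variants) per configuration, level and clade; and per-clade
    off-target percentages per configuration and level.
    """
    insert = insert or InsertModel()
    oracle = OracleAligner(reference)
    canon = annotations.canonical()
    regions = canon.quant_regions()
    by_name = canon.by_name()
    groups = groups or GeneGroupSet.trivial(canon)
    eval_rows = []
    ot_rows = []
    for strategy in strategies:
        for L in read_lengths:
            for paired in paired_modes:
                errors: dict[str, list[tuple[str, float]]] = {lv: [] for lv in LEVELS}
                all_records: list[AlignmentRecord] = []
                for rep in range(replicates):
                    for d in canon:
                        for c in copies:
                            s = _subseed(seed, strategy.value, L, paired, rep, d.name, c)
                            rng = np.random.default_rng(s)
                            spec = SimSpec(
                                read_length=L, paired=paired, copies=c,
                                haploid_coverage=haploid_coverage, insert=insert,
                            )
                            reads = simulate_spike_in(d, reference, spec, rng)
                            recs = oracle_align(reads, oracle, strategy, seed=s)
                            all_records.extend(recs)
                            frags = reads_to_fragments(recs, insert.mean)
                            cov = domain_coverage(frags, regions)
                            dom_copies = cov["coverage"] / haploid_coverage
                            for level in LEVELS:
                                unit = unit_of(d, level, groups)
                                measured = sum(
                                    dom_copies[n]
                                    for n in dom_copies.index
                                    if unit_of(by_name[n], level, groups) == unit
                                )
                                errors[level].append((d.clade, measured - c))
                for level in LEVELS:
                    clades = sorted({cl for cl, _ in errors[level]})
                    for scope in ["total"] + clades:
                        errs = np.array(
                            [e for cl, e in errors[level] if scope in ("total", cl)]
                        )
                        eval_rows.append(
                            {
                                "strategy": strategy.value,
                                "read_length": L,
                                "paired": paired,
                                "level": level,
                                "clade": scope,
                                "rmse": float(np.sqrt((errs**2).sum())),
                                "rmse_mean": float(np.sqrt((errs**2).mean())),
                                "n": len(errs),
                            }
                        )
                    matrix = ambiguity_matrix(all_records, canon, level, groups)
                    clade_of = {
                        unit_of(d, level, groups): d.clade for d in canon
                    }
                    ot = off_target(matrix, clade_of)
                    for _, row in ot[ot["scope"] == "clade"].iterrows():
                        ot_rows.append(
                            {
                                "strategy": strategy.value,
                                "read_length": L,
                                "paired": paired,
                                "level": level,
                                "clade": row["unit"],
                                "off_target_pct": row["off_target_pct"],
                            }
                        )
    return pd.DataFrame(eval_rows), pd.DataFrame(ot_rows)
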