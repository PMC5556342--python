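"""Coverage-based copy-number quantification.

Alignments become weighted genomic fragments (proper pairs joined into a
single fragment; discordant mates treated as single-end and extended to
half the sample mean insert size; every fragment weighted by 1/n_loci
for multi-read correction).  Fragment base-overlap with each domain's
quantification region, divided by region length, gives coverage; copies
are coverage over the expected haploid coverage (15x in simulations,
half the background mean in real samples).  Real samples are further
normalised by conserved single-copy background regions and a GC
correction fitted on 1 kb bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aligner import AlignmentRecord, Strategy, proper_combos
from .intervals import GenomicInterval
from .simulator import SimulatedRead

EXPECTED_HAPLOID = 15.0


@dataclass(frozen=True)
class Fragment:
    """A weighted genomic fragment contributing to coverage."""

    interval: GenomicInterval
    weight: float
    read_id: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 1:
            raise ValueError("fragment weight must be in (0, 1]")


def _extend_three_prime(iv: GenomicInterval, target_len: int) -> GenomicInterval:
    if iv.length >= target_len:
        return iv
    if iv.strand == "-":
        return GenomicInterval(iv.chrom, max(0, iv.end - target_len), iv.end, "-")
    return GenomicInterval(iv.chrom, iv.start, iv.start + target_len, "+")


def reads_to_fragments(
    records: list[AlignmentRecord],
    sample_mean_insert: float = 350.0,
    max_insert: int = 800,
) -> list[Fragment]:
    """Convert alignment records to weighted fragments.

    Proper mate combinations are joined into fragments spanning the
    outermost coordinates (weight 1/#combinations).  Mates of discordant
    pairs are kept as single-end reads extended 3'-ward to half the
    sample mean insert size, weight 1/n_loci.  Reads from single-end
    libraries keep their own length (extension is a paired-library
    correction for the missing mate).
    """
    half_insert = int(round(sample_mean_insert / 2))
    by_id: dict[str, dict[int, list[AlignmentRecord]]] = {}
    order: list[str] = []
    for r in records:
        if r.read_id not in by_id:
            order.append(r.read_id)
        by_id.setdefault(r.read_id, {}).setdefault(r.mate, []).append(r)
    frags: list[Fragment] = []
    for rid in order:
        mates = by_id[rid]
        if 1 in mates and 2 in mates:
            combos = proper_combos(mates[1], mates[2], max_insert)
            if combos:
                w = 1.0 / len(combos)
                for a, b in combos:
                    frags.append(Fragment(a.placement.span(b.placement), w, rid))
                continue
            for recs in (mates[1], mates[2]):
                for r in recs:
                    frags.append(
                        Fragment(_extend_three_prime(r.placement, half_insert),
                                 1.0 / r.n_loci, rid)
                    )
            continue
        for mate, recs in mates.items():
            for r in recs:
                iv = r.placement
                if mate in (1, 2):  # orphaned mate of a paired library
                    iv = _extend_three_prime(iv, half_insert)
                frags.append(Fragment(iv, 1.0 / r.n_loci, rid))
    return frags


def domain_coverage(
    fragments: list[Fragment],
    regions: dict[str, GenomicInterval],
) -> pd.DataFrame:
    """Weighted base-overlap coverage of each (disjoint) region.

    Returns a frame indexed by unit name with columns ``covered_bases``
    (sum over fragments of overlap x weight), ``length``, ``coverage``
    and ``n_fragments`` (weighted count of overlapping fragments).
    """
    names = list(regions)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in {iv.chrom for iv in regions.values()}:
        sub = [(n, iv) for n, iv in regions.items() if iv.chrom == chrom]
        sub.sort(key=lambda t: t[1].start)
        starts = np.array([iv.start for _, iv in sub])
        ends = np.array([iv.end for _, iv in sub])
        by_chrom[chrom] = (starts, ends, [n for n, _ in sub])
    covered = {n: 0.0 for n in names}
    nfrag = {n: 0.0 for n in names}
    for f in fragments:
        entry = by_chrom.get(f.interval.chrom)
        if entry is None:
            continue
        starts, ends, sub_names = entry
        lo = int(np.searchsorted(ends, f.interval.start, side="right"))
        hi = int(np.searchsorted(starts, f.interval.end, side="left"))
        for i in range(lo, hi):
            ov = min(ends[i], f.interval.end) - max(starts[i], f.interval.start)
            if ov > 0:
                covered[sub_names[i]] += ov * f.weight
                nfrag[sub_names[i]] += f.weight
    df = pd.DataFrame(
        {
            "unit": names,
            "covered_bases": [covered[n] for n in names],
            "length": [regions[n].length for n in names],
            "n_fragments": [nfrag[n] for n in names],
        }
    ).set_index("unit")
    df["coverage"] = df["covered_bases"] / df["length"]
    return df


def copies_from_coverage(
    coverage: pd.DataFrame | float,
    expected_haploid: float = EXPECTED_HAPLOID,
) -> pd.DataFrame | float:
    """Copies = coverage / expected haploid coverage (15x in simulations).

    Accepts either a coverage frame (a ``copies`` column is added) or a
    bare coverage value.  The additional per-clade normalisation of the
    align-all strategies is applied at aggregation time (see
    :func:`aggregate`).
    """
    if expected_haploid <= 0:
        raise ValueError("expected_haploid must be > 0")
    if isinstance(coverage, pd.DataFrame):
        out = coverage.copy()
        out["copies"] = out["coverage"] / expected_haploid
        return out
    return coverage / expected_haploid


# --------------------------------------------------------------------------
# GC correction and background normalisation
# --------------------------------------------------------------------------

@dataclass
class GCModel:
    """Multiplicative depth-correction factors as a function of %GC.

    ``factor(gc)`` equals global mean depth over the loess-fitted depth
    at that GC, so multiplying observed depth by the factor flattens the
    GC trend; the factor is ~1 where depth matches the genome mean.
    """

    gc_grid: np.ndarray
    fitted_depth: np.ndarray
    global_mean: float
    identity: bool = False

    def factor(self, gc: float | np.ndarray) -> float | np.ndarray:
        if self.identity:
            return np.ones_like(np.asarray(gc, dtype=float)) if np.ndim(gc) else 1.0
        fitted = np.interp(gc, self.gc_grid, self.fitted_depth)
        return self.global_mean / fitted


def fit_gc_model(
    depths: np.ndarray, gc: np.ndarray, frac: float = 0.5
) -> GCModel:
    """Fit the GC-bias model on binned depth (1 kb windows) vs %GC.

    A loess curve of depth against GC defines the correction factor per
    GC value.  A degenerate GC range (fewer than 3 distinct values)
    yields an identity model with a warning.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    depths = np.asarray(depths, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if len(depths) != len(gc) or len(depths) < 10:
        raise ValueError("need >= 10 depth/GC bins of equal length")
    mean = float(depths.mean())
    if len(np.unique(np.round(gc, 6))) < 3:
        warnings.warn("degenerate GC range; returning identity GC model")
        return GCModel(np.array([0.0, 1.0]), np.array([mean, mean]), mean, identity=True)
    sm = lowess(depths, gc, frac=frac)
    grid, fitted = sm[:, 0], np.maximum(sm[:, 1], 1e-9 + 0.0)
    # collapse duplicate grid points for interp
    grid, idx = np.unique(grid, return_index=True)
    return GCModel(grid, fitted[idx], mean)


def gc_content(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    return (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0


def binned_depth_and_gc(
    fragments: list[Fragment],
    reference: dict[str, str],
    bin_width: int = 1000,
) -> pd.DataFrame:
    """Weighted read depth and %GC per genome bin (default 1 kb)."""
    rows = []
    for chrom, seq in reference.items():
        n_bins = len(seq) // bin_width
        depth = np.zeros(n_bins)
        for f in fragments:
            if f.interval.chrom != chrom:
                continue
            lo = max(0, f.interval.start) // bin_width
            hi = min(len(seq) - 1, f.interval.end - 1) // bin_width
            for b in range(lo, min(hi, n_bins - 1) + 1):
                bs, be = b * bin_width, (b + 1) * bin_width
                ov = min(be, f.interval.end) - max(bs, f.interval.start)
                depth[b] += max(0, ov) * f.weight / bin_width
        for b in range(n_bins):
            rows.append(
                {
                    "chrom": chrom,
                    "start": b * bin_width,
                    "depth": depth[b],
                    "gc": gc_content(seq[b * bin_width : (b + 1) * bin_width]),
                }
            )
    return pd.DataFrame(rows)


def normalize_sample(
    coverage: pd.DataFrame,
    background_mean: float,
    gc_model: GCModel | None = None,
    region_gc: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Normalise region coverage by the conserved-background mean depth
    and the region's GC factor; diploid copies = 2 x normalised value."""
    if background_mean <= 0:
        raise ValueError("background regions have zero mean coverage")
    out = coverage.copy()
    factors = np.ones(len(out))
    if gc_model is not None and region_gc is not None:
        factors = np.array([gc_model.factor(region_gc.get(u, 0.5)) for u in out.index])
    out["normalized"] = out["coverage"] / background_mean * factors
    out["copies"] = 2.0 * out["normalized"]
    return out


# --------------------------------------------------------------------------
# Aggregation to the four measurement levels
# --------------------------------------------------------------------------

LEVELS = ("domain", "gene-clade", "group-clade", "clade", "gene")


def aggregate(
    domain_copies: dict[str, float] | pd.Series,
    annotations,
    groups=None,
    strategy: Strategy | None = None,
) -> pd.DataFrame:
    """Sum domain-level copies up to gene-clade, group-clade and clade
    levels (conservation is exact by construction).

    ``groups`` is a :class:`~dupdepth.ambiguity.GeneGroupSet`; without
    one, every gene forms its own group.  Under the align-all strategies
    the clade totals are additionally divided by the clade's haploid
    reference domain count.
    """
    if isinstance(domain_copies, pd.Series):
        domain_copies = domain_copies.to_dict()
    by_name = annotations.by_name()
    rows = []
    gene_clade: dict[tuple[str, str], float] = {}
    group_clade: dict[tuple[str, str], float] = {}
    clade_tot: dict[str, float] = {}
    for name, copies in domain_copies.items():
        d = by_name[name]
        rows.append({"level": "domain", "unit": name, "copies": copies})
        gene_clade[(d.gene, d.clade)] = gene_clade.get((d.gene, d.clade), 0.0) + copies
        if groups is not None:
            grp = groups.group_of(d.gene, d.clade)
            if grp is None:
                raise ValueError(f"domain {name}: gene {d.gene} has no group for {d.clade}")
        else:
            grp = d.gene
        group_clade[(grp, d.clade)] = group_clade.get((grp, d.clade), 0.0) + copies
        clade_tot[d.clade] = clade_tot.get(d.clade, 0.0) + copies
    for (gene, clade), v in gene_clade.items():
        rows.append({"level": "gene-clade", "unit": f"{gene}:{clade}", "copies": v})
    for (grp, clade), v in group_clade.items():
        rows.append({"level": "group-clade", "unit": f"{grp}:{clade}", "copies": v})
    norm: dict[str, int] = {}
    if strategy in (Strategy.ALL_CROP36, Strategy.ALL_FULL):
        for clade, doms in annotations.clades.items():
            norm[clade] = len(doms)
    for clade, v in clade_tot.items():
        if clade in norm:
            v = v / norm[clade]
        rows.append({"level": "clade", "unit": clade, "copies": v})
    return pd.DataFrame(rows)


def gene_copy_number(
    fragments: list[Fragment],
    unique_regions: dict[str, list[GenomicInterval]],
    background_mean: float,
    gc_model: GCModel | None = None,
    region_gc_of=None,
) -> pd.DataFrame:
    """Diploid gene copy number from unique (single-copy) regions.

    Per gene, the length-weighted mean normalised depth across its
    unique regions, doubled.  Genes with no unique bases are flagged
    unmeasurable (copies NaN).
    """
    if background_mean <= 0:
        raise ValueError("background regions have zero mean coverage")
    rows = []
    for gene, regs in unique_regions.items():
        total_len = sum(iv.length for iv in regs)
        if total_len == 0:
            rows.append({"gene": gene, "copies": np.nan, "measurable": False,
                         "unique_bases": 0})
            continue
        named = {f"{gene}.{i}": iv for i, iv in enumerate(regs)}
        cov = domain_coverage(fragments, named)
        weighted = 0.0
        for key, iv in named.items():
            norm = cov.loc[key, "coverage"] / background_mean
            if gc_model is not None and region_gc_of is not None:
                norm *= gc_model.factor(region_gc_of(iv))
            weighted += norm * iv.length
        rows.append(
            {
                "gene": gene,
                "copies": 2.0 * weighted / total_len,
                "measurable": True,
                "unique_bases": total_len,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


# --------------------------------------------------------------------------
# Read filtering and sample-level coverage (real-data preprocessing)
# --------------------------------------------------------------------------

def trim_low_quality_tail(read: SimulatedRead, qual_threshold: int = 10) -> SimulatedRead:
    """Strip 3' bases whose Phred quality is below the threshold."""
    quals = [ord(c) - 33 for c in read.qual]
    end = len(quals)
    while end > 0 and quals[end - 1] < qual_threshold:
        end -= 1
    if end == len(quals):
        return read
    return SimulatedRead(read.name, read.seq[:end], read.qual[:end], read.mate)


def filter_reads(
    reads: list[SimulatedRead],
    qual_threshold: int = 10,
    min_length: int = 80,
) -> tuple[list[SimulatedRead], dict]:
    """Quality-trim 3' ends (Phred < 10) and drop reads trimmed shorter
    than 80 bases; a dropped mate drops its pair as well."""
    trimmed = [trim_low_quality_tail(r, qual_threshold) for r in reads]
    bad_names = {r.name for r in trimmed if len(r.seq) < min_length and r.mate in (1, 2)}
    kept = [
        r for r in trimmed
        if len(r.seq) >= min_length and r.name not in bad_names
    ]
    stats = {
        "n_input": len(reads),
        "n_kept": len(kept),
        "n_dropped": len(reads) - len(kept),
        "n_trimmed": sum(1 for r, t in zip(reads, trimmed) if len(t.seq) < len(r.seq)),
    }
    return kept, stats


def estimate_genome_coverage(
    n_filtered_reads: int, insert: float, genome_size: int, min_coverage: float = 10.0
) -> tuple[float, bool]:
    """Sample coverage = filtered reads x insert size / genome size.

    Returns ``(coverage, remove)`` where ``remove`` flags samples below
    the 10x cutoff.
    """
    if n_filtered_reads <= 0 or insert <= 0 or genome_size <= 0:
        raise ValueError("all inputs must be positive")
    cov = n_filtered_reads * insert / genome_size
    return cov, cov < min_coverage
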