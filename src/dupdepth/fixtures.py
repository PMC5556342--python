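"""Synthetic reference genomes with controlled duplication structure.

Every other module is testable without a real genome: these generators
build genomes containing gene families whose domains have tunable
within- and between-gene sequence divergence (emulating the clade
structure of a highly duplicated domain family), plus worked-example
and copy-number-variant scenarios with exactly known truth.

Divergence is substitution-only and uniform across sites — enough to
reproduce read-ambiguity phenomena without modelling indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .annotation import AnnotationSet, DomainAnnotation
from .intervals import GenomicInterval, subtract_intervals
from .simulator import SimSpec, SimulatedRead, simulate_spike_in

BASES = np.array(list("ACGT"))


@dataclass
class FamilySpec:
    """Parameters of a synthetic duplicated-domain family.

    ``divergence_within`` is the target pairwise divergence between
    domains of the same clade within one gene; ``divergence_between``
    between genes (substitutions per bp).  The hierarchical construction
    (clade ancestor -> gene variant -> domain copy) requires
    ``divergence_within <= divergence_between``.
    """

    n_genes: int = 6
    clades: tuple[str, ...] = ("CON1", "CON2", "CON3", "HLS1", "HLS2", "HLS3")
    domains_per_clade: int = 1
    divergence_within: float = 0.02
    divergence_between: float = 0.05
    domain_length: int = 1000
    short_exon_length: int = 80
    intra_gene_spacer: int = 300
    intergenic_length: int = 300_000
    seed: int = 2017
    chrom: str = "chrT"

    def __post_init__(self) -> None:
        for d in (self.divergence_within, self.divergence_between):
            if not 0 <= d <= 0.5:
                raise ValueError("divergence must be in [0, 0.5]")
        if self.divergence_within > self.divergence_between:
            raise ValueError(
                "infeasible divergence triangle: within-gene divergence "
                "exceeds between-gene divergence"
            )
        if self.domain_length < 350:
            raise ValueError("domain length must exceed the longest read")


@dataclass
class TruthSet:
    """A synthetic genome with its annotation and known copy numbers."""

    reference: dict[str, str]
    annotations: AnnotationSet
    true_copies: dict[str, int]  # domain name -> diploid copies
    background_regions: list[GenomicInterval] = field(default_factory=list)

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "genome.fa"), "w") as fh:
            for chrom, seq in self.reference.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(os.path.join(outdir, "domains.bed"), "w") as fh:
            fh.write(self.annotations.to_bed())
        with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
            fh.write("domain\tdiploid_copies\n")
            for name, c in self.true_copies.items():
                fh.write(f"{name}\t{c}\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute exactly round(rate * len) distinct positions."""
    n = int(round(rate * len(seq)))
    if n == 0:
        return seq
    pos = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for p in pos:
        alts = [b for b in "ACGT" if b != out[p]]
        out[p] = alts[rng.integers(3)]
    return "".join(out)


def pairwise_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("sequences must be equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def make_toy_genome(spec: FamilySpec | None = None) -> TruthSet:
    """Build a genome of ``n_genes`` genes, each carrying
    ``domains_per_clade`` domains of every clade, at the requested
    divergences.  Deterministic under ``spec.seed``."""
    spec = spec or FamilySpec()
    rng = np.random.default_rng(spec.seed)
    ancestors = {c: _random_seq(rng, spec.domain_length) for c in spec.clades}
    parts: list[str] = []
    domains: list[DomainAnnotation] = []
    pos = 0

    def emit(seq: str) -> None:
        nonlocal pos
        parts.append(seq)
        pos += len(seq)

    emit(_random_seq(rng, spec.intergenic_length))
    for g in range(spec.n_genes):
        gene = f"GENE{g + 1}"
        for clade in spec.clades:
            gene_variant = _mutate(ancestors[clade], spec.divergence_between / 2, rng)
            for idx in range(1, spec.domains_per_clade + 1):
                dom_seq = _mutate(gene_variant, spec.divergence_within / 2, rng)
                start = pos
                emit(dom_seq)
                iv_short = GenomicInterval(spec.chrom, start, start + spec.short_exon_length)
                iv_long = GenomicInterval(
                    spec.chrom, start + spec.short_exon_length, start + spec.domain_length
                )
                quant = GenomicInterval(spec.chrom, start, start + spec.domain_length)
                domains.append(
                    DomainAnnotation(
                        gene=gene, clade=clade, index=idx,
                        exon_long=iv_long, exon_short=iv_short, quant_region=quant,
                    )
                )
                emit(_random_seq(rng, spec.intra_gene_spacer))
        emit(_random_seq(rng, spec.intergenic_length))
    reference = {spec.chrom: "".join(parts)}
    annotations = AnnotationSet(domains)
    true_copies = {d.name: 2 for d in domains}
    # intergenic background windows (single copy by construction): the
    # leading and trailing intergenic blocks, trimmed away from the genes
    margin = min(500, spec.intergenic_length // 4)
    bg = [
        GenomicInterval(spec.chrom, margin, spec.intergenic_length - margin),
        GenomicInterval(spec.chrom, pos - spec.intergenic_length + margin, pos - margin),
    ]
    return TruthSet(reference, annotations, true_copies, bg)


def make_confusable_genome(
    n_pairs: int = 2,
    pairwise_sites: int = 5,
    domain_length: int = 700,
    intergenic_length: int = 2500,
    seed: int = 41,
    chrom: str = "chrC",
) -> TruthSet:
    """Genome of domain pairs that are confusable *across* genes and
    clades: each pair shares an ancestor, the two copies differing at
    exactly ``pairwise_sites`` positions, but they sit in different
    genes and carry different clade labels.

    This emulates cross-clade sequence similarity (the situation in
    which one clade's reads inflate another's estimate), so alignment
    ambiguity produces copy-number error at *every* aggregation level —
    the regime in which read length and pairing visibly matter.
    """
    clade_cycle = ("CON1", "HLS1", "CON2", "HLS2", "CON3", "HLS3")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    domains: list[DomainAnnotation] = []
    pos = 0

    def emit(seq: str) -> None:
        nonlocal pos
        parts.append(seq)
        pos += len(seq)

    emit(_random_seq(rng, intergenic_length))
    for i in range(n_pairs):
        ancestor = _random_seq(rng, domain_length)
        variant = _mutate(ancestor, pairwise_sites / domain_length, rng)
        for j, (dom_seq, clade) in enumerate(
            ((ancestor, clade_cycle[(2 * i) % 6]), (variant, clade_cycle[(2 * i + 1) % 6]))
        ):
            gene = f"GENE{2 * i + j + 1}"
            start = pos
            emit(dom_seq)
            domains.append(
                DomainAnnotation(
                    gene=gene, clade=clade, index=1,
                    exon_short=GenomicInterval(chrom, start, start + 80),
                    exon_long=GenomicInterval(chrom, start + 80, start + domain_length),
                    quant_region=GenomicInterval(chrom, start, start + domain_length),
                )
            )
            emit(_random_seq(rng, intergenic_length))
    reference = {chrom: "".join(parts)}
    return TruthSet(reference, AnnotationSet(domains), {d.name: 2 for d in domains})


# --------------------------------------------------------------------------
# Worked example: the constant-10%-off-target domain
# --------------------------------------------------------------------------

WORKED_DOMAIN_LENGTH = 1000
WORKED_READ_LENGTH = 100


def make_worked_example(genome_seed: int = 97) -> tuple[TruthSet, SimSpec]:
    """Scenario in which a constant 10% of a domain's reads align off
    target, so measured copies are 0.9x the simulated copies.

    A block of the focal domain is duplicated exactly once elsewhere in
    the genome.  Reads falling entirely inside the block have two
    equally good placements and are lost to the decoy half the time (or
    carry half weight under multi-read correction); reads touching the
    block boundary are anchored by flanking sequence and map uniquely.
    For single-end reads of length L over a domain of length D, the
    expected fraction of read-bases lost is (d - L + 1) / (2 D) for a
    block of d bp, so d = 0.2 D + L - 1 makes it exactly 10%.
    """
    D, L = WORKED_DOMAIN_LENGTH, WORKED_READ_LENGTH
    d = int(0.2 * D) + L - 1  # 299 bp for D=1000, L=100
    rng = np.random.default_rng(genome_seed)
    pre = _random_seq(rng, 2000)
    domain_seq = _random_seq(rng, D)
    mid = _random_seq(rng, 1500)
    post = _random_seq(rng, 3000)
    block = domain_seq[350 : 350 + d]
    seq = pre + domain_seq + mid + block + post
    chrom = "chrW"
    dom_start = len(pre)
    quant = GenomicInterval(chrom, dom_start, dom_start + D)
    domain = DomainAnnotation(
        gene="FOCAL", clade="HLS1", index=1,
        exon_short=GenomicInterval(chrom, dom_start, dom_start + 80),
        exon_long=GenomicInterval(chrom, dom_start + 80, dom_start + D),
        quant_region=quant,
    )
    truth = TruthSet({chrom: seq}, AnnotationSet([domain]), {domain.name: 2})
    spec = SimSpec(read_length=L, paired=False, haploid_coverage=15.0, copies=1)
    return truth, spec


def measure_worked_example(
    truth: TruthSet,
    spec: SimSpec,
    copies: int,
    seed: int,
    strategy=None,
) -> float:
    """Simulate the focal domain at ``copies`` copies, align with the
    oracle BEST strategy and return the measured copy number."""
    from .aligner import OracleAligner, Strategy, oracle_align
    from .quantify import domain_coverage, reads_to_fragments

    strategy = strategy or Strategy.BEST
    spec = dc_replace(spec, copies=copies)
    rng = np.random.default_rng(seed)
    domain = truth.annotations.domains[0]
    reads = simulate_spike_in(domain, truth.reference, spec, rng)
    records = oracle_align(reads, OracleAligner(truth.reference), strategy, seed=seed)
    frags = reads_to_fragments(records, spec.insert.mean)
    cov = domain_coverage(frags, truth.annotations.quant_regions())
    return float(cov.loc[domain.name, "coverage"] / spec.haploid_coverage)


# --------------------------------------------------------------------------
# Copy-number-variant samples
# --------------------------------------------------------------------------

def make_cnv_sample(
    truth: TruthSet,
    events: list[tuple[str, int]],
    spec: SimSpec,
    rng: np.random.Generator,
) -> tuple[list[SimulatedRead], dict[str, int]]:
    """Simulate a whole-genome sample with duplication/deletion events.

    ``events`` are ``(unit, new_diploid_copies)`` pairs where unit is a
    domain name or a gene symbol (a gene event rescales every domain of
    the gene).  Copy-number states are emulated by scaling read counts:
    event regions are sampled at the event's copy count, everything else
    at the diploid baseline of 2.
    """
    by_name = truth.annotations.by_name()
    genes = truth.annotations.genes
    event_regions: list[tuple[GenomicInterval, int, str]] = []
    new_truth = dict(truth.true_copies)
    for unit, n in events:
        if n < 0:
            raise ValueError(f"negative copy count for {unit}")
        if unit in by_name:
            doms = [by_name[unit]]
        elif unit in genes:
            doms = genes[unit]
        else:
            raise ValueError(f"event unit {unit!r} is neither a domain nor a gene")
        for d in doms:
            event_regions.append((d.quant_region or d.exon_span, n, d.name))
            new_truth[d.name] = n
    reads: list[SimulatedRead] = []
    for region, n, name in event_regions:
        if n == 0:
            continue
        sub = dc_replace(spec, copies=n)
        reads.extend(
            simulate_spike_in(
                DomainAnnotation(
                    gene=name, clade="EVT", index=1, exon_long=region, quant_region=region
                ),
                truth.reference, sub, rng,
            )
        )
    # diploid background over the rest of the genome; a one-fragment
    # margin around each event keeps background fragments from bleeding
    # depth across the event boundary (the event region itself already
    # samples every fragment overlapping it)
    pad = int(spec.mean_fragment)
    for chrom, seq in truth.reference.items():
        whole = [GenomicInterval(chrom, 0, len(seq))]
        padded = [
            GenomicInterval(r.chrom, max(0, r.start - pad), r.end + pad)
            for r, _, _ in event_regions
            if r.chrom == chrom
        ]
        rest = subtract_intervals(whole, padded)
        for iv in rest:
            if iv.length < spec.read_length:
                continue
            sub = dc_replace(spec, copies=2)
            reads.extend(
                simulate_spike_in(
                    DomainAnnotation(
                        gene=f"bg:{chrom}:{iv.start}", clade="BG", index=1,
                        exon_long=iv, quant_region=iv,
                    ),
                    truth.reference, sub, rng,
                )
            )
    return reads, new_truth
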