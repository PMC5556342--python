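"""Reference model for a duplicated domain family.

Builds the annotation that the rest of the pipeline quantifies against:
profile-HMM hits on the genome are parsed, each hit (the long exon of a
domain) is paired with the short exon that precedes it, domains are
assigned to sequence-similarity clades by diagnostic protein motifs,
named ``GENE_CLADE_INDEX``, and merged into per-domain quantification
regions with optional boundary extension into unique flanking sequence.

Clades follow the domain-family convention: CON1-3 (conserved across
primates), HLS1-3 (human lineage specific), CON4-8 (non-canonical),
plus HYBRID (short exon of one clade, long exon of another) and
UNASSIGNED.  Only the six canonical clades are quantified by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .intervals import GenomicInterval

CANONICAL_CLADES = ("CON1", "CON2", "CON3", "HLS1", "HLS2", "HLS3")
NONCANONICAL_CLADES = ("CON4", "CON5", "CON6", "CON7", "CON8")
HYBRID = "HYBRID"
UNASSIGNED = "UNASSIGNED"
ALL_CLADES = CANONICAL_CLADES + NONCANONICAL_CLADES + (HYBRID, UNASSIGNED)

SHORT_EXON_MIN = 50
SHORT_EXON_MAX = 111


@dataclass(frozen=True)
class DomainHit:
    """A profile-HMM hit on the genome (already 0-based half-open)."""

    target: GenomicInterval
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")


@dataclass
class DomainAnnotation:
    """One domain: paired exons, clade, name, quantification region."""

    gene: str
    clade: str = UNASSIGNED
    index: int = 0
    exon_long: GenomicInterval | None = None
    exon_short: GenomicInterval | None = None
    quant_region: GenomicInterval | None = None
    short_exon_missing: bool = False

    @property
    def name(self) -> str:
        return f"{self.gene}_{self.clade}_{self.index}"

    @property
    def chrom(self) -> str:
        return self.exon_long.chrom

    @property
    def exon_span(self) -> GenomicInterval:
        """Smallest interval covering both exons (long exon alone if unpaired)."""
        if self.exon_short is None:
            return self.exon_long
        return self.exon_long.span(self.exon_short)

    @property
    def is_canonical(self) -> bool:
        return self.clade in CANONICAL_CLADES


class AnnotationSet:
    """Ordered collection of :class:`DomainAnnotation` with lookups by gene/clade."""

    def __init__(self, domains: list[DomainAnnotation]):
        self.domains = sorted(
            domains, key=lambda d: (d.exon_long.chrom, d.exon_long.start)
        )

    def __len__(self) -> int:
        return len(self.domains)

    def __iter__(self):
        return iter(self.domains)

    @property
    def genes(self) -> dict[str, list[DomainAnnotation]]:
        out: dict[str, list[DomainAnnotation]] = {}
        for d in self.domains:
            out.setdefault(d.gene, []).append(d)
        return out

    @property
    def clades(self) -> dict[str, list[DomainAnnotation]]:
        out: dict[str, list[DomainAnnotation]] = {}
        for d in self.domains:
            out.setdefault(d.clade, []).append(d)
        return out

    def by_name(self) -> dict[str, DomainAnnotation]:
        out = {}
        for d in self.domains:
            if d.name in out:
                raise ValueError(f"duplicate domain name {d.name}")
            out[d.name] = d
        return out

    def canonical(self, include_all: bool = False) -> "AnnotationSet":
        """Domains used for quantification.

        CON4-8, HYBRID and UNASSIGNED domains are annotated but excluded
        unless ``include_all`` is set.
        """
        if include_all:
            return self
        return AnnotationSet([d for d in self.domains if d.is_canonical])

    def quant_regions(self) -> dict[str, GenomicInterval]:
        return {d.name: d.quant_region or d.exon_span for d in self.domains}

    # --- BED I/O (BED6, name = GENE_CLADE_INDEX, score = 0) -----------------

    def to_bed(self) -> str:
        lines = []
        for d in self.domains:
            q = d.quant_region or d.exon_span
            lines.append(
                f"{q.chrom}\t{q.start}\t{q.end}\t{d.name}\t0\t{d.exon_long.strand}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_bed(cls, text: str) -> "AnnotationSet":
        domains = []
        for ln, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"BED line {ln}: need >= 4 columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            parts = name.rsplit("_", 2)
            if len(parts) != 3:
                raise ValueError(f"BED line {ln}: name {name!r} is not GENE_CLADE_INDEX")
            gene, clade, idx = parts
            iv = GenomicInterval(chrom, start, end, strand)
            domains.append(
                DomainAnnotation(
                    gene=gene, clade=clade, index=int(idx),
                    exon_long=iv, quant_region=iv,
                )
            )
        return cls(domains)


@dataclass
class CladeMotifTable:
    """Diagnostic amino-acid motifs per clade.

    ``short_motifs``/``long_motifs`` map clade -> exact peptide substrings
    expected in the short/long exon translation.  ``max_mismatches`` allows
    approximate matching (default 0, exact).
    """

    short_motifs: dict[str, list[str]] = field(default_factory=dict)
    long_motifs: dict[str, list[str]] = field(default_factory=dict)
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        for clade, motifs in list(self.short_motifs.items()) + list(
            self.long_motifs.items()
        ):
            if not motifs or any(not m for m in motifs):
                raise ValueError(f"empty motif for clade {clade}")

    def _matches(self, seq: str, motif: str) -> bool:
        if self.max_mismatches == 0:
            return motif in seq
        L = len(motif)
        for i in range(len(seq) - L + 1):
            mm = sum(1 for a, b in zip(seq[i : i + L], motif) if a != b)
            if mm <= self.max_mismatches:
                return True
        return False

    def match_clades(self, seq: str, exon: str) -> list[str]:
        """Clades whose ``exon`` ('short'|'long') motifs occur in ``seq``."""
        table = self.short_motifs if exon == "short" else self.long_motifs
        return [c for c, motifs in table.items() if any(self._matches(seq, m) for m in motifs)]

    def to_tsv(self) -> str:
        lines = ["clade\texon\tmotif"]
        for table, exon in ((self.short_motifs, "short"), (self.long_motifs, "long")):
            for clade, motifs in table.items():
                for m in motifs:
                    lines.append(f"{clade}\t{exon}\t{m}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, max_mismatches: int = 0) -> "CladeMotifTable":
        short: dict[str, list[str]] = {}
        long: dict[str, list[str]] = {}
        for ln, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.startswith("clade\t"):
                continue
            f = line.split("\t")
            if len(f) != 3:
                raise ValueError(f"motif TSV line {ln}: need 3 columns")
            clade, exon, motif = f
            (short if exon == "short" else long).setdefault(clade, []).append(motif)
        return cls(short, long, max_mismatches)


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def parse_domain_hits(
    domtbl_text: str,
    max_evalue: float = 1e-10,
    valid_chroms: set[str] | None = None,
) -> list[DomainHit]:
    """Parse HMMER domtblout text into position-sorted :class:`DomainHit` records.

    Hits with independent E-value >= ``max_evalue`` are dropped (the
    annotation threshold is 1e-10).  HMMER alignment coordinates are
    1-based inclusive and may be reversed on the minus strand; they are
    converted to 0-based half-open intervals here and nowhere else.
    """
    if max_evalue <= 0:
        raise ValueError("max_evalue must be > 0")
    hits = []
    for ln, line in enumerate(domtbl_text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 22:
            raise ValueError(f"domtblout line {ln}: expected >= 22 fields, got {len(f)}")
        chrom = f[0]
        if valid_chroms is not None and chrom not in valid_chroms:
            raise ValueError(f"domtblout line {ln}: unknown sequence name {chrom!r}")
        try:
            evalue = float(f[12])  # independent E-value of this domain
            score = float(f[13])
            ali_from, ali_to = int(f[17]), int(f[18])
        except ValueError as exc:
            raise ValueError(f"domtblout line {ln}: malformed numeric field") from exc
        strand = "+"
        if ali_from > ali_to:
            ali_from, ali_to = ali_to, ali_from
            strand = "-"
        target = GenomicInterval(chrom, ali_from - 1, ali_to, strand)
        if evalue < max_evalue:
            hits.append(DomainHit(target=target, evalue=evalue, score=score))
    hits.sort(key=lambda h: (h.target.chrom, h.target.start))
    return hits


def pair_exons(
    hit: DomainHit, gene_exons: list[GenomicInterval], gene: str = ""
) -> DomainAnnotation:
    """Pair a long-exon hit with the short exon that precedes it.

    The HMM search finds only the long exon of each domain; the short
    (50-111 bp) exon immediately preceding it in transcription order
    encodes the domain N-terminus.  ``gene_exons`` must be sorted in
    transcription order (5'->3'; for minus-strand genes that is
    descending genomic coordinate).
    """
    containing = None
    idx = None
    for i, ex in enumerate(gene_exons):
        if ex.contains(hit.target):
            containing, idx = ex, i
            break
    if containing is None:
        raise ValueError(f"hit {hit.target} is not contained in any exon")
    short = None
    prev = gene_exons[idx - 1] if idx > 0 else None
    if prev is not None and SHORT_EXON_MIN <= prev.length <= SHORT_EXON_MAX:
        short = prev
    missing = short is None
    return DomainAnnotation(
        gene=gene,
        exon_long=containing,
        exon_short=short,
        short_exon_missing=missing,
    )


def assign_clade(
    long_seq: str,
    motifs: CladeMotifTable,
    short_seq: str | None = None,
) -> str:
    """Assign a domain's clade from its exon peptide sequence(s).

    A unique motif match gives that clade; a short-exon motif of one
    clade combined with a long-exon motif of a different clade gives
    HYBRID; no match gives UNASSIGNED.  Multiple motif matches within
    the same exon are a hard error (ambiguous motif table).
    """
    if not long_seq:
        raise ValueError("empty sequence")
    long_hits = motifs.match_clades(long_seq, "long")
    if len(long_hits) > 1:
        raise ValueError(f"conflicting long-exon motif matches: {sorted(long_hits)}")
    if short_seq is None:
        # single concatenated sequence: also scan short motifs over it
        short_hits = motifs.match_clades(long_seq, "short")
    else:
        short_hits = motifs.match_clades(short_seq, "short") if short_seq else []
    if len(short_hits) > 1:
        raise ValueError(f"conflicting short-exon motif matches: {sorted(short_hits)}")
    long_clade = long_hits[0] if long_hits else None
    short_clade = short_hits[0] if short_hits else None
    if long_clade and short_clade and long_clade != short_clade:
        return HYBRID
    return long_clade or short_clade or UNASSIGNED


def name_domains(annotations: AnnotationSet) -> AnnotationSet:
    """Number domains 1..n per (gene, clade) in genomic order and set names.

    Numbering is independent per clade within a gene (interleaved clades
    each count from 1).  Idempotent; raises on duplicate resulting names.
    """
    counters: dict[tuple[str, str], int] = {}
    renamed = []
    for d in annotations.domains:  # already genomic order
        key = (d.gene, d.clade)
        counters[key] = counters.get(key, 0) + 1
        renamed.append(replace(d, index=counters[key]))
    out = AnnotationSet(renamed)
    out.by_name()  # raises on duplicates
    return out


def build_quant_regions(
    annotations: AnnotationSet,
    max_extension: int = 250,
    gap_threshold: int = 1000,
    chrom_sizes: dict[str, int] | None = None,
) -> AnnotationSet:
    """Merge each domain's exons into a quantification region, extending
    boundaries into unique flanking sequence.

    A boundary facing a neighbouring domain is extended only when the
    gap exceeds ``gap_threshold`` (1 kb), by
    ``min(max_extension, (gap - gap_threshold) // 2)`` — up to 250 bp,
    while always preserving at least ``gap_threshold`` of separation, so
    extended regions can never overlap.  Outermost boundaries on a
    chromosome extend the full ``max_extension`` (clipped to the
    chromosome).
    """
    by_chrom: dict[str, list[DomainAnnotation]] = {}
    for d in annotations.domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    out = []
    for chrom, doms in by_chrom.items():
        doms = sorted(doms, key=lambda d: d.exon_span.start)
        spans = [d.exon_span for d in doms]
        for i, d in enumerate(doms):
            s, e = spans[i].start, spans[i].end
            # left boundary
            if i == 0:
                left = max_extension
            else:
                gap = s - spans[i - 1].end
                left = min(max_extension, (gap - gap_threshold) // 2) if gap > gap_threshold else 0
            # right boundary
            if i == len(doms) - 1:
                right = max_extension
            else:
                gap = spans[i + 1].start - e
                right = min(max_extension, (gap - gap_threshold) // 2) if gap > gap_threshold else 0
            new_s = max(0, s - left)
            new_e = e + right
            if chrom_sizes and chrom in chrom_sizes:
                new_e = min(new_e, chrom_sizes[chrom])
            out.append(replace(d, quant_region=GenomicInterval(chrom, new_s, new_e)))
    return AnnotationSet(out)


def annotate(
    domtbl_text: str,
    gene_exons: dict[str, list[GenomicInterval]],
    motifs: CladeMotifTable,
    peptides: dict[str, tuple[str | None, str]] | None = None,
    max_evalue: float = 1e-10,
    max_extension: int = 250,
    gap_threshold: int = 1000,
) -> AnnotationSet:
    """Full annotation pipeline: parse -> pair -> assign -> name -> regions.

    ``peptides`` maps a hit key ``"chrom:start-end"`` (long-exon interval of
    the hit, 0-based) to ``(short_exon_peptide, long_exon_peptide)`` for
    clade assignment; hits without peptides stay UNASSIGNED.
    """
    hits = parse_domain_hits(domtbl_text, max_evalue)
    domains = []
    for hit in hits:
        gene = None
        for g, exons in gene_exons.items():
            if any(ex.contains(hit.target) for ex in exons):
                gene = g
                break
        if gene is None:
            warnings.warn(f"hit {hit.target} outside all gene exons; skipped")
            continue
        d = pair_exons(hit, gene_exons[gene], gene=gene)
        key = f"{hit.target.chrom}:{hit.target.start}-{hit.target.end}"
        if peptides and key in peptides:
            short_pep, long_pep = peptides[key]
            d.clade = assign_clade(long_pep, motifs, short_seq=short_pep)
        domains.append(d)
    named = name_domains(AnnotationSet(domains))
    return build_quant_regions(named, max_extension, gap_threshold)
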