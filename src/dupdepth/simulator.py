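"""Truth-tagged WGS read simulator.

Generates single- or paired-end reads from reference regions under an
empirical-style error model: insert sizes Normal(350, 50) matching
1000 Genomes libraries, mate-asymmetric substitution rates (mean 0.0026
for mate 1, 0.004 for mate 2) ramping linearly from 0.5x the mean at
the 5' end to 1.5x at the 3' end, and a smoothed per-position quality
profile extendable to any read length.  Every read name carries a truth
tag recording the originating domain, interval and copy index, so that
off-target alignment can be scored exactly.

Spike-in experiments emulate copy-number states by scaling the *number*
of reads sampled from a region (1-10 copies at 15x haploid coverage),
not by duplicating reference sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

QUAL_MIN, QUAL_MAX = 2, 41


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class InsertModel:
    """Fragment (insert) length distribution for paired-end libraries."""

    mean: float = 350.0
    sd: float = 50.0

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd < 0:
            raise ValueError("insert mean must be > 0 and sd >= 0")


@dataclass(frozen=True)
class ErrorModel:
    """Substitution-error model: per-mate mean rates plus a linear ramp."""

    mean_rate_mate1: float = 0.0026
    mean_rate_mate2: float = 0.004
    ramp_start: float = 0.5
    ramp_end: float = 1.5

    def __post_init__(self) -> None:
        for r in (self.mean_rate_mate1, self.mean_rate_mate2):
            if not 0 <= r <= 1:
                raise ValueError("error rates must be in [0, 1]")
        if self.ramp_start <= 0 or self.ramp_end <= 0:
            raise ValueError("ramp endpoints must be positive")

    def mean_rate(self, mate: int) -> float:
        return self.mean_rate_mate1 if mate != 2 else self.mean_rate_mate2


def positionwise_error(model: ErrorModel, read_length: int, mate: int) -> np.ndarray:
    """Per-position substitution probabilities along a read.

    A linear ramp from ``ramp_start * c`` to ``ramp_end * c`` whose
    arithmetic mean is exactly ``c``, the mate's mean rate (errors are
    1.5x as likely at the 3' end and half as likely at the 5' end).
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    c = model.mean_rate(mate)
    if read_length == 1:
        return np.array([c])
    ramp = np.linspace(model.ramp_start, model.ramp_end, read_length)
    ramp *= read_length / ramp.sum()  # pin the mean exactly at c
    return c * ramp


@dataclass
class QualityProfile:
    """Per-position expected Phred qualities per mate, with a linear
    extension rule so any requested read length sees the same shape."""

    q_mate1: np.ndarray
    q_mate2: np.ndarray
    slope_mate1: float = 0.0
    slope_mate2: float = 0.0

    def for_length(self, read_length: int, mate: int) -> np.ndarray:
        base = self.q_mate1 if mate != 2 else self.q_mate2
        slope = self.slope_mate1 if mate != 2 else self.slope_mate2
        if read_length <= len(base):
            q = base[:read_length]
        else:
            ext = base[-1] + slope * np.arange(1, read_length - len(base) + 1)
            q = np.concatenate([base, ext])
        return np.clip(np.rint(q), QUAL_MIN, QUAL_MAX).astype(int)


def fit_quality_profile(
    observed_mate1: np.ndarray,
    observed_mate2: np.ndarray | None,
    target_length: int,
    span: float = 0.3,
) -> QualityProfile:
    """Smooth observed per-position mean qualities (locally weighted
    regression) and extend the fitted trend to ``target_length``.

    Mate 2 is modelled separately (it systematically runs lower than
    mate 1 on Illumina data); pass ``None`` to reuse the mate-1 fit.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    def fit_one(obs: np.ndarray) -> tuple[np.ndarray, float]:
        obs = np.asarray(obs, dtype=float)
        if len(obs) < 10:
            raise ValueError("need >= 10 observed positions to fit a profile")
        if target_length < len(obs):
            raise ValueError("target_length must be >= observed profile length")
        x = np.arange(len(obs))
        smooth = lowess(obs, x, frac=span, return_sorted=False)
        slope = float(np.polyfit(x, smooth, 1)[0])
        if target_length > len(obs):
            ext = smooth[-1] + slope * np.arange(1, target_length - len(obs) + 1)
            smooth = np.concatenate([smooth, ext])
        return np.clip(smooth, QUAL_MIN, QUAL_MAX), slope

    q1, s1 = fit_one(observed_mate1)
    if observed_mate2 is None:
        q2, s2 = q1.copy(), s1
    else:
        q2, s2 = fit_one(observed_mate2)
    return QualityProfile(q1, q2, s1, s2)


def default_quality_profile(length: int = 100) -> QualityProfile:
    """Default profile: Q35-centred with a gentle linear 3' decay,
    mate 2 running 3 Phred units below mate 1."""
    x = np.arange(length)
    q1 = 38.0 - 6.0 * x / max(1, length - 1)
    return QualityProfile(q1, q1 - 3.0, slope_mate1=-6.0 / max(1, length - 1),
                          slope_mate2=-6.0 / max(1, length - 1))


@dataclass
class SimSpec:
    """Full parameterization of one simulation run."""

    read_length: int = 100
    paired: bool = True
    haploid_coverage: float = 15.0
    copies: int = 2
    insert: InsertModel = field(default_factory=InsertModel)
    errors: ErrorModel = field(default_factory=ErrorModel)
    quality: QualityProfile | None = None

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copies must be >= 0")
        if self.haploid_coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.quality is None:
            self.quality = default_quality_profile(self.read_length)

    @property
    def mean_fragment(self) -> float:
        return self.insert.mean if self.paired else float(self.read_length)


@dataclass(frozen=True)
class TruthTag:
    """Origin of a simulated read, encoded in its FASTQ name."""

    domain: str
    origin: GenomicInterval
    copy: int
    serial: int = 0

    def encode(self) -> str:
        o = self.origin
        return f"origin|{self.domain}|{o.chrom}:{o.start}-{o.end}|{self.copy}|{self.serial}"

    @classmethod
    def decode(cls, read_name: str) -> "TruthTag":
        m = re.match(r"origin\|([^|]+)\|([^|:]+):(\d+)-(\d+)\|(\d+)\|(\d+)$", read_name)
        if not m:
            raise ValueError(f"read name {read_name!r} carries no truth tag")
        dom, chrom, s, e, copy, serial = m.groups()
        return cls(dom, GenomicInterval(chrom, int(s), int(e)), int(copy), int(serial))


@dataclass
class SimulatedRead:
    name: str
    seq: str
    qual: str
    mate: int = 0  # 0 = unpaired


def sample_fragments(
    region: GenomicInterval,
    spec: SimSpec,
    rng: np.random.Generator,
    domain_name: str = "",
) -> list[tuple[GenomicInterval, TruthTag]]:
    """Sample fragment intervals overlapping ``region``.

    Start positions are uniform over the region extended by one fragment
    length on each side, keeping only fragments that overlap the region;
    the fragment count is set so the expected on-region depth equals
    ``copies * haploid_coverage``.  Paired fragments draw their length
    from the insert model (floored at the read length); single-end
    fragments are exactly one read long.
    """
    D = region.length
    if D < spec.read_length:
        raise ValueError(
            f"region {region} shorter than read length {spec.read_length}"
        )
    if spec.copies == 0:
        return []
    fbar = spec.mean_fragment
    # expected overlap of a random overlapping fragment is F*D/(D+F-1);
    # solve n * E[overlap] = copies * coverage * D for n
    n = int(round(spec.copies * spec.haploid_coverage * (D + fbar - 1) / fbar))
    out = []
    for i in range(n):
        if spec.paired:
            F = max(spec.read_length, int(round(rng.normal(spec.insert.mean, spec.insert.sd))))
        else:
            F = spec.read_length
        start = int(rng.integers(region.start - F + 1, region.end))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = GenomicInterval(region.chrom, start, start + F, strand) if start >= 0 else \
            GenomicInterval(region.chrom, 0, start + F, strand)
        tag = TruthTag(domain_name or region.chrom, region, (i % spec.copies) + 1, i)
        out.append((frag, tag))
    return out


_ALTS = {
    "A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG",
}


def mutate_read(
    seq: str,
    probs: np.ndarray,
    quals: np.ndarray,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Apply position-wise substitution errors and build the quality string.

    Each base is substituted with probability ``probs[i]``, the
    replacement drawn uniformly from the three alternatives.  ``N``
    bases pass through unchanged and are never introduced.
    """
    if len(seq) != len(probs):
        raise ValueError("seq and probs length mismatch")
    bases = list(seq)
    hit = rng.random(len(bases)) < probs
    for i in np.flatnonzero(hit):
        b = bases[i].upper()
        if b in _ALTS:
            bases[i] = _ALTS[b][rng.integers(3)]
    qual = "".join(chr(33 + int(q)) for q in quals)
    return "".join(bases), qual


def _fragment_reads(
    frag: GenomicInterval,
    tag: TruthTag,
    ref_seq: str,
    spec: SimSpec,
    rng: np.random.Generator,
) -> list[SimulatedRead]:
    L = spec.read_length
    start = max(0, frag.start)
    end = min(len(ref_seq), frag.end)
    fseq = ref_seq[start:end]
    if len(fseq) < L:
        return []
    name = tag.encode()
    reads = []
    if spec.paired:
        five = fseq[:L]                # 5' end, forward
        three = revcomp(fseq[-L:])     # 3' end, reverse-complemented
        # library strand decides which physical end is sequenced first
        m1_seq, m2_seq = (five, three) if frag.strand == "+" else (three, five)
        for mate, s in ((1, m1_seq), (2, m2_seq)):
            probs = positionwise_error(spec.errors, L, mate)
            quals = spec.quality.for_length(L, mate)
            seq, qual = mutate_read(s, probs, quals, rng)
            reads.append(SimulatedRead(name, seq, qual, mate))
    else:
        s = fseq[:L] if frag.strand == "+" else revcomp(fseq[:L])
        probs = positionwise_error(spec.errors, L, 1)
        quals = spec.quality.for_length(L, 1)
        seq, qual = mutate_read(s, probs, quals, rng)
        reads.append(SimulatedRead(name, seq, qual, 0))
    return reads


def simulate_spike_in(
    domain,
    reference: dict[str, str],
    spec: SimSpec,
    rng: np.random.Generator,
) -> list[SimulatedRead]:
    """Simulate ``spec.copies`` copies of one domain at
    ``spec.haploid_coverage`` per copy (the spike-in experiment).

    ``domain`` is a :class:`~dupdepth.annotation.DomainAnnotation` or a
    bare :class:`GenomicInterval`.
    """
    if isinstance(domain, GenomicInterval):
        region, name = domain, f"{domain.chrom}:{domain.start}"
    else:
        region, name = (domain.quant_region or domain.exon_span), domain.name
    ref_seq = reference[region.chrom]
    reads = []
    for frag, tag in sample_fragments(region, spec, rng, domain_name=name):
        reads.extend(_fragment_reads(frag, tag, ref_seq, spec, rng))
    return reads


def simulate_baseline(
    annotations,
    reference: dict[str, str],
    spec: SimSpec,
    rng: np.random.Generator,
) -> list[SimulatedRead]:
    """Diploid baseline: every canonical domain simulated at ``spec.copies``
    (default 2) so total on-domain depth is ``copies * haploid_coverage``."""
    reads = []
    for d in annotations.canonical():
        reads.extend(simulate_spike_in(d, reference, spec, rng))
    return reads


# --------------------------------------------------------------------------
# FASTQ I/O
# --------------------------------------------------------------------------

def write_fastq(reads: list[SimulatedRead], path1, path2=None) -> None:
    """Write reads to FASTQ; paired reads are split by mate across the
    two files (names identical for both mates, modern convention)."""
    import gzip

    def opener(p):
        return gzip.open(p, "wt") if str(p).endswith(".gz") else open(p, "w")

    if path2 is None:
        with opener(path1) as fh:
            for r in reads:
                fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")
    else:
        with opener(path1) as f1, opener(path2) as f2:
            for r in reads:
                fh = f2 if r.mate == 2 else f1
                fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(path, mate: int = 0) -> list[SimulatedRead]:
    import gzip

    op = gzip.open if str(path).endswith(".gz") else open
    reads = []
    with op(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            plus = fh.readline()
            qual = fh.readline().strip()
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record near {header!r}")
            reads.append(SimulatedRead(header[1:].split()[0].strip(), seq, qual, mate))
    return reads
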