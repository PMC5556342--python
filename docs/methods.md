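# Methods

This note documents the models, parameter choices and numerical
conventions behind `dupdepth`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Coordinates and annotation

All coordinates are BED-style 0-based half-open. The single exception is
the HMMER-parse boundary: domtblout alignment coordinates are 1-based
inclusive (and reversed for minus-strand hits) and are converted once,
at parse time. Hits are kept when their independent E-value is below
1e-10, the conventional genome-search threshold for this domain family.

Profile-HMM searches find only the long exon of each domain doublet; the
short exon encoding the N-terminus is taken to be the immediately
preceding exon when its length falls in 50–111 bp, and its absence is
flagged rather than guessed. Clade assignment uses exact peptide motif
substrings per clade (a table supplied as TSV config, with an
allowed-mismatch knob defaulting to 0): a unique match assigns the
clade, a short-exon motif of one clade with a long-exon motif of another
marks a HYBRID, no match leaves UNASSIGNED, and two motifs of different
clades in the *same* exon is a hard error, since it means the motif
table itself is ambiguous. Non-canonical clades (CON4–8), hybrids and
unassigned domains are annotated but excluded from quantification unless
explicitly included — they are rare, mostly outside the core gene
family, and would otherwise distort clade totals.

Quantification regions merge the two exons' span. A boundary facing a
neighbouring domain is extended only when the gap exceeds 1 kb, by
`min(250, (gap - 1000) // 2)` bp. The cap-to-half-the-*excess* rule
(rather than half the gap) keeps at least 1 kb of separation between
extended regions, makes the extension continuous in the gap size, and
guarantees disjointness — the property the rest of the pipeline relies
on. Outermost boundaries on a chromosome take the full 250 bp.

## Read simulation

Study conditions are encoded as defaults: 100 bp paired-end reads,
insert length Normal(350 bp, 50 bp), 15× expected haploid coverage,
diploid baseline of 2 copies, spike-ins of 1–10 copies obtained by
scaling the *number* of reads (never by duplicating reference
sequence). Substitution error rates are 0.0026 (mate 1) and 0.004
(mate 2) on average, ramping linearly from 0.5× the mean at the 5' end
to 1.5× at the 3' end; the ramp is renormalized so its arithmetic mean
is exactly the mate's rate at any read length. Indels, PCR duplicates
and chastity filters are out of scope.

Fragment starts are uniform over the target region extended by one
fragment length per side, keeping fragments that overlap the region; the
fragment count is `round(copies × coverage × (D + F̄ − 1) / F̄)` so the
expected base-overlap depth on the region equals copies × coverage
exactly (up to rounding). Fragment strand is uniform — the standard
null. Quality strings are Phred+33. The per-position quality profile is
fitted by locally weighted regression (span 0.3 by default) to observed
per-position means, per mate, and extended to longer read lengths by
continuing the fitted linear trend, clipped to Phred 2–41. When no
empirical profile is supplied, a default of ~Q35 with a gentle linear 3'
decay (mate 2 three units lower) is used; qualities do not influence
alignment in the oracle, so this choice only matters for the read
filter.

Every read name encodes a truth tag (`origin|domain|interval|copy|serial`),
which is what makes off-target alignment directly measurable.

## Alignment

Four strategies are defined. `BEST` keeps one minimum-mismatch placement
(paired reads prefer a minimum-total-mismatch proper-pair combination
within an 800 bp insert), breaking ties pseudo-randomly by a CRC32 hash
of run seed + read id — reproducible and independent of read order.
`BEST_TIES` keeps the whole best stratum with `n_loci` recorded, for
multi-read correction. `ALL_CROP36` crops reads to their first 36 bases
and reports every placement within 2 mismatches; `ALL_FULL` does the
same at full length. The published external command lines (bowtie2
`--very-sensitive -X 800`; mrsFast `--crop 36 -e 2`; bowtie
`--all -v 2 -X 800` and `--best --strata --all -v 2`) are emitted
verbatim and dry-run testable; a `bwa-best` backend (bwa `aln`/`samse`,
end-to-end with a mismatch budget and random tie pick) provides an
installed best-strategy aligner for verification against the oracle.

The built-in oracle mapper is for references up to roughly 10 Mbp. It
indexes 12-mers, finds candidates by the pigeonhole principle (with ≤ m
mismatches some read segment of length ≥ L/(m+1) is exact), and verifies
each candidate exhaustively on both strands. Only substitutions are
scored — the simulator emits substitution-only errors, so the system is
closed — and `N` counts as a mismatch. A consequence worth knowing: a
read drawing 3+ errors (≈1% of mate-2 reads at 100 bp) exceeds the
2-mismatch budget and goes unmapped, exactly as `-v 2`-style aligners
behave.

## Quantification

Proper mate combinations are joined into single fragments spanning the
outermost coordinates; with several equally good combinations each gets
weight 1/#combinations. Mates of discordant pairs are treated as
single-end and deterministically extended 3'-ward to half the sample
mean insert (a stochastic extension would break reproducibility for no
accuracy gain). Reads from genuinely single-end libraries are *not*
extended: the extension estimates the unobserved remainder of a
sequenced fragment, which single-end spike-ins do not have — extending
them would inflate single-end coverage by ~75% and break the
`copies = coverage / 15` calibration.

Coverage is base-weighted: each fragment contributes overlap × weight,
so fractional (multi-mapped) reads accumulate fractionally. Copies are
coverage over expected haploid coverage — the configured 15× for
simulations, background-mean/2 for real samples. Under the align-all
strategies, clade totals are further divided by the clade's haploid
reference domain count. Aggregation to gene-clade, group-clade and clade
levels is by summation, so conservation across levels is exact by
construction; the gene level of the copy-number table comes from the
unique-region estimator below, not from summing domains (a sum of
domain copies is not a gene dosage).

Real-sample normalization divides by the mean coverage of supplied
conserved single-copy background regions and multiplies by a GC factor:
depth per 1 kb bin is loess-fitted against bin GC, and
`factor(gc) = global mean / fitted(gc)`. The loess span default is 0.5;
sharply non-monotone biases need a shorter span (the knob is exposed). A
degenerate GC range yields an identity model with a warning. Read
filtering trims 3' bases below Phred 10, drops reads shorter than 80 bp
(pairs drop together), and samples below 10× estimated coverage
(filtered reads × insert / genome size) are flagged for removal.

Gene copy number uses regions that map uniquely within one mismatch,
intersected with a window around each gene, minus domain regions and
flagged exons *widened by about one fragment length*: reads straddling a
domain boundary carry the domain's dosage, not the gene's, and the
margin keeps an intragenic expansion from leaking into the gene-level
estimate. The estimate is twice the length-weighted mean normalized
depth; genes with no unique bases are reported unmeasurable rather than
guessed.

## Evaluation

Ambiguity matrices are computed on joined fragments (a mate protruding
past a domain edge is not an off-target event); each fragment
contributes 1/n_loci per landing, a landing being the region of maximal
overlap. Row denominators count all aligned fragment units from the
source, so rows sum to ≤ 100 (landings outside every region stay in the
denominator). Off-target is 100 − on-target per source; clade summaries
are read-weighted, not domain-averaged, so heavily sequenced domains
count proportionally.

Gene groups are connected components, per clade, of the graph joining
genes whose same-clade units share at least 5% of reads in either
direction. The threshold is a config knob; 5% separates "essentially
unique" from "must be aggregated" cleanly on the synthetic families and
the grouping is invariant to gene ordering by construction.

RMSE is the root of the *summed* squared copy errors, as printed in the
field's convention for this analysis; a `mean=True` variant (root mean
square) is provided since summed values grow with the number of
configurations accumulated. Whether replicates are accumulated or
averaged is therefore always explicit in the output (`rmse` and
`rmse_mean` columns).

## Synthetic data: what it shows and what it does not

The toy generator builds domain families hierarchically (clade ancestor
→ gene variant → domain copy) with substitution-only, uniform-rate
divergence; exact substitution counts make realized pairwise identity
hit the target within ±0.5%. Within-gene divergence above between-gene
divergence is rejected as an infeasible triangle under this
construction. The default family (6 genes × 6 clades, 1 kb domains, 2 Mb
genome) runs end-to-end in minutes on one CPU; the test suite uses
smaller instances (2–3 genes, 600–700 bp domains, tens of kb) chosen so
the full suite completes in well under the time a coffee takes.

The worked example places a block of `0.2·D + L − 1` bp (299 bp for a
1 kb domain and 100 bp single-end reads) from the focal domain as an
exact duplicate elsewhere: reads falling entirely inside the block are
perfectly ambiguous, reads touching its boundary are anchored, and the
expected fraction of read-bases lost to the decoy is exactly 10%. The
measured copy number is therefore 0.9× the simulated copies — 0.9 for 1
copy, 4.5 for 5 — which the acceptance script reproduces over 20 seeds.

The cross-clade "confusable" genome (pairs of domains in different genes
*and* clades differing at exactly 5 sites) reproduces the qualitative
accuracy ordering: RMSE falls with read length (36 → 100 → 300 bp) and
paired-end never trails single-end, at every measurement level. That is
the regime where ambiguity hurts even clade-level totals — the situation
the grouping strategy exists to mitigate.

What the synthetic data does not model: indels and structural
complexity, GC-content heterogeneity (toy genomes are i.i.d. uniform
base composition, so GC correction is exercised on constructed bins, not
on the toy genomes), sequencing-center batch effects, and the sheer
scale of a real genome (the oracle replaces heuristic index structures,
so heuristic-specific artifacts of bowtie/mrsFast are only covered by
the external-backend contract tests and the bwa agreement check).
Passing tests demonstrate the estimator's correctness and calibration
under its stated model, not robustness to every real-data pathology.

## CNV sample emulation

Copy-number events scale read counts region by region: event regions are
sampled at their event copy number, the rest of the genome at diploid.
Background sampling leaves a one-fragment margin around each event so
background fragments do not bleed depth across the event boundary (the
event region itself already samples every overlapping fragment). This
emulates dosage, not breakpoints: split-read or discordant-pair
breakpoint signals are intentionally absent.

## Known limitations

- The oracle's reference-size ceiling (~10 Mbp) makes hg38-scale runs
  depend on external aligners; the package emits their exact command
  lines but does not bundle them.
- The 2-mismatch budget applied to full-length reads (`ALL_FULL`)
  discards most 300 bp reads at realistic error rates; this is the
  strategy's published contract, implemented as stated and flagged here.
- Unique-region discovery tiles single-end reads; paired uniqueness
  would classify slightly more sequence as unique, so the single-end
  rule is conservative.
- Ambiguity matrices weight multi-locus reads fractionally (1/n_loci
  per landing), keeping rows probability-like; a count-once-per-locus
  convention would change row sums' interpretation and is not offered.
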