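# Methods

## Coordinate and counting conventions

All coordinates are 0-based half-open (BED convention); WIG input,
which is 1-based, is shifted on read, and `span` fields are honored.
Coverage tracks store read **5'-end positions** per strand by default —
piRNA counting is read-count based, not base-cover based — but the
container is agnostic and accepts full-cover pileups. The library size
used for RPM (reads per million mapped: RPM(x) = x·10⁶/`library_size`)
is always supplied from the mapping manifest, never inferred from the
track, because a track may be a strand- or region-subset of the
library. RPKM divides RPM by region length in kb, and cross-species
expression values are further expressed as ratios to a housekeeping
gene (RpL32; Rp49 in older fly nomenclature) so that libraries of
different depth and composition can be compared.

Gene models come from BED12. The 5'UTR / ORF / 3'UTR segments
partition the exon bases exactly, with the 3'UTR on the 3' side of the
CDS respecting strand. A record with `thickStart == thickEnd` (the
BED12 convention for non-coding transcripts) carries all exon bases in
the 3'UTR slot, so non-coding entries still flow through 3'UTR
counting and are then removed by the curation name filters.

## Genic piC calling

Reads are counted on the mRNA strand only. The annotated 3'UTR (and,
for reporting, the 5'UTR) is extended iteratively in windows of
2000 bp (mammal preset) or 500 bp (Drosophilid preset): each next
window must hold ≥ 1 RPM of same-strand reads; the first failing
window stops the extension. Extension is capped at 5 windows and
clipped at the chromosome end and at the nearest same-strand
neighboring gene — the clip is applied to calling as well as to
feature analysis, since an extension that runs into another gene would
attribute that gene's reads to the wrong locus. Iteration (rather than
a single extension step) captures unannotated 3'UTR ends that extend
beyond one window while staying bounded; the cap and the per-window
threshold are both configuration.

A gene is retained as a genic piC iff its same-strand 3'UTR signal
(annotated + extension) is ≥ `genic_min_rpm` (default 10 RPM, 20 in
the stringent mode); the comparison is inclusive. Genes whose ORF
carries ≥ 50 RPM are flagged (`orf_retained`) but the keep/drop
decision cites only the 3'UTR. The 5'UTR extension never affects
retention.

Curation quantifies a manual grooming step, so the thresholds are
explicit and auditable rather than baked in: a candidate is removed
when ≥ 50% (`te_frac`) of its 3'UTR signal lies inside annotated
repeat intervals (`TE_overlap`), when an overlapping/adjacent gene's
own span explains ≥ 50% (`neighbor_frac`) of the signal
(`neighbor_gene_source`), when it duplicates a gene name already kept
with more signal (`duplicate_name`), when its name matches a
non-coding pattern such as `Gm####` (`ncRNA_pattern`), or when it
belongs to a repetitive family prefix list — histones, olfactory
receptors, zinc fingers (`blacklist_family`). Every removal carries
its reason code.

## Intergenic piC calling

The genome is tiled in non-overlapping 5 kb windows (step = window
size; `window_step` is configuration). The published description says
"sliding window" without a step; tiling makes calls deterministic and
matches the 5 kb decomposition used by the strand index. Both strands
are summed for detection, since intergenic clusters may be single- or
dual-stranded; per-strand RPMs are retained. A cluster starts at a
window whose combined RPM **exceeds** `start_rpm` (1 RPM) and extends
while windows hold **at least** `stop_rpm` (1 RPM); it is kept when
the run totals ≥ 10 RPM. The terminal partial window of a chromosome
is included with its actual counts. Clusters overlapping called genic
piCs are flagged or dropped (configuration; the pipeline default drops
them so the two classes stay disjoint).

Clusters are equated across species by the **synteny anchor**: the
ordered (upstream, downstream) pair of reference-rooted names of the
nearest non-overlapping flanking genes within 1 Mb; a side with no
gene in range yields a one-sided anchor, flagged.

## Strand-configuration index

Per 5 kb window with plus/minus RPMs A and B the index is
(A−B)²/(A²+B²); a cluster's index is the unweighted mean over its
windows. The statistic is scale-invariant (counts vs RPM is
immaterial), symmetric, bounded in [0,1], 1 iff exactly one strand is
silent and 0 iff the strands balance exactly. Windows with A = B = 0
are undefined and are **excluded** from the mean — imputing either 0
or 1 would bias the average; a `zero_policy="zero"` switch exists for
sensitivity probes. Partial terminal windows are included.

## Cross-species comparison

Repertoire tables are species × locus matrices rooted to reference
gene names (D. melanogaster for flies, human/mouse for amniotes, via
the ortholog table); *absent* (no ortholog / no measurement) is NaN
and distinct from a measured 0. piC overlap assigns each locus to the
subset of species where RPM ≥ 10 (≥ 20 stringent). Expression overlap
uses housekeeping-normalized values: a pair shares a gene when
|log₁₀x − log₁₀y| ≤ 0.5, a triple when the sample standard deviation
(ddof = 1, which reproduces SD = 1.0 for a 10/100/1000 spread) of the
three log₁₀ values is ≤ 0.3; stringent mode uses 0.3 and 0.177. Zero
or missing expression makes the locus absent in that species (log
undefined). Assignment precedence is triple > pairwise > singleton;
when a locus meets the pairwise criterion for two pairs but not the
triple, it goes to the pair with the smallest log₁₀ difference
(deterministic, documented here because no published rule covers the
case), and a locus shared with nobody falls to the singleton of the
species where it is highest.

Partition differences are tested by chi-square over the subset-count
vectors and by per-subset pooled two-proportion Z tests, two-sided,
Bonferroni-multiplied by the number of tested subsets and capped at 1.
Subsets with expected counts < 1 are flagged and fall back to Fisher's
exact test.

ECpiC (Eutherian-Conserved) classification requires expression ≥ the
RPM threshold in at least *k* species of **every** clade (Primates,
Glires, Laurasiatherians, or user clades); *k* defaults to 1 because
no formal quorum is published — the rule and the per-locus evidence
vector are emitted with every run.

## Gain/loss inference

Binary presence characters (RPM ≥ threshold) are reconstructed by
Wagner parsimony via Sankoff dynamic programming, vectorized across
characters. Default costs are 1:1; asymmetric costs are supported.
Root-state ties break toward absence, consistent with small ancestral
repertoires; internal-node ties prefer the parent's state (no event)
and then absence. With the gain cost driven large the reconstruction
degenerates to an ancestral single origin with losses below — the
Dollo-like limit. Events are summed per branch and divided by branch
lengths (million years); zero-length branches yield flagged undefined
rates. Per-branch identities are exposed as leaf-sets below the
branch, which is stable across tree serializations.

## Conservation scores and negative controls

Per-base phastCons/phyloP dumps are averaged over gene segments as
(sum of scores)/(segment length); bases missing from the track count
as 0 by default (the phastCons genome-dump convention) with an
`exclude` mode for phyloP. Both the raw per-base mean and the
per-segment normalization are emitted since the published
normalization is not specified. Structural elements arrive as BED
intervals from external predictors (RNAz/EvoFold/REAPR are not
invoked); an element spanning the ORF/3'UTR boundary counts once per
segment. Negative controls are drawn (seeded RNG) from expressed genes
producing no piRNAs, 3 per piC gene, and their 3'UTRs are padded
toward the piC-set mean length within 250–500 bp (fly) or 500–1100 bp
(mouse), truncated at same-strand neighbors.

## Antisense target search

Matches are exact reverse-complement stretches ≥ 13 nt (the effective
criterion of a short-word BLAST at e-value ≤ 1), found by
seed-and-extend over 13-mers with maximal bidirectional extension and
deduplication; U ≡ T on input. The exact-match model is conservative
relative to BLAST's heuristic; a single-mismatch mode is left to
configuration rather than default. Results join a supplied
differential-expression table; computing differential expression
itself is out of scope.

## What the synthetic scenarios emulate — and what they do not

The generator lays each species' genes on one chromosome at a 10 kb
pitch (two exons, 200 bp 5'UTR, 2 kb ORF, 1.8 kb 3'UTR, alternating
strands), designates piC genes according to a planted conservation
pattern, and places Poisson-distributed read 5' ends uniformly over
the target 3'UTRs at 50 RPM against a 0.2 RPM background, with
intergenic clusters of three 5 kb windows at ~40 RPM per window in
single- or dual-strand configuration. Reads carry a 23–32 nt length
law with mode 29 nt (mammalian testes piRNA libraries peak near
29–30 nt) and an 80% 5'U bias; mRNA tables share per-gene baselines
across species with 0.05 log₁₀ cross-species noise, so mRNA
repertoires overlap far more than piC repertoires, as in real testes
data. Conservation patterns are planted as explicit events (ancestral
presence, clade-stem gains, terminal gains, terminal losses) and
propagated to the leaves, and library sizes default to 2×10⁶ mapped
reads so a 50 RPM locus receives ~100 reads.

Passing recovery tests on this generator shows the algorithms
faithfully implement their definitions and are well-calibrated at the
stated thresholds. It does **not** show robustness to what the
generator omits: transposon landscapes and multi-mapping reads,
ping-pong biogenesis signatures, annotation errors, overlapping gene
models, expression-level confounding between neighboring loci,
incomplete draft assemblies, or ortholog misassignment — the factors
the curation filters and manual inspection address in real data.

## Problem sizes and numerical choices

Test scenarios use 5 species × 200 genes (caller recovery), 9 species
× 200 genes (conservation round trip) and 200 planted clusters
(strand-index recovery); parsimony is verified against exhaustive
enumeration on trees of ≤ 6 leaves. These sizes exercise every code
path while keeping the whole suite and the acceptance script in the
tens of seconds. Window sums use cumulative-sum range queries on
sparse per-chromosome arrays, so calling is independent of track
storage order. All randomness flows from a single integer seed through
`numpy.random.default_rng` spawn keys; two runs with the same seed
produce byte-identical file bundles.

## Known limitations

- The intergenic window step and strand-combination rule of the
  original caller are unpublished; both are configuration here, and
  the defaults (tiling, combined strands) are this package's choice.
- Extension iteration count, curation thresholds (0.5/0.5), the ECpiC
  quorum (k = 1) and the parsimony root prior are likewise exposed
  defaults, not assertions about the original scripts.
- Expression overlap supports 2 or 3 species, matching the published
  pairwise/triple criteria; larger sets need a generalization of the
  SD criterion that is deliberately not invented here.
- The headline biological counts of the study (e.g. 21 intergenic +
  56 genic conserved loci) depend on the deposited sequencing
  libraries and cannot be recomputed from synthetic data; the package
  reports recovery of planted truth instead.
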