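# Methods

## Gene model and coordinates

Transcript structures come from GFF3 (gene → mRNA → exon/CDS with `Parent`
links, parsed with gffutils) and sequence from FASTA (pyfaidx).  All
coordinates are 1-based inclusive throughout; nothing converts silently.
Exons and CDS intervals are kept in transcription order, so exon 1 is
first for either strand, and the spliced CDS is read 5′→3′ in coding
orientation (minus-strand pieces reverse-complemented).  Each CDS base
carries its genomic coordinate, which makes genomic↔CDS mapping an exact
inverse pair; protein position and codon offset follow arithmetically
(`aa = ⌈c/3⌉`, `offset = ((c−1) mod 3)+1`).

Canonical selection is MANE-first: a uniquely MANE-labelled transcript
wins outright; otherwise the best APPRIS label
(principal1 … alternative2) decides.  Remaining ties break by longest CDS,
then lexicographically smallest transcript id — arbitrary but
deterministic, which matters more here than any biological argument.
MANE/APPRIS labels are read from plain two-column TSVs so the whole tool
stays offline.  Internal stop codons warn rather than fail by default
(`on_internal_stop="error"` upgrades), so imperfect annotations remain
viewable.

## SNV enumeration

Every CDS base can mutate into three alternate bases, giving exactly 3·L
simulated variants.  Consequences follow the standard genetic code
(Biopython's table): same residue → synonymous (including stop→stop),
gain of stop → nonsense, loss of stop → stop-lost, otherwise missense.
Changes in the initiator codon are classified start-lost by default and
excluded from missense profiles — the scores model substitutions, not
translation loss; `initiator_aware=False` restores plain classification,
matching how precomputed score tables list those rows.  Enumeration order
is fixed (CDS position, then coding-strand alternate base A<C<G<T) so
exports are byte-stable; for minus-strand transcripts the reported
ref/alt alleles are on the genomic strand (the join key used by external
tables), codons on the coding strand.

## External tables

Clinical significance strings normalize case-insensitively into a closed
vocabulary; combined "Pathogenic/Likely pathogenic" entries map to
likely-pathogenic so they land in the P/LP group; unknown strings become
`uncertain` with a logged warning.  Allele frequencies are always
recomputed as ac/an (ac = 0 and an = 0 rows dropped).  The score table is
queried through its tabix index (pysam); per-transcript `;`-separated
cells resolve by matching the transcript-id slot, falling back to the
first numeric entry, with `.` as missing — the common convention for
dbNSFP-style tables.  The shipped registry covers the 43 score columns of
the dbNSFP v4.3a dialect with orientation and published cutoff; a TSV can
extend or override it.

Group membership is deliberately overlapping: the four groups are defined
by independent predicates, and the in-silico group is "all possible
variants", so one variant may contribute its score value to several
groups.  Pooling exomes and genomes into one population group is the
default (a flag restricts).

## Score profiles

Both smoothers regress on the duplicated (position, value) points rather
than per-position means, so positions with more scored substitutions
weigh more.  The size rule is a hard switch at 1000 points:

* **loess** (n < 1000): local quadratic regression with tricube weights
  over the nearest 75% of points — the classical smoother defaults.
  Pointwise SE comes from the equivalent-kernel row
  (`var = σ²‖l(x)‖²`), with σ² estimated from the residuals and the
  smoother-matrix trace as model degrees of freedom.
* **penalized spline GAM** (n ≥ 1000): a cubic B-spline basis (k = 10)
  with a second-difference penalty plus a small ridge (1e-3 relative) so
  the penalty null space — the linear trend — can also shrink toward
  zero; this is the shrinkage behaviour of mgcv's `cs` basis,
  approximated with a standard difference penalty.  The smoothing
  parameter is chosen by GCV over a 30-point log-spaced grid; SE uses the
  Bayesian covariance σ²(XᵀX + λP)⁻¹.

The 95% band is fit ± 1.96·SE (normal approximation).  The evaluation
grid is every integer position in the data's span.  Both smoothers are
linear in the responses, giving exact shift-equivariance, and both
reproduce noiseless lines to numerical tolerance; with fewer than 10
points or a single distinct position the profile is refused as
degenerate.  The heat-strip is the plain arithmetic per-position mean,
NaN (a gap) where nothing is scored.  Orientation is never flipped: the
curve shows the raw score scale with the registry cutoff as a reference
line, and the heat-strip color map puts the damaging end hot.

## Group statistics

Welch's unequal-variance t-test is the default for all six group pairs —
group variances differ strongly by construction (the in-silico group is
orders of magnitude larger and broader than the curated ones); a flag
selects the pooled-variance Student variant.  Quartiles per group come
from linear-interpolation percentiles.  Asterisk thresholds are strict
(`p < 0.05/0.01/0.001`).  No multiple-testing correction is applied by
default since the raw asterisks are the conventional display; a
Bonferroni flag exists, and any cross-pair inference should be drawn with
caution either way.  Groups under two values are skipped with a warning
rather than failing the run.

## Figures and export

All six builders are pure functions of their inputs; the SVG hash salt is
pinned and timestamps stripped, so identical inputs give byte-identical
SVG — the run manifest's SHA-256 checksums are reproducible across runs.
Choices where the convention was open: exon-true/intron-compressed layout
reserves 20% of the axis for introns, split equally, so intronic
lollipops stay visible while exons keep their true relative scale; kernel
densities use Silverman's bandwidth and are normalized independently per
group (shape comparison; a count-scaled mode exists by flag); the
allele-frequency panels draw one bar per variant at its position on a
log10 axis clipped at half the smallest observed frequency; at most three
score profiles stack in one figure.  Tables export as CSV or XLSX with a
`<score>_class` damaging/tolerated tag derived from the registry cutoff.

## Synthetic data

The fixture generator emulates the full input surface: a gene with
codon-unaligned exon boundaries, UTRs and GT…AG introns on either strand;
two decoy transcripts with worse APPRIS labels and 3′-trimmed CDS so
canonical selection is exercised; a score table covering all 3·L SNVs
with a planted positional signal (constant / linear / quadratic /
bimodal) plus Gaussian noise, ~5% missing cells and `;`-slotted
per-transcript cells; ClinVar-like records with a planted pathogenic
hotspot and benign background; allele counts with benign frequencies
log-uniform in [1e-5, 1e-2] and pathogenic variants absent or singletons.
Defaults describe a mid-sized disease gene: 412 residues (1239-nt CDS,
4 exons), hotspot at amino acids 260–280 with 30 P/LP variants, 30 B/LB
elsewhere, quadratic signal with sd 0.05, and a +0.4 score offset of
pathogenic variants over background.  One seed threads through every
generator, making all files byte-reproducible.

What the fixtures do **not** emulate: realistic mutational signatures,
transition/transversion bias, linkage, population structure, annotation
errors, multi-gene loci, indels or splice-site variation.  Passing tests
therefore demonstrate correctness of the mechanics (enumeration,
mapping, smoothing, statistics, rendering) under clean planted structure,
not robustness to the full messiness of the live databases.

## Problem sizes and numerics

Tests and the acceptance script run at the fixture scale above (a
~1.2-kb CDS, ~3.7k SNVs, score fits with up to 3000 points, 1000-replicate
null calibration) — sizes chosen so planted effects are comfortably
recoverable while the full suite stays fast.  Degenerate inputs are
handled explicitly: single-exon genes lay out without introns, groups
with fewer than two distinct positions draw rug-only densities, empty
population panels render empty, and constant inputs yield zero-width
confidence bands.

## Known limitations

Single-gene, single-transcript analysis only; no VCF ingestion; no
nonparametric test beyond the flags documented above; splice-region SNVs
outside the CDS are displayed (ClinVar lollipops) but not enumerated; the
spline approximates mgcv's shrinkage basis rather than reimplementing its
exact eigen-decomposition; REML is not offered (GCV only).
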