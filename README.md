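# varscape

Per-gene exhaustive SNV simulation, pathogenicity-score profiling and
variant-group statistics, with six publication-style plots and exportable
tables — all from local files, no web services.

## The problem

Interpreting a rare coding variant usually means asking three questions at
once: where does it sit in the gene and the protein, what do in-silico
pathogenicity scores say about every substitution that *could* occur there,
and how do known pathogenic, benign and population variants distribute
along the same axis?  `varscape` answers these for a single gene: it picks
the canonical transcript (MANE first, then the best APPRIS isoform),
enumerates **every biologically possible coding SNV** — each of the 3·L
single-base changes of an L-base CDS — classifies each at the protein level
(synonymous / missense / nonsense / stop-lost / start-lost), joins them
with ClinVar-like annotation, gnomAD-style allele counts and a
tabix-indexed dbNSFP-style score table, and renders the results.

## The core model

Scores of the possible missense substitutions give several data points per
amino-acid position *p*.  Two complementary summaries are computed:

* **heat-strip** — the arithmetic mean of the score values at each
  position, `s̄(p) = (1/n_p) Σᵢ s(p, i)`, drawn as a one-row heat map;
* **smoothed profile** — a conditional-mean curve over the duplicated
  `(p, s)` points with a 95% band (`fit ± 1.96·SE`).  The smoother is
  size-dependent: with **n ≥ 1000** points a penalized cubic regression
  spline with shrinkage (a GAM; smoothing parameter by GCV), with
  **n < 1000** loess (local quadratic regression, tricube weights,
  span 0.75).

Score values are then partitioned into four (non-exclusive) groups —
`ClinVar_pathogenic` (P/LP), `ClinVar_benign` (B/LB), `gnomAD` (present in
either population dataset) and `InSilico` (all possible nsSNVs) — and all
six pairs compared with Welch's t-test, annotated `*` (p < 0.05),
`**` (p < 0.01), `***` (p < 0.001), strict inequalities.

## Worked example

Everything runs offline; a synthetic bundle with planted structure (a
412-residue protein, a pathogenic hotspot at amino acids 260–280, a
quadratic positional score signal) stands in for the live databases:

```sh
varscape fixtures --out demo --seed 7     # writes inputs + run_config.yaml
varscape run --config demo/run_config.yaml
```

The log reports the canonical transcript and group sizes:

```
INFO varscape: canonical transcript: TX001 (mane=True, appris=principal1)
INFO varscape: simulated 3717 SNVs over 1239 CDS bases
INFO varscape: group sizes for REVEL_score: {'ClinVar_pathogenic': 28,
  'ClinVar_benign': 30, 'gnomAD': 39, 'InSilico': 2502}
```

`demo/results/` then holds the six figures (`utp.svg`, `protein.svg`,
`clinvar_density.svg`, `af_hist.svg`, `score_model.svg`, `violins.svg`),
the two variant tables, the profile and stats tables, and a
`manifest.json` of SHA-256 checksums (byte-identical across re-runs).
`group_stats.csv` starts:

```
score,group_a,group_b,n_a,n_b,t,df,p,stars
REVEL_score,ClinVar_pathogenic,ClinVar_benign,28,30,8.0896,34.29,1.85e-09,***
REVEL_score,ClinVar_pathogenic,gnomAD,28,39,6.4680,45.27,6.13e-08,***
```

The planted +0.4 score offset of hotspot variants shows up exactly where
it should: pathogenic vs benign and pathogenic vs population are highly
significant, benign vs population is not (p ≈ 0.18).

Stages can also run separately (`simulate`, `profile`, `stats`, `plot`),
chaining through plain TSVs; see `varscape --help`.

## Inputs

GFF3 + FASTA for the gene model; two-column MANE/APPRIS label TSVs;
ClinVar-like summary TSV; per-dataset allele-count TSVs; a
bgzip-compressed, tabix-indexed per-SNV score table (dbNSFP v4.3a column
dialect, 43 scores registered with orientation and cutoff); a UniProt-like
protein-feature TSV.  All coordinates are 1-based inclusive.
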