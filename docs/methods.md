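# Methods

`hydromark` analyses paired 5-methylcytosine (5mC) and
5-hydroxymethylcytosine (5hmC) peak sets from a normal and a cancer cell
line, working entirely at the level of called peaks (BED intervals).  This
note records the models, the parameter choices, and the numerical
decisions behind each stage, and what the synthetic-data experiments do
and do not demonstrate.

## Coordinates and interval algebra

All coordinates are BED-style 0-based half-open `[start, end)`.  Two
intervals sharing only a boundary coordinate do not overlap; "at least
partial overlap" means an overlap length of at least 1 bp
(`min_overlap_bp=1`, configurable).  Merging unifies overlapping *or
book-ended* intervals and preserves covered basepairs.  Peak-to-gene
assignment uses the peak midpoint, `floor((start+end)/2)`, against each
gene's transcription start site (TSS; transcript start on the + strand,
transcript end on the − strand).  Nearest-TSS ties are broken by the
lexicographically smallest gene name, then the left-most TSS, making the
assignment deterministic.

## Feature windows

Window definitions (all configurable via `FeatureParams`):

| feature        | definition                                           | default |
|----------------|------------------------------------------------------|---------|
| promoter       | TSS − upstream … TSS + downstream (strand-aware)     | 2500 / 500 bp |
| genic          | TSS + downstream … transcript end                    | —       |
| exon / intron  | transcript block structure                           | —       |
| intergenic     | peak midpoint > threshold from every TSS             | 100 kb  |
| CGI            | overlap with the CpG-island track                    | —       |
| CGI-in-promoter| CGI overlapping a promoter window; peak must overlap both | —  |
| DHS-proximal   | within radius of a DNase I hypersensitive site       | 5 kb    |

Labels are not exclusive: one peak may carry several.  Because exons and
introns are labelled wherever the peak overlaps them, while the genic
*window* begins 500 bp past the TSS, `genic` is defined as (genic-window
∪ exon ∪ intron) overlap so that the implications exon ⊆ genic and
intron ⊆ genic always hold.  `intergenic` is suppressed whenever
`promoter` or `genic` applies.  Peaks between 2.5 kb and 100 kb of a TSS
that miss every window carry no positional label ("unassigned flanking"
zone).  The fate-class and background tests stratify over seven features
(intergenic, genic, exon, intron, promoter, CGI, DHS-proximal), which is
also the Bonferroni divisor m = 7.

## Consensus and differential regions

Candidate consensus regions are the merged union of all replicate peaks; a
region is kept when peaks from at least k distinct replicates overlap it
(k = 3 for triplicate 5mC capture-seq, k = 1 for single-replicate 5hmC
sets, where consensus degenerates to the replicate itself).  Differential
regions between cell lines use a presence/absence rule: a region is
condition-unique when it overlaps nothing in the other condition's
consensus set.  Read-count fold-change/FDR modelling is deliberately out
of scope — peaks, not alignments, are the input — but a coarse analogue
(ratio of mean replicate BED scores, threshold 1) can flag shared regions
with asymmetric intensity; these are reported separately so the unique
sets stay strictly non-overlapping.

## Expression tiers and association statistics

Per-gene expression is the arithmetic mean over replicate columns.  Genes
are sorted ascending and split into three contiguous tiers (low, medium,
high); remainders go to the lower tiers and boundary ties break by gene
name.  Each differential peak is assigned to its nearest-TSS gene with no
distance cap (intergenic peaks are legitimately > 100 kb out) and counted
in that gene's tier under every feature label it carries; both peak counts
and distinct marked-gene counts are kept.  Three statistics are computed
per feature:

* **Trend**: Cochran–Armitage chi-square for linear trend in marked-gene
  proportions with equally spaced scores (0, 1, 2), 1 df, no continuity
  correction, upper-tail p.  Degenerate margins return p = 1.
* **Fisher**: two-tailed Fisher exact test on the low-vs-high 2×2 table
  (sum of hypergeometric probabilities ≤ the observed table's).
* **Pearson**: r between tier index and raw peak counts (the quantity a
  per-tier abundance bar chart displays); constant counts are flagged and
  reported as r = 0.

A feature's direction is the trend sign when p < α, "nonlinear" when the
middle tier is a strict extremum, else "none".

## 5hmC fate classes and the dual-null test

Fate classes compare the normal (N) and cancer (C) lines by overlap:
absent = 5hmC(N) ∩ 5mC(C); retained = 5hmC(N) ∩ 5hmC(C); gained =
5mC(N) ∩ 5hmC(C).  A source peak overlapping several partners counts once
per class; classes are not mutually exclusive (diagnostic tallies are
kept).  Each class is tested against two nulls — random change of the
N-line mark and random placement of the C-line mark.  For each null the
observed counts are the deduplicated class peaks of that side; the
expected count in feature f is E = T·p(f) with p(f) the marginal
proportion of the corresponding *full* peak set; the statistic is the
1-df two-cell goodness-of-fit chi-square (in-feature vs not), Bonferroni
corrected over the 7 features, with direction sign(O − E).  A 2×3
chi-square compares the three classes per feature, falling back to an
exact conditional (Fisher–Freeman–Halton by enumeration) when any expected
cell drops below 1.

Same-cell-line co-incidence takes every 5mC/5hmC overlapping pair and
records the intersection span.  Technique concordance reports the
gene-level fraction (share of technique-1 genes also detected by
technique 2) and the strict same-region fraction (shared genes with a
≥ 1 bp peak-level overlap), denominated both over all technique-1 genes —
which guarantees strict ≤ gene-level — and over the shared genes.  The
random-background expectation sets each feature's expected peak proportion
to the fraction of CpG positions in that feature and applies the same
two-cell chi-square.

## Region-based enrichment

Regions map to genes by nearest TSS.  Each gene set is tested with an
upper-tail hypergeometric p for k foreground members among n foreground
genes drawn from N background genes containing K members, against a
user-supplied background (intended: all marked regions of both
conditions, no significance filter).  Benjamini–Hochberg FDR runs across
the tested sets; sets without background members are skipped and flagged.
Enrichment-map nodes are sets with p < 0.05 and FDR < 0.1; edges connect
pairs by Jaccard similarity of enriched-gene lists.  The conventional
rule (edge when J ≥ 0.25) is the default, but the inverted inequality is
selectable (`edge_when="below"`) because published figure legends
sometimes print it that way; the choice is echoed in the run log.

## ΔΔCt quantification

A capture-qPCR assay pairs bound Ct values with an input-dilution Ct.  A
dilution holding fraction f of the input amplifies log2(1/f) cycles late,
so the full-input-equivalent Ct is Ct(input) + log2(f); ΔCt = Ct(bound) −
that, ΔΔCt subtracts the reference locus per replicate, and fold =
2^(−mean ΔΔCt).  The SD is the sample SD of per-replicate folds.  The
input fraction is a parameter (default 0.027%); it cancels whenever
target and reference use the same dilution.  Identities that hold exactly:
fold(target, target) = 1, fold(ΔΔCt = −2) = 4, invariance under any
constant Ct shift.

## Synthetic data generator

The generator emulates the statistical structure of the experiment at
desk scale; defaults (2 chromosomes × 10 Mb, 300 genes, ~2000 peaks per
set, full pipeline < 1 minute) are the study conditions for all recovery
and calibration experiments.

* **Genome**: per chromosome, gene clusters alternate with 8 intergenic
  deserts of 250–400 kb so the > 100 kb intergenic zone is populated;
  gene lengths 2–20 kb with 2–8 exons; 200 CGIs (60% placed at TSSs),
  150 DHS sites, 20 000 CpG positions (40% inside CGIs).
* **Marks**: peak midpoints are drawn from per-(mark, condition)
  placement-weight vectors over {promoter, genic, CGI, DHS, intergenic};
  widths uniform 300–1500 bp (sheared-fragment to called-region scale).
  5mC sets have 3 replicates (Gaussian positional jitter SD 30 bp,
  dropout 10%); 5hmC sets have one.  The cancer condition keeps half the
  normal 5hmC peak count (global loss factor 0.5) and doubles the
  intergenic placement weight (0.48 vs 0.24) — the planted
  retention/gain excess.
* **Expression**: latent log2 expression ~ Normal(8, 2) per condition.
  Effects are per-tier odds multipliers per (mark, feature), realised as
  a shift of log2(multiplier)·σ on the latent scale for genes whose
  nearest peaks carry that mark in that feature — a monotone mapping with
  multiplier 1 ⇒ exactly no effect.  Defaults: genic 5hmC ×2.0,
  DHS-proximal 5hmC ×1.5, intergenic 5hmC ×0.5 (positive genic /
  negative intergenic coupling).  Replicate columns add Normal(0, 0.25)
  noise.

What the generator does **not** emulate: read-level coverage and peak
calling noise, copy-number effects, probe-level microarray artefacts,
inter-replicate biological variability beyond jitter/dropout, and any
sequence composition.  Passing recovery tests therefore demonstrates that
the statistical machinery detects effects of the planted kind and size in
clean interval data — not that those effect sizes are attainable from raw
reads.

## Calibration and recovery experiments

* **Null calibration** uses each test's own null: tier counts drawn
  multivariate-hypergeometrically with marks independent of expression
  (the exact Cochran–Armitage conditional null) and in-feature counts
  drawn Binomial(T, p_f) from the reference marginal.  Type-I error at
  (corrected) α = 0.05 must sit within 2 Monte-Carlo SE of nominal over
  ≥ 2000 simulations.  A zero-effect full-generator dataset is *not* a
  null for the dual-null test — overlap feature shares are products of
  two densities, not marginals — which mirrors the caveat that applies to
  the real-data version of that test; a coarse full-generator check of
  the trend test's null behaviour is kept separately.
* **Recovery**: over 200 generator seeds, the pipeline must detect the
  planted positive genic and negative intergenic 5hmC expression trends,
  and a Bonferroni-significant positive (gained, intergenic) direction
  against the normal-line marginal, in ≥ 90% of seeds each.
* **Permutation cross-check**: the analytic trend p is compared against a
  1e5-draw conditional permutation null on 20 fixed large tables using
  the mid-p convention (lattice ties half-weighted), with family-wise
  control across the 20 simultaneous Monte-Carlo comparisons (mean
  squared standardised deviation ≤ 2; per-table cap 3.3 SE).  Fisher and
  hypergeometric p-values are checked against exact-integer enumeration
  for every table with N ≤ 60 (one evaluation per symmetry orbit for the
  Fisher sweep; the invariances are themselves verified).

## Numerical choices and degenerate inputs

Chi-square variants carry no continuity correction.  `E = 0` with `O > 0`
reports p = 0 with an infinite statistic and a flag; empty fate classes
skip testing; an all-zero marked vector returns p = 1.  BH adjustment uses
`scipy.stats.false_discovery_control`.  Duplicate gene names collapse to
the longest transcript; duplicate expression rows are an error (probe
mapping is the caller's responsibility).  All tables are written with
`%.6g` float formatting, and every stochastic stage is driven by
`numpy.random.default_rng` seeded from a single run seed, so reruns are
bitwise identical.

## Known limitations

Presence/absence differential calling cannot distinguish intensity
changes within shared regions (the score-ratio screen is a coarse proxy).
The dual-null test conditions on class totals and treats features
marginally; correlated features (CGI ⊂ promoter, exon ⊂ genic) make the
Bonferroni correction conservative.  Gene-level concordance depends on
the nearest-TSS convention and will differ from exon-resolved mappings.
The enrichment stage tests over-representation among nearest genes and
inherits every caveat of region-to-gene assignment.
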