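# Methods

This note documents the model, the numerical choices, and the design
decisions behind `gxetools`, and states what the synthetic-data tests do
and do not demonstrate about real data.

## The classification model

The unit of analysis is a gene observed as replicate FPKM values in a
two-genotype x time-course grid (default 0, 6, 12, 24 hr; 3 replicates per
cell). One genotype is designated the *reference*: it is the numerator of
every genotypic log-ratio. All statistics operate on replicate means per
cell:

* `GD_t = log2(mean FPKM_ref,t / mean FPKM_alt,t)` — genotypic difference
  at time *t* (a GD of 2 is a four-fold difference);
* `ED_g,t = log2(mean FPKM_g,t / mean FPKM_g,0)` — environmental
  difference of genotype *g* at time *t* relative to the untreated control;
  `ED_g,0 = 0` identically. With this orientation an up-regulated gene has
  positive ED, which is what makes the "Up"/"Down" shape vocabulary
  meaningful; the opposite orientation, reading the ratio as control over
  treatment, is the same numbers negated and is not separately supported.

**Degenerate-expression heuristic.** Log-ratios are undefined or explosive
when one side is near zero. When either side of a comparison is below
1 FPKM, the ratio is replaced by a capped score: +5 if the denominator is
< 1 and the numerator > 5; −5 in the mirrored case; 0 when the other side
does not exceed 5 (the comparison carries no usable information). The
bounds are strict as stated — a compared entry of exactly 5 against a side
below 1 scores 0. ±5 represents an upper limit on the observable dynamic
range. Capped scores participate in classification at face value, but are
excluded from range statistics (maximum |ED| summaries and the per-time
genotypic-difference distributions), where a capped bound would
masquerade as a measurement.

**Significance.** SGD/SED flags mark GDs/EDs whose differential-test
q-value is below 0.05. The package treats the test as a pluggable
provider:

* *external*: per-contrast q-values parsed from a Cuffdiff-style
  `gene_exp.diff` table (`sample_1`/`sample_2` encoded as
  `<genotype>_<time>`), the first-class path for data that already went
  through a count-aware differential pipeline;
* *internal*: Welch's t on log2(FPKM+1) replicates, two-sided, with
  Benjamini–Hochberg correction per contrast family (all GD contrasts one
  family; each genotype's ED contrasts one family), restricted to genes
  passing the FPKM > 1 expression gate. A variance floor of
  `(0.01*mean + 0.01)^2` per side keeps the statistic finite on
  zero-variance (exact synthetic) replicates while leaving identical means
  at p = 1. The internal test is a transparent desk-scale stand-in, not a
  replacement for a dispersion-modelling RNA-seq test; its q-values will
  not numerically match such a test.

**Replicate-quality gate (CV+).** A gene passes when the replicate
coefficient of variation (sample sd over mean, raw FPKM scale) is below
0.4 in at least 7 of the 8 cells. A CV is undefined for a zero-mean cell
or fewer than 2 replicates and counts as a failing cell (conservative).

**The cascade.** Categories are assigned by ordered rules, first match
wins: Untested (no cell mean above 1 FPKM); Low-expression (max cell mean
below 4 and grand mean below 2); GxE (CV+ and some SGD more than 2.8-fold
the |GD| at another time-point — a zero GD elsewhere qualifies whenever
the SGD is nonzero, the literal reading of the fold comparison); G+E
(CV+, ≥3 SGDs, ≥1 SED in each genotype, all nonzero GDs one sign); E-only
(CV+, ≤1 SGD, ≥1 SED in each genotype); G-only (CV+, no SED for at least
one genotype, ≥3 SGDs, same sign); Constant (CV+, no SED for at least one
genotype, ≤1 SGD, no |ED| above 2); G+E-ambiguous (some |ED| > 2 and an
SGD with q < 0.001); E-ambiguous (some |ED| > 2); else Ambiguous. The
ambiguity rules deliberately skip the CV gate: a gene too erratic for the
stringent calls can still show an unmistakable environmental response.
Two deliberately resolved ambiguities: the "no ED above 2" and "some ED
above 2" bounds are applied to |ED| (down-responses qualify equally), and
SGD counting runs over all four time-points including the control. Both
are threshold-level choices surfaced in `ClassifierThresholds` rather than
buried in logic.

**Derived statistics.** `classifiable` = total − Untested −
Low-expression − Ambiguous. Shares of classifiable genes are reported for
Constant, E-type (E-only + E-ambiguous) and GxE; among genotypically
different genes (G-only + GxE + G+E + G+E-ambiguous) the environmental-
response share is (GxE + G+E + G+E-ambiguous) / total. Zero denominators
produce NaN markers, never exceptions.

## Response-curve shapes

An ED time-course is normalised by its maximum |ED| (so down-profiles
reach −1; normalising by the maximum signed ED would fold all down-shapes
onto one another) and compared to nine explicit templates over
(0, 6, 12, 24) hr:

| label | vector |
|---|---|
| Up-early | (0, 1, 1, 1) |
| Up-linear | (0, 0.25, 0.5, 1) — proportional to elapsed time |
| Up-late | (0, 0, 0, 1) |
| Down-early/linear/late | negations of the Up templates |
| Peak | (0, 1, 1, 0) |
| Trough | (0, −1, −1, 0) |
| Constant | (0, 0, 0, 0) |

The assignment is the template with the lowest sum of squared differences;
ties break by the fixed order above, making the fit deterministic. All
templates are config-overridable, and the constructors generalise to any
time grid with ≥3 points. E-type genes, which respond by definition, are
fitted against the eight non-constant templates on the *pooled* (two-
genotype mean) ED profile — their per-genotype profiles are similar by
construction of the category; GxE genes are fitted per genotype against
all nine. A profile whose maximum |ED| is below 1e-9 is degenerate: it is
Constant where that model is admissible and an error where it is not.

For GxE genes, the 9x9 joint table of (reference shape, alternate shape)
is compared to the outer product of its own marginals with a Pearson
chi-squared statistic over positive-expectation cells, df = (r−1)(c−1)
over non-empty margins; an optional label-permutation Monte-Carlo p-value
serves sparse tables. GxE genes sharing one profile in both genotypes are
summarised per time-point by the distribution (median, quartiles, 1.5-IQR
whiskers) of the displayed genotypic difference
log2(FPKM_alt / FPKM_ref) = −GD, split into All/Up/Down by the shared
profile direction, with capped values excluded.

## Subset enrichment

For subset-vs-genome comparisons the ten labels are merged into coarser
groups — E-type, G+E-type (GxE + G+E + G+E-ambiguous), G-only, Constant,
Low-expression, Ambiguous — and Untested genes are excluded from both
subset and background. The background is all labelled non-Untested genes.
The Pearson goodness-of-fit statistic is always reported with its
asymptotic p-value; when any expected cell is below 5 (typical for
gene-family-sized subsets) a Monte-Carlo p-value is computed from ≥10,000
fixed-seed draws of equal-size subsets from the background without
replacement (multivariate hypergeometric), and becomes the headline
p-value. Interval membership uses 0-based half-open arithmetic throughout
(GFF3 input is converted at the boundary); a gene belongs to a subset when
its span overlaps any interval by at least one base. GxE candidates inside
intervals are ranked by maximum |GD| with gene-id tie-breaks — a
deterministic convenience ordering, not a statistical claim.

## The synthetic-data generator

The generator emulates the study design it is meant to exercise: two
genotypes, time grid (0, 6, 12, 24) hr, 3 replicates, log2-uniform
baselines on [2, 8] (4–256 FPKM), planted effects of 3 log2 units, and
multiplicative lognormal replicate noise with
`sigma = sqrt(ln(1 + cv^2))` and a mean-1 correction, so the planted cell
mean is preserved and the empirical replicate CV converges to `noise_cv`.
Defaults: `noise_cv = 0.1` (a tight-replicate bulk RNA-seq regime well
inside the CV < 0.4 gate), `effect_size_log2 = 3` (8-fold, comfortably
detectable at 3 replicates yet biologically ordinary). The planted
category mixture (22% Constant, 22% E-only, 12% GxE, 8% each G-only and
G+E, 5% each of the two ambiguous-with-signal classes, 8% Untested, 7%
Low-expression, 3% Ambiguous) over-represents the interesting categories
relative to a real transcriptome so every rule is exercised at moderate
gene counts.

Category-specific constructions: baselines are re-drawn from
[2 + drop, 8] for genes with downward excursions so no mean crosses the
heuristic's 1-FPKM floor; Untested genes draw every replicate uniform on
[0, 1]; Low-expression genes sit flat between 1.2 and 1.8 FPKM; GxE genes
either respond in one genotype against a flat profile or with two
different shapes of equal amplitude. The three ambiguous classes scale one
replicate 3x in two cells (both genotypes, first stress time-point): the
sample CV of (m, m, 3m) is 2*sqrt(3)/5 ≈ 0.69, which fails the CV gate
*deterministically* — a noise-inflation scheme would fail to trip the 0.4
limit at small `noise_cv` and would break the noiseless-limit property.
The 3x single-replicate distortion shifts the affected cell mean by
log2(5/3) ≈ 0.74, small enough relative to the 3-unit amplitude that
planted shapes remain the SSD-nearest template.

What the generator does *not* emulate: count-level (negative binomial)
sampling and its mean-variance relation, library-size and gene-length
biases, isoform mixtures, correlated replicates, or genes whose profiles
lie genuinely between templates. Passing the recovery tests therefore
demonstrates that the implementation is faithful to its rules and that the
rules are mutually consistent at realistic noise — not that the category
or shape assignments on a real transcriptome have any particular accuracy.

## Numerical choices and degenerate inputs

* GD sign: zero GDs (|GD| ≤ 1e-9) are ignored by the same-sign predicate;
  an all-zero GD vector satisfies it vacuously.
* The replicate-concordance check between two replicate libraries (the
  "reproducibility" number) cannot reuse a two-sample test at n = 1 per
  side; the generic internal form calls a gene discordant when the
  heuristic log2 ratio of the two replicate values exceeds 1 (2-fold)
  among expression-gated genes, and accepts external per-gene q-values
  when a replicate-level differential test is available.
* Monte-Carlo p-values use the (count + 1)/(draws + 1) estimator, so they
  are never exactly 0.
* All randomness (simulation, Monte-Carlo, permutations) flows through
  explicitly seeded `numpy` generators; pipeline runs with a fixed seed
  are bitwise reproducible, and the run manifest records the seed, all
  thresholds, and a content hash of the report.
* Problem sizes in the shipped checks (2,000-gene simulations, 10,000
  randomized cascade evaluations, 10,000-draw calibrations) were chosen as
  the smallest sizes at which the binomial/multinomial error bars are
  comfortably inside the asserted tolerances.

## Known limitations

* The internal significance stand-in ignores count-level dispersion;
  external q-values are preferred whenever available.
* Template ordinates for the shape models are principled defaults (the
  linear template proportional to elapsed hours, saturating and delayed
  variants at the grid extremes) and are deliberately overridable; other
  reasonable ordinates would shift boundary assignments.
* Classification thresholds are frozen study constants by default; the
  package does not learn them from data and offers no probabilistic
  category membership.
* Enrichment assumes exchangeability of genes under the null; linkage
  between neighbouring genes inside an interval is not modelled.
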