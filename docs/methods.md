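# Methods

## Signal model

Partial alkaline hydrolysis cuts RNA phosphodiester bonds approximately
uniformly; a 2′-O-methyl group on nucleotide *i* blocks in-line attack of
the 2′-OH and protects the bond 3′ of *i*. We adopt a linear-protection
model: if a fraction *f* of molecules carry the methyl group, a fraction
*f* of potential cleavages at that bond are suppressed, so the expected
cleavage-event count at bond *i* is λ(1 − *f*ᵢ) while flanking bonds see λ.
This is the assumption under which score C is an unbiased estimator of *f*.

### Coordinates and the bond convention

Positions and bonds are 1-based; bond *i* lies between nucleotides *i* and
*i* + 1, so a molecule of length *L* has bonds 1..*L* − 1 and the score for
a site at position *p* is read at bond *p*. A cleavage at bond *i* is
observed either as a 5′ read end at position *i* + 1 (the downstream
fragment) or as a 3′ read end at position *i* (the upstream fragment); end
counting sums both into the per-bond cleavage profile, so each cleavage can
be witnessed up to twice. Counting only one end type is available
(`--ends five|three`) as a sensitivity switch. Read ends at the first/last
nucleotide of a molecule correspond to transcript termini, not hydrolysis,
and are tallied separately. For reverse-strand alignments the biological 5′
end is the rightmost aligned position; soft-clipped bases are outside the
aligned span because clipping reflects trimming, not cleavage.

## Score C parameterization

The flanking average uses half-width *l* = 6 with linear-decay weights
*w*ⱼ = *l* − *j* + 1, each side normalized by the weights actually present
(windows truncate at molecule ends; a bond with an empty flank on either
side is invalid). The left/right means are averaged, not pooled, so a
coverage gradient across the site biases the baseline less. Raw values
below 0 (sampling noise at unmethylated sites) clip to 0 and the score is
capped at 1, matching the bounded "fraction methylated" scale. The local
coverage μ gates validity: below `min_coverage` (default 10 cleavage
events) a site is reported but flagged invalid. Both the half-width and the
weights are exposed because published variants of the score differ in
window detail; the combination above is fixed here so results are exactly
reproducible and testable against a direct-summation oracle.

## End-nucleotide bias correction

Ligation and barcode chemistry can prefer particular 5′ nucleotides. The
optional correction estimates, over all non-site bonds, the mean cleavage
count per identity of the bond's 5′ nucleotide; factor(b) = grand mean /
class mean, normalized to mean 1, and counts at b-bonds are multiplied by
factor(b) (counts become reals from that point). Classes with fewer than 50
usable bonds fall back to factor 1 with a warning. Correction is opt-in
(`--bias-correct`), reflecting that it is only warranted when a library
shows the bias.

## SNORD quantification

Primary mapped reads passing the same length/MAPQ filters are tallied per
SNORD reference; RPKM = count × 10⁹ / (length × total). The denominator
defaults to all retained mapped reads library-wide (rRNA + SNORD), because
the libraries are whole-cell; `--denominator snord` restricts it. Group
summaries report mean ± SEM (sd/√n, absent at n = 1). Multi-mapping among
near-identical paralogs is resolved by the aligner's primary-alignment
choice; only primary records are counted, which keeps the tally
deterministic for a given input file.

## Misincorporation

Mismatch fraction at a position = non-reference read bases / aligned bases
covering it, over primary reads passing the standard filters. Deletions
count as mismatches by default (a reverse-transcriptase drop or skip is
itself a modification signal); insertions are ignored by default. Both are
flags. Replicate fractions are summarized by the sample median with a
distribution-free confidence interval from order statistics: trimming k
from each tail is admissible when P[Binomial(n, ½) ≤ k − 1] ≤ (1 − level)/2,
and the widest admissible trimming gives the interval; for n = 15 at 95%
this is the 4th and 12th order statistics. When even (min, max) cannot
reach nominal coverage the full range is returned with a warning. The
order-statistic interval was chosen over the bootstrap because it is
deterministic and assumption-free; a seeded percentile bootstrap is
available behind `method="bootstrap"`.

## Differential statistics

ΔRMS = sample replicate-mean score − control-group mean, on valid records
only. Significance per (sample, site) comes from a two-tailed unpaired
Student's *t*-test (pooled variance, df = nA + nB − 2) of the sample's
replicates against the pooled replicates of all control samples; Welch is
available behind a flag but pooled is the default because the equal-variance
test is the stated analysis. Classes use strict thresholds: \* p < 0.05,
\*\* p < 0.01, \*\*\* p < 0.001. Degenerate cases: n < 2 in a group gives a
flagged undefined result; two zero-variance groups with equal means give
t = 0, p = 1 by convention, with unequal means t = ±∞, p = 0. No
multiple-testing correction is applied by default (per-site asterisks are
the reported quantity); a Benjamini–Hochberg column can be added by users
from the p column and is deliberately not the default.

The deviation-from-average table centers each sample's per-site mean on the
panel mean (deviations sum to zero per site) and flags samples by a
one-vs-rest *t*-test — this sample's replicates against all other samples'
replicates — the documented construction for "significantly above/below
average", which the source analysis leaves open.

Spearman correlations use mid-ranks for ties. The two-sided p-value is
exact for n ≤ 10 — full enumeration of the n! pairings of the rank vectors
(vectorized in chunks; ρ is affine in Σ rxᵢ·ry<sub>π(i)</sub> so only that
sum varies) — and the *t* approximation with n − 2 df otherwise. ΔΔCq fold
change is 2^−[(Cq_t,s − Cq_r,s) − (Cq_t,c − Cq_r,c)], i.e. double
normalization to a reference gene and a control sample.

Biological and technical triplicates are treated identically as
within-group replicates.

## Simulator

Two generative levels:

* **Per-bond Poisson** (`simulate_end_counts`): cleavage[i] ~
  Poisson(λ(1 − fᵢ)), independent across bonds, optionally scaled by
  per-5′-nucleotide bias multipliers and gamma-mixed per bond for replicate
  overdispersion (CV parameter, default 0 — real libraries' overdispersion
  is unknown, so it is a parameter, not an assertion). Fast; used for
  scoring and statistics validation.
* **Fragment-level** (`simulate_reads`): each molecule copy is cut at bond
  *k* with probability p(1 − fₖ) (p defaults to 2/(min+max fragment
  length), giving a mean fragment near the window center); fragments inside
  the size window (default 20–40 nt) are emitted as perfectly aligned SAM
  records until the requested count is reached. Targeted misincorporation
  substitutes a random non-reference base at annotated positions with the
  stated rate; SNORD reads are drawn by abundance weight with uniform
  placement. The returned truth tallies (per-position end arrays, per-site
  depth/mismatch counts, per-SNORD counts) let end counting, SNORD
  quantification and misincorporation be validated *exactly*, read for
  read.

`simulate_cohort` adds the study design: a control group at the base
fractions and case groups with per-site additive effects, scaled per sample
by a severity drawn uniformly from (0.4, 1.6) (mean 1) to model inter-tumor
heterogeneity. The Ki-67-like labeling index is generated as
clip(20 + 15 · severity · mean|effect| · 10 + N(0, 5), 0, 100) — a stated
monotone function of the sample's true summed methylation change — so
correlation analyses have a planted, known-sign signal.

Simulated references place sites at least 2·half-width + 1 nucleotides
apart so scoring windows never overlap a neighboring site, and at least
half-width + 1 from the ends. All randomness flows from explicit seeds;
identical seeds give byte-identical outputs.

### What the simulator does and does not emulate

It emulates methylation-dependent cleavage protection, size selection,
Poisson sampling depth, replicate noise (optionally overdispersed),
group-level effects, SNORD abundance and targeted misincorporation. It does
not model sequencing error outside the targeted positions, adapter or
quality artifacts, alignment ambiguity, or position-dependent cleavage
preferences beyond the 5′-nucleotide bias. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not robustness to every artifact of real libraries.

## Validation scale and numerical choices

The standard validation setup is a 2000-nt reference with 40 sites,
f ~ U(0, 1), λ = 500, 3 replicates per group; at this depth score recovery
is RMSE ≈ 0.03–0.04 with rank correlation > 0.98, the null 3v3 *t*-test is
calibrated near 0.05, and an injected Δ = −0.2 is detected essentially
always. Calibration checks use 50 independent two-group cohorts (2000
site-tests); misincorporation recovery uses ~70 000 fragments on a 150-nt
reference to reach ≥10⁴ depth at the target site; median-CI coverage uses
2000 draws of n = 15. Score-C equivalence to the direct-summation oracle is
asserted to 1e−12; Spearman's exact branch is asserted against full
enumeration to 1e−12.

## Known limitations

* The score assumes flanking bonds are unmethylated background; closely
  spaced real sites (closer than the window half-width) bias each other's
  baseline. The simulator avoids this by construction; on real data, reduce
  the half-width at clustered sites.
* Fractions near 0 or 1 are clipped, so replicate distributions at extreme
  sites are non-normal; the *t*-test there is conservative rather than
  anti-conservative, but confidence in exact p-values at extreme
  stoichiometries is limited.
* RPKM inherits the usual compositional caveats; it is comparable within a
  library set normalized the same way, not an absolute abundance.
* The per-(sample, site) test pools all control samples' replicates;
  control inter-sample variance is therefore counted as replicate noise.
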