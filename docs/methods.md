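# Methods

## Sequence statistics

All sequence statistics operate on alignments over the strict alphabet
{A, C, G, T, N, -}. IUPAC ambiguity codes are rejected at import: different
haplotype-collapsing programs disagree on how to treat them, and silently
coercing them to N changes haplotype counts. Under the default
`complete_sites` policy, every column containing a gap or N in *any*
sequence is removed before haplotypes are defined and before S, π and k̂
(mean pairwise differences) are computed, so the per-group summary
statistics are mutually consistent; the `pairwise` policy compares each
sequence pair over its own non-gap/N sites and is the convention used for
distance matrices.

Haplotype diversity uses Nei's unbiased estimator Hd = n/(n−1)·(1 − Σp²).
Tajima's D is the 1989 statistic with its canonical constants a₁…e₂
recomputed from n at each call; D is undefined (returned as `None`) when
S = 0. Fu's Fs takes θ = k̂ and computes S′ = Pr(K ≥ k₀) under the Ewens
sampling distribution, Pr(K = k) = |s(n,k)| θᵏ/(θ)₍ₙ₎, with unsigned
Stirling numbers of the first kind evaluated by the triangular recurrence
entirely in log space; Fs = ln(S′/(1−S′)). When S′ saturates to 0 or 1 in
double precision the statistic is signalled as ∓∞ rather than silently
clipped. Undefined statistics propagate as explicit `None` markers
throughout.

## AMOVA and differentiation

AMOVA partitions the sum of squared pairwise distances at three levels
(among groups / among populations within groups / within populations) with
the classical unequal-sample-size coefficients; the default distance is raw
pairwise differences, the usual substrate for haplotype data, with TN93 or
p-distance matrices available. Negative variance components are reported as
computed (a truncation flag is available). Permutation schemes follow the
standard design: Φ_CT permutes whole populations among groups (preserving
the number of populations per group), Φ_SC permutes individuals among
populations within their group, Φ_ST permutes individuals among all
populations. P-values use the add-one rule (count+1)/(n_perm+1), so p = 0 is
impossible; defaults are 20,000 permutations for AMOVA and 10,000 for
pairwise tests. With a single group (or no group layer) a two-level AMOVA is
returned with the among-group fields set to `None`; with exactly one
population per group the design degenerates gracefully (σ²_b = 0) and Φ_CT
equals the pairwise Φ_ST — a property the tests assert.

Gene flow uses the haploid/maternal island-model convention
Nm = (1 − F_ST)/(2 F_ST), appropriate for a maternally inherited marker;
F_ST ≤ 0 maps to an infinite-flow marker and F_ST ≥ 1 to 0.

The grouping search runs AMOVA per candidate pop→group map and ranks by
Φ_CT descending, breaking ties toward fewer groups and then input order;
candidates that error or have undefined Φ_CT are recorded and sink to the
bottom rather than aborting the search.

## Divergence dating

TN93 distances are computed per pair from the two transition proportions,
the transversion proportion and the base frequencies pooled over the two
sequences being compared (gap/N sites skipped pairwise). Zero base
frequencies make individual correction terms vanish in the limit and are
handled that way; a non-positive logarithm argument (saturation) yields a
NaN marker, and saturated pairs are excluded from group means with a count.
Note that toy sequences with very skewed composition can saturate at modest
divergence because the correction denominators scale with 2·g_R·g_Y.

The net between-group distance is D = Pi_XY − (Pi_X + Pi_Y)/2 (unweighted
means over cross pairs and within-group pairs), which removes the expected
contribution of ancestral polymorphism. Confidence intervals resample
alignment columns with replacement (site bootstrap, default 500 replicates)
and report the 2.5–97.5 percentile interval of D; bootstrap replicates that
saturate are skipped.

The clock is parameterized by the *between-lineage* divergence rate,
default 0.02 substitutions/site/My (the conventional "2% rule" for avian
mtDNA, i.e. 1%/My per lineage), so t = D/rate = D/(2µ) with per-lineage
µ = 0.01; the pipeline log prints both conventions once per run. Negative D
(within-group diversity exceeding between-group divergence) has no
meaningful clock date and returns `None` with a warning.

## Maximum-entropy niche model

The niche model is a deliberately minimal exponential-family (Gibbs) model.
Features are a z-standardized linear and quadratic term per layer
(standardization statistics from the background sample); the coefficient
vector maximizes

    mean_presences(λ·f) − log mean_background(exp(λ·f)) − β‖λ‖₁

which is convex; the L1 term is handled by the positive/negative split so
L-BFGS-B applies. The background is a uniform sample of unmasked cells
(default 10,000, all cells if fewer); presences can optionally be added to
the background. Convergence tolerance defaults to 10⁻⁵. The raw output is
the normalized density exp(λ·f)/Z over unmasked cells (sums to 1); the
logistic output is τ·e^H·q/(1 + τ·e^H·q) with τ = 0.5 and H the entropy of
the raw distribution — a strictly monotone transform, so AUC and LPT maps
are identical under either form. Hinge/threshold features, clamping and
replicate scheduling of full Maxent are intentionally not reproduced: the
role of the model here is a fast, refittable suitability surface for
overlap randomization.

Points map to cells by flooring against the geotransform; boundary points go
to the higher-index cell. Occurrence thinning is greedy in input order with
a strictly-less-than drop rule (points at exactly the separation distance
are kept; a 10⁻⁹-degree tolerance absorbs float round-off). Layer pruning
computes Pearson r over unmasked cells for all pairs and iteratively drops
the lower-priority member of the most-correlated pair above the threshold
(default 0.8); the priority ordering is user input, defaulting to input
order — the intended use is to prefer seasonality/extreme variables over
means. Constant layers have undefined r and are kept with a warning.

AUC is the rank-based (Mann–Whitney) probability that a presence outranks a
background point, ties counted ½; constant predictions degenerate to 0.5
with a warning. The train/test split defaults to 25% training — an unusual
but deliberate convention, exposed as a parameter. Jackknife importance
refits only-this-layer and all-but-this-layer models on one fixed split and
background and reports both AUC columns.

## Niche overlap and randomization tests

Suitability surfaces are renormalized to densities over the *shared*
unmasked region before comparison; Schoener's D = 1 − ½Σ|p−q| and
I = 1 − ½Σ(√p−√q)². The identity test pools both occurrence sets, randomly
repartitions them into the original sizes, refits both models and recomputes
D and I per pseudoreplicate (default 100); it is lower-tailed — identity is
rejected when observed overlap is below the null. The background test draws
|B| points uniformly from B's accessible region, refits, and compares
overlap with A's model; it is two-tailed, since both "more similar than
expected" and "more divergent" are meaningful, and the pair wrapper runs
both directions. The accessible region defaults to the bounding rectangle of
the points buffered by 1.0° intersected with the grid mask — "the geographic
range of the other taxon" has no unique operational definition, so the
region is an explicit input with this documented default. All refits inside
a test reuse the observed fits' background sample and optimizer settings, so
null variation reflects only the point assignment; with the observed
partition exchangeable under H0 this makes the identity test exactly sized
up to Monte-Carlo error. Empirical p-values use the add-one rank rule;
two-tailed p = 2·min(lower, upper) capped at 1. Everything is bit-reproducible
under a fixed seed.

## Synthetic data

Sequences come from a structured coalescent without migration on a binary
population-split tree with times in My. Within each deme, lineages coalesce
at rate C(k,2)/ν where ν is the coalescent time scale (female effective
size × generation time, in My; mtDNA is haploid and maternally inherited);
survivors merge into the ancestral deme at each split time. Branches then
evolve sites by the exact transition-probability matrix exp(Qµt) (JC by
default; TN93 with chosen frequencies and the two transition ratios
optionally), with the rate matrix normalized to one expected substitution
per unit µt, so a split T My ago yields E[D] = 2µT and the clock estimator
t = D/0.02 is unbiased for µ = 0.01. Defaults: ν = 0.05 My (per-site
θ = 2νµ = 10⁻³, in the range typical of intraspecific mtDNA), µ = 0.01/My,
2,000 sites.

Environment layers are white noise passed through repeated box blurs
(kernel width 2·correlation_length+1, 3 passes, wrap-around boundaries) and
standardized to mean 0/sd 1; options add pure-noise layers and a
near-duplicate layer (for pruning tests). The true suitability is
logistic(α + Σβ·layer); identical-niche lineage pairs share coefficients
exactly, which is what the identity-test calibration uses. The default
single-driver truth is a narrow-band specialist, logistic(−10 + 8·z),
occupying roughly the top decile of the gradient: weaker responses leave so
much moderately suitable area that even scoring with the *true* suitability
cannot discriminate presences from background at AUC > 0.9, i.e. they are
not an "excellent performance" regime for any model. Occurrences sample
cells proportional to truth (optionally within a region) and jitter
uniformly within the cell.

What the generator does *not* emulate: recombination and post-split
migration (lineages never exchange after a split, matching a strict
vicariance scenario), rate variation among sites, realistic bioclimatic
covariance structure, and spatial sampling bias in occurrences. Passing tests therefore demonstrate
correctness of the estimators under their own model assumptions, not
robustness to the messiness of real data.

## Problem sizes and numerical choices

The stochastic test batteries use sizes chosen to keep Monte-Carlo error
well inside the asserted tolerances while remaining desk-scale: 220 neutral
replicates for the Tajima's D calibration (mean within 3 SE of 0), 50
replicates per true split time for clock recovery (median within 25%), 100
synthetic identical-niche datasets with 50 pseudoreplicates each for the
identity-test size check (rejection rate in [0.01, 0.12] at α = 0.05), and a
30×30 grid with a 256-cell background for randomization-test fits (the
convex fit has 4–6 active features, so small backgrounds are adequate).
Permutation p-values are compared with a 10⁻¹² slack on the ≥-observed rule
to make tie handling deterministic. The optimizer treats the L-BFGS-B
objective tolerance as the convergence threshold and warns, with the final
gradient norm, if the iteration cap (default 500) is hit.

## Known limitations

* AMOVA p-values for Φ_CT with two populations in two groups are always 1:
  there is only one distinct permutation of populations among groups. This
  is inherent to the permutation design, not a defect.
* TN93 is undefined (NaN) past saturation and for change types whose
  frequency product is zero yet observed; group means exclude such pairs and
  log the count rather than failing the analysis.
* The ENM is not Maxent bit-for-bit (no hinge features, clamping or
  replicate averaging beyond a simple AUC-averaging wrapper); comparisons
  with Maxent outputs should be qualitative.
* The background-test region default (buffered bounding rectangle) is a
  declared stand-in for "the taxon's geographic range"; supply an explicit
  rectangle or mask raster when a better definition exists.
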