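# Methods

This note documents the models, procedures and design choices behind
`fecaldiet`. It is the place to look when a default needs justifying or a
degenerate input needs a defined outcome.

## The analysis problem

Faecal DNA metabarcoding estimates a consumer's diet from amplicon read
counts assigned to food taxa. Reads are amplified in triplicate PCR from
each faecal extract, so the raw observation is a long table of
(sample, replicate, marker, taxon, reads). Two libraries (markers) are
carried through the pipeline — a plant marker and a vertebrate marker —
and pooled onto a single per-sample composition. The questions the
pipeline answers: how much of the diet is anthropogenic, per sample and
per social group; how well the molecular readout agrees with direct
behavioural observation; and how dietary similarity between samples is
structured by group, sex, age and relatedness.

## Quality control and relative read abundance

1. **Minimum-reads filter.** A taxon with fewer than 10 reads in a library
   (totalled over all samples and replicates of that marker) is removed.
   "Fewer than" is strict: exactly 10 reads survive. The threshold is a
   parameter (`min_reads`).
2. **Replicate-consensus filter.** Within a sample, a taxon detected
   (nonzero reads) in fewer than 2 of the 3 PCR replicates is removed:
   single-replicate detections are the signature of contamination and PCR
   artefacts. Samples with fewer than 2 successful replicates (replicates
   with any reads) are excluded entirely — the consensus rule is undefined
   for them — and logged with the reason `insufficient replicates`.
3. **Event-date exclusion.** Reads of a named taxon are removed from
   samples collected exactly one day after listed provisioning events
   (e.g. peanuts used as experimental food rewards appear transiently in
   next-day faeces).
4. **RRA.** Within each (sample, replicate), relative read abundance is
   `reads / total reads`, with plant and vertebrate markers pooled onto
   one simplex first. Replicates with zero total reads are dropped.
5. **Merge.** Per-sample RRA is the arithmetic mean over contributing
   replicates, a taxon absent from a replicate counting as 0, followed by
   renormalization to sum 1. Renormalization is needed because
   zero-imputation pulls row sums below 1 exactly when replicates disagree;
   it is exposed as `merge.renormalize` since "mean RRA" alone does not
   determine it. Marker pooling is likewise exposed (`markers.pool`);
   pooling before RRA was chosen so natural and anthropogenic percentages
   of both food kingdoms add to 100% of one composition.

All filters only remove rows (monotone), and the default order is the
order above.

## Provenance scoring

Each taxon carries a score s ∈ {0, 0.5, 1}: confirmed natural, uncertain,
confirmed anthropogenic. The per-sample anthropogenic percentage is
100·Σ s_t·rra_t / Σ rra_t. It decomposes as A + U/2 where N, U, A are the
RRA masses (in %) of score-0, score-0.5 and score-1 taxa; the partition
(N, U, A) is reported per sample and per group. Group summaries weight
samples equally: RRA already normalizes sequencing depth, so re-weighting
by reads would reintroduce depth artefacts.

Because score-1 mass is only a floor on the true anthropogenic share,
`allocate_uncertain` reports an interval: rule `half` adds U/2 to the
floor, rule `proportional` splits U like the resolved mass
(A + U·A/(A+N)). Neither rule is privileged; the choice is the analyst's
statement about where uncertain taxa probably came from.

Group density plots use a Gaussian KDE with Silverman bandwidth on the
percentage scale, evaluated on a fixed grid over [0, 100] and renormalized
to integrate to 1 on the grid; a zero-variance group falls back to a
narrow (sd 0.5 point) kernel instead of failing.

## Method comparison

Focal-follow records measure diet as seconds of active feeding per taxon.
Both readouts are converted to proportions over their full taxon sets and
harmonized at genus level or above (species collapse to their genus; the
observational data cannot resolve species). Agreement is summarized by

- a Venn partition of detected taxa (shared / observation-only /
  eDNA-only), optionally split by food class;
- per-period breakdowns over consecutive half-open blocks of 33/32/33/32
  days (half-open so boundary dates belong to exactly one period);
- OLS of eDNA proportions on observational proportions over the taxa
  detected by both methods, raw and logit-transformed
  (logit p = log(p/(1−p))). Proportions of exactly 0 or 1 are clamped to
  [1e-6, 1−1e-6] before the logit. Observation is the predictor and eDNA
  the response; matching never renormalizes, so proportions stay relative
  to the full diet.

## Similarity analysis

Bray-Curtis dissimilarity d(x,y) = Σ|x−y| / Σ(x+y) between per-sample RRA
rows; NMDS (SMACOF, lowest stress over random restarts, Kruskal stress-1)
for visualisation; one-way PERMANOVA for group/month structure with the
add-one permutation p-value (1 + #{F* ≥ F}) / (1 + n_perm).

Each unordered within-group sample pair becomes one model row:
similarity = 1 − d, z-standardized over all retained pairs (the
"standardised similarity"); relationship category Same individual /
Mother-Infant / Other; unordered covariate combos (sex FF/FM/MM, age
adult-adult/adult-juvenile/juvenile-juvenile). Cross-group pairs are
available via `scope="all"` and are labelled group `between`. Two Gaussian
mixed models are specified:

    Similarity-Z ~ Group*Sex*Age + (1|Individuals) + (1|Date) + (1|Relationship)
    Similarity-Z ~ Group*Relationship + (1|Individuals) + (1|Date)

### Random intercepts for dyadic rows

A pairwise row belongs to two individuals and two dates, so
"(1|Individuals)" is ambiguous. Two encodings are implemented:

- **membership** (default): each individual (and each date) of the dyad
  contributes its own intercept, all levels of a factor sharing one
  variance — the classic multiple-membership encoding. Dyads sharing a
  member are correlated through the shared intercept, which is exactly the
  dependence pairwise data exhibit.
- **pair**: the unordered id pair encoded as a single factor. Simpler, but
  dyads sharing one member get independent intercepts, so member-sharing
  correlation leaks into the residual. In null simulations this made the
  Group test strongly anticonservative (rejection ≈ 0.35 at α = 0.05),
  which is why membership is the default.

Numerical fitting is delegated to statsmodels `MixedLM` (variance
components under a single all-encompassing group), by maximum likelihood
so that likelihood-ratio tests and AIC/BIC are comparable across nested
fits.

### Term tests

Per-term type-II likelihood-ratio tests: the reduced model holds every
term not containing the tested factors, the full model adds the term;
the statistic is 2Δll with df the change in fixed-effect rank. Terms that
are constant across all dyads of each individual (Group, under
within-group scope) are *between-individual* effects: the number of
independent units is the number of individuals, not the number of dyads,
and the asymptotic χ² reference is anticonservative in small studies. For
such terms the p-value therefore uses an F(df, ν) reference with a
containment denominator df, ν = #individuals − rank of the
individual-level fixed design — the same small-sample guard lmerTest- and
nlme-style df corrections provide. Within-individual terms (Relationship,
Sex, Age and interactions involving them) keep the χ² reference. Reported
model-comparison indices: AIC, BIC, RMSE of residuals, and
1 − var(resid)/var(y) as a simple R².

Known limitation: neither encoding is a full dyadic-dependence model
(no MRQAP or multiple-membership-with-interaction corrections). In large
designs the additive membership approximation can still leave some
member-sharing correlation unabsorbed, so between-individual term tests
are best interpreted at the calibrated design sizes documented below.

## Synthetic data generator

A Dirichlet-multinomial hierarchy, chosen as the simplest generative model
exhibiting the analysed structure (group, individual and matriline
compositional effects):

- taxa: 20 natural (score 0, two of them on the vertebrate marker),
  8 uncertain (0.5), 5 anthropogenic (1), plus 4 contaminant taxa that are
  scored natural but never eaten;
- group base composition ~ Dirichlet(α_g · target), α_g = 5000, where the
  target gives group 1 a 5% anthropogenic share and group 2
  5% + shift (default shift 10 points), uncertain mass fixed at 12%, and
  mildly uneven within-class weights for a realistic dominance structure;
- individual profile ~ Dirichlet(τ · group base), τ = 100; infant profile
  ~ Dirichlet(κ · mother profile), κ = 200, so infants resemble their
  mothers more than random group mates;
- default census: 2 groups × 12 individuals, 3 mother-infant pairs per
  group, 3 samples per individual on shared collection days (every 4 days
  over a 130-day window), never two samples of one individual per day;
- reads: per (sample, replicate) Multinomial(20 000, profile) over 3
  replicates; a replicate fails (zeroed) with probability 0.02; with
  probability 0.05 a contaminant taxon (uniform 50–500 reads) is injected
  into exactly one replicate, never the same taxon twice in a sample, and
  logged in the ground truth — so the consensus filter's removal rate is
  an exact, assertable quantity;
- observations: per individual, 3600 feeding seconds allocated
  Multinomial(seconds, profile·h·δ / Σ) with per-taxon handling-time bias
  h and detectability δ, spread over 4 focal days; food class follows the
  provenance score (0.5 → unknown). By default the readout is deliberately
  biased, as field observation is: one natural taxon is over-observed at
  h = 3 and one anthropogenic taxon at h = 2 (long handling time), while
  one natural and one uncertain taxon are under-detected at δ = 0.25 and
  0.5 (eaten out of sight); all other taxa have h = δ = 1.

What the generator does *not* emulate: seasonal phenology, spatial
structure and home ranges, taxonomic mis-assignment, index hopping or
cross-sample contamination gradients, and overdispersion beyond the
Dirichlet hierarchy (no taxon-specific amplification bias). Passing
recovery tests therefore show the pipeline's logic is correct under a
plausible compositional model, not that real studies achieve these error
rates.

## Validation conditions and problem sizes

- **Oracle equivalence**: naive loop reimplementations of the filters,
  RRA, anthropogenic percentage and Bray-Curtis agree with the pipeline to
  1e-12 on 100 random fixtures.
- **PERMANOVA calibration**: 500 structureless datasets (20 samples, 8
  taxa, balanced labels, 999 permutations); rejection at α = 0.05 must
  stay within [0.03, 0.07].
- **Parameter recovery** (generator defaults, 100 runs): estimated group
  anthropogenic difference within 3 points of the configured 10-point
  shift in ≥ 90% of runs; mean-similarity ordering Same individual >
  Mother-Infant > Other in ≥ 90%; injected contaminants removed at 100%.
- **Model-term calibration**: a scaled-down design (2 groups × 8
  individuals, 2 mother-infant pairs per group, 2 samples per individual,
  2000 reads per replicate) keeps each mixed-model fit fast enough to
  repeat hundreds of times. The null configuration removes the group
  effect (zero shift, group bases pinned to the shared target at
  α_g = 10⁶) while keeping all within-individual structure; Group-term
  rejection must lie in [0.02, 0.08] over 200 simulations, and the
  Relationship term must reject in ≥ 90% of 100 simulations at the
  generator's own effect (samples of one individual share a profile;
  infants track mothers at κ = 200).

Numerical tolerances elsewhere: RRA rows sum to 1 within 1e-9; partitions
sum to 100 within 1e-9; densities integrate to 1 within 1e-3 on their
grid; NMDS uses SMACOF convergence eps 1e-12 so exactly embeddable
configurations reach stress < 1e-6.
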