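# Methods

`moltsucc` analyzes how segment-specific gut bacterial communities
(foregut, midgut, hindgut) reassemble after a crustacean molts. Samples are
ASV count tables collected at fixed hours postmolt plus a premolt control
("CK"), with candidate source habitats (carapace surface, rearing water,
gill, hepatopancreas) sampled alongside and a pathway relative-abundance
table predicted upstream (e.g. by PICRUSt2) consumed as-is. This note
records the models actually implemented, their assumptions, the defaults
that matter, and what the synthetic benchmark does and does not show.

## Data model

Counts are integers; relative abundances are a distinct type; the two are
never mixed implicitly. A premolt CK sample carries no postmolt clock time —
CK is a flag, not a negative time. Samples with zero total reads are
rejected at load, not imputed. Rarefaction is subsampling without
replacement (multivariate hypergeometric), dropping samples below the target
depth with a warning; it never invents counts for absent taxa.

## Turnover relative to the 0 h baseline

Two complementary classifications, applied per gut segment and comparison
group:

* **Presence ("emerged"/"lost").** An ASV is *emerged* when it has zero
  counts in every 0 h replicate and at least `min_count` reads (default 2)
  in at least `min_prevalence` (default 50%) of the comparison group's
  replicates. *Lost* is the mirror image with the premolt CK group as the
  comparison. The thresholds are explicit configuration, not a claim about
  any particular study's definition. Raising `min_count` can only shrink the
  emerged set.
* **Differential abundance ("enriched"/"depleted").** Two-sided Wilcoxon
  rank-sum per ASV on relative abundances (exact null up to 8 replicates per
  side), Benjamini–Hochberg correction across tested ASVs, and a fold filter
  (default 2×) on group-mean relative abundances with a pseudo-fraction of
  1e-6 guarding zero baselines. With two groups the rank-sum test is the
  two-sample equivalent of the Kruskal–Wallis test used for the multi-group
  panels. Compositional (CLR-based) differential abundance is deliberately
  out of scope.

## Diversity and dissimilarity

Richness is the count of observed ASVs; Shannon entropy is reported in nats
(natural log; the base is configurable). Bray–Curtis dissimilarity
`d(x, y) = Σ|x−y| / Σ(x+y)` is computed on row-normalized abundances.

The *mixed gut* is a mock whole-gut sample: for each crab and time point
with all three segment samples present, segment counts are summed
element-wise (the count-level equivalent of merging sequencing reads) and
optionally rarefied to a common depth so mixed and segment samples stay
comparable. Incomplete triplets are skipped with a warning.

Distance decay regresses within-habitat pairwise dissimilarity on the
absolute time interval by ordinary least squares; significance comes from
permuting sample time labels within habitat (999 permutations by default,
+1 smoothing). Segment-versus-whole relationships are per-segment simple
linear regressions of a reference metric series on the segment's series,
ranked by r².

## Tipping points

The community's displacement from baseline is summarized per sample as the
mean Bray–Curtis dissimilarity to all 0 h replicates of the same habitat.
A continuous two-segment ("hinge") model

    y = a + b·t + c·max(t − τ, 0)

is fitted by exhaustive grid search over τ (default step 0.1 h, between the
2nd and penultimate distinct sampling times), so the estimate is continuous
rather than snapped to sampling hours. Because τ is estimated, the
classical F test does not apply; significance against the single-line model
uses a residual bootstrap under the null (resampled linear-fit residuals,
inflated by √(n/(n−p)) for the lost degrees of freedom), and the τ
confidence interval is a percentile bootstrap of the hinge fit. The grid
search is vectorized (per-τ orthonormal bases applied to all bootstrap
responses at once), so 200-replicate bootstraps cost milliseconds. "No
tipping point" is reported as `significant=False`; τ is then not propagated
to staging.

## Co-occurrence networks

Per group, taxa are prevalence-filtered (default ≥ 1/3 of samples),
Spearman correlations are computed for all retained pairs, BH-corrected
together, and edges kept when |ρ| ≥ 0.6 and q < 0.05 (both configurable;
the correlation sign is kept as an edge attribute, but topology uses the
unweighted graph). The attribute panel: node/edge counts, average degree,
mean shortest-path length on the largest component, mean local clustering
(degree < 2 contributes 0), greedy modularity with node order fixed by
sorted id for reproducible tie-breaks, random-removal robustness, and
single-node vulnerability.

*Robustness* ("network stability") is the mean, over seeded random trials,
of the largest-component fraction among nodes remaining after removing a
fixed fraction (default 50%) of nodes — 1 for complete graphs.
*Vulnerability* is the maximal relative drop in global efficiency (mean
inverse shortest-path length over ordered pairs) caused by deleting a single
node. The leave-one-out computation is exact but decomposed by connected
component, since removing a node only re-routes paths inside its own
component.

## Community and functional stability

Stability uses the average variation degree (AVD): for every taxon with
nonzero variance over a reference sample set, each replicate contributes the
standardized absolute deviation from the *slice mean*, scaled by the
*reference* population standard deviation; AVD is the mean over
taxa × replicates and the reported stability index is 1/(1+AVD) ∈ (0, 1].
Centering on the slice mean makes identical replicates exactly maximally
stable; scaling by the habitat-wide σ keeps per-time-point values on a
common scale along a succession series. AVD is scale-free per taxon.

Multifunctionality is the averaging flavor: z-score each pathway across
samples (zero-variance pathways dropped with a warning) and report the
per-sample mean z; scores average to zero over the standardization set by
construction. Threshold-based multifunctionality is deliberately omitted.
Functional stability is AVD applied to the pathway table.

Taxon–function screening is Spearman over a (taxon × pathway) grid with BH
correction across the whole grid. Group comparisons use a Kruskal–Wallis
omnibus followed by pairwise rank-sum tests with BH; compact letters are the
maximal cliques of the non-significance graph (deterministic ordering), so
every non-significant pair shares a letter and no significant pair does.

## Staging and key taxa

The tipping points motivate a stage mark (default 24 h): postmolt samples at
or before the mark are "early", later ones "late", CK excluded. A random
forest ranks taxa by impurity importance; the error of each panel size n
(Fibonacci-style grid 1, 2, 3, 5, 8, … capped at the taxon count) is
estimated by stratified 10-fold cross-validation in which the ranking is
recomputed inside each training fold before truncation — the curve is
leakage-free. The split is repeated (default 2 repeats) with fresh shuffles
to smooth the curve against fold-assignment noise. The selected panel is
the smallest n attaining the minimum mean CV error; a positive
`se_multiplier` recovers the usual 1-standard-error parsimony rule. The
minimum-error default is the choice consistent with biomarker panels of a
few dozen taxa; the 1-s.e. rule collapses to 1–8 taxa whenever any single
taxon is individually strong. Forest sizes are split between the final
ranking forest (default 1000 trees) and the in-fold forests
(`cv_n_trees`), which are refit dozens of times.

Selected taxa are partitioned into *early*/*late* clusters by rank-sum + BH
on stage means (failing taxa, and all non-selected taxa, are *general*, so
the three clusters partition the community exactly once). Per-cluster
panels report AVD stability, total relative abundance, and richness per time
point with compact-letter groups. The crab-weight screen is Spearman
taxon-versus-weight with BH, intersected with the selected panel.

## Source tracking

A sink count vector is modeled as a multinomial mixture of smoothed named
source profiles (pooled replicate counts, pseudo-count 1e-6) plus an
*unknown* component whose profile is re-estimated each M-step from the
sink's unexplained mass. A fully free unknown profile makes the model
degenerate (it can reproduce any sink exactly), so the M-step update is MAP
with a symmetric Dirichlet prior whose total mass defaults to the sink
depth; the reported trace is the EM objective (log-likelihood plus prior),
which is non-decreasing at every iteration. Seeded random restarts keep the
best objective.

Two practical guards matter. First, the sink is rescaled to an *effective
depth* (default 1000) before the likelihood is formed: amplicon counts are
overdispersed relative to multinomial sampling, and at nominal depths of
1e5 the adaptive unknown component would otherwise absorb ordinary
replicate-level profile noise. The rescaling leaves the maximizer of the
fixed-source part unchanged. Second, subset tracking (e.g. of emerged
ASVs) drops sources that carry none of the subset taxa (proportion 0); if
no source carries any, the attribution is trivially all-unknown.

Single-ASV attribution is the degenerate case — a one-taxon multinomial
mixture is unidentifiable — so the proportion for habitat h is the ASV's
mean relative abundance in h's samples normalized over habitats where it
occurs.

## The synthetic benchmark

The generator emulates the study design: 3 gut segments × (8 postmolt hours
+ CK) × 6 replicate crabs, 4 source habitats, 300 ASVs at depth 5×10⁴ by
default, with Dirichlet-multinomial replicate noise (concentration 300,
giving replicate-level Bray–Curtis around 0.2–0.3, typical of amplicon
biological replicates). Planted, machine-readable structure:

* a convex slide of each segment's mean composition toward a target
  composition, piecewise-linear in time with a hinge at the planted
  breakpoint (defaults: none for the foregut, 24 h midgut, 21.3 h hindgut;
  slopes 0.02/h before, 0 after) — so the true tipping point is well
  defined in dissimilarity space;
* 50 *emerged* ASVs with exactly zero mean before a 6 h onset, fed by the
  source habitats in known proportions (near-disjoint per-source taxon
  pools sized by the mixing proportions) plus an unknown pool;
* 20 *lost* ASVs present only premolt; 30 *enriched* ASVs multiplied by the
  fold change (default 4×) from 24 h onward;
* 10 *stage-discriminative* ASVs at controlled baseline abundances
  (0.4–1.2%), each elevated in a given sample of its stage with
  colonization probability 0.65 — single indicators are partial stage
  markers, the panel is a strong one, which is the regime in which a CV
  error curve over panel sizes is informative;
* pathway tables whose designated pathways are monotone functions of
  designated taxon abundances (loading exponent 1, lognormal noise), so
  taxon–function links exist by construction and vanish at loading 0.

Everything is deterministic for a given seed.

**What passing the benchmark shows, and what it does not.** The planted
effects are recovered at the stated rates (emerged recall ≥ 95% at depth
1e5; hinge breakpoints within ±3 h; two-source mixtures within ±0.05;
stage-panel recall ≥ 80%; taxon–function link recall ≥ 90%), and the tests
that report significance are calibrated on matched nulls. The generator
does not simulate raw reads, chimeras, taxonomy errors, compositional
correlation structure between ordinary taxa, or time-autocorrelated
replicate noise, so these results certify the statistical machinery, not
performance on any particular real dataset. Two known limits: planted
emergence/enrichment onsets add abrupt structure to every segment's
trajectory, so even the drift-free "foregut" scenario can test significant
for a regime change in the default scenario; and the per-segment sink
mixtures behind the emerged taxa are not identifiable from one pooled sink
at the default noise level — the tracker honestly assigns most mass to the
unknown component there, as field studies of this design also report.

## Numerical choices

Ties in forest importance break by column order (stable sort); compact
letters and greedy modularity fix node order by id; the hinge grid runs
between the 2nd and penultimate distinct times inclusive; BH is applied
within each screen's own test family; EM stops at max |Δα| < 1e-8 or 2000
iterations. All Monte Carlo procedures (rarefaction, bootstraps,
permutations, node removals, restarts) take explicit seeds and are
reproducible bit-for-bit; the pipeline report records the seed and input
checksums, and `--resume` re-uses a run only when both are unchanged.
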