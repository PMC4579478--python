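# Methods

## The core-membership rule

An OTU belongs to the core of a scope (host species × preparation type) at
threshold *t* percent iff it is detected (count ≥ 1 by default; the floor is
configurable via `min_count`) in at least *t*% of the scope's samples.
Membership is decided in integer arithmetic — `100·k ≥ t·n` for *k*
detections in *n* samples — so boundary cases (5 of 16 samples at 30%) never
depend on floating-point rounding, and "at least" is inclusive: an OTU
exactly on the boundary is a member. Prevalence is always computed within
one preparation type at a time, never pooled across preparations; a pooled
"ALL" scope is available explicitly.

## The stabilization threshold

Core size is swept over the threshold grid 0, 2, …, 100%. The stabilization
threshold is the smallest grid point at which the core size shows zero net
change from the previous grid point in **every** preparation-type curve
simultaneously, considering only grid points after some curve has actually
changed. The qualifier matters at small sample sizes: with *n* samples the
integer presence cutoff `⌈t·n/100⌉` only moves every ≈ 100/n percent, so a
2% grid at n ≈ 10–30 contains many flat steps, including at the very start
of the sweep. Leading flatness is resolution, not stability, and is
skipped; a family of curves that never changes at all is reported stable
from the first grid step; curves that never jointly settle after changing
yield no threshold, with a warning surfaced in the run report. A per-curve
variant (`per_curve_stabilization`) is exposed for diagnostics. On deeply
replicated designs (n ≥ 50) every grid step moves the cutoff and the rule
reduces to "first flat step of the sweep". The interpretation of the sweep
quantity is the **number** of core OTUs, not their summed read abundance.

## Core combination, universality, and the rare biosphere

The combined core of a species is the union of its per-niche cores with
per-OTU provenance (which niches' cores contain it). This deliberately
re-admits taxa that a whole-colony preparation under-samples: a phylotype
confined to microdissected endosymbiotic cell clusters can be consistently
present there while invisible in the crushed whole-colony community.
Universality across host species is decided taxonomically (genus rank by
default): OTU identifiers from independent sequencing runs share no id
space, so the universal core is the intersection of the genus labels
carried by each species' combined core, excluding unclassified labels.
Rare-biosphere summaries band combined-core members by their mean relative
abundance across the whole-community (holobiont) samples, with default
cutoffs at 1% and 5%; prevalence-defined cores are typically dominated by
the sub-1% band, which is the methodological point of prevalence (rather
than abundance) thresholds.

## Community statistics

* **Diversity**: richness = detected OTUs per sample; Shannon index in
  natural log units (no rarefaction; the GLM offset and relative-abundance
  distances absorb library-size differences instead).
* **Diversity models**: ordinary least squares of a per-sample diversity
  measure on niche (categorical, treatment-coded with alphabetically first
  level as reference) and depth (numeric, meters), with sequential (Type-I)
  F tests in the order given. Rank-deficient designs raise, naming the
  aliased term. Degenerate inputs (zero residual variance) return F = 0,
  p = 1 when the term explains nothing, F = ∞, p = 0 otherwise.
* **Bray–Curtis** on counts or relative abundances (the pipeline uses
  relative abundances); a pair of all-zero samples is an error, not a 0.
* **PCoA**: Gower centering −½·J·D²·J, symmetric eigendecomposition, axes
  scaled by √eigenvalue for eigenvalues above a relative 1e-12 tolerance.
  Negative eigenvalue mass is reported; no Lingoes/Cailliez correction is
  applied, matching common practice for Bray–Curtis ordinations.
* **PERMANOVA**: sequential sums of squares via incremental orthogonal
  projectors on the Gower-centered matrix (the behaviour of `adonis` with
  `by="terms"`), pseudo-F per term against the residual mean square, free
  permutation of sample labels, and add-one p-values
  `(1 + #{F* ≥ F})/(1 + B)` so p is never exactly zero. Interactions are
  products of the component codings.
* **ANOSIM**: ranks of the condensed distances,
  `R = (r̄_between − r̄_within)/(M/2)`, `M = n(n−1)/2`, same permutation and
  p-value scheme. All permutation procedures are exactly reproducible given
  (n_perm, seed).
* **Differential abundance**: per-OTU quasi-Poisson GLM fit by IRLS, log
  link, log library-size offset, linear predictor clipped at ±30 for
  numerical safety, convergence on relative deviance change ≤ 1e-12 within
  100 iterations. Dispersion is Pearson X²/(n−p) from the full model (or
  fixed by the caller; φ = 1 recovers ordinary Poisson deviance testing);
  the full-vs-intercept comparison uses F = (ΔDeviance/Δdf)/φ̂ on
  (Δdf, n−p) degrees of freedom. OTUs absent everywhere are flagged
  `all_zero`; non-converged fits are flagged and excluded from the BH
  adjustment, which is applied across the fitted OTUs of one contrast only.

## Functional prediction

Predicted gene-family counts divide each OTU's reads by its 16S (SSU) copy
number — converting read abundance to an organism-abundance scale — and
multiply by its per-family gene copy numbers. OTUs missing from the
copy-number reference are excluded and the excluded read fraction is
reported per sample; no nearest-neighbour (NSTI-style) imputation of
missing reference entries is attempted, keeping the projection transparent
and exactly linear. Pathway aggregation counts a family once in every
pathway it maps to, with unmapped families collected in an `UNMAPPED`
bucket. Per-pathway group tests run one-way ANOVA across niches on
per-sample-normalized pathway abundances (cell / sample total), since
predicted totals scale with library size; note that this normalization
makes pathways compositional — a genuine enrichment of one pathway induces
apparent depletion of the others, which is why contribution shares and
group means are reported alongside F statistics.

## The synthetic community generator

The generator emulates a three-species, multi-niche amplicon study: one
species with holobiont / tissue / endosymbiotic preparations (11 samples
each) and two with holobiont / tissue / skeletal preparations (6 and 10
samples per niche), ~1450 OTUs per species, 10,000 reads per sample.
Defaults encode the community structure the pipeline targets: two universal
symbiont phylotypes planted in every species — sharing genus labels
(Propionibacterium-like and Ralstonia-like) while OTU id spaces stay
disjoint — at fixed niche mean relative abundances (42% and 22% in the
endosymbiotic niche; 0.3% and 4% in the whole community; intermediate in
tissue), 60 planted core OTUs per species at presence probability 0.9
(one quarter core in every niche, the rest core in a single niche each,
which creates niche-exclusive Venn regions), and a background whose
per-OTU presence probabilities are uniform on (0, 0.28].

Per sample the model draws presence indicators (symbionts are always
present — they are "universal"), assigns the symbionts their fixed niche
means, splits the remaining mass among present OTUs by renormalized
log-normal(0, σ²) weights (σ = 2 by default: a heavy-tailed rare
biosphere; the model literature offers log-normal and log-series variants
and the log-normal is the simpler, standard choice), and draws counts from
one multinomial at the library size. After the draw, any planted
core/symbiont OTU that was present but received zero reads is given one
read taken from the sample's largest count (≈ 10 reads in 10,000 moved at
most), so planted membership is exactly recoverable from `counts > 0` while
library sizes are preserved; background OTUs may still drop out, as in real
shallow sequencing. `GroundTruth` records the Bernoulli presence draws, the
per-OTU presence probabilities, and model-implied expected relative
abundances (exact for symbionts; a 1/E[K] concentration approximation for
the log-normal tail).

The gene-copy reference assigns each background OTU an SSU copy number in
1..10 and sparse integer gene-copy vectors over 24 opaque families (three
of which map to the transporter pathways). The planted symbionts are
transport specialists: SSU = 3, 6 copies of each transport family, 2 of
each housekeeping family, nothing else. The background transport copies are
then rescaled — by a short Monte-Carlo pass over the generative model, on a
pseudo-random stream independent of the data draw — so that the symbionts'
expected contribution share over the transport families equals 0.70 in the
endosymbiotic niche. Calibrating this way keeps both planted signals
simultaneously recoverable: the 70% contribution share and a transporter
pathway that is genuinely endosymbiotic-enriched.

All randomness derives from a single spec seed; sub-stage generators use
deterministically derived child streams, so identical specs give
byte-identical artifacts and the community and the gene reference can be
generated independently yet consistently.

### What the generator does not emulate

Sequencing error, chimeras and OTU-picking artifacts; phylogenetic
correlation between taxa (lineages are assigned cyclically from a small
pool); spatial/temporal autocorrelation between samples; depth effects on
composition (depth varies in the metadata but does not enter the generative
model, making it a true null covariate); overdispersion beyond what
presence-resampling and the multinomial induce; and symbiont abundance
variation around the niche means. Passing recovery tests therefore
demonstrates correctness of the algorithms under a controlled model, not
robustness to every artifact of real amplicon data.

## Problem sizes and numerical choices

The test suite exercises the pipeline at reduced scale (hundreds of OTUs,
thousands of reads) chosen so planted effects are comfortably detectable;
calibration checks use 1000 null datasets × 199 permutations for the
permutation tests and 200 replicates for the GLM false-discovery check.
Recovery of the transporter contribution share is tested under a tamer
abundance tail (σ = 1) because the per-sample share is a ratio statistic
whose heavy-tail Jensen bias would otherwise confound the calibration
check; the aggregate (ratio-of-sums) estimator is used for the same reason.
Ties in permutation tests count as exceedances (with a 1e-12 tolerance);
all permutation p-values are add-one; BH q-values are monotone-enforced and
capped at 1.

## Known limitations

- The stabilization rule is resolution-limited at small n (see above); at
  ~11 samples per niche it settles near the grid's attainable resolution
  rather than at a biologically tuned threshold, so the conventional 30%,
  50%, 75% and 90% annotation levels are always reported alongside it.
- BIOM support covers the classic dense TSV dialect only (HDF5/JSON BIOM is
  out of scope), and no sequence-level computation is performed anywhere —
  the pipeline starts from an OTU table.
- Quasi-Poisson is the only count model; zero-inflated and mixed-effects
  alternatives are out of scope.
- Cross-species matching is taxonomy-based; sequence-identity matching of
  core members is not implemented.
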