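# Methods

This note documents the statistical model behind `qminet`, the parameters
that matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## 1. From beads to the MFI matrix

One QMI well contains, for every `IP_probe` interaction in the panel, a bead
fluorescence distribution of roughly 50–150 reads. The pipeline collapses
each well to its **median** (the MFI — the Luminex-standard summary, robust
to the heavy right tail of fluorescence), then averages a sample's two
technical-duplicate wells **on the linear scale**. Interactions whose median
MFI across all samples falls below **100 units** are removed as instrument
noise; the filter keys on the per-interaction median across samples because
the aggregate is otherwise unspecified and the median matches the pipeline's
robust-summary style. The filter is idempotent and never changes the sample
set. Downstream network analysis consumes log₂ MFI.

## 2. Batch correction

Batches (assay days, bead conjugations) act multiplicatively per
interaction; on log₂ MFI this is an additive location shift plus a scale
change. `empirical_bayes_batch_correct` implements the parametric
empirical-Bayes location/scale model: per interaction, fit grand mean +
condition effects by least squares, standardize by the pooled residual
scale, estimate per-batch location γ̂ and scale δ̂² per interaction, shrink
them toward batch-level priors (normal for γ, inverse-gamma for δ², with
method-of-moments hyperparameters) by iterative conditional estimation to
absolute tolerance 1e-4, then remove the shrunken effects and restore the
fitted means. Including the condition design in the standardization
preserves condition contrasts unless a batch is perfectly confounded with a
condition, which triggers a warning. A batch with one sample has no
estimable scale and is an error by default; an explicit shrink-to-prior-only
mode adjusts location only. A single batch returns the input unchanged. The
implementation is cross-checked in the test suite against scanpy's ComBat on
identical input (agreement to ~1e-4 log₂ units).

Shrinkage leaves a per-interaction residual batch difference on the order of
the shrunken sampling noise; with ≳10 samples per batch and interaction-level
noise around 0.1 log₂ units this residual is well below 0.05 log₂ units for
essentially all interactions, which is what the validation suite asserts.

## 3. ANC — adaptive nonparametric comparison

ANC never collapses the bead distributions. For each interaction and each
matched pair (control vs. treated sample of one biological replicate, linked
by `pair_key`), the two *pooled* duplicate-well distributions are compared
with the two-sample Kolmogorov–Smirnov statistic D, with the asymptotic
p-value from the limiting Kolmogorov distribution at effective size
nₑ = nₐnᵦ/(nₐ+nᵦ). Bead counts ≥ 50 per well put the test in the asymptotic
regime; exact small-sample p-values are deliberately out of scope.

**Empirical alpha.** The cutoff starts at the Bonferroni level
α_B = base α / G for a panel of G tested interactions. Technical-duplicate
wells of the same sample are true null comparisons available in every
experiment; if their p-values fall below α_B more often than base α of the
time, the cutoff is lowered to the largest level at which the null
exceedance fraction is ≤ base α (stepping through the sorted null
p-values; if even the smallest positive null p-value is exceeded too often,
α* is set just below it). With no null comparisons, α* = α_B.

**Hit rule.** A hit requires strictly more than 70% of matched-pair
comparisons to be significant at α* *and* to agree with the modal direction
of the median shift (ties between directions break toward the direction of
the median log₂FC). Direction-inconsistent significant comparisons count
against the denominator, not toward the hit — the stricter reading of
"consistency of replicates". A pair missing one side is skipped with a
warning and the comparison count decremented. Duplicate wells are pooled for
the pair test rather than treated as pseudo-replicates; they are reserved
for the null calibration.

## 4. CNA — weighted correlation network analysis

* **Adjacency**: unsigned, a_ij = |Pearson(x_i, x_j)|^β on log₂,
  batch-corrected MFI. Unsigned is the historical default of the power
  adjacency function and tolerates modules mixing rising and falling
  interactions. Constant profiles get zero correlation with a warning.
* **Soft power β**: smallest candidate (1–20) whose signed scale-free fit
  −sign(slope)·R² reaches 0.8, else the fit-maximizing candidate. The fit
  regresses log₁₀ bin frequency on log₁₀ mean connectivity over 10
  **equal-width** connectivity bins (equal-count bins would flatten the
  frequency axis by construction and void the regression). Powers that
  leave the network with mean connectivity below 1 are ineligible: a
  near-empty network fits a power law spuriously well, and without this
  floor the selection drifts to arbitrarily large powers and module
  detection degenerates. If every power is degenerate, β defaults to 6 with
  a warning.
* **TOM**: TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij),
  ℓ_ij = Σ_{u≠i,j} a_iu a_uj, diagonal 1, denominator guarded at 1e-12;
  validated against a brute-force triple loop to 1e-12.
* **Modules**: average-linkage clustering of 1 − TOM with a **static cut**
  at 0.9 × the maximum merge height (plus a 1e-12 guard so numerically-zero
  trees stay whole). Clusters smaller than `min_size = 5` become `grey`.
  Deterministic and nearly parameter-free; dynamic hybrid tree cutting is a
  documented extension point, not implemented. Modules are named by the
  conventional color sequence (turquoise, blue, brown, …) in decreasing size
  order, ties broken by first member position.
* **Eigenvector**: first right singular vector of the z-scored member ×
  sample matrix (ddof = 1), unit norm, sign-oriented so the mean correlation
  with member profiles is positive (ties → positive first coordinate).
  Constant member profiles are dropped with a warning.
* **Module–trait / membership**: Pearson r with two-sided p from
  t = r√((n−2)/(1−r²)), df = n−2; |r| = 1 maps to p = 0. kME is the plain
  Pearson correlation of an interaction profile with a module eigenvector
  (z-scoring does not change it). CNA hits for a module require p < 0.05
  *and* kME > 0.

## 5. Intersection and reporting

Modules of interest are those whose eigenvector correlates with a selected
hypothesis at p < 0.05; the selection may be one trait, several, or any
trait (the default — a module is interesting if it tracks *an* experimental
variable). High-confidence interactions are ANC hits with significant
positive membership in a module of interest; the invariant
HCS ⊆ ANC hits ∩ CNA hits is asserted on every run. log₂FC uses condition
group means of per-sample MFI (matching the generator's expectation
algebra); heatmap values divide each row by its across-sample median (row
median exactly 1, invertible); module activity is the per-sample mean of
member scaled values, compared across conditions by one-way ANOVA with
pairwise Welch t tests and Bonferroni correction over the tested pairs.
PCA centers interaction profiles and takes sample scores from the SVD;
sample clustering uses 1 − Pearson distance with average linkage over
lexicographically ordered samples (deterministic ties). Self-interactions
(`AKT_AKT`) are apparent-abundance proxies: they pass through every
statistic unchanged and are only flagged in the edge-list export.

## 6. The synthetic-data generator

For interaction g in condition c, replicate r, batch b, well w:

    m = μ_g · 2^{e_gc} · ρ_gr · β_gb · w_well,   bead ~ LogNormal(mean m, CV 0.30)

with μ_g log-uniform on 150–20,000 MFI units, replicate multiplier
ρ ~ LogNormal(0, σ(CV 0.10)) shared by both matched samples of a replicate,
batch multiplier β with 0.25 log₂ s.d., and one well multiplier
(CV 0.05) per duplicate well shared across the panel (emulating loading
differences — these are exactly the comparisons the empirical alpha
calibrates on). Bead counts are drawn uniformly in 50–150 per
(interaction, well), since Luminex bead regions yield distinct counts per
analyte. Defaults: 384 interactions (a square protein panel including
self-pairs), 8 biological replicates split evenly over 2 batches so batch
never confounds condition. Log-normal noise keeps fluorescence positive and
right-skewed, and the mean parameterization makes planted log₂ effects
exact in expectation (the mean of log₂ fluorescence is offset by
σ²/(2 ln 2), which the validation suite accounts for).

Planted modules are disjoint member sets with shared per-condition log₂
effects; the truth object records memberships, expected effects, and every
multiplier drawn, and serializes losslessly to JSON. The trait table carries
one 0/1 indicator per non-reference condition plus configurable composite or
ordinal rows (e.g. time since refeeding). Identical config + seed is
bit-identical.

**What the generator does not emulate**: background/bare-bead fluorescence,
inter-well normalization controls, antibody epitope occlusion, saturation at
high MFI, and — importantly — broad correlated structure among *unplanted*
interactions. Real panels share proteins across interactions and co-regulate
widely, which is what makes real degree distributions approximately
scale-free; in the simulation the background is independent noise, so the
scale-free fit rarely reaches 0.8 and β falls back to the fit maximizer.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted structure under realistic noise, not that real
data will show the same power.

## 7. Validation conditions (chosen once, stated here)

* ANC type-I control: 200-interaction null panels, 4 matched pairs,
  100-bead wells, 50 seeds; mean hits/run ≤ 1.
* ANC power: 10-member planted module among 40 interactions, 8 pairs;
  effect grid 0.1/0.2/0.4/0.8 log₂ (sensitivity at 0.4 ≥ 0.8,
  non-decreasing), bead count 50 vs 150 at effect 0.2.
* Module recovery: 60 interactions, 8 conditions × 5 replicates, three
  planted modules (10/9/11) with mutually orthogonal ±0.25 log₂ Walsh-type
  condition patterns — orthogonality is required for three *distinct*
  modules under an unsigned network, since anti-correlated patterns merge
  by construction; adjusted Rand index ≥ 0.8 in ≥ 8/10 seeds.
* End-to-end: 384 interactions, 4 refeeding conditions × 8 replicates, a
  sustained and a late module (+0.5 log₂, 10 members each); ≥ 80% recovery
  with ≤ 5% false discovery in ≥ 8/10 seeds, and ≤ 1 call on matched null
  runs. These sizes keep the full suite within a few minutes on one CPU.

## 8. Known limitations

* The asymptotic KS p-value is anti-conservative below ~25 beads per side;
  the assay regime (≥ 50/well, wells pooled) avoids this, but the function
  does not warn on small inputs beyond the n ≥ 2 requirement.
* Static tree cutting cannot split nested modules the way dynamic hybrid
  cutting can; at panel scale (~10²–10³ nodes) this mainly costs
  sensitivity for weakly separated modules.
* The empirical alpha calibrates on duplicate-well nulls, which carry
  slightly *more* within-pair noise than matched-pair nulls (two independent
  well multipliers vs. two averaged ones); the calibration is therefore
  conservative.
* Whether the original analysis ran CNA on linear or log₂ MFI after batch
  correction is ambiguous; log₂ is the default here and a linear-scale
  input is accepted via the same API.
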