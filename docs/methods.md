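# Methods

## The composite fermentation-ability score

### Model

Let X be the n × p matrix of phenotype indicators over n strains after
direction correction (every lower-is-better column multiplied by −1, so
"larger = better" holds everywhere; by default only hardness is flipped,
since its redundant proxies are normally pruned before scoring). Columns
are z-scored with the sample standard deviation (ddof = 1, matching the R
convention the field predominantly uses); the Pearson correlation matrix R
of the columns is eigendecomposed, R = V Λ Vᵀ. Loadings are defined as
V √Λ, i.e. loading_{ji} is the correlation between variable j and component
i, and Cos2_{ji} = loading_{ji}² is the share of variable j's variance
carried by component i. Cos2 rows sum to 1 per variable and columns sum to
λ_i per component — both identities are asserted to 1e-9 in the tests.

Components with λ > 1 (strict) are retained — the Kaiser criterion for a
correlation-matrix PCA, where an eigenvalue of 1 is the variance of a
single standardized variable. The composite weight of indicator j is

    w_j = Σ_{i ∈ retained} λ_i · Cos2_{ji}

and a strain's score is the dot product of its z-row with w. This choice of
weights — eigenvalue-weighted Cos2 rather than raw loadings — is identified
by the reference data itself: the per-component weight vectors of the
published two-component formula sum to the corresponding eigenvalues
(0.35+0.57+0.02+0.55 = 1.49 ≈ λ₁; 0.17+0.09+0.81+0.03 = 1.10 ≈ λ₂), which
is the Cos2 column-sum identity.

### Assumptions

* Indicators respond monotonically to an underlying fermentation ability,
  so sign-flipping suffices for direction correction (no nonlinear
  transform).
* The panel is complete: missing cells are a hard error in scoring input
  rather than imputed, since imputation would silently alter the
  correlation structure the whole method rests on.
* Strains are exchangeable replicates; no batch or block structure is
  modelled.

### Numerical choices

* PCA is computed by `eigh` on the correlation matrix, not SVD of the data;
  an SVD oracle cross-checks the eigenvalues to 1e-9 in the tests.
* Component signs are fixed so each loading column sums to a non-negative
  value. Cos2 is sign-free, so this affects only the reported loadings, not
  the score — it exists to make intermediate output reproducible across
  eigen-solvers.
* Ranks break ties by ascending strain ID.
* If no component clears the Kaiser line, `composite_coefficients` raises
  rather than guessing; `CompositeScoreModel.fit` falls back to the leading
  component explicitly and records that in the retained-component list.
* When a reference score column is attached, the single positive scale c
  minimizing Σ(c·y − ref)² is reported as a diagnostic, never applied. On
  the packaged reference table c = 25.000 and c·y matches every attached
  score within 0.5%, i.e. the reference scores are exactly 25 × the
  full-precision composite; the two-decimal published coefficients
  (0.68/0.93/0.89/0.84 vs full-precision 0.70/0.96/0.92/0.86) reproduce the
  same ranking but not the near-zero scores to tight relative error, which
  is why score-reconstruction checks use the full-precision path.

### Redundancy pruning

Pruning is a greedy sweep over an explicit priority list: keep an indicator
iff its |r| with every already-kept indicator is below the threshold
(default 0.6, the lower edge of the interchangeability band reported for
this panel). |r| rather than r is used because redundancy is about shared
information, not sign — a proxy that tracks its parent negatively (pH
against titratable acidity, chemically) is just as redundant. Correlation
significance is reported (exact t-transform, n−2 df) but deliberately not
used as a pruning criterion. The default priority
(TTA, Volume, Hardness, Springiness, pH, Cohesiveness, Gumminess,
Chewiness) encodes the domain judgement of which proxy is canonical; there
is no data-driven rule for that choice, so it is an explicit, overridable
parameter.

## Group-discriminating variant contrast

Genotype states are classified per decomposed alternate allele:
REF_CONSISTENT (0/0), HOM_ALT (x/x), HET (0/x), LOW_QUALITY (missing or
malformed calls, and any cell whose depth falls below the threshold). A
genotype involving a different alternate allele than the row's is
OTHER_ALT: reference-inconsistent, but it neither anchors nor matches a
shared mutation state (a strict mode that drops such sites entirely can be
had by pre-filtering multi-allelic records).

Record-level filters: QUAL ≥ 20 and mapping quality ≥ 30, inclusive at the
boundary; per-cell depth ≥ 10. Absent QUAL/MQ/DP fields pass with a
warning, because third-party VCFs vary in which fields they populate and a
hard failure would make the reader unusable on otherwise fine files.

A site discriminates in direction A→B iff all members of A share one state
s ∈ {HOM_ALT, HET} and no member of B has s. HET and HOM_ALT are distinct
mutation states — all-het vs no-het discriminates even when the other group
carries hom-alt. Both directions are evaluated and unioned with the
direction recorded. The published rule is stated for trios; it generalizes
to arbitrary group sizes, and `min_shared_fraction` < 1 relaxes
"all members" to a majority threshold for exploratory use (the strict rule
remains the default and the only one used in validation). Sites touching a
LOW_QUALITY call in either group are excluded by default
(`require_full_groups`); how such cells were handled upstream in published
analyses is generally unstated, and excluding them is the conservative
choice that cannot manufacture a hit from missing data.

The closed-form false-positive probability of the strict rule on i.i.d.
states (inclusion–exclusion over the four directional events) ships with
the package and is validated against simulation within binomial error.

## Enrichment

Upper-tail hypergeometric p-values (via `scipy.stats.hypergeom.logsf`, in
log space for stability), fold enrichment (k/n)/(K/N), and in-package
Benjamini–Hochberg step-up FDR cross-checked against statsmodels. Terms
with zero query overlap are excluded from the output and the FDR family by
default, mirroring common overrepresentation-test tools; the FDR procedure
is BH because the reference tool family publishes BH-based FDR columns.
Only overrepresentation is tested. No GO-graph ancestor propagation is
performed — the annotation table is taken at face value, so term p-values
are only as complete as the supplied annotation.

## Synthetic data: what it emulates and what it does not

**Phenotypes.** A standard-normal latent ability a_s drives four
informative indicators (core_j = loading_j·a_s + N(0, σ); defaults
TTA 0.3, Volume 0.8, Hardness −0.8, Springiness 0.8, σ = 0.3, n = 36) and
four redundant proxies generated as affine functions of their parent's
core (pH from TTA with proxy noise 0.05, giving r ≈ 0.99; cohesiveness/
gumminess/chewiness from hardness with noise 0.5–0.7, giving r ≈ 0.78–0.86,
inside the 0.6–1.0 interchangeability band). Outputs are affine-mapped to
realistic units (e.g. hardness 25 ± 8 N), which leaves every correlation
untouched. The generator reproduces the redundancy structure and the
latent-driven ranking; it does not emulate measurement batch effects,
nonlinear saturation of texture measures, or indicator-specific error
distributions — passing recovery tests therefore show the pipeline's
statistics are sound, not that real panels meet the model's assumptions.
Note the three 0.8-loading indicators are mutually correlated at
r ≈ 0.73/0.88 under these defaults, so pruning at 0.6 legitimately thins
them; recovery tests score the informative quartet directly.

**Genotypes.** Planted sites set every strong-trio member to one shared
non-reference state and every weak-trio member to reference; defaults plant
33 non-synonymous sites over 19 genes between trios, mirroring the
planted-truth scale the pipeline is meant to recover. Background sites draw
i.i.d. states (ref/hom/het/missing). Because the strict rule has a ~3·10⁻³
per-site false-positive probability on i.i.d. trios, default background
rows are rejection-sampled to not discriminate between the two configured
groups, making planted truth and discriminating truth coincide exactly;
setting `exclude_background_contrast=False` restores pure i.i.d. background
for false-positive studies. Sites are simulated as states directly — no
reads, no reference sequence, no linkage — so the generator validates the
contrast logic and file round-trips, not variant calling.

**Annotations.** A random gene → term table with one planted term
(defaults: N = 1000, 50 terms, planted K = 10, query n = 20, overlap
k = 8, fold 40). Term overlaps are independent, unlike real GO's nested
hierarchy.

All generators fan a single seed out to per-stream substreams, so adding
one stream never perturbs another; identical seeds give byte-identical
VCF output (fixed header and one-decimal float formatting).

## Problem sizes used in validation

The test suite exercises the contrast rule exhaustively over all 4096
two-trio state combinations against a brute-force oracle, hypergeometric
p-values against full enumeration at N ≤ 12, the false-positive closed
form against a 10,000-site simulation, phenotype correlation convergence at
n = 10,000, and enrichment planted-term recovery over 100 seeded
replicates. These sizes give stable statistics while keeping the default
suite fast.

## Known limitations

* The composite score is linear; indicators with non-monotone optima
  (e.g. an ideal intermediate pH) would need pre-transformation.
* The Kaiser criterion is a blunt retention rule; no parallel analysis or
  broken-stick alternative is provided.
* The contrast rule is deterministic and unpowered — it reports
  qualitative fixed differences, not association statistics; with trios,
  i.i.d. noise alone produces occasional hits (see the closed form), so
  candidate genes need downstream validation.
* The enrichment test inherits whatever incompleteness and bias the
  supplied annotation table carries, and treats genes as exchangeable
  (no gene-length or mutability correction).
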