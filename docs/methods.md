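# Methods

## The model

The package asks whether *molecular convergence* between two diseases
predicts their *clinical comorbidity*, and builds the network of pairs
where both hold.

**Molecular arm.** A disease D is linked by GWAS to a SNP set S(D); each
tissue t supplies an eQTL map from SNPs to the RNAs whose expression
they associate with. The disease's eQTL-RNA set in tissue t is
R_t(D) = ∪_{s∈S(D)} eQTL_t(s). For an unordered pair (D₁, D₂) testable
in t (both sets non-empty), the overlap is scored by a one-sided Fisher
exact test on

|            | in R₂ | not in R₂ |
|------------|-------|-----------|
| **in R₁**  | a     | b         |
| **not**    | c     | d         |

where a+b = |R₁|, a+c = |R₂| and a+b+c+d equals the tissue's expressed
eQTL-RNA background. "One-sided, greater" is the default because the
question is overrepresentation; a two-sided mode is available by flag.
p-values are BH-adjusted **within each tissue** (FDR_eRNA); a pair is
molecularly convergent if significant in at least one tissue, and the
number of significant tissues becomes the network edge weight. A global
(across-tissue) BH scope exists as a sensitivity flag. SNPs associated
with both diseases of a pair are included by default; the
`exclude_shared_snps` flag removes them so overlap cannot come from a
literally shared locus.

**Clinical arm.** Patient-level 0/1 indicators per disease bundle are
built from billing codes (a patient is positive if any code belongs to
the bundle's descendant-closed code set). Patients missing any required
covariate (age, sex, race) are excluded and counted. For each bundle
pair, two directional logistic regressions are fitted by IRLS — the risk
of D₁ given D₂ and of D₂ given D₁, each adjusted for age (standardized),
sex, and race (one-hot, largest level as reference). Wald p-values of
the exposure coefficients from *both directions of all pairs* are
BH-adjusted jointly within a claims dataset. Across datasets the best
(minimum) directional FDR is reported; the pair-level odds ratio is the
maximum of the directional exp(β̂). A pair is comorbid when any
direction of any dataset has FDR < 0.05 *and* OR above the cut (1.5 by
default, 3.0 for the stringent network).

**Concordance.** Over the universe of pairs testable in both arms
(configurable to union-tested or all pairs), a final one-sided Fisher
exact test on convergent × comorbid. Robustness is assessed on a grid
of FDR cutoffs (log-spaced down to 1e-18 for the molecular arm and
1e-11 for the clinical arm, crossed with OR > 1.5 / OR > 3); degenerate
grid cells (a cutoff flags all or none of the universe) are reported as
missing rather than errors. A sensitivity variant excludes pairs whose
ontology similarity exceeds 0.9, so enrichment cannot be driven by the
same disease appearing under two names.

**Semantic similarity.** Concept information content follows the
intrinsic (corpus-free) estimator

IC(c) = −ln( (|leaves(c)|/|subsumers(c)| + 1) / (max_leaves + 1) ),

with leaves(c) the leaf descendants of c (c itself when a leaf),
subsumers(c) its ancestors including c. This makes IC(root) = 0 exactly
and IC monotone non-decreasing toward the leaves. Pair similarity is
Lin's measure 2·IC(MICA)/(IC(a)+IC(b)), defined as 0 when both concepts
carry no information. Bundle-level similarity aggregates concept-level
scores by **maximum** over the cross product — a deliberate choice (the
aggregation is genuinely open): max is conservative for the ≥ 0.9
exclusion rule, since any one highly similar concept pair suffices to
drop the bundle pair.

**Networks.** Disease-network edges require both arms' criteria; edge
weight is the distinct significant-tissue count. Mechanism networks are
tripartite disease → locus → RNA: per disease, SNPs with pairwise LD
r² ≥ 0.8 collapse into one locus (connected components of the
thresholded LD graph; loci are never merged across the two diseases),
and only loci linked to the pair's shared RNAs in significant tissues —
and only those RNAs — are drawn.

## Numerical choices

- Fisher p-values come from hypergeometric tail sums; the two-sided mode
  sums all tables whose point probability is at most the observed one
  (with a 1+1e-7 relative guard against floating-point ties). The
  convergence scan evaluates the one-sided tail vectorized per tissue;
  this path is asserted identical to the scalar test.
- OR conventions for a 2×2 table: ad/bc, +∞ when bc = 0 < ad, 0 when
  ad = 0 < bc, NaN when both vanish; an optional Haldane–Anscombe +0.5
  correction affects the OR only, never the exact p-value.
- IRLS converges on |Δ log-likelihood| < 1e-8 with at most 100
  iterations; a fit is flagged separated when any |β̂| > 20 (the MLE is
  then effectively at infinity) and its Wald inference is suppressed;
  non-converged fits are recorded but excluded from BH adjustment. The
  pairwise scan runs a batched IRLS — all models sharing a response
  disease iterate in lockstep, warm-started from the covariate-only fit —
  which is unit-tested to agree element-for-element with the scalar
  fitter.
- `min_cases` (default 100) removes bundles too rare to support the
  logistic fits; both cases and non-cases must reach the floor.
- BH adjustment is the statsmodels step-up implementation, clipped at 1,
  stable under ties. Adjusted values are *not* an idempotent map (no
  non-constant vector is a fixed point of the step-up transform); the
  meaningful invariant, which the tests assert, is that thresholding
  adjusted values at α reproduces the classic step-up rejection set.
- Natural logarithms throughout the information-content code; Lin scores
  are base-invariant but reported IC values need a fixed convention.
- Inconsistent concept→code mappings (one claim code listed under
  several concepts) keep the first-listed concept and log a warning —
  a deterministic stand-in for expert curation of such conflicts.

## The synthetic universe

The generator emulates the five restricted inputs with known ground
truth. Its defaults are a reduced echo of the real study's scale
(hundreds of disease bundles, thousands of SNPs, 19 tissues, tens of
millions of patients): 40 diseases with ~10 SNPs each, 2000 RNAs, 5
tissues, 20 000 patients per claims dataset.

- **Ontology**: a rooted DAG — root, ~one organ-system class per 10
  diseases, one concept per disease (10% get a second class parent so
  the graph is a genuine DAG), 1–3 coded leaves per concept. 10% of
  diseases also emit an alias term ("... (clinical subtype)") to
  exercise bundle merging.
- **GWAS catalog**: SNPs partitioned among diseases — planted pairs
  never share a SNP, so any RNA overlap must arise through the eQTL
  layer.
- **eQTL maps**: per tissue, each SNP present (p = 0.85) regulates a
  Poisson(2) number of RNAs drawn uniformly from the tissue background
  (90% of the RNA universe); the uniform wiring makes null overlaps
  exactly hypergeometric, which the tests verify against the closed-form
  mean. Planting wires one SNP of each disease of a pair to
  `shared_rna_count` common RNAs in one designated tissue. A nominal
  p-value column below the upstream 0.2 threshold is emitted for
  interface realism only.
- **Claims**: age ~ U(18, 90), sex ~ Bernoulli(0.5), race categorical
  (4 levels, probabilities 0.6/0.2/0.1/0.1); logit-scale effects 0.3 per
  SD of age, 0.2 for sex, (0.2, −0.1, 0.1) for race — shared across
  diseases, so demographics genuinely confound. Disease prevalence is
  log-uniform on (0.01, 0.10); every disease touched by a planted pair
  draws from (0.06, 0.12) so planted effects sit above the testability
  floor. Comorbidity is planted by adding β·(D_i − prev_i) to the
  partner's logit, making the planted value the conditional log-odds
  given covariates; intercepts use the centred exposure so marginal
  prevalences stay near target. 1% of patients lack one covariate,
  exercising the complete-case rule. Two datasets ("NIS", "NEDS") share
  all disease-level parameters but use independent patient streams.
- **LD**: within each disease, consecutive SNP blocks of 3 get
  r² ~ U(0.8, 1); occasional cross-block entries stay below 0.8.

What the generator does **not** emulate: realistic LD decay and
population structure, ICD-9-CM code semantics, claims sampling design
and survey weights, temporal ordering of diagnoses, correlated eQTL
sharing across tissues. Passing tests therefore demonstrate the
statistical machinery — calibration, power against planted effects,
invariances — not performance on real claims or eQTL data.

## Study sizes used by the test suite

All stochastic checks fix their seeds. Sizes were chosen once, by power
analysis of the planted effects (a planted conditional OR of 3 at 8–15%
prevalence gives Wald z ≳ 6 at n = 2000–2500 per dataset, comfortably
clearing the BH threshold at the observed discovery counts):

- Parameter recovery: one claims dataset, n = 100 000, uniform 5%
  prevalence, planted conditional OR = 3.
- Null calibration: 50 seeds each for the comorbidity and convergence
  arms at small scale.
- End-to-end: coupled universes with 200 diseases and 20 coupled pairs
  (n = 2000 patients per dataset; background diseases at 0.5–5%
  prevalence mostly below the min_cases floor, planted diseases at
  8–15%), 50 seeds; decoupled universes with 80 diseases and 160 + 160
  *independently sampled* molecular/comorbid pairs, 50 seeds. The
  independent (rather than disjoint) sampling is what makes the
  decoupled concordance exactly null — the two significant sets then
  overlap hypergeometrically — and the planted counts give an expected
  chance overlap of ~8 pairs, dense enough for the discrete exact-test
  p-values to be meaningfully compared with a uniform distribution
  (with sparser planting the support collapses to a handful of values
  and the test is conservative by construction).

## Known limitations

- The directional models are fitted marginally per pair; no multivariate
  or graphical adjustment for other diseases is attempted (matching the
  method's design), so strong triangles of comorbidity can propagate.
- pair OR = max of directional estimates is upward-biased by selection
  (max of four noisy estimates); on planted data the bias is ~10% at the
  test suite's sample sizes.
- Exact logistic regression, Firth correction, and permutation p-values
  are out of scope; separated fits are flagged and dropped rather than
  rescued.
- The concordance universe definition ("tested in both arms") is a
  config choice; with very sparse tissues or rare diseases the universe
  can shrink enough to make the final test underpowered, which the run
  report makes visible (`n_tested_both_arms`).
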