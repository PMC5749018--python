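# Methods

`fishpanel` re-implements, as a tested pipeline over synthetic data, a
discovery analysis for a multicolour FISH biomarker panel intended to
predict progression of clinically localised prostate cancer under active
surveillance. The pipeline has five stages: cohort simulation, signal
enumeration, marker screening, combination selection, and association
modelling. This note documents the model behind each stage, the defaults
and why they were chosen, and what the synthetic cohorts do and do not
establish.

## The classification problem

Specimens are diagnostic needle-biopsy samples from a nested case-control
design: *cases* progressed to clinical intervention within 10 years of
diagnosis, *controls* did not progress over at least 10 years. Each
specimen is hybridised with three four-colour probe mixes covering ten
probes — copy-number probes for recurrent prostate-cancer lesions (PTEN,
CDKN1B and NKX3.1 deletions; MYC, FGFR1 and NMYC gains), same-chromosome
centromeric controls (CEP8, CEP10), and break-apart rearrangement probes
(ERG, ETV1) — and 100 consecutive intact interphase nuclei are enumerated
per specimen per mix.

## Synthetic cohort generator

The study's raw enumeration tables are not publicly deposited, so every
stage is exercised against a seeded generator that emulates their
statistical structure. The generative model, per specimen:

- **Clinical record.** An NCCN-style risk group is drawn from a cohort
  distribution, then tumour stage, PSA and Gleason score are sampled
  consistently with a deterministic simplification of the NCCN rule
  (High if Gleason >= 8 or PSA > 20 ng/mL; Intermediate if Gleason = 7,
  PSA 10-20, or stage T2b/T2c; VeryLow requires T1c, Gleason <= 6,
  PSA < 10 plus an explicit very-low flag standing in for core-level
  criteria the data model does not carry; else Low). Age ~ N(64, 6) years,
  truncated to 50-82 and independent of outcome. The default risk-group
  distribution is shared between arms (20% VeryLow, 30% Low, 27%
  Intermediate, 23% High), reflecting the matched case-control design in
  which controls are matched to cases on stage, grade and PSA; a
  case-tilted variant (`CASE_TILTED_RISK_GROUP_PROBS`, roughly e^1.2 odds
  per ordinal risk step) is provided for analyses that need a planted
  clinical effect.
- **Lesion fractions.** For each probe and compatible lesion type (gain;
  hemizygous and homozygous deletion; split; rearrangement-with-deletion),
  the specimen's abnormal-cell fraction is drawn from a Beta prior. The
  control-arm baseline is Beta(1.5, 58.5) — mean 2.5% abnormal cells,
  weakly informative. *Planted effects* multiply the prior mean for case
  specimens at fixed concentration; the default plants all seven candidate
  parameters at multiplier 1.4, chosen so that the optimised combinations
  land in the regime the assay showed on real biopsies (best-combination
  AUC roughly 0.70-0.78, panel odds ratios roughly 3-7). An effect can be
  restricted to one risk stratum to emulate stratum-specific signal.
- **Per-cell signals.** Given the fractions, each nucleus independently
  draws a lesion. True signal counts are deterministic per lesion: a
  normal locus shows 2 signals, gain 3-6 (uniform), hemizygous loss 1,
  homozygous loss 0; a normal break-apart locus shows 2 fusion signals,
  a split 1 fusion + 1 isolated red + 1 isolated green, the ERG
  rearrangement-with-deletion pattern ("2Edel") 1 fusion + 2-4 isolated
  red + 0 green. **Truncation** — apparent signal loss because thin FFPE
  sections physically slice nuclei — is modelled as independent Bernoulli
  loss of each true signal with probability 0.08, the simplest mechanism
  that reproduces the observed sub-diploid centromere means: the expected
  observed CEP count is 2 x (1 - 0.08) = 1.84, matching the ~1.84-1.87
  regime reported for such sections.
- **Confounded marker.** NKX3.1 hemizygous-loss fractions are coupled to
  the Gleason score (default slope 0.05 fraction per Gleason unit above
  5), emulating a marker that tracks tumour grade rather than adding
  independent information; the screening stage exists to catch exactly
  this and is expected to drop the NKX3.1 probe on essentially every run.

All randomness flows from a single `numpy` generator seeded by the
configuration; identical seed and configuration reproduce byte-identical
TSV output. Probes within a mix are simulated independently given the
specimen (no per-nucleus coupling between, say, a PTEN deletion and the
ERG rearrangement), and there is no within-specimen spatial structure —
the mixture is exchangeable by design.

What the generator does **not** emulate: tumour heterogeneity and field
effects, enumeration-to-enumeration reader variability, correlated lesions
on the same chromosome arm, nuclei-quality QC failures (hybridisation
failure can be injected only by removing rows), or survival time. Passing
tests therefore demonstrate that the algorithms are implemented correctly
and recover planted structure under the stated noise model — not that the
panel's clinical performance would replicate.

## Signal enumeration

Specimen-level parameters are percentages of enumerated cells (or a copy
ratio), computed from the cell records. Parameters follow each probe's
lesion class: amplification probes are scored for **Gain** (percent of
cells with more than 2 signals), deletion probes for **Loss** (fewer than
2) and **Homozygous** (exactly 0), locus probes with a same-chromosome CEP
control additionally for **Ratio** (mean probe count / mean control
count), and break-apart probes for **Split** (at least one isolated red
and one isolated green signal) and, for ERG, **2Edel** (two or more
isolated red with fewer isolated green than red). Three readings of the
microscope-level definitions are fixed here as design decisions:

- signal separation (the ">= 1 signal width" criterion) is resolved at
  enumeration time and carried as fused-vs-isolated counts, since it
  cannot be reconstructed from totals;
- 2Edel requires isolated red >= 2 ("gain of single red signals") with
  green < red ("loss of at least one green relative to red multiplicity");
- Split and 2Edel are disjoint cell classes: a 2Edel-pattern cell is not
  additionally counted as Split, because they enter the candidate list as
  distinct parameters.

Homozygous cells count toward Loss as well (Loss is strictly "fewer than
2"), so `pct_loss >= pct_homozygous` always, and both PTEN Loss and PTEN
Homozygous legitimately coexist in the candidate list. Specimens lacking
cells for any panel probe are excluded from the matrix and reported, never
silently dropped.

Note that truncation inflates Loss (a diploid nucleus shows < 2 signals
with probability 1 - 0.92^2 ~ 15.4% at the default truncation), which is
why the deletion cut-off range sits at 10-20% while amplification ranges
start at 2%.

## Marker screening

Every scored parameter is tested against age, Gleason score, PSA and
ordinally-coded stage (T1c=1 .. T2c=4) by Pearson correlation, with the
two-sided p-value from the t-transform on n-2 degrees of freedom. If any
parameter of a probe reaches p < 0.05 against any clinical variable, the
entire probe is excluded from the candidate list — probe-level rather than
parameter-level exclusion, because a confounded probe's other parameters
share the same hybridisation and the same interpretation problem. No
multiplicity correction is applied, deliberately mirroring a raw-0.05
screen. A consequence worth stating plainly: with 15 parameters x 4
variables = 60 tests at n ~ 107, one to three unconfounded probes are
typically lost to chance correlations per cohort. The pipeline aborts with
a named error if fewer than `k_min` candidates survive. Constant
parameters are reported as not evaluable and never trigger exclusion.

## Combination selection

The core algorithm. Seven candidate parameters (PTEN Homozygous, MYC Gain,
FGFR1 Gain, NMYC Gain, ETV1 Split, PTEN Loss, ERG 2Edel) are grouped into
all subsets of 3-6 (98 subsets when all seven survive screening). For each
subset, every vector in the Cartesian product of per-parameter candidate
cut-offs is evaluated under the **any-positive rule**: a specimen is
panel-positive iff any parameter value is >= its cut-off (inclusive). The
retained vector minimises the distance from ideal,

    DFI = sqrt((1 - sensitivity)^2 + (1 - specificity)^2),

the Euclidean distance from the perfect corner of ROC space (0 ideal,
sqrt(2) worst).

Cut-off grids are integer percent steps over class-specific ranges —
amplification 2-15, deletion 10-20, break-apart 4-10. With 100 enumerated
cells per specimen, observed percents are integers, so step 1 exhausts the
search space.

Numerical choices:

- **Exhaustive search via dominance counting.** A specimen is negative at
  a cut-off vector iff every cut-off exceeds its value, so per-vector
  negative counts over the whole grid are multidimensional prefix sums of
  corner indicators — O(specimens + D x grid cells) per subset instead of
  O(specimens x vectors). The result is bit-identical to naive
  enumeration, which the tests verify.
- **Tie-break.** Among equal-DFI vectors: prefer higher specificity
  (fewest false positives), then the lexicographically largest cut-off
  vector — which is the element-wise largest whenever one exists. This is
  deterministic and conservative.
- **Combination AUC.** How a multi-parameter combination's AUC should be
  formed is genuinely open: a single dichotomised panel call yields one
  ROC point, not a curve, yet AUC and minimum DFI are reported as separate
  ranking criteria. The default scores specimens by fitted probabilities
  of an unpenalised logistic model on the combination's *continuous*
  parameter values and takes the Mann-Whitney AUC (ties one half) of that
  score; a one-parameter combination then reduces exactly to the
  single-parameter AUC. Because the score is fitted, this AUC is
  direction-learned and >= 0.5 in sample. If the fit does not converge
  (e.g. quasi-separation), the fallback score is the row-wise maximum of
  rank-standardised parameters, and the result is flagged. The alternative
  single-point reading, (sensitivity + specificity) / 2 at the optimised
  cut-offs, is available behind `auc_method="single-point"`.
- Combinations are ranked by AUC descending, ties by DFI ascending, then
  lexicographically; duplicate parameters in a requested combination are
  dropped at entry.

No cross-validation or optimism correction is applied anywhere: reported
sensitivities, specificities, DFIs and AUCs are apparent (resubstitution)
performance, exactly as in the analysis this pipeline reproduces. On null
data the cut-off optimiser overfits accordingly; this is a property of the
method, not a defect of the implementation.

## Association models

Logistic regressions with Wald inference, fitted by iteratively reweighted
least squares (tolerance 1e-8 on the coefficient update, max 50
iterations, step damping at +/-5 per update), standard errors from the
inverse observed information, 95% limits exp(beta +/- 1.959964 SE),
p-values from the Wald chi-square. The IRLS core is shared by a vectorised
batch routine for 2x2 tables used in the validation sweep (for the
saturated 2x2 model the MLE odds ratio is the cross-product ratio ad/bc
and the Wald SE is sqrt(1/a + 1/b + 1/c + 1/d), which the implementation
reproduces to 1e-6 over all tables with cells 1-30).

Model set, per selected combination:

- FISH-only: `outcome ~ panel call`;
- FISH + clinical: `outcome ~ panel call + NCCN risk group`, risk entered
  as a single ordinal score (VeryLow=1 .. High=4) so that one odds ratio
  summarises the clinical gradient; dummy coding is available via
  `risk_coding="dummy"`;
- clinical-only: `outcome ~ NCCN ordinal + age`; age is kept only here, as
  it proves non-informative by construction in the default generator;
- risk-stratified: the FISH-only model within lower (VeryLow + Low),
  intermediate, and higher (High) strata.

Degenerate inputs are handled explicitly, never silently: a rank-deficient
design raises an error naming the collinear terms; a constant risk
covariate is dropped with a diagnostic so the adjusted model degrades to
the FISH-only fit; quasi-complete separation sets `converged=False` with a
diagnostic, and for 2x2 layouts with an empty cell a Haldane-Anscombe
(+0.5 per cell) corrected odds ratio is attached as a clearly labelled
auxiliary value. Strata missing an outcome class are skipped with a
reason. Matching in the design is ignored by the models (unconditional
rather than conditional logistic regression), consistent with the analysis
being reproduced.

## Problem sizes and test design

The test suite checks each operation against an independent oracle: AUC
against brute-force case-control pair counting on 200 random tied
datasets; the cut-off search against naive Cartesian enumeration
(including the tie-break) on 50 random instances; the logistic fit against
the 2x2 closed form over the full [1,30]^4 table space (batched) and
against `statsmodels` on continuous designs; and the pipeline against
planted-signal recovery — cohorts of 58 cases / 49 controls with two
strongly enriched markers (multiplier 3.5) must place both markers in the
top-ranked 3-parameter combination in >= 90% of 20 seeds, and an
intermediate-stratum-only effect (multiplier 4) must yield the largest
stratum odds ratio in >= 80% of 20 seeds. Recovery simulations use
3-parameter subsets and 20 replicates; unit-level simulations use 25-55
specimen cohorts. These sizes keep the full suite to a few minutes while
leaving the Monte-Carlo acceptance margins comfortably wide.

## Known limitations

- The generator's abnormality priors and planted-effect sizes are free
  parameters; nothing calibrates them to the study's (undeposited)
  per-marker distributions beyond the centromere-truncation anchor and the
  targeted performance regime.
- The uncorrected screen plus probe-level exclusion loses unconfounded
  probes to chance at a non-trivial rate (see above); this faithfully
  reproduces the screening rule rather than an idealised one.
- Apparent performance only; no optimism correction.
- The NCCN rule here omits criteria the data model does not carry
  (metastatic status, core counts, PSA density); VeryLow therefore needs
  an explicit flag.
- Break-apart truncation treats each fusion signal as a single loss unit;
  partial truncation of one colour of a fusion pair (which could mimic a
  split) is not modelled.
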