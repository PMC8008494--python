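# Methods

## Assay model and score estimation

Each variant's raw readout is a fold increase in GFP-positive cells,
measured in replicate experiments on independently derived clones. Raw
fold changes are mapped to the score scale by the affine 1:5
normalization

    s = 1 + 4 · (x − m_path) / (m_wt − m_path)

where `m_path` and `m_wt` are the mean raw fold changes of the
pathogenic control (p.Asp2723His) and wild-type BRCA2. The anchor means
map to exactly 1 and 5 by construction; the map is order-preserving and
is rejected when `m_wt ≤ m_path`.

Scores are modelled on the log scale (fold changes are positive and
multiplicative noise is the natural error model for them). To absorb the
clone-level random effect, measurements are first averaged within clone
(log scale); the model unit is the per-clone mean log score. For a
variant with k ≥ 2 clone units, under a flat prior on the mean and a
Jeffreys prior on the variance, the posterior of the mean log score is
Student-t with k − 1 degrees of freedom, located at the sample mean with
scale `s/√k`. The reported score is the exponentiated posterior median;
the interval is the exponentiated 2.5/97.5 posterior percentiles. This
conjugate ("analytic") backend is exact and deterministic, and its
intervals have nominal frequentist coverage — a plain z interval at
these small unit counts (k = 4 by default) covers at only ≈ 90% and
would fail the package's own coverage check, which is why the t form is
the default. Single-clone variants fall back to replicate-level units
(df n − 1); variants with < 2 measurements are excluded with a warning;
zero-variance inputs return a degenerate width-0 interval with a
warning. Rescaled values ≤ 0 (possible when noise drops a raw value
below the pathogenic anchor) are floored at a configurable ε = 0.01
before the log and flagged.

The optional MCMC backend samples (μ, log σ) with emcee under a
weakly-informative normal prior on μ (scale 2.5; `None` = flat) and a
Jeffreys prior on σ. On flat-prior cases it must and does agree with the
analytic posterior within Monte-Carlo error; it exists as an independent
route for cross-checking and for non-flat priors.

Point estimate = posterior median (equal to the mean here) was chosen
because the published per-variant table does not state mean vs median;
the two coincide for the symmetric posterior on the log scale.

## Functional calls

NonFunctional iff the upper 95% credible bound < 1.66; Functional iff
the lower bound > 2.25; otherwise Indeterminate. Comparisons are strict,
exactly as the cutoffs are stated; boundary-equal values are
Indeterminate. Since 1.66 < 2.25 and the bounds are ordered, the two
positive calls are mutually exclusive. The cutoffs themselves are taken
as constants from the prior calibration of this assay (probability of
pathogenicity > 0.99, probability of neutrality > 0.95); re-deriving
them is out of scope. One source passage reads "99% confidence interval"
for the pathogenic rule, but the assay's interval definition and the
published table's footnote both use 95%; 95% is the default and the 99%
reading is available as configuration, not default.

## The transcribed per-variant table

`data/table1.tsv` transcribes the published table of the 90
non-functional variants verbatim (score, upper 95% bound, applied
evidence codes, before/after classifications); a checksum guards the
fixture against silent edits. Lower bounds are not printed and are
carried as missing. One row (p.Glu2599Gly) prints its upper bound as
exactly 1.66: printed values are rounded to two decimals, so the printed
boundary value is ambiguous, while the row's printed PS3 code — applied
only when the unrounded bound is below 1.66 — resolves it. The loader
therefore classifies printed-boundary rows by the transcribed functional
code and all other rows by the strict rule; `classify_function` itself
is always strict. The table also yields a sub-domain census note: eight
of the 90 variants fall in OB2 (2804–3054) although the accompanying
text says seven; the fixture records the discrepancy and nothing asserts
either count.

## Calibration and OddsPath

Sensitivity and specificity on the control standards use exact
Clopper–Pearson intervals (beta quantile form). Evidence strength is
expressed as OddsPath = [P2(1−P1)]/[(1−P2)P1] with P1 the prior
pathogenic proportion among controls and P2 the pathogenic proportion
among abnormal readouts. Under perfect separation the
next-variant-misclassified correction P2 = TP/(TP+1) applies; this is
the convention that reproduces both published values (46.0 and 32.0),
and algebraically it makes OddsPath equal the benign-control count
exactly — the implementation computes in odds form (integer count
ratios) so the identity holds bit-exactly in floating point, and a
property test checks it for all control-set sizes 1..100. The benign
direction mirrors the computation on normal readouts (corrected
P2 = 1/(TN+1)), giving a reciprocal OddsPath equal to the
pathogenic-control count. Strength mapping uses strict inequalities:
> 18.7 strong (the stated validation bar), with > 350 / > 4.3 / > 2.1
for very strong / moderate / supporting as the standard extrapolation,
reciprocals for the benign direction; everything is overridable, and
18.7 exactly maps to moderate because the bar is strictly "greater
than". Indeterminate control calls shrink the effective control set and
are reported.

## ACMG/AMP engine

Quantitative inputs are converted by strict-threshold rules: BayesDel
< 0.0560 → BP4, > 0.431 → PP3, between → inconclusive (no code);
PROVEAN < −6 → deleterious for non-SNVs; filtering allele frequency
≥ 0.1% → BA1, ≥ 0.01% → BS1, else ≤ 1 carrier → PM2_supporting. FAF
selection (lower of genomes/exomes) happens at table ingestion; the
engine sees a single number. PM1/PM5/PP1/PM3/BP2 are consumed as curated
assertions with validated strength modifiers — the structural,
co-segregation, and trans-phase analyses behind them are out of scope,
as is any conservation computation behind a BP4_strong upgrade.

The categorical combiner implements the standard five-tier combining
rules, counting codes at applied strength, with two SVI modifications:
PM2 only ever enters as supporting, and a lone strong benign code (BS3)
suffices for LB (toggleable). BS3 on a variant with predicted splice
impact is recorded but gated: it can never drive LB/B, because the assay
reads out protein function only.

Conflict policy (both directions firing): `strict_vus` always returns a
conflicted VUS; the default `pathogenic_dominant` lets a P/LP result
stand when benign evidence totals at most one supporting code — the
behaviour the transcribed table exhibits (p.Ala3028Pro is P despite
BP4) — and, symmetrically, lets an LB/B result stand when the
pathogenic side is a single supporting code. The mirrored clause is this
package's own extension of the stated policy: without it, every rare
functional variant (BS3 + PM2_supporting) would be forced to conflicted
VUS, which contradicts the study's benign reclassification arm; the
transcribed table contains no counterexample to the mirror.

The points backend (supporting 1, moderate 2, strong 4, very strong 8;
benign negative; P ≥ 10, LP 6–9, VUS 0–5, LB −6..−1, B ≤ −7) is a
disclosed cross-check, monotone by construction, not the primary
backend.

Replaying the transcribed table through the engine reproduces 40 of the
63 observed rows from the printed codes alone. The 23 divergent rows
(frozen in `KNOWN_DIVERGENT_ROWS`) all sit *above* the engine's tier and
include pairs with identical printed codes but different printed
classes, so they encode internal laboratory evidence that is not
disclosed; row-level reproduction of those rows is impossible and is not
asserted.

## Synthetic data generator

The generator emulates the assay's data-generating process, not its
biology: true scores sit in a two-mode mixture at the anchor scores
(1 and 5, log-normal spread sd 0.04, optional intermediate mass), and a
measurement is `true · exp(clone_effect + noise)` with clone sd 0.04 and
replicate noise sd 0.12 on the log scale, under a 4-clone × 2-replicate
design (eight wells per variant, matching the "duplicate experiments on
at least two clones" design). The noise scales were set so that default
interval widths resemble the published per-variant intervals (upper
bound ≈ 0.1–0.25 above the score near the non-functional mode). Control
wells for both anchors are always generated and the anchors are their
raw means, so anchor sampling noise propagates exactly as in the real
normalization. Cohort defaults are the study's: 252 variants, 90 truly
non-functional; control standards 20 pathogenic / 46 benign with a
10/32 held-out subset.

Evidence profiles draw BayesDel and curated-code occurrences at rates
conditional on the variant's functional call, with the non-functional
rates taken from the observed rows of the transcribed table (PP3 23/63,
BP4 2/63, PM1 29/63, PM5 12/63, PP1 12/63, PM3 5/63, PM2_supporting
57/63) and curated pathogenic codes on functional variants scaled down
by 0.05 — real predictors and curated evidence correlate with true
pathogenicity, and an independence assumption would produce far more
evidence conflicts than the study observed. Assertion tables draw 1 +
Poisson submitters per variant with a configurable conflict rate,
data-sharing flags, and collaborating-lab rows to exercise the exclusion
paths.

What the generator does **not** emulate: genuinely intermediate
(hypomorphic) scores unless configured, inter-experiment batch effects,
correlated errors between anchor wells and variant wells, the spatial
domain structure of non-functional variants, and any real relationship
between a variant's identity and its evidence profile. Passing tests on
synthetic data therefore demonstrate the statistical machinery
(estimation, calibration, combination, tabulation) at the study's design
points — not that the assay itself has the published operating
characteristics on new wet-lab data.

The synthetic external-comparison tables
(`synthetic_quantitative_model_overlap`,
`synthetic_drug_sensitivity_overlap`) are constructed to the published
marginals (49 overlapping variants, 48 concordant, p.Arg2502Cys the sole
outlier; 63 drug-assay variants, none non-functional-yet-resistant, six
functional-yet-sensitive) because the underlying per-variant tables are
supplementary data not shipped here; they validate the tabulation code,
not the marginals themselves.

## Concordance rules

Assertion filtering drops non-qualifying submitters, then excludes a
variant when the collaborating laboratory is the only qualifying
submitter or the sole classification outlier — interpreted at the
grouped level (LP/P vs VUS vs LB/B): the lab's group is unrepresented
among the other qualifying submitters while those all share one group.
Ties are not outliers (the lab must be strictly alone in its group), and
when the other submitters disagree among themselves the lab is not "the
sole" outlier. Retained statuses group LP with P and LB with B;
VUS + one non-VUS group is a conflicting status; LP/P together with LB/B
is "opposing", a category kept distinct so its absence can be verified.
ClinVar snapshot counts are snapshot-dependent and are not computed
here; the module consumes offline tables only.

## Numerical and reproducibility choices

Seeds are required for every stochastic path (default 20210219).
Generator functions draw from per-function seeded streams, so adding a
stage never perturbs another stage's draws, and every pipeline run with
the same config and seed produces a byte-identical manifest. Problem
sizes in the test-suite simulations (500-variant coverage check, 400
variants per design point for the error-decay check, 20 seeds for label
recovery) were chosen to make the Monte-Carlo bands in the assertions
comfortably tight at desk scale.

## Known limitations

- The regression structure of the original score model is not published;
  the clone-mean t posterior is this package's reconstruction, and
  per-variant numbers will not match the original fit exactly (the
  transcribed table is used where exact published numbers matter).
- The engine cannot reproduce the 23 divergent table rows (undisclosed
  internal evidence); concordance is asserted only on the consistent
  subset.
- PM5's "worse than the known pathogenic missense" qualifier has no
  published cutoff, so PM5 is input-only.
- The printed sensitivity interval of the prior validation (79%–100%)
  implies a different control count than 20/20 (Clopper–Pearson gives
  83%–100%); the package reports intervals computed from its own inputs.
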