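# Methods

This note documents the models and procedures implemented in `careseq`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Cohort construction

Four claims-like tables (patients, diagnoses, events, hospitalizations) are
filtered by conjunctive rules, applied in a fixed order only for attrition
reporting:

1. **Confirmed diagnosis** in the lookback year (default 2016): the T1DM
   code appears in ≥2 *distinct calendar quarters* in the outpatient
   setting, or ≥1 time in the inpatient setting. Quarters are the German
   claims convention Jan–Mar, Apr–Jun, Jul–Sep, Oct–Dec. Any two distinct
   quarters qualify (adjacency is not restricted), and any inpatient record
   counts (no primary-diagnosis restriction) — the rule is taken at face
   value.
2. **Age eligibility**: birth year in 2003–2006 inclusive (ages 11–14 in
   the first observation year), configurable.
3. **Continuous insurance**: the patient's coverage intervals must jointly
   span the lookback + observation years with *no gap of one day or more*.
   The gap tolerance is a package choice; claims sources rarely state one.
4. **Hospital-outpatient exclusion**: hospital-outpatient-setting events in
   ≥8 of the 12 observation quarters (distinct quarters, not event counts).
   These patients' procedures are billed as quarterly lump sums and cannot
   be itemized, which would masquerade as care gaps.

Because the flags are conjunctive, the included set is independent of rule
order; a patient failing several rules is attributed to the first failing
rule in the exclusion log, so attrition counts sum exactly to
`n_input − n_included`.

## Sequence encoding

Intervals are half-open `[start, end)`; an event dated exactly on a
boundary belongs to the later interval. Within a quarter, test-strip
quantities are *summed across prescriptions* before the ≥200 threshold is
applied — the total supplied quantity is what matters clinically, and the
threshold is a config parameter (`strips_threshold`). HbA1c and contact
events count only in the outpatient setting: inpatient measurements are
part of an admission, not ambulatory monitoring, and hospital-outpatient
contacts never satisfy the contact state (those patients are excluded
upstream anyway). Both behaviors are localized in
`sequences._flag_matrices` if a different convention is needed.

Screening state labels use the fixed letter order R, C, T (e.g. `RT`, never
`TR`), and the empty combination is labeled `N` in every dimension, giving
alphabet sizes 2, 4 and 8. Events outside the observation window are
ignored with a logged warning rather than an error, since claims extracts
routinely include out-of-window rows.

## LCS distance, normalization, pooling

`d(x,y) = |x| + |y| − 2·L(x,y)` with L computed by dynamic programming.
Compound states are atomic symbols: `RT` vs `RCT` contributes no partial
credit. This is deliberate — the sequence elements are states, not events,
so dissimilarity is defined on the state alphabet. Distances are exact
integers before normalization (bit-reproducible); the production path
deduplicates identical sequences and runs the DP vectorized over unique
pairs, which makes the n = 900 cohort (~4·10⁵ pairs per dimension) take
about a second per dimension.

**Normalization.** "Min–max" on a dissimilarity matrix is ambiguous. The
default divides every off-diagonal entry by the *observed* off-diagonal
maximum with the minimum anchored at the theoretical 0: subtracting a
positive observed minimum would destroy the zero diagonal and the identity
property, and 0 is the true minimum of a dissimilarity. Two variants are
available behind the `normalization` flag for sensitivity analysis:
`observed_range` (subtract the observed minimum; diagonal kept at 0) and
`theoretical_max` (divide by the maximal attainable distance, 2·length).
A dimension whose distances are all zero normalizes to the zero matrix with
a `DegenerateDimensionWarning` and acts as the additive identity in
pooling.

Pooling is the entrywise sum of the normalized matrices, so pooled entries
lie in [0, D] for D dimensions and the quarterly dimensions (max raw
distance 24) cannot dominate the annual one (max raw distance 6).

## PAM and model selection

PAM is the classic deterministic algorithm: BUILD seeds the first medoid as
the minimizer of total distance and each further medoid as the maximal cost
reducer; SWAP repeatedly applies the single best improving
(medoid, non-medoid) exchange. All ties break toward the lowest index
(lexicographically lowest (medoid, candidate) pair in SWAP), so results are
platform-independent. The SWAP deltas are evaluated vectorized from the
nearest/second-nearest medoid distances, so a full k = 2..10 scan at
n = 900 takes a few seconds.

**PAM is a local search.** Its output is guaranteed to be single-swap
optimal — no exchange of one medoid for one non-medoid lowers the cost —
but not globally optimal over all medoid subsets. On small uniform random
Euclidean instances (n ≤ 12, k ≤ 3) roughly 9% of runs terminate at a
swap-local optimum above the exhaustive optimum, and R's reference
`cluster::pam` returns the identical suboptimal set on such instances. The
test suite therefore verifies swap-local optimality by exhaustive exchange
enumeration and exact optimality on structured instances; global optimality
on arbitrary instances is not a property PAM has.

Quality indices per candidate k: average silhouette width (singletons
contribute s(i) = 0), point-biserial correlation between pairwise distances
and the different-cluster indicator over all unordered pairs, and Hubert's
C comparing the within-cluster distance sum to the best/worst sums over the
same number of pairs. `recommended_k` maximizes ASW (ties toward smaller
k); the other two indices are reported, not aggregated, since no principled
weighting exists — the full table is retained so a human can apply visual
inspection. All indices are computed on the pooled matrix as produced by
the distance module. Degenerate inputs (zero variance, constant distances)
return NaN with a warning instead of raising.

## Cluster profiling

Cluster labels from PAM are arbitrary, so orientation is post hoc from care
content: the cluster with the higher mean number of HbA1c quarters is
labeled guideline-adherent.

Descriptive tests per covariate type: chi-square (no Yates correction) for
binary covariates, Kruskal–Wallis for ordered multi-category covariates
(birth year, job type, district type), Welch t-test for counts. Tests run
at the 5% level with *no multiple-testing correction* — a deliberate
faithful-reproduction choice for descriptive cluster tables. Missing SES is
reported as its own row and never drops a patient from the descriptives or
the clustering; it only reduces the regression n.

The membership model is a maximum-likelihood logistic regression (Newton
IRLS via statsmodels) of adherent-cluster membership on mean-centered birth
year, DMP enrollment, autoimmune comorbidity, parental Abitur and parental
unemployment — the compact predictor set; a wider set can be passed via
`predictors`. CIs are Wald intervals on the log-odds scale exponentiated to
the OR scale (symmetric in log space; a profile-likelihood variant was
considered unnecessary at these n). Perfect or quasi separation is reported
as a non-converged result with a diagnostic and NaN estimates plus a
`NonConvergenceWarning` — never silent output. At n ≲ 150 with a ~5%
unemployment prevalence, quasi-separation is expected occasionally; it is a
sample-size phenomenon, not an error.

Hospitalization outcomes: the binary any-T1DM-primary-hospitalization
indicator is compared by chi-square, the per-patient count by Welch t-test,
and the ratio of mean counts (care-with-gaps over adherent) is reported.
All-zero outcomes yield NaN ratios with an explanatory note.

## Synthetic-data generator

The generator emulates the statistical structure of a pediatric T1DM claims
cohort, not its billing-code granularity:

* **Mixture**: each patient is latently `adherent` or `gaps`. Membership
  follows a logistic model whose slopes are the configured log-odds
  (defaults: ln 0.875 per birth year, ln 2.428 DMP, ln 1.695 autoimmune,
  ln 1.387 Abitur, ln 0.433 unemployment) and whose intercept is calibrated
  by root-finding so the expected adherent share equals
  `mixture_proportion_adherent` (default 0.75). Slopes are therefore
  recoverable parameters; the intercept is not.
* **Events**: conditionally independent Bernoulli draws per interval given
  the archetype. Defaults — adherent: contact 0.96, HbA1c 0.85, strips 0.65
  per quarter, each screening 0.75 per year; gaps: 0.90 / 0.35 / 0.35 and
  0.30. These reproduce the qualitative margins of the planted structure
  (≈95% contact quarters cohort-wide, ≈85% vs ≈35% HbA1c quarters, ≈80% of
  adherent years with ≥2 screenings, ≈70% of gaps years with ≤1). No
  temporal autocorrelation, seasonality or provider-network structure is
  modeled; passing tests show the pipeline recovers *this* conditional-
  independence structure, not that it would recover arbitrary real-world
  temporal dependence.
* **Strips quantities**: a qualifying quarter gets a total ≥200 (200–350 in
  steps of 50); a non-qualifying quarter still carries a sub-threshold
  prescription row (quantity 50–199) with probability 0.10, so the
  threshold filter is genuinely exercised.
* **Diagnosis confirmation**: 90% of patients get two outpatient diagnoses
  in distinct lookback-year quarters, 10% one inpatient diagnosis, covering
  both branches of the confirmation rule.
* **SES covariates**: drawn from configurable cohort-wide marginals
  (defaults: Abitur 44.9%, university degree 31.9%, unemployment 5.1%, DMP
  47.8%, the four job-type and district-type shares, etc.). With
  probability `ses_missing_rate` (default 0.16) all parental SES fields go
  missing *jointly* — missingness masks observation after the archetype
  draw, so it is MCAR by construction.
* **Hospitalizations**: Poisson counts per 3 years with archetype means
  1.11 (adherent) and 1.54 (gaps), uniformly dated, all flagged
  T1DM-primary.
* **Hospital outpatients**: an optional fraction (default 0) receives
  hospital-outpatient-setting contacts in 10 of 12 quarters to exercise the
  exclusion rule.

Identical config + seed reproduces byte-identical CSV output. The
ground-truth archetype is written to a separate `truth.csv` that the
analysis pipeline never reads.

## Problem sizes and numerics

The default study-replica analyses run at n = 900 (the full pipeline in a
few seconds on one CPU); rate-recovery checks use n = 5000 and
coefficient-recovery/coverage checks 200 replicates of n = 900 via the
patient-level generation path. Distances are exact integers until
normalization; PAM's swap acceptance uses a 1e-12 tolerance against float
drift in the pooled sums; seeds below 2³¹ are used everywhere and every
random draw flows from a single `numpy` Generator per run.

## Known limitations

* The generator's conditional independence given archetype understates the
  within-patient persistence of real care patterns; real ASW values will
  differ from synthetic ones (the replica yields ≈0.30 at k = 2; weaker,
  more entangled real-world structure yields lower values).
* District types are consumed as plain categoricals; no geography is
  modeled. Billing-code operationalization (ICD-10-GM / EBM) is out of
  scope: the event and diagnosis tables are assumed pre-resolved.
* PAM is exact k-medoids only in the swap-local sense discussed above;
  CLARA-style subsampling for much larger n is not implemented.
* The membership model deliberately fits the compact predictor set; no
  variable-selection procedure is provided.
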