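# careseq

Multidimensional state-sequence analysis of pediatric type 1 diabetes (T1DM)
care pathways from longitudinal claims-like tables.

Managing pediatric T1DM requires care along several dimensions at once —
regular outpatient contact, quarterly HbA1c measurement with sufficient
blood-glucose test strips, and annual screening for retinopathy, thyroid
disease and hypercholesterolemia. `careseq` is for health-services
researchers who want to find *latent groups of children who consistently
receive suboptimal care across these dimensions* in routinely collected
insurance claims, and to relate those groups to parental socioeconomic
status (SES) and hospitalization outcomes. Because real statutory-insurer
claims are access-restricted, the package ships a synthetic-data generator
that plants the study's statistical structure, so every stage is testable
and reproducible end to end.

## Method

Each patient contributes one categorical state sequence per care dimension
over a 3-year observation window (2017–2019 by default):

| dimension | tracked | states |
|---|---|---|
| HCP contact | quarterly (12) | `O` (T1DM outpatient contact) / `N` |
| diagnostics | quarterly (12) | `N`, `H` (HbA1c), `B` (≥200 strips), `HB` |
| screening | annually (3) | 8 combinations of `R`, `C`, `T` |

Patients are compared with the longest-common-subsequence dissimilarity

d(x, y) = |x| + |y| − 2·L(x, y),

where L(x, y) is the length of the longest (not necessarily contiguous)
common subsequence. Because the quarterly dimensions have a larger maximal
distance (24) than the annual one (6), each per-dimension matrix is min–max
normalized onto [0, 1] before the three are summed into a pooled matrix.
Partitioning around medoids (PAM, deterministic BUILD + best-improvement
SWAP) clusters the pooled matrix; the number of clusters k ∈ [2, 10] is
chosen by the average silhouette width (ASW), with the point-biserial
correlation and Hubert's C reported alongside. Clusters are then profiled:
chi-square / Kruskal–Wallis / Welch tests per covariate, a logistic
regression of adherent-cluster membership on SES predictors (odds ratios
with Wald 95% CIs), and T1DM-primary hospitalization outcomes.

The cohort rules mirror claims practice: a confirmed diagnosis in the
lookback year (E10 twice in distinct outpatient quarters, or once
inpatient), birth years 2003–2006, continuous insurance coverage, and
exclusion of hospital outpatients (hospital-outpatient care in ≥8 of 12
quarters, whose procedures are billed as lump sums and cannot be tracked).

## Worked example

```python
from careseq import GeneratorConfig, PipelineConfig, run_pipeline

config = PipelineConfig(generator=GeneratorConfig(n_patients=900, seed=1))
res = run_pipeline(config, "out/")
```

Running `examples/05_full_pipeline.py` (exactly this, plus recovery
scoring) prints:

```
cohort size:    900
recommended k:  2
cluster sizes:  {'0': 216, '1': 684} (adherent = cluster 1)
ASW at k:       0.298
ARI vs planted archetypes: 0.860  (1 = perfect recovery)
DMP odds ratio: 2.59  (planted 2.43)
hospitalization mean ratio: 1.40  (planted 1.54/1.11 = 1.39)
```

The ASW peak at k = 2 recovers the planted two-archetype mixture: a
guideline-adherent cluster (76% of patients) and a care-with-gaps cluster.
The adjusted Rand index of 0.86 against the generator's ground truth means
the pooled-LCS + PAM pipeline reassigns almost all patients to their true
archetype. The odds ratio of 2.59 for disease-management-program (DMP)
enrollment and the 1.40 ratio of mean hospitalization counts
(care-with-gaps over adherent) recover the planted effect sizes within
sampling error. The other `examples/` scripts demonstrate each capability
separately; `careseq run-all --out DIR` is the shell equivalent, and
`careseq simulate | cohort | sequences | distances | cluster | profile |
plot` expose the individual stages.

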