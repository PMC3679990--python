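# Methods

## The validation design

The package compares two ways of assigning a two-level risk stratum (SR /
HR) to children with ALL. The biology-based algorithms are the reference
standard: four nested rule sets over chart-review variables, each adding one
feature group in a fixed order (age+WBC, immunophenotype, cytogenetics,
MRD), with any high-risk feature forcing the HR stratum. The registry-based
algorithm is the index test: it sees only treatment protocol name and age
at diagnosis, the two fields reliably present in a population-based
pediatric cancer registry. Criterion validity is summarized by Cohen's
kappa and by diagnostic metrics with registry HR as the positive call.

Assumptions worth making explicit:

* **Half-open age intervals.** "1–9 years" is 1.0 ≤ age < 10.0; "<1" is
  age < 1.0; "≥10" is age ≥ 10.0. WBC exactly 50×10⁹/L is high risk, since
  "<50" is the SR-defining condition.
* **Missing data are non-informative for biology algorithms.** Missing
  immunophenotype or cytogenetics, and MRD that was not performed or could
  not be performed because the child died before testing, never contribute
  an HR vote. Biology calls are therefore always SR or HR. Only the
  registry algorithm can fail to classify (age 1–9 with no recognizable
  protocol).
* **Protocol eligibility metadata is documentation, not logic.** The
  knowledge base stores each protocol's lineage/age/WBC/genetics criteria
  verbatim, but classification uses only the name→risk mapping and age —
  the registry side never sees WBC or genetics, which is precisely the
  proxy being validated.
* **Biology calls do not depend on diagnosis date.** Changes in risk
  knowledge over the study era appear only on the registry side, as the
  knowledge-drift discordance mechanism.

## Protocol-record disambiguation

Registries may list several protocols per child. The selection rule keeps
the earliest record plus any record starting within four weeks of it —
implemented as ≤ 28 calendar days, inclusive at day 28, since no finer
grain is stated — then prefers a specific cooperative-group name over a
generic descriptor, and among specific candidates takes the latest start
date (capturing prognosticators that emerge shortly after diagnosis).
Records starting beyond the window are ignored. A tie between two specific
protocols with the same start date is broken by normalized-name order with
a logged warning; real registry extracts essentially never hit this case.

## Eligibility cascade

Filters apply in a fixed order — residency, early transfer, second
malignancy, no active treatment, registry linkage — so each child is
counted under exactly one reason and tallies are reproducible. The audit
reports the analyzed fraction against both the pre-exclusion total
(579/596 = 97.1%) and the post-exclusion denominator (579/584 = 99.1%),
since both summaries are in circulation for this cascade.

## Agreement statistics

For the 2×2 table with rows = registry and columns = biology,
κ = (p₀ − p_e)/(1 − p_e). The default SE is the simple large-sample form
√(p₀(1−p₀)/(n(1−p_e)²)) with z = 1.96; it reproduces the published interval
for the reconstructible row. The Fleiss–Cohen–Everitt corrected SE is
available via `se_method="fleiss"` but is not the default. Landis-Koch
bands are stated to two decimals (0.00–0.20 slight, 0.21–0.40 fair,
0.41–0.60 moderate, 0.61–0.80 substantial, 0.81–1.00 almost perfect);
values falling in a gap between bands (e.g. 0.205) are assigned upward, and
negative kappas are reported as slight with a warning. Sensitivity is
a/(a+c), specificity d/(b+d), PPV a/(a+b), NPV d/(c+d) with a = both-HR and
d = both-SR; a zero denominator yields a missing value, not an exception.
All statistics are computed unrounded; rounding happens only at
presentation.

Children the registry cannot classify are excluded from the cross-table by
default and tallied in the report; a `--fallback-age-only` switch instead
classifies them by age alone. The replica assigns protocols to all 579
analyzed children so that the n = 579 agreement analysis is exactly
reproducible (the original cohort had four protocol-less children whose
handling in the published kappa is not stated).

## The deterministic replica

`build_study_replica()` lays out 596 children with no randomness. The
construction pins exactly the published cells: the exclusion cascade
(7+3+1+1 excluded, 5 unlinked, 579 analyzed); algorithm SR/HR marginals
359/220, 347/232, 340/239, 324/255; 57 T-lineage children of whom 12 are SR
under algorithm 1; 36 with high-risk cytogenetics (19 MLL, 10 t(9;22), 7
hypodiploid) of whom 7 are SR under algorithms 1–2; 38 MRD-positive of whom
16 are SR under algorithm 3; 277 MRD-not-performed and 6 deaths before
testing; and registry-vs-biology-3 off-diagonals of 14 and 27 (reason mix:
2+7 data-entry errors, 12 knowledge drift, 12 unmeasured risk factors, 8
clinician overrides, the override cases carrying WBC 45×10⁹/L). The
remaining joint cells are under-determined by the published counts and are
filled by a fixed canonical allocation (deterministic ordering by patient
index; the overall cytogenetic category totals also match the published
marginals). Protocol names are assigned so the two workhorse protocols
carry their published share (184 × AALL0331, 107 × AALL0232) with the rest
cycling round-robin within risk class. The builder validates every pinned
cell at build time and raises on any mismatch.

Because the off-diagonal discordance counts were published only for
algorithm 3, the replica's agreement rows for algorithms 1, 2 and 4 follow
from the canonical fill rather than from published cells; they come out
within a few hundredths of the published kappas but are not pinned, and no
test asserts them.

On the reconstructed algorithm-3 table the computed specificity is
313/340 = 0.92 while the published table prints 0.96 (which equals the
reconstructed NPV); the published sensitivity, PPV, NPV and CI all match
the reconstruction, so the specificity column appears to be defined or
labelled differently at source. The discrepancy is documented here and
deliberately left unresolved. Similarly, the computed kappa is 0.8551,
which the source prints as 0.85 (its own CI 0.81–0.90 matches the
reconstruction exactly).

## The stochastic generator

`generate_cohort(GeneratorConfig(...))` draws features independently except
for one documented coupling and is reproducible for a fixed seed
(numpy `default_rng`). Defaults, chosen once from the published marginals:

| parameter | default | basis |
|---|---|---|
| `p_T` | 0.10 | 57/579 T lineage |
| `cytogenetics_probs` | published counts / 579 | category table |
| `p_mrd_available` | 0.51 | 296/579 with a result (assay adopted mid-study) |
| `p_mrd_positive_given_available` | 0.13 | 38/296 |
| `mrd_hr_cyto_multiplier` | 3.0 | MRD positivity and high-risk cytogenetics are related; ×3 (capped at 1) encodes that coupling |
| `age_probs` | discrete pmf over 0–17 | median 4, IQR 3–8, ~2% infants, ~20% aged ≥10 |
| `wbc_log_mu`, `wbc_log_sigma` | ln 10, 1.95 | right-skewed; P(WBC ≥ 50) ≈ 0.20 so that ~62% meet NCI SR criteria |
| `discordance_rates` | 9/579, 12/579, 12/579, 8/579 | observed mechanism counts |
| `exclusion_rates`, `p_unlinked` | published counts / 596 | cascade |

Ages are generated as integer years so median/IQR statements are crisp; the
classifiers accept real ages. Each child is assigned a protocol concordant
with their biology level-3 call unless a discordance mechanism fires.
Mechanisms are injected in a second pass: each draws a binomial(n, rate)
target count and samples that many children without replacement from its
applicable pool (data-entry error: anyone; knowledge drift: B-lineage,
NCI-SR children with a high-risk lesion; unmeasured risk factor: any
biology-3 SR child; clinician override: biology-3 SR with WBC in
[40, 50)). This makes the empirical injection fraction recover the
configured rate, which the property tests check at n = 5790 within 99%
binomial bounds. If a pool is smaller than the target the count is capped;
with default rates the pools are several times larger than the targets.
About 10% of children additionally carry a generic "three drug induction"
record preceding the specific protocol, exercising the disambiguation rule.

What the generator does **not** emulate: any joint distribution of
age × WBC × lineage beyond independence (none is published), protocol eras
or calendar drift in protocol usage, survival or relapse outcomes, and
within-mechanism heterogeneity (every discordance mechanism flips the
protocol risk class deterministically once selected). Passing tests on
generated cohorts therefore demonstrate the pipeline's correctness and the
calibration of the stated marginals, not fidelity of higher-order structure
in real registry data.

## Numerical and degenerate-input choices

* Kappa requires n > 0 and non-degenerate marginals (p_e < 1); both raise
  informative errors, and the per-level report catches them so one
  degenerate level (e.g. a single-patient cohort) does not abort the rest.
* κ is computed in double precision from integer counts; tests compare the
  closed form against a brute-force label-expansion oracle on every table
  with n ≤ 12 and against an independent library implementation on random
  tables, to 1e-12.
* CSV IO is strict by default (any bad row aborts with row-level
  diagnostics); `lenient=True` drops bad rows. A missing mandatory column
  is always a hard error naming the column.
* Enum vocabularies accept the common clinical spellings (`t(9;22)`,
  `11q23`, `MLL rearrangement`) case-insensitively; the canonical forms are
  what the writers emit, so read(write(x)) = x.

## Problem sizes

The replica is fixed at 596 children. Generator-based tests and the
calibration script use n = 5790 (ten times the study size), large enough
for the 99% binomial recovery bounds to be meaningful while the entire
suite runs in a few seconds.

## Known limitations

* The replica reproduces published *counts*; individual synthetic children
  are not real patients, and unpinned joint cells are a canonical fill.
* The registry algorithm's behavior for protocol-less children is a policy
  choice (exclude vs age-only fallback), not an empirical finding.
* The generator's discordance mechanisms are labels with deterministic
  effects; they support pipeline validation and agreement arithmetic, not
  causal interpretation of why clinicians deviate.
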