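# Methods

This note documents the algorithms, the synthetic data-generating model,
the defaults and the numerical conventions used by `lotline`, and what the
passing test suite does and does not establish about real claims data.

## Line-of-therapy segmentation

**Exposure intervals.** Each drug claim covers `[date, date + days_supply − 1]`.
Administrations recorded without a days supply (typical for parenteral
agents such as bortezomib) are assigned a configurable cadence,
`administration_default_supply_days = 7`, so that exposure logic is uniform
across routes.  Covered spans of one agent separated by at most
`merge_gap_days` (default 0, i.e. only abutting/overlapping spans merge)
form one exposure interval.

**Segmentation.**  A line starts at the earliest remaining claim.  Agents
whose first exposure begins within `regimen_formation_window_days = 60` of
the line start join the regimen; a literal mode with window 0 is available
but fragments staggered combination starts.  The line then ends at the
first of three events:

* **new agent** — the first administration of a non-regimen agent after
  the formation window; the line ends the day before;
* **gap** — a regimen agent's exposure lapses for
  `discontinuation_gap_days = 60`; the event fires on the day the gap
  completes and the line ends on the agent's last covered day.  In the
  default `any_agent_discontinued` mode the first lapsing agent ends the
  line; the alternative `all_agents_discontinued` mode requires the union
  coverage of the regimen to lapse;
* **censoring** — follow-up end or death; the line end is clipped there.

Events are ordered by *when the rule fires*, which is what a literal
day-by-day scan of the rule produces: a pending lapse that has not yet
reached 60 days loses to a new agent administered in the meantime.  Ties
resolve to `new_agent`, whose start defines the next line unambiguously.
The next line begins at the next claim after the line end; segmentation
re-derives exposure from the remaining claims so that a refill of a
previously seen agent can anchor the new line.  A restart of the identical
regimen after a ≥60-day gap therefore counts as a new line.

**Steroid handling.**  With `steroids_trigger_new_line = false` (default),
dexamethasone/prednisone neither opens nor closes a line, but a steroid
administered during the line joins its regimen set (so Vd and V remain
distinct categories).  If a regimen consists of steroids only, the gap rule
applies to them normally.

**Durations.**  Line duration counts inclusive covered days:
`(end − start + 1) / 30.4375` months, so a single-day line is ≈0.03 months.
Follow-up months use the exclusive convention `(end − start)/30.4375`.
The constant 30.4375 = 365.25/12 keeps month arithmetic calendar-free and
deterministic; "4 months" and "1 month" in the consolidation rule are
rendered as 122 and 30 days for the same reason.

## Transplant phases

The line active at (or most recently started before) the first ASCT is the
induction line.  Consolidation is post-ASCT treatment that starts within
`consolidation_window_days = 122` of ASCT, persists at least
`consolidation_min_duration_days = 30` beyond it, and whose agent set
equals or contains the induction regimen; it is folded into the induction
line (either because the line simply continued through transplant, or by
merging the qualifying next segment and renumbering).  Post-ASCT treatment
failing any condition — e.g. a strict subset such as lenalidomide
maintenance after VRd — opens LOT2.  An ASCT with no preceding exposure is
ignored for phase labeling with a warning.

## Cohort rules

Criteria apply in a fixed order (each logged): index MM diagnosis
≥2007-01-01; known sex; medical **and** pharmacy coverage on the index
date; ≥365 days of continuous coverage before index; no prior-malignancy
diagnosis in those 365 days; ≥1 constructed LOT.  "Continuous" tolerates a
configurable `coverage_gap_days` bridge between eligibility intervals
(default 0; 30–45-day bridging is a common claims convention and is a
config change).  Follow-up ends with the coverage interval containing the
index date for claims-type sources and at the last observed activity for
EMR-type sources; death truncates either.  Age is index year minus birth
year, banded <65 / 65–74 / 75–84 / ≥85.  The prior-malignancy code list is
configuration; MM precursor conditions are not included by default.

## Comorbidity

A flag or Charlson category is present iff ≥1 mapped diagnosis falls in
`[anchor − 180 d, anchor − 1 d]`; both anchors (index diagnosis,
first-LOT start) are supported because baseline tables use either.  One
qualifying claim suffices (no two-claim confirmation rule).  The CCI uses
the classic 17-category 1/2/3/6 weighting with hierarchy (complicated
hypertension suppresses simple; severe liver suppresses mild; complicated
diabetes suppresses uncomplicated; metastatic disease suppresses other
malignancy).  Multiple myeloma itself is a Charlson malignancy but is
excluded from the score by default (configurable): the index disease would
otherwise add 2 to every patient.  The code map is data (category, code,
weight); shipped codes are representative ICD-10, since claims dialects
vary.  The cardiovascular composite used in the models is the OR of
arrhythmia, CHF, complicated hypertension and valvular disease.

## Attrition

Outcomes after line k partition its cohort: subsequent treatment if line
k+1 exists; else death if the death date lies within follow-up; else no
subsequent treatment.  A patient who starts line k+1 and dies later counts
as subsequent treatment at k.  Whether "death" required death during the
line or any time before follow-up end is ambiguous in the study
definitions; this package uses the latter, which ties attrition directly
to "death or loss to follow-up".  Duration summaries report the arithmetic
mean, the n−1 sample SD (undefined at n = 1) and the midpoint median.
Rounding to one decimal happens only in the presentation layer.

## Inference

Categorical contrasts use the uncorrected Pearson chi-squared — the
single-stratum reduction of the Mantel–Haenszel statistic, whose
stratification variable the study never names; a stratified CMH
general-association statistic is available when strata are supplied.
Continuous contrasts use Welch's t by default (a pooled-variance mode
exists).  No multiple-testing correction is applied.  The logistic model
of receiving LOT2+ uses age category (reference 65–74), male sex, the
cardiovascular composite, liver disease, pulmonary circulation disorders
and renal impairment; Newton–Raphson ML with tolerance 1e-8, Wald 95% CIs.
Subsets 6+/12+/24+ months filter on follow-up from first-LOT start.
Separation and non-convergence are flagged in the results, never returned
as silent infinite estimates.

## Cell suppression

Counts 1–10 are replaced by `NR`; zero is exempt.  If exactly one cell in
a margin group is masked it could be back-solved from the margin, so the
smallest other positive cell is co-masked; when no positive partner
exists, the group margin itself is masked — without this fallback the lone
cell is exactly recoverable.  Groups are rows; this layer does not publish
cross-row column totals.  Safety is tested by an exhaustive back-solver
that re-applies the policy to every feasible integer fill and demands ≥2
surviving values per masked cell.

## Synthetic data-generating model

Per patient: transplant stratum with probability 0.111; age
N(72, 10.4) (non-transplant) or N(65, 8.7) (transplant) truncated to
[20, 100]; sex and race from stratum mixes; index date uniform over
2007-01-01..2015-12-31; MM diagnosis at index; comorbidity diagnoses
planted uniformly in the 180-day pre-index window at stratified
prevalences taken from published baseline tables; 2% receive a
prior-malignancy code inside the look-back (exercising the exclusion).

The treatment journey is drawn line by line: at line k the patient
continues with probability `continuation[k]`, dies with `death[k]`, else
is censored treatment-free.  Defaults are the published per-line values
(non-transplant continuation 0.431/0.545/0.573/0.574/0.580, death ≈0.12;
transplant 0.790/0.692/0.631/0.648/0.629, death 0.013–0.079).  Line
durations are log-normal in months with (μ, σ) solved from the published
mean/median pairs (σ² = 2 ln(mean/median)); between-line gaps are
61 + LogNormal(3.5, 0.6) days, always exceeding the discontinuation gap.
Claims realize each line exactly: every regimen agent refills at its
cadence (30-day oral, 7-day parenteral) with the final supply trimmed to
the line end, so the engine reconstructs the planned lines verbatim.
Transplant patients receive one ASCT — after LOT1 for the frontline-
induction share (overall 60.9%), during LOT2 otherwise — and 11.1% of
frontline-induction patients get a consolidation segment (same regimen,
start ≤60 days post-ASCT, 30–120 days long).  Non-consolidation follow-on
lines are pushed beyond the 122-day window so they cannot be mistaken for
consolidation.  Death, when planned, falls 1–30 days after the last
activity; coverage spans from 365–730 days before index to 90–365 days
after the last activity (or past death), so planned journeys are fully
observed.  A configurable `violation_fraction` (default 5%) injects a
mid-line ≥60-day gap or a late add-on agent to exercise the engine;
ground-truth flags mark these patients.

**What the generator does not emulate:** costs, ICD coding noise,
plan-switch record linkage, dose/schedule structure, disease progression,
or informative censoring — `coverage_censor_rate` and `emr_fraction`
default to 0 so that the configured journey parameters are exactly
recoverable; raising them introduces loss to follow-up (and, for EMR
sources, last-activity follow-up ends) and correspondingly depressed
observed continuation.  Passing recovery tests therefore demonstrate the
*correctness of the constructions*, not the realism of any particular
claims source.

## Problem sizes and determinism

The test suite exercises the engine-vs-oracle equivalence on 1,000 random
claim streams, journey recovery on a 20,000-patient cohort, logistic
recovery at n = 10,000, and suppression safety on 200 fuzzed tables; the
acceptance script uses a 25,000-patient cohort.  All randomness flows
from `numpy.random.default_rng` seeded from the config or the `--seed`
argument; identical seeds give byte-identical tables and report bundles,
and patient identifiers embed the seed so different seeds produce disjoint
id sequences.

## Known limitations

* The published business-rule supplement for LOT construction is not
  public; the formation window, steroid exemption and restart-as-new-line
  behavior here are declared defaults, each exposed as configuration.
* Maintenance therapy is not labeled as a named phase, and second-line
  regimen taxonomy is out of scope.
* Cross-database deduplication and Medicare-Advantage exclusion mechanics
  require real linkage keys and are not modeled.
* Attrition comparisons across strata are not exposure-adjusted, and no
  survival analysis is performed.
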