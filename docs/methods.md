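# Methods

## The estimand

The package estimates *persistence* of newly prescribed oral
5-aminosalicylic acid (5-ASA, mesalamine-class) in ulcerative colitis
(UC): the proportion of a new-user cohort whose prescription stream has
not yet been interrupted at a given number of days after the first
(index) dispensing. Persistence is tracked for the drug class as a
whole — switches among the three oral release mechanisms
(time-dependent, pH-dependent, multi-matrix/MMX) never count as
interruption — and reported overall and stratified by index subtype,
age group and fiscal year of initiation.

## Cohort definition

A patient is a new user when all four criteria hold, applied in this
order (the attrition report records the count surviving each step):

1. **Index**: at least one oral 5-ASA dispensing during the accrual
   window (default April 1, 2015 – September 30, 2019). The earliest
   such dispensing sets day 0; same-day ties break lexicographically by
   (subtype, drug code), a deterministic convention the design itself
   leaves open.
2. **Diagnosis**: a UC diagnosis carried as *principal* — for DPC
   (bundled inpatient) claims any of the four principal-style fields,
   collapsed to one flag at ingestion — and never flagged *suspected*,
   at the institution that dispensed the index prescription, dated
   within day −28 .. +28.
3. **Washout**: no oral or topical 5-ASA and no salazosulfapyridine
   (SASP) dispensing on days −365 .. −1.
4. **Enrollment**: at least one visit of any kind between the database
   start (April 1, 2013) and day −366, proving the washout window is
   observable.

All window endpoints are inclusive; none of the criteria's sources use
exclusion language, and the inclusive reading is applied uniformly.

## Episode construction and the grace period

Coverage is tracked as a **supply frontier**: the running first
uncovered day implied by fill dates plus days-supply. Overlapping
fills are absorbed by a max rule — early refills shift the frontier to
the later supply end but stockpiles are not summed, since the grace
period already absorbs irregular dispensing.

With grace period *g* (default 90 days; 30 and 60 for sensitivity):

* if the next fill starts more than *g* days after the frontier, the
  episode ends and the discontinuation day is **backdated to the
  frontier** — the last day of continuously supplied treatment. This
  backdating is what produces a visible first-month drop even under a
  90-day grace: a patient with a 30-day index supply and no refill is
  discontinued at day 30, not day 120.
* if no further fill exists and frontier + *g* falls on or before the
  monitoring horizon, the episode ends at the frontier as well; if the
  grace window extends past the horizon the patient counts as
  persistent, since a refill could lie beyond observation.
* death before any gap ends the episode at the death offset; when both
  causes land on the same day, death is taken as the earlier cause (an
  arbitrary but documented tie-break).

A day-by-day brute-force oracle implements the same contract by
literal simulation and is held equal to the scan implementation on
randomized instances in the test suite.

The monitoring horizon defaults to 500 days so that the published
evaluation grid (0/30/90/180/365/500) is computable; the headline
monitoring period of the design is 365 days. Members whose potential
follow-up is cut short by the end of the data window are logged, never
silently censored.

## Persistence tables

At evaluation day *t*, `n_persistent` counts members whose episode end
is absent or strictly after *t*; the proportion uses the stratum's
**fixed day-0 denominator** (deceased members stay in the
denominator — the published counts are exact ratios of survivors to
n0, which identifies this convention). Confidence intervals are Wald
intervals on the percent scale, z = Φ⁻¹(0.975) ≈ 1.959964 at the 95%
level, clipped to [0, 100]. The Wald form reproduces every printed
interval checked to one decimal; score and exact intervals do not.
Displayed values round half away from zero to one decimal; output CSVs
carry full-precision columns alongside.

This is deliberately *not* Kaplan–Meier estimation: there is no
censoring-adjusted denominator, no time-to-event regression, and no
adherence metric such as proportion of days covered.

## Synthetic claims generator

The real study population (a national claims database) is not
distributable, so the generator emulates its structure with known
ground truth. Per patient:

* **Demographics**: age at index ~ Normal(43.2, 16.7) truncated at 0,
  male fraction 0.565 — the shape of the published cohort. Birth is
  stored at year-month precision; age uses the born-on-day-1
  convention (claims carry no day of birth, and month precision cannot
  misclassify the 20/40/65 cut points by more than one month).
* **Index date** uniform over the accrual window; index subtype drawn
  from a per-fiscal-year mixture in which pH-dependent leads in FY2015
  (53.2% vs 46.8%) and MMX rises steadily after its November 2016
  market entry; MMX probability is forced to zero before that date.
* **Refill process**: a discrete refill-cycle hazard. Each cycle
  dispenses a days-supply from {14, 28, 30, 56, 90} (mode 30); after a
  cycle the patient stops with probability 0.14 on the first cycle
  (the early-intolerance spike — clinically 5–10% of patients abandon
  the drug class in the first month) and 0.055 per later cycle; the
  next fill arrives at the frontier plus a delay whose distribution
  has a long tail (up to 75 days), so that some refills only survive
  the wider grace periods. These defaults were fixed once to mimic the
  published curve shape (≈ 12% first-month drop, ≈ 56–58% one-year
  persistence, and 30-/60-/90-day grace values ordered ≈ 44% < 53% <
  57%).
* **Contamination classes** (defaults 50% prior users, 4% suspected
  only, 6% no principal diagnosis, 5% unenrolled — roughly the
  published funnel, where about two thirds of diagnosed patients fail
  new-user screening) each violate exactly one criterion while
  satisfying the rest, so the included set must equal the eligible set
  exactly. Two constructions protect that exactness: oral prior-user
  fills are kept at least 57 days before the intended index so they
  can never themselves qualify as an index with a matching diagnosis,
  and deaths are drawn at offset ≥ 29 so truncation can never delete
  the qualifying diagnosis.
* **Deaths** occur post-index at a low rate (0.2%/year); they truncate
  the event stream and are recorded explicitly.

The ground-truth table stores each patient's intended label, index
subtype and raw stopping day (the frontier at the hazard-driven stop).
`true_persistence(params, t)` computes the exact distribution of that
stopping day by convolving the per-cycle (delay + supply)
distributions cycle by cycle — a deterministic closed form used as the
parameter-recovery target; deaths are excluded from it (their bias at
the default rate is far below sampling noise at the problem sizes
used). With fixed 30-day cycles, zero delay and constant hazard *h*
this reduces to the geometric form (1−h)^⌊t/30⌋, which the tests
assert.

### What the generator does not emulate

Real claims carry unstable patient identifiers across insurer changes,
incomplete death ascertainment, true national drug/disease code
dictionaries, DPC bundling economics, seasonal prescribing, and
informative loss to follow-up. Passing tests therefore demonstrate
that the pipeline implements the stated design correctly on data of
the stated structure — not that the design is robust to those
real-data pathologies, which the underlying study handled with methods
out of scope here (stable IDs and explicit death records are assumed).

## Numerical and design choices

* Problem sizes: acceptance-style checks use 5,000 generated patients
  for point recovery and 20 replicates of 2,000 for interval coverage;
  unit fixtures use a few hundred. These sizes put Monte Carlo error
  well inside the tolerances asserted.
* Determinism: one `numpy` Generator seeded per run drives every draw
  in a fixed patient order; CSV writers fix column order, sort rows,
  and use `\n` endings, so identical inputs give byte-identical
  artifacts.
* Degenerate inputs: empty bundles round-trip as header-only CSVs;
  empty strata are omitted with a logged warning; a zero denominator
  for a confidence interval is an error, not a NaN.
* The cohort step rejects (rather than drops) patients whose death
  predates their index dispensing — in this data model that is a
  defect, not a clinical state.

## Known limitations

* The fixed-denominator design understates uncertainty late in
  follow-up relative to survival-analysis estimators when deaths or
  disenrollment are common; here they are rare by construction.
* Wald intervals degrade near 0%/100% and small n; they are used
  because they are the published convention, and displayed intervals
  clip to [0, 100].
* The generator's hazard process is stationary beyond the first cycle;
  real discontinuation hazards decline with treatment duration.
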