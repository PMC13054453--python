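# Methods

## The data model

An ICSR database is five tidy tables: reports (country, reporting year,
reporter type, seriousness, age, sex), report–drug links (with role:
suspect, interacting, or concomitant, and a possibly partial start date),
report–event links (MedDRA-like PT code, possibly partial onset date), a
drug dictionary (ATC codes, class tags, a treatment-exclusion flag), and
a single-axis event dictionary (PT → HLT → SOC). Seriousness is a single
boolean summarising the regulatory criteria (death, life-threat,
hospitalisation, disability, congenital anomaly, medically significant).
Referential-integrity violations on load are skipped row-wise and
collected, never silently dropped wholesale; a database with zero valid
reports is an error.

Case series are defined by a PT set. The narrow definition is the single
index PT (Raynaud's phenomenon); the broad definition adds peripheral
ischaemia and chilblains to absorb coding variability. Reports carrying
any drug of the treatment-exclusion classes — in **any** role — are
removed from the analysis entirely: a vasodilator prescribed
concomitantly signals pre-existing disease just as a suspect one does, so
role-restricted exclusion would leak indication bias into the case
series. The exclusion list ships as configurable ATC prefixes (calcium
channel blockers C08, PDE5 inhibitors G04BE, endothelin antagonists
C02KX, ARBs C09C/C09D, ACE inhibitors C09A/C09B, alpha blockers C02CA,
prostanoid codes B01AC09/11/21); an explicit dictionary flag can be used
instead.

Excluded cases leave the comparator universe as well: the comparator for
every analysis is "all remaining reports", not "all reports".

### Dates and time to onset

Partial dates are completed deterministically: a missing day becomes the
15th; a missing month (and day) becomes July 2, the middle of the year.
Time to onset (TTO) is onset minus drug start in real calendar days —
never 30-day months. If either date is absent entirely the TTO is
missing; if completion produces a negative TTO the value is discarded,
because its sign is then an imputation artefact. A genuine same-day
start and onset (TTO = 0) is kept. Drug start dates use the same
completion rule as event onsets.

## The information component

For a 2×2 of drug × event over N reports, with O observed co-reports and
E = n_drug · n_event / N expected under independence,

    IC    = log2((O + 0.5) / (E + 0.5))
    IC_LB = log2(q_0.025),   q_α = α-quantile of Gamma(shape O + 0.5,
                                                       rate  E + 0.5)

The +0.5 offsets shrink small-count ratios toward 1 (IC(0, 0) = 0), and
the gamma posterior of the shrunk ratio has mean (O+0.5)/(E+0.5), so the
interval is centred on the point estimate. The significance rule is
IC_LB > 0. A closed-form approximation

    IC_LB ≈ IC − 3.3 (O + 0.5)^(−1/2) − 2 (O + 0.5)^(−3/2)

is implemented as an independent cross-check; the two agree within 0.1
bits for O ≥ 10 (verified on a grid in the test suite, alongside an
arbitrary-precision bisection oracle for the gamma quantile).

Drug marginals count suspect and interacting entries only; concomitant
drugs appear in case summaries but never in contingency tables. No
minimum-count filter is imposed at computation time; reporting layers may
filter (the screening helper takes `min_obs`).

### Sensitivity analyses

1. **hcp_only** — cases and comparator both restricted to reports by
   health-care professionals (the conservative reading: restricting only
   the cases would mix reporter populations across the 2×2).
2. **atc3_background** — per drug, the comparator is the set of reports
   carrying ≥ 1 suspect/interacting drug sharing any ATC level-3 prefix
   (first 4 characters) with it, the index drug's own reports included.
   Multi-class drugs take the union of their classes. Drugs without an
   ATC code, or with no case in the restricted background, are flagged
   not-evaluable rather than dropped.
3. **mh_stratified** — strata are sex × age band (<18, 18–44, 45–64,
   65–74, ≥75, with "unknown" its own level on both axes). The expected
   count is pooled across strata, E_MH = Σ_s n_drug,s · n_event,s / N_s,
   and the IC machinery is applied to (O_total, E_MH); with one stratum
   this reduces bit-for-bit to the crude analysis. Pooling expected
   counts (rather than averaging stratum ICs) keeps the statistic defined
   when strata are sparse.
4. **broad_definition** — the three-PT case set, with the exclusion rule
   re-applied to the broader series.

The consistency workflow calls a drug *consistent* when it is significant
in the primary analysis and in every sensitivity analysis where it is
evaluable; non-evaluable analyses are excluded from the requirement and
flagged, so a drug with zero HCP reports is not penalised for silence.
Ranking is by (consistent, primary IC_LB) descending. Fixed-dose
combination products (class tag `combination`) are dropped from rankings
— their signals are not attributable to a single substance. Prior
awareness, when a lookup table is supplied, is carried through verbatim;
plausibility adjudication is expert work and is deliberately not
automated.

## Symptom networks

Within the reports of one drug class, each PT (other than the index PTs)
gets a 2×2 of (PT present) × (report is an index case); PTs with
IC_LB > 0 form the node set. The binary case-by-term matrix over the
class's index cases feeds two estimators:

- **Ising**: each column is regressed on all others by L1-penalised
  logistic regression over a 30-point log-spaced λ path (λ_max from the
  score at the null model down to λ_max/100), the per-node penalty chosen
  by the extended BIC, EBIC = −2ℓ + k log n + 2γ k log(p−1), with
  γ = 0.25. The intercept is left effectively unpenalised
  (`intercept_scaling = 100`); penalising it distorts edge selection and
  measurably inflates the false-edge rate. Couplings are symmetrised by
  the AND rule — an edge survives only if selected in both directions,
  with weight the mean of the two coefficients (the OR rule is available
  and the AND network is always a subgraph of it). Fits are refused below
  20 rows or 3 columns, where the estimate is unstable; perfectly
  collinear columns (equal or complementary) are dropped with a warning.
- **PPMI**: pmi(a,b) = log2(p(a,b) / (p(a) p(b))) with probabilities as
  relative frequencies and +0.5 smoothing on the joint count (a finite
  value for zero joints, which clip to 0 regardless); PPMI = max(pmi, 0).
  Symmetry and non-negativity are asserted on every run.

Communities are found by walktrap (4 steps) on positive edge weights —
deterministic, standard in symptom-network work; Louvain is available
and seedable. Partitions from the two estimators are compared by the
adjusted Rand index plus a Jaccard overlap of the positive edge sets,
because the two methods need not agree and the disagreement is itself a
finding. No consensus partition is constructed: averaging two unstable
partitions would manufacture precision.

## Target aggregation

Given a drug → (target, action) map, each (target, action) pair
accumulates the number of distinct signal drugs hitting it and the sum of
their primary-analysis case counts, ordered by case count, then drug
count, then target id. A drug with k targets contributes its count k
times — the multiplicity is deliberate (the question is which mechanism
the most reports touch) and visible in the schema. Unmapped drugs are
reported, not dropped silently.

## The synthetic generator

The generator emulates the structure of a large spontaneous-report
database at a desk-scale default of 20,000 reports, 80 drugs, and 60 PTs.
Each report draws demographics (sex 60/37/3% F/M/unknown; age normal with
mean 47.4 and SD 19 years, matching published Raynaud case-series
demographics, 8% missing; reporter type 59% health-professional; country
and reporting year 2005–2024), then 1–5 drugs from a rank-power-law pool
(the first selected drug is the suspect anchor; later ones draw
suspect/interacting/concomitant at 65/10/25%), then events as
**independent per-PT Bernoulli draws** given the drugs and stratum. That
conditional-independence design is the point: planted rate ratios are
exact in expectation, and any pair without planted structure is
independent given the stratum, so calibration tests have a clean null.
Base PT rates follow a power law (0.10 down to 0.004); the index PT's
baseline is 1%, giving ~200 cases per database.

Planted structure:

- **Signals**: a (drug, PT, rate ratio ≥ 1) triple multiplies the PT's
  probability when the drug is present as suspect/interacting. Optionally
  the drug is included through an independent Bernoulli channel with a
  fixed prevalence, making the pair's expected O available in closed form
  (used to put the power scenario at rate ratio 4 with E[O] = 25).
- **Confounders**: a drug and a PT each multiplied (default ×3) in one
  stratum (default: female reports), independent within every stratum —
  the canonical scenario where the crude O/E sits near 1.2 while every
  stratum is null, so the crude analysis flags the pair and the MH
  analysis must not.
- **Clusters**: a latent per-report switch (on with probability 0.3 in
  reports carrying a tagged class drug) OR-adds 0.35 occurrence
  probability to each member PT. Making the index PT itself a member ties
  the others to it, which is what gives the event–event selection and the
  network estimators a recoverable target.

Probabilities pushed above 1 by multipliers are a hard error naming the
offending pair. Reports are conditioned to carry ≥ 1 event by redrawing
event vectors for empty reports (a rejection step whose effect on
pairwise association is negligible at these rates) and capped at 10
events. Dates are generated around a per-report anchor with exponential
onset delays (scale 45 days) and configurable missingness (15% absent,
8% month-less, 20% day-less) so the completion rules are exercised.
Everything is deterministic given the seed — the same configuration
serialises to byte-identical TSVs — and the ground-truth ledger records
the planted structure plus realised stratum and reporter counts exactly.

What the generator does **not** emulate: reporting-lag dynamics, country
reporting cultures, duplicate reports, masking by blockbuster drugs,
narrative text, or MedDRA's true multi-axiality. Passing recovery tests
on this generator therefore demonstrates that the statistics do what
they claim under their own assumptions — not that real-database signals
are causal, which still requires the expert review the workflow's output
feeds.

## Problem sizes and numerical choices

Calibration and power checks run 10–20 databases of 20,000 reports;
network recovery uses 1,000 exact draws (full 2^10-state enumeration)
from a planted two-clique Ising model over 5–10 seeds. These sizes put
Monte-Carlo noise well inside the asserted bands while keeping a full
run in minutes on one core. All randomness descends from one seed;
sub-seeds are derived arithmetically and kept below 2^31. Gamma quantiles
come from scipy; liblinear fits are pinned with a fixed random state so
pipeline reruns are byte-identical. TSV output uses a fixed `%.6g` float
format; manifests record SHA-256 hashes of all inputs and outputs and
contain no timestamps.

## Known limitations

- The single-axis event dictionary ignores MedDRA multi-axiality; HLT/SOC
  levels are carried but unused by the statistics.
- The ATC3 background treats a multi-class drug as the union of its
  classes; a per-class decomposition is not attempted.
- The Ising false-edge rate is controlled empirically by EBIC, not by a
  formal error guarantee; bootstrap stability analysis is out of scope.
- Duplicate-report detection is not implemented; the generator plants
  none.
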