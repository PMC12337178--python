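# Methods

`dispro` implements a disproportionality (signal-detection) analysis for
spontaneous adverse-event report databases distributed in the FAERS
quarterly ASCII dialect, together with a synthetic-data generator that
emulates that dialect with known ground truth. This note records the
statistical model, the data-processing rules, the defaults and the design
decisions, in the package's own words.

## The screening problem

A spontaneous-report database holds reports, each naming one or more drugs
(with a role code: 1 = suspect, 2 = concomitant, 3 = interacting) and one
or more adverse-event terms coded to a MedDRA-style hierarchy (PT nested in
SOC). Disproportionality analysis asks, for a target drug and each event
stratum, whether the event is reported *relatively* more often with the
target drug than with everything else in the database. It estimates
reporting associations, not incidence or causation: the database has no
denominators of exposed patients and is subject to under- and
over-reporting.

The unit of counting is the (report, term) pair — a term repeated within a
report counts once; a report with three gastrointestinal PTs contributes
three pairs to the gastrointestinal SOC. Each stratum is reduced to a 2x2
table

|                | target event | other events |
|----------------|--------------|--------------|
| target drug    | a            | b            |
| other drugs    | c            | d            |

with `N = a+b+c+d` and the expected count under independence
`E = (a+b)(a+c)/N`.

## Cohort construction

1. **Deduplication.** Cases (CASEIDs) are re-submitted across quarters
   under increasing version identifiers (PRIMARYIDs). Per CASEID, only the
   row with the largest PRIMARYID is retained; PRIMARYIDs are compared
   numerically when all parse as integers, else lexicographically on
   zero-padded strings. Deduplication runs *before* drug filtering.
2. **Deleted cases.** Any CASEID on the package's deleted-cases list is
   removed, whatever its version.
3. **Primary-suspect cohort.** A report enters the cohort iff some drug
   row *simultaneously* matches the target-name rule and carries role
   code 1. A matching drug listed only as concomitant never qualifies a
   report (the stricter same-row reading; the alternative — PS role
   anywhere on a matching report — was rejected as it would admit reports
   whose suspect drug is a different product).
4. **Name matching.** Raw drug strings are case-folded,
   whitespace-collapsed and stripped of trailing dose/form tokens; a
   string matches if a target name (generic or brand) is a substring, or
   if the normalised Levenshtein distance to a target name is at most
   0.1 (configurable). Edit distances come from `edlib`.

## The four statistics

* **ROR** `= ad/bc`, 95% CI `exp(ln ROR ± 1.96·sqrt(1/a+1/b+1/c+1/d))`
  (Woolf). Any zero cell makes the estistic undefined and it is reported
  as such — no silent continuity correction; a Haldane–Anscombe 0.5
  correction is available behind `continuity=0.5`.
* **PRR** `= [a/(a+b)] / [c/(c+d)]` with the Yates-corrected Pearson
  chi-squared (the convention in this literature; the uncorrected variant
  is a switch).
* **BCPNN IC** (default variant): the relative reporting rate λ gets a
  Gamma(a+1/2, rate E+1/2) posterior; `IC = log2` posterior mean
  `= log2[(a+0.5)/(E+0.5)]` and `IC025` is log2 of the posterior 2.5th
  percentile. This is the modern shrunk observed/expected form; the
  original 1998 closed-form posterior moments (Beta priors on the
  margins, `IC025 = E[IC] − 1.96·sd`) are selectable with
  `variant="bate1998"`. Both are validated against numerical integration
  of the posterior.
* **MGPS EBGM**: λ has a two-component gamma mixture prior
  `P·Gamma(α1,β1) + (1−P)·Gamma(α2,β2)` fitted *database-wide* by
  maximising the negative-binomial-mixture marginal likelihood over all
  drug×PT cells of the loaded package (not only the target drug's rows —
  the shrinkage prior is a property of the database). Optimisation is
  L-BFGS-B on log/logit-transformed parameters, initialised at the classic
  values (0.2, 0.1, 2.0, 4.0, 1/3), convergence at relative
  log-likelihood change < 1e-8 or 500 iterations, parameters bounded to
  e^±12 to keep sparse fits away from under/overflow. The posterior per
  cell is again a two-component gamma mixture with weights proportional
  to P_j times the negative-binomial marginal;
  `EBGM = 2^{E[log2 λ | a, E]}` and `EBGM05` is the posterior 5th
  percentile, obtained by Brent root-finding on the monotone mixture CDF
  to 1e-6. Hyperparameters of the mixture are weakly identified (two
  parameterisations can give near-identical marginals), so the fit is
  validated by marginal likelihood, not by parameter recovery.

**Signal criteria** (each threshold configurable): ROR flag `a ≥ 3` and
lower CI bound `> 1`; PRR flag `a ≥ 3`, `PRR ≥ 2`, `χ² ≥ 4`; BCPNN flag
`IC025 > 0` (strict); MGPS flag `EBGM05 > 2`; the combined flag is their
conjunction. Undefined statistics fail closed with a recorded reason.

Useful identities kept under test: on any positive table ROR and PRR sit
on the same side of 1 with |ROR−1| ≥ |PRR−1|; IC → log2(EBGM) as counts
grow at fixed a/E; IC and EBGM are nondecreasing in a *at fixed E* (for
fixed b, c, d the expected count grows with a, which can reverse the raw
ratio on tiny tables — the fixed-E statement is the true one).

## Descriptives and time-to-onset

Every categorical block (sex, age group, country, reporter type, receipt
year) is summarised over its known (non-missing) denominator, with the
denominator reported as a share of the cohort. Age is normalised to years
from the FAERS unit code (DEC×10, MON÷12, WK÷52, DY÷365; unknown units →
missing). Reporting year uses the FDA receipt date, which is essentially
complete, rather than the often-missing event date.

A report is *serious* iff it carries at least one outcome code. Two views
of the serious subcategories are produced: (i) a precedence view (death >
life-threatening > disability > hospitalisation > other; one category per
report) whose percentages sum to 100; and (ii) a per-code view in which a
report counts in every code it carries — the counting convention of
published safety profiles, where subcategory percentages can sum past
100. Both use the serious count as denominator.

Time-to-onset is the day difference between the event date and the
earliest therapy-start date on a primary-suspect target-drug row. Pairs
are excluded (and counted by reason) when either date is missing, lacks
day precision (FAERS dates are 8-, 6- or 4-digit strings), or the
difference is negative. Day-0 (same-day) onsets are retained. Quartiles
use linear interpolation (the numpy default; a published IQR bound of
115.75 days implies an interpolating convention). Onset bins are fixed as
[0, 30], (30, 90], (90, 365] and (365, ∞) days — "first month" means ≤ 30
days, day 31 opens the second bin — and are stated in the output
metadata.

## The synthetic world

The generator emits complete quarterly packages ("$"-delimited DEMO /
DRUG / REAC / OUTC / RPSR / THER / INDI plus a deleted-cases list) whose
regime follows a real post-marketing cohort for a recently approved
orphan drug:

* ~4% of reports name the target drug (desk-scale cohorts of ~2,000 from
  50,000 reports; the target share mirrors the cohort size, not the
  1:2,000 dilution of the full national database);
* 81.65% missing sex, 82.58% missing age, 32.68% serious, 24.23% of
  reports with a computable onset, 99% US reports, 85% consumer reporters,
  receipt-year weights 0.19/0.55/0.25 over a three-year window;
* event frequencies follow a Zipf law (s = 0.7) over a bundled ~200-term
  mock vocabulary, with clinically common terms at the head;
* the comparator background holds 500 drugs, each with its event profile
  tilted by mean-1 log-normal factors (σ = 0.8 per drug×PT cell):
  across-drug heterogeneity is what the empirical-Bayes prior exists to
  capture. In a homogeneous world the fitted prior collapses to a point
  mass at 1 and over-shrinks genuine signals, which contradicts the
  documented large-database regime in which EBGM tracks the PRR at counts
  in the hundreds; many drugs with dispersed profiles reproduce that
  regime, while the per-package noise they add to any one PT's background
  rate shrinks as 1/sqrt(n_drugs);
* onset times are log-normal with median 27 days and σ = 1.5 on the log
  scale — a stand-in calibrated only by the published median/IQR, not an
  inferred shape;
* duplicates are exact content copies under the next version number, so
  the max-PRIMARYID rule is sufficient to resolve them; deleted cases
  remain in the tables and are listed in DELETED.txt.

**Planted signals.** Reactions are drawn per (report, PT) as independent
Bernoulli trials with inclusion probability q_j (summing to the mean
pairs-per-report, 2.3). A planted PT with relative reporting ratio λ gets
exactly λ·q_j among target-drug reports, with the other PTs rescaled to
preserve the total; the realised (a/(a+b))/(c/(c+d)) therefore estimates λ
directly. (A draw-then-deduplicate multinomial scheme was rejected: within-
report collapse shrinks frequent PTs more, biasing the realised ratio —
measurably, a planted λ = 4 came out near 3.6.)

What the generator does *not* emulate: reporting dynamics over time
(Weibull onset hazards, stimulated-reporting waves), country-specific
reporting cultures, free-text noise beyond simple name decorations,
multi-drug interaction signals, and MedDRA version migration. Passing
tests on this world show the pipeline's bookkeeping and statistics are
correct under a realistic missingness/heterogeneity regime; they do not
validate causal interpretation on real data.

## Problem sizes and verification

The test suite and the acceptance script run the recovery study at 50,000
reports per package and 100 seeded replicates (three planted ratios λ ∈
{1, 2, 4} per package), the scale at which a ~2,000-report cohort gives
the planted-signal cells counts of the order seen in published tables.
Verification is three-layered: worked examples reconstructed from
published marginal counts recompute exactly; ROR/PRR/χ² match closed-form
arithmetic and scipy; IC025 and EBGM05 match quadrature oracles (numerical
integration of the posterior densities, with marginal weights themselves
obtained by numerical integration) to 1e-3; and on the synthetic world the
dedup stage recovers the canonical cohort exactly, λ = 4 plants are
flagged by all four criteria, λ = 1 plants are flagged in ≤ 5% of
replicates, and ROR CIs cover λ at ≥ 90%.

## Known limitations

* The mock vocabulary is two-level (PT → SOC); HLT/HLGT aggregation and
  SMQ groupings are out of scope, as is multi-axial SOC assignment
  (each PT has a single primary SOC).
* MGPS is unstratified; age/sex-stratified expected counts are not
  implemented.
* No multiple-comparison correction is applied across PTs (none is
  conventional in this screening setting).
* Full-scale FAERS ingestion works through the same reader but is not
  performance-tuned; files are read whole, not streamed.
* Real FAERS drug strings are far noisier than the generator's
  decorations; the fuzzy matcher's 0.1 threshold is a default to audit,
  not a guarantee.
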