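# Methods

## The case/non-case design

`pvsignal` screens a spontaneous-reporting database (a collection of
individual case safety reports, ICSRs) for disproportionate reporting of a
target adverse event with particular drug classes. Reports coded with the
target event term are the *cases*; every other report in the database is a
*non-case*. For each drug class X the report-level 2×2 table is

|              | case | non-case |
|--------------|------|----------|
| exposed to X | a    | b        |
| not exposed  | c    | d        |

where "exposed" means the report carries at least one *suspect-role* drug
of class X (concomitant medication is excluded by default, switchable).
The counting unit is the report: a report with several suspect drugs of
one class contributes one count to that class; a report with suspect drugs
of several classes contributes one count to each. The comparator (c, d) is
all remaining reports regardless of their drug content — in particular, c
contains cases exposed only to *other* classes. This convention is what
published screens of this type tabulate, and it is the one the reference
reconstruction reproduces exactly.

The reporting odds ratio is ROR = ad/bc, with the log-normal (Woolf)
interval

    exp( ln ROR ± z · √(1/a + 1/b + 1/c + 1/d) ),   z = Φ⁻¹((1+level)/2),

and a Pearson χ² p-value (1 df, no continuity correction). Classes with
fewer than `min_exposed_cases` (default 3) exposed cases are reported with
their counts but no statistics ("not evaluable"). A class is flagged as a
*signal* when the lower CI bound exceeds 1. The ROR is a reporting
association, not a causal effect; no multiple-testing correction is
applied (recorded in the output metadata).

Method choices that the underlying analyses usually leave unstated were
fixed by arithmetic against a published vaccine screen of anti-NMDA
receptor encephalitis (anti-NMDAR encephalitis, ~70 cases among ~29.8M
reports): the Woolf interval reproduces every printed CI bound, and the
uncorrected Pearson χ² reproduces the one p-value printed above 0.001
(0.262 for the COVID-19 class, where a Wald log-OR test would give 0.268).
These printed counts live in `pvsignal.reference` and serve as fixture
inputs; the five classes excluded by the minimum-count filter have
synthetic stand-in counts (their true cells were not published) used only
to exercise the filter.

## Zero cells and rounding

With the default `min_exposed_cases ≥ 3`, a = 0 cannot reach the
statistics; b = 0 can occur on tiny data. The default policy is to refuse
with an explicit error naming the zero cell; the Haldane–Anscombe +0.5
correction (applied to all four cells when any is zero) is available
behind `zero_correction=True`. Display rounding follows the conventions of
published tables: ROR to 2 decimals, CI bounds to 3 significant figures,
p-values to 3 decimals with "<0.001" below 0.0005; all writers also emit
full-precision values. Rounding is half-away-from-zero (`Decimal`), not
banker's rounding, to match printed tables.

## Descriptive case-series statistics

Medians use the arithmetic midpoint of the two central order statistics
for even n (so half-integer medians occur). Every percentage is computed
over the known-value denominator of its field, and the denominator is
stored in `CaseSummary.denominators` so any figure can be re-derived.
Age strata are [0, 15) and [15, 30], with exactly 15 years assigned to the
older stratum. Time to onset for a (report, class) pair is the earliest
onset date of a matching event minus the latest administration date of a
suspect drug of the class on or before that onset; negative-only
configurations are dropped with a logged warning, and the per-case value
summarised is the minimum over the case's exposed classes. Drug-class
shares in the case summary are *mention-level* (denominator: all suspect
mentions in exposure classes), unlike the report-level contingency counts;
both conventions coexist deliberately and are labelled.

## Synthetic databases

`pvsignal.simulate` emulates the statistical structure the design assumes:

* each report is exposed to each class independently with the class's
  `exposure_prevalence` (the class's share of database reports);
* the target event occurs with probability `background_event_prob ×
  max(rr over exposed classes)` — a multiplicative relative reporting
  rate, the simplest mechanism whose induced ROR approaches the injected
  rr when the event is rare (for common events the odds ratio exceeds the
  rate ratio; a small-sample/rare-event bias documented here);
* demographics, onset lags (log-normal, median 4 days, capped at 730),
  seriousness and outcome are drawn from configurable marginals,
  independent of exposure — real databases likely correlate seriousness
  with reporting probability, which is not modelled.

Defaults are anchored to the reference case series: background event
probability 2.4 per million reports, 56% female, mostly paediatric ages
for childhood-vaccine classes, country weights concentrated on the three
top reporting countries, outcome weights matching the published outcome
distribution. The generator produces suspect-role exposures only; it does
not model drug-name vocabularies, duplicate reports, or country-specific
reporting cultures — so passing tests demonstrate correctness of the
pipeline's counting and statistics, not realism of any particular
database.

Two generation paths share the same random draws: a materialized path
building full `ICSReport` objects, and a counts-only path
(`simulate_tables`) tallying the 2×2 tables directly; a test asserts they
produce identical tables for the same seed. Replicated
operating-characteristic runs use the counts-only path with per-replicate
seeds spawned from the config seed (`numpy` `SeedSequence`), making them
deterministic.

`generate_tabulated` reconstructs a minimal report set from explicit
per-class (a, b) counts and totals; class exposures among cases are
assigned least-loaded-first over a configurable number of exposed cases,
so multi-class case reports absorb the excess when Σa exceeds the number
of vaccine-involved cases. A counts-only twin (`tabulate_virtual`) yields
the same tables without materializing rows, which is how the full
29.8M-report reconstruction is screened in well under a second.

## Operating characteristics

`evaluate_operating_characteristics` replicates generate→screen and
aggregates per-class flag frequencies. Because the signal flag
(`ci_low > 1`) is a one-sided rejection of a two-sided interval, its null
rate is nominally (1−level)/2, i.e. 2.5% at the default level; the
conventional type-I error — the rate at which the interval excludes 1 on
either side, nominally 5% — is reported as `type1_error`, with the
directional flag rate alongside as `flag_rate_null`. Two stock designs are
provided:

* `null_config()` — 10 classes, prevalence 0.10, rr = 1, background 0.01,
  n = 20,000: expected a ≈ 20 per class, chosen so the normal-theory
  interval is in its intended regime when measuring calibration (at much
  smaller cells the interval is visibly conservative and a calibration
  check would measure discreteness, not the method).
* `power_config()` — one class, prevalence 0.004 (an HPV-like database
  share), rr = 10, background 2.4e-4, n = 2×10⁶: expected a ≈ 19, a design
  point at which detection should be near-certain (measured power 1.00
  over 200 replicates). The parameter-recovery grid (rr ∈ {1, 2, 10, 50})
  uses prevalence 0.02 at the same background and size so the rr = 1 corner
  still yields enough exposed cases (≈ 10) for the estimate to exist.

Problem sizes in the test suite are scaled-down variants (database totals
divided by 1,000 for materialized fixtures; the full-scale reconstruction
runs through the counts-only path), keeping the default suite fast while
still exercising every stage end to end.

## Known limitations

* Exact term matching only — no MedDRA hierarchy roll-up.
* No deduplication or follow-up handling; report ids are assumed final.
* ISO-8601 full dates only (no partial dates).
* Independence of exposures across classes in the generator; real
  vaccination co-administration is correlated.
* The ROR quantifies reporting disproportionality; it supports signal
  detection, not causal inference or incidence estimation.
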