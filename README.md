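# pvsignal

Case/non-case disproportionality screening for spontaneous adverse-event
reporting databases, with a synthetic ICSR generator for validation.

Pharmacovigilance teams mine databases of individual case safety reports
(ICSRs) — VigiBase, FAERS, EudraVigilance — for *signals*: drug–event pairs
reported disproportionately often. `pvsignal` implements the case/non-case
design end to end: read an ICSR line listing, select cases by event term,
tally a report-level 2×2 table per drug class,

|              | case | non-case |
|--------------|------|----------|
| exposed      | a    | b        |
| not exposed  | c    | d        |

compute the reporting odds ratio ROR = ad/bc with its Woolf 95% interval
exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)) and Pearson χ² p-value, exclude classes
with fewer than three exposed cases, and flag classes whose lower CI bound
exceeds 1. A descriptive case-series summary (age, sex, time to onset,
seriousness, outcomes, countries, drug-mention shares) accompanies the
signal table. Because real ICSR databases are access-restricted, the
package ships a synthetic-database generator with controllable exposure
prevalences and injected relative reporting rates, plus an
operating-characteristics harness (type-I error, power) — see
`docs/methods.md`.

## Worked example

The package includes, as reference inputs, the printed per-class counts of
a published screen of the event term "Anti-NMDA receptor encephalitis"
against vaccine classes (70 cases among 29,758,737 reports). Rebuilding the
tables from those counts and screening them:

```python
import pvsignal as pv
from pvsignal import reference as ref

tables = pv.tabulate_virtual(ref.full_screen_counts(), ref.N_CASES, ref.N_REPORTS)
screen = pv.screen_tables(tables, ref.reference_class_map())
print(pv.signal_table_to_frame(screen, rounded=True).to_string(index=False))
```

```
        class_id             display_name  a       b  c        d   ror  ci_low  ci_high p_value  included  signal
       DTP_POLIO        DTP-polio vaccine  8   70006 62 29688661 54.72  26.200   114.00  <0.001      True    True
    YELLOW_FEVER     Yellow fever vaccine  3   26614 67 29732053 50.02  15.700   159.00  <0.001      True    True
             HPV              HPV vaccine  8  116283 62 29642384 32.89  15.800    68.70  <0.001      True    True
             HIB              HIB vaccine  4   89544 66 29669123 20.08   7.320    55.10  <0.001      True    True
VARICELLA_ZOSTER Varicella zoster vaccine  5  193141 65 29565526 11.78   4.740    29.20  <0.001      True    True
       INFLUENZA        Influenza vaccine  7  280525 63 29478142 11.68   5.350    25.50  <0.001      True    True
    PNEUMOCOCCAL     Pneumococcal vaccine  4  241627 66 29517040  7.40   2.700    20.30  <0.001      True    True
         COVID19         COVID-19 vaccine  4 2881218 66 26877449  0.57   0.206     1.55   0.262      True   False
          HEP_AB    Hepatitis A/B vaccine  2   29900 68 29728767   NaN     NaN      NaN             False   False
          ...
```

Reading the output: seven vaccine classes are flagged as signals (lower
95% bound above 1); the COVID-19 class is evaluable but not flagged
(ROR 0.57, interval spanning 1, p = 0.262); classes with fewer than three
exposed cases carry their counts but no statistics. The same pipeline runs
from a line listing on disk via the CLI:

```sh
pvsignal simulate --sim-config sim.yaml --seed 42 --out listing.csv
pvsignal screen --input listing.csv --class-map classes.yaml \
    --term-code LLT0001 --out-dir results/
pvsignal describe --input listing.csv --class-map classes.yaml \
    --term-code LLT0001 --out-dir results/
pvsignal evaluate --sim-config sim.yaml --replicates 200 --out oc.json
```

Each run writes a manifest (parameters, input checksums, version) next to
its outputs; exit codes are 0 success, 2 configuration error, 3 data
error, 1 unexpected.

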