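# silatro-cea

Decision-analytic cost-effectiveness modelling of **SilAtro-5-90** (a complex
homeopathic product taken as an adjuvant to usual care) versus **usual care
alone** for people with recurrent acute throat infections (ATIs, i.e.
recurrent tonsillitis/pharyngitis). The package is aimed at health economists
and methodologists who want a fully scripted, testable re-implementation of
this kind of published Markov cohort analysis: every input lives in a plain
configuration file, every published figure-level result is a function call,
and an independent patient-level microsimulation validates the cohort engine.

## The model

A 4-state Markov cohort model (well → post-tonsillectomy → dead, with the
transient "ATI" state accrued as within-cycle events) is evaluated over a
2-year horizon at 3 cycles per year (each cycle: 8 weeks of adjuvant
treatment, 8 weeks of observation), from a societal perspective in 2019
euros, discounted at 3%/year. Per cycle, the expected number of ATI events on
the at-risk cohort is

```
e = occ_well · p_ATI(arm) · n_ATI|ATI(arm)
```

with arm-specific per-cycle ATI probability `p_ATI` (0.11 intervention, 0.21
usual care) and conditional event intensity `n_ATI|ATI` (0.54 / 0.66). Events
drive antibiotic courses, GP consultations and travel time (valued at the
mean wage €24.78/h), and productivity (adults) or informal-care (children)
losses. Once cumulative expected events plus the baseline ATI history (2.5)
reach 4, a fraction of the cohort may receive tonsillectomy, which is
curative and absorbing. The primary outcome is the **incremental cost per
ATI averted**:

```
ICER = (C_int − C_uc) / (E_uc − E_int)
```

with dominance ("cheaper and more effective") reported instead of an ICER
where it applies. Around the deterministic base case the package provides
one-way (tornado) sensitivity analysis, bisection threshold search,
scenario runs, and probabilistic sensitivity analysis (Beta/Gamma/PERT
parameter distributions, cost-effectiveness plane, CEAC), plus an
individual-level microsimulation of the same pathway that serves both as a
synthetic trial-data generator and as a brute-force oracle for the cohort
engine.

## Worked example

```bash
silatro-cea run --group adults
```

prints (base case, shipped ledger):

```
Age group: adults_adolescents  (horizon 6 cycles)
Cost category (EUR)             Intervention    Usual care
Adjuvant therapy                      157.11          0.00
Antibiotics                             1.68          6.15
GP consultations                       58.51         84.42
GP - travel time                       77.68        112.06
Tonsillectomy surgery                   0.00          0.00
Tonsillectomy - travel time             0.00          0.00
Productivity loss                       3.05         22.79
Total cost                            298.03        225.41
ATIs                                  0.3469        0.8095
ICER (EUR/ATI averted): 156.99
```

Adults pay about €73 more over two years and avert 0.46 ATIs, i.e. roughly
€157 per ATI averted; no one reaches the 4-ATI tonsillectomy bar. For
children (`--group children`) the cheaper paediatric dosage makes the
intervention **dominant** (total €219.89 vs €225.55, with the same ATIs
averted). Other subcommands: `owsa` (tornado.csv), `threshold` (e.g. the
per-cycle adjuvant price at which children's dominance is lost, ≈ €14.4),
`psa` (`psa_points.csv`, `ceac.csv`, summary JSON) and `microsim`
(patient-level synthetic trial CSV plus an oracle report). Every run writes
a manifest sufficient to regenerate its outputs bit-identically.

The same analyses are available as library calls:

```python
from silatro_cea import load_config, run_arm, compare

settings, ledgers = load_config()          # shipped published inputs
adults = ledgers["adults_adolescents"]
result = compare(run_arm(adults, "intervention", settings),
                 run_arm(adults, "usual_care", settings))
print(round(result.icer, 2))               # 156.99
```

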