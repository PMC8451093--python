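# Methods

## Model structure

A cohort of identical patients with suspected moderate recurrent tonsillitis
enters 100% in the *well* (at-risk) state. Time advances in 4-month cycles
(3/year; 6 over the default 2-year horizon), matching a regimen of 8 weeks of
adjuvant SilAtro-5-90 followed by 8 weeks of observation. States are *well*,
*post-surgery* (tonsillectomy, assumed curative: no further ATIs, costs or
mortality are modelled there) and *dead*; both non-well states are absorbing.
ATIs themselves are transient and are accrued as expected within-cycle events
rather than as an end-of-cycle occupancy, which keeps the recursion linear in
the parameters and is what the printed conditional intensities (values < 1)
imply.

Per cycle, in order: (1) background mortality removes `p_death_cycle` of the
well occupancy (one third of the annual all-cause probability); (2) expected
events accrue on survivors, `e = occ_well · p_ati · n_ati_given_ati`; (3)
costs accrue (below); (4) if baseline history + cumulative expected events
per surviving patient ≥ 4, a fraction `p_surgery_if_eligible` (0.25) of the
well occupancy is operated, incurring the DRG surgery price, 3 h of hospital
travel time at the mean wage, recovery losses (10 working days adults, 5
informal-care days children) and operative mortality (2.4 × 10⁻³).

### Cost accrual

All amounts in 2019 euros, societal perspective (out-of-pocket medication,
insurer-borne consultations/antibiotics, travel time and productivity or
informal-care losses; no direct transport costs).

| component | rule |
|---|---|
| adjuvant therapy | monthly price × 2 months × well occupancy (intervention arm only; preventive self-medication continues every cycle while alive and unoperated) |
| antibiotics | `e` × p(antibiotics\|event) × course price (€13.09 adults / €12.41 children, as printed; a config switch adds the €5 dispensing fee on top) |
| GP consultations | visits × €28, with visits = 0.239 × well occupancy + 2.0 × `e` |
| GP travel | visits × 1.5 h × €24.78 |
| productivity / informal care | `e` × diary "time out of role" days per cycle × €175.94 (wage × 7.1 h workday) |

The two GP-visit constants are **calibration**: the care pathway has ATI
sufferers presenting with a suspected infection *and* returning for a
follow-up consultation (2 visits per event), plus a small arm-independent
stream of suspected-ATI presentations (0.239 visits per alive cycle). They
are fixed once so that both arms' published GP-consultation and travel
components are matched simultaneously, are exposed in
`CalibrationConstants`, and are not tuned per run.

### Discounting

Costs and outcomes are discounted at the ledger rates (3%/year each).
Default convention is `per_cycle` (geometric from cycle 1,
`(1+r)^(−(i−1)/3)`); an `annual_step` convention (full-year steps, year 1
undiscounted) is available. The per-cycle convention reproduces the
published component values essentially exactly. No half-cycle correction is
applied.

## Parameters

Every input is one row of the shipped YAML ledger: deterministic value,
one-way bounds (printed bounds where available, else ±50%, probabilities
clamped to [0, 1]) and a PSA law — Fixed, Beta(α, β) for probabilities,
Gamma(shape α, rate λ, mean α/λ) for non-negative quantities, or PERT(min,
mode, max, shape 4) for the baseline ATI history. The deterministic 2.5
prior ATIs is interpreted as the PERT *mode* (the published support is only
[2, 3.75]), giving an analytic mean of 2.625; the loader flags this and the
one other published row whose distribution mean sits > 2% from its
deterministic value (the intervention-arm diary Gamma, 3.3% high) with a
warning rather than an error. Children's per-cycle all-cause mortality is
Fixed in PSA, as published.

## Sensitivity analyses

**One-way / tornado.** Each parameter is set to its bounds with all else at
base case and both arms re-run. Entries are ranked by the width of the
resulting ICER range; ties break alphabetically. For ordering, a *dominant*
outcome is mapped to the dominance boundary (ICER 0) rather than to a large
negative sentinel: negative ICERs are savings, and clamping at the boundary
keeps ranges commensurate — with a sentinel, any parameter that merely
touches dominance at one bound would outrank every genuinely influential
one. A *dominated* outcome maps to a large positive sentinel (10⁶). Note
that `p_ati_uc` and `n_ati_given_ati_uc` enter the model only through their
product and both carry ±50% bounds, so their tornado ranges tie exactly.

**Threshold search.** Bisection on a boolean condition (becomes/ceases
dominant, or NMB < 0 at a given willingness to pay) to a default tolerance
of 10⁻³. The bracket is first scanned on a coarse grid (≤ 64 points) because
dominance regions can be interior windows — e.g. raising adult baseline
history opens dominance near 3.17 prior ATIs (usual care alone reaches the
surgery bar) but closes it again near 4 (both arms then trigger together) —
and the lower flip point is bisected and verified post hoc at ±tol.

**Scenarios.** Any run-setting override (horizon cycles, discount rates).
Because the accrual is time-homogeneous, the engine's ICER is essentially
horizon-invariant (≈ €157 at 1 cycle, 3 cycles or 6), whereas the published
analysis reports €204 (one cycle) and €166 (one year); the published
horizon-dependence cannot be produced from the stated time-homogeneous
inputs and the divergence is reported, not forced.

## Probabilistic sensitivity analysis

10,000 replications by default. One seeded generator; parameters are drawn
in canonical name order, each non-fixed row independently (no correlation
is specified), and the joint draw is shared by both arms within a
replication (common random numbers; arm-specific rows have their own
distributions). Outputs: quadrant shares of the incremental plane (strict
`ΔC < 0` / `ΔE > 0` conventions, shares sum to 1), empirical 2.5/97.5
percentile intervals per arm, a bivariate-normal 95% ellipse
(mean/covariance of (ΔE, ΔC) with the χ²₂ 0.95 quantile), and the CEAC —
the fraction of replications with `wtp·ΔE − ΔC ≥ 0`, ties counting as
cost-effective — on a €0–2000 grid in steps of 10 (covering the ≈ €230
crossing and the €1000 reference point).

The PSA mean ATI counts produced by independent sampling of the printed
distributions sit below the published PSA means (0.46/0.92); those published
values are not derivable from the printed inputs under any accrual rule
tested, so the package reports its own sampled means with intervals.

## Microsimulation

The patient-level simulator draws, per cycle: death; an ATI-cycle Bernoulli
(`p_ati`); within an ATI cycle an event Bernoulli with success
`n_ati_given_ati` — the printed conditional intensities are < 1, so a
count law with that conditional mean is required and the Bernoulli is the
minimal integer-valued choice (Poisson is available behind a switch); an
antibiotics draw per event; diary days out per event; and a surgery draw
once *integer* cumulative events + baseline history ≥ 4, followed by an
operative-mortality draw. Costs and discounting replicate the cohort engine
exactly. Baseline history is drawn per patient from the PERT law (held at
its deterministic value for oracle comparisons).

What it emulates — and does not. The generator reproduces the *population
moments* the model consumes (event rates, antibiotic shares, diary
fractions, group sizes such as 128 per arm); it does not emulate dropout,
centre effects, secular trends or any within-patient correlation beyond the
pathway structure. Passing oracle and recovery tests therefore shows the
two engines agree and the generator is self-consistent — not that the model
is clinically correct for real trial data.

Validation surfaces: `oracle_check` (surgery disabled; with 200,000 patients
every cost category and the ATI count match the cohort engine within 1%,
i.e. ≈ 3 Monte-Carlo standard errors for the smallest component) and
`recover_parameters` (method-of-moments estimates of the Bernoulli
generators with binomial standard errors; unbiased within 3 SE at 10,000
patients per arm). The integer-count surgery trigger is deliberately
different from the cohort's expected-count trigger: with baseline history 3
the cohort performs zero operations while the microsim operates on every
patient who accumulates one event — a structural-sensitivity property the
tests assert directionally.

## Numerical choices and degenerate inputs

Occupancy conservation is enforced at 10⁻¹² each cycle. An incremental
effect of exactly zero yields an undefined ICER (reported `n/a`, never ±∞);
boundary comparisons ("cheaper, equally effective") classify as dominance,
keeping classification antisymmetric under arm swap. Zero denominators in
moment recovery are reported as missing, not zero. All stochastic outputs
(PSA, microsim) are bit-reproducible from their seed.

## Problem sizes

Defaults mirror the published analysis: 6 cycles, 10,000 PSA replications.
Validation sizes were chosen for statistical resolution: 200,000 patients
for the oracle (1% ≈ 3 SE on the smallest usual-care component; the
intervention arm's smaller antibiotics component is checked at 800,000),
10,000 patients per arm for recovery, 100,000 draws for sampling-support
checks.

## Known limitations

* The published per-patient ATI totals (0.46/0.92) carry PSA credible
  intervals and exceed the deterministic product of the printed inputs; the
  deterministic quantities drive the ICER here (which matches the published
  €156.64 to < 1%), and both discounted and undiscounted ATI totals are
  reported.
* No QALY/utility analysis (no published utility values exist for ATIs), no
  currency uprating, no tonsillotomy, reoperation, ATI hospitalisation or
  surgical-complication costs, and no trial-level statistics (hazard
  ratios, p-values) — all out of scope by design.
* The GP baseline-visit constant and visits-per-event multiplier are
  calibration against the published cost breakdown, not independently
  sourced quantities.
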