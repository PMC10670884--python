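# Methods

## Model structure

`mammosim` simulates one woman at a time on a yearly grid from birth to
age 109 (every life table forces death by then). Within a year the event
order is fixed: other-cause death cuts everything off at its sampled
(continuous) age; tumor growth and progression update on onset
anniversaries; a scheduled screen — if the woman attends, is alive and
undiagnosed — precedes clinical surfacing in the same year; breast-cancer
death is resolved after diagnosis or surfacing. A tie between
breast-cancer and other-cause death age goes to the other cause.

The natural history of a woman's tumor is generated independently of
screening: onset age (inverse transform of the piecewise-constant onset
hazard), in-situ status, subtype, growth rate, annual in-situ→invasive /
nodal / distant transitions, and the clinical surfacing age are all fixed
before any screen is considered. Stage at any age is then a pure function
of the trajectory. This makes common-random-numbers comparison exact:
regimens differ only in *when* the fixed trajectory is interrupted by a
detection.

### Random-number streams

Every stochastic quantity is drawn from a `Philox` counter-based stream
keyed by `(base_seed, woman_id, purpose)`, where purpose separates
mortality, onset, tumor attributes, progression, surfacing, survival,
attendance and screen draws. Streams are jumped to a woman's block in
O(1), so results are independent of aggregation order and cohort size
(woman *i* is the same woman in every run with the same seed). Screen
draws are additionally indexed by screen *age*: nested schedules share
the detection and false-positive uniforms at shared ages, so a superset
regimen detects every tumor no later than its subset. Combined with the
survival anchor (below) this turns the expected orderings — deaths
nonincreasing, Stage 0+1 diagnoses nondecreasing, total diagnoses
nondecreasing with screening intensity — into per-woman identities rather
than statistical tendencies.

### Survival anchoring and lead time

Post-diagnosis survival is a stage-specific cure-fraction model: with
probability `cure(stage)` the woman never dies of breast cancer,
otherwise her breast-cancer death time is exponential with
`rate(stage)`. Validation *enforces* (not assumes) that cure decreases
and rate increases strictly with stage, which is what makes the shared
`(u_cure, u_time)` coupling monotone: the same woman diagnosed at an
equal-or-lower stage never dies earlier.

The survival clock starts at the age the tumor would have surfaced
clinically in the absence of screening; only when it never would surface
does it start at screen detection. Earlier screen detection therefore
changes the stage entering the draw but never subtracts lead time from
survival — naïvely anchoring at diagnosis would credit screening with the
lead-time interval even if treatment changed nothing. Mortality benefit
in this model is stage shift, exactly.

Undiagnosed cancers cannot kill: a tumor that never surfaces and is never
screened is the overdetection pool. In-situ disease (stage 0) has cure
probability 1 — pure in-situ disease is not lethal without invasion — so
overdetected never-invasive lesions also add no deaths under screening.

## Parameters

All defaults live in `make_default_params`; everything is configurable
through the YAML schema (`schema_version: 1`).

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| Life table (Gompertz–Makeham a, b, c) | 5e-4, 3e-5, 0.095 | 1/yr | survival-to-40 ≈ 0.97, median death ≈ 81, a plausible contemporary female population |
| Onset hazard | Gaussian bump, peak 0.004/yr at 68, zero before 25 | 1/yr | cumulative risk to 80 ≈ 0.11 (the familiar ~1-in-9), peak in the late 60s |
| Growth rate γ | lognormal(ln 0.25, 0.6) | 1/yr | right-skewed; median preclinical sojourn (1→20 mm) ≈ 4 yr |
| d₀, d_max | 1, 128 | mm | ~1 mm detectability floor; bounded Gompertz growth |
| In-situ fraction / annual progression | 0.40 / 0.35 | — | a screen-detectable in-situ phase for a minority of cancers, mean dwell ≈ 3 yr, with death sometimes intervening (non-progressive pool) |
| Nodal spread | logistic: max 0.45, d50 22 mm, k 0.15/mm | 1/yr | node positivity climbing through the 2–5 cm range |
| Distant spread (after nodal) | logistic: max 0.35, d50 40 mm, k 0.12/mm | 1/yr | metastasis concentrated in large tumors |
| Stage size cutoffs | 20, 50 | mm | AJCC-like size/node table |
| Screen sensitivity | smax 0.95, d50 11 mm, k 0.45/mm; in situ 0.25 | — | mammography-like: ~0.37 at 10 mm, ~0.9 at 20 mm |
| Clinical surfacing | c₀ 0.18/yr at d_ref 15 mm | — | unscreened diagnoses mostly at 25–70 mm (stage 2–3 heavy) |
| FP recall / biopsy given recall | 0.055 / 0.09 per screen | — | ≈ 55 recalls and ≈ 5 negative biopsies per 1000 screens, typical program scale |
| Cure by stage 0…4 | 1.0, 0.90, 0.80, 0.70, 0.50, 0.05 | — | strictly decreasing (enforced) |
| Death rate by stage 0…4 | 0.02, 0.04, 0.07, 0.11, 0.20, 0.45 | 1/yr | strictly increasing (enforced) |

Reporting defaults: window ages 40–76 (set `horizon_age=110` for full
lifetime), national scale 235,820 women per cohort-year, US multiplier
8.3. Per-1000 and per-100,000 denominators are women alive at the entry
age (the simulator still runs from birth).

## What the synthetic generator emulates — and what it does not

The defaults emulate the *qualitative* conditions of a screening
evaluation in a Western female population: increasing adult all-cause
mortality, an onset hazard peaking in the late 60s with ~12% lifetime
risk, right-skewed growth rates, size-dependent screen sensitivity, and
survival worsening monotonically with stage. They are not fitted to any
registry: absolute levels (e.g. deaths per 1000 unscreened women) come
out larger than calibrated national models report, mainly because the
synthetic stage mix at clinical surfacing is more advanced and
stage-specific fatality is generic. Passing tests therefore demonstrate
the mechanics and the directions (stage shift, monotone mortality
ordering, recall scaling), not predictive accuracy for any real
population. That is also why the reporting layer has a printed-values
mode: the exact derived arithmetic is tested against published levels
directly, independent of this package's synthetic calibration. No
calendar time is modeled; the published tables' year-2051 truncation is
represented by the age-76 horizon alone, and national scaling is a
multiplication, not a multi-birth-cohort simulation.

## Numerical choices

- Onset and surfacing inversion use the piecewise-constant hazard
  exactly; onset interpolates within the year, surfacing stays on the
  yearly grid (so constant-hazard surfacing delays are geometric).
- Other-cause death ages are continuous: the year from the table CDF,
  the sub-year offset from the residual of the same uniform.
- Uniforms feeding `−ln(u)` are clipped to the open interval (0, 1) at
  1e-12.
- The progression loop consumes exactly three uniforms per anniversary
  regardless of tumor state, so trajectories are invariant to anything
  downstream.
- A screen scheduled at integer age `a` happens iff the woman is alive at
  `a` and undiagnosed; a same-year tie with clinical surfacing goes to
  the screen. Screens stop after diagnosis, so the screen counter is a
  count of performed examinations (this is the one field that
  legitimately differs between a zero-sensitivity regimen and no
  screening).
- Degenerate inputs are defined, not special-cased: zero hazards mean
  "never", γ = 0 freezes the diameter, participation 0 reproduces no
  screening field-for-field, an empty regimen is "no screening".
- NNS values are undefined (error) at zero benefit rather than infinite.
- With participation p < 1, per-offered-cohort quantities are p-weighted
  mixtures with the baseline; per-actually-screened quantities (LY saved
  per 1000 screened, both NNS values) are unchanged, so the algebraic
  identities `NNS·reduction = 1000` and `NNS_LY·LY = 1000` hold exactly
  at p = 1.

## Design choices made where the design was open

- **Gompertz–Makeham life table** as the synthetic stand-in: the minimal
  monotone adult hazard that produces the qualitative effect of competing
  mortality (fewer screens completed, benefit truncated at older ages).
- **One primary tumor per woman**: multiple primaries add state without
  changing the definition of any reported statistic.
- **All-or-none lifetime participation**: a Bernoulli(p) draw per woman,
  which is exactly the p:(1−p) mixture interpretation used by the
  weighted reporting mode.
- **False positives only at screens, constant per-screen rate**, and
  every false-positive biopsy negative by construction — the negative
  biopsy statistic counts women without cancer.
- **Distant spread only after nodal spread**, keeping event ages ordered
  and stages monotone along a trajectory.

## Problem sizes

The test suite and acceptance script use cohorts of 100,000 women
(statistical oracles use 50,000–200,000 draws), chosen so the full suite
runs on a single CPU in a few minutes while keeping Monte-Carlo standard
errors far below every asserted margin; the batch-means test quantifies
that error directly. The per-woman monotonicity theorem is checked on
10,000 paired histories.

## Known limitations

- No calendar time, birth-cohort mixing, or risk-factor subgroups.
- Subtype is carried as a label only; it does not modulate growth,
  detection or survival.
- In-situ lesions never surface clinically and have no size; their screen
  sensitivity is a single constant.
- Screening stops at diagnosis; surveillance mammography, interval
  imaging and supplemental modalities are out of scope.
- Costs and cost-effectiveness are out of scope.
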