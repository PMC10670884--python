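# mammosim

Microsimulation of breast-cancer natural history and mammography
screening regimens.

## The problem

Guidelines disagree about when women should start breast screening and
how often they should attend. Because randomized trials of every
candidate regimen are infeasible, policy analyses use *microsimulation*:
simulate individual life histories — cancer initiation, tumor growth,
spread, detection, competing mortality and post-diagnosis survival — and
compare regimens (e.g. biennial 50–74 vs annual 40–74) on the same
simulated population. `mammosim` is a compact, fully synthetic model of
this kind, in the tradition of the Canadian OncoSim-Breast and the CISNET
family of breast models, for methodologists who want a transparent,
testable implementation of the whole pipeline: natural history →
screening → stage at diagnosis → mortality → regimen comparison
statistics.

## The model

For each woman *i*, with every random quantity drawn from a
counter-based stream keyed by `(seed, i, purpose)`:

- **Other-cause death** age `T_oc` by inverse-transform sampling of a
  female life table `q_x` (synthetic Gompertz–Makeham by default:
  `q_x = 1 − exp(−(a + b·e^{cx}))`).
- **Onset** age by inverting the cumulative age-dependent onset hazard
  `H(t) = Σ h(x)`; onset occurs iff `H(109) ≥ −ln U`. A fraction of
  cancers begins in situ and becomes invasive with annual probability
  `π`; the rest are invasive at onset.
- **Growth**: Gompertz diameter growth
  `d(t) = d_max (d_0/d_max)^{exp(−γt)}` with lognormal growth rate γ.
- **Spread**: annual nodal and (after nodal) distant transitions with
  logistic diameter-dependent probabilities; stage at any age follows an
  AJCC-like size/node/distant decision table (cutoffs 20 and 50 mm;
  substages 0, 1, 2A, 2B, 3, 4).
- **Clinical surfacing** at the first year where the cumulative hazard
  `Σ c₀·d(t)/d_ref` exceeds `−ln U`; slow or late cancers may never
  surface (the overdetection pool — undiagnosed cancers cannot kill).
- **Screening**: at each attended screen, an invasive tumor is detected
  with probability `s_max / (1 + e^{−k(d−d_50)})` (a fixed constant for
  in-situ lesions); women without detectable cancer face a per-screen
  false-positive recall risk, and a fraction of recalls leads to a
  negative biopsy. Participation is all-or-none per woman.
- **Survival**: cure-fraction model per stage — cured with probability
  `cure(stage)`, else breast-cancer death after an `Exp(rate(stage))`
  time measured from the age the tumor would have surfaced *without*
  screening (or from screen detection when it never would). Earlier
  detection therefore changes only the stage entering the draw, never
  subtracts lead time — mortality benefit arises purely through stage
  shift.

Regimens are compared with **common random numbers**: natural-history
streams are identical across regimens and screen draws are keyed by
screen age, so for nested schedules (no screening ⊂ biennial 50–74 ⊂
biennial 40–74 ⊂ annual 40–74) fewer deaths, earlier stages and more
diagnoses under more screening hold woman-by-woman, not just on average.

The reporting layer turns per-regimen outcomes into the standard
comparison statistics: absolute reduction in deaths per 1000 women,
relative mortality reduction, life years saved, national annual deaths
averted, number needed to screen per death averted (`1000/reduction`)
and per life year gained (`1000/LY`), participation-weighted mixtures
`p·screened + (1−p)·unscreened`, and stage distributions per 100,000. It
accepts either simulated cohorts or published per-regimen levels
(printed-values mode), since absolute levels of calibrated national
models are not reproducible without their calibration while the derived
arithmetic is exact.

## Worked example

```python
from mammosim import BUILTIN_REGIMENS, build_report, make_default_params, run_regimens
from mammosim.config import mortality_frame

params = make_default_params(seed=1)
outcomes = run_regimens(params, list(BUILTIN_REGIMENS.values()), 20_000)
print(mortality_frame(build_report(outcomes)).to_string(index=False))
```

prints (deaths evaluated between ages 40 and 76, per 1000 women alive at
40; this is `examples/03_compare_regimens.py`):

```
             regimen  deaths_per_1000  reduction_per_1000  relative_reduction_pct  national_annual_averted  ly_saved_per_1000
      biennial_50_74              8.5                14.0                    62.3                     3303              117.8
      biennial_40_74              5.8                16.7                    74.3                     3936              173.3
hybrid_40_49a_50_74b              5.2                17.3                    77.0                     4082              184.7
        annual_40_74              3.6                18.9                    83.9                     4448              197.7
        annual_40_49             18.2                 4.3                    19.1                     1011               81.5
```

The unscreened baseline has 22.5 deaths per 1000; every screening
regimen reduces mortality, more intensive schedules reduce it more, and
the early-invasive (Stage 1 or 2A) fraction of diagnoses rises from 0.37
(no screening) to 0.95 (annual 40–74) in the accompanying stage table.
The synthetic parameter set is a stand-in, not a calibration, so these
levels are larger than a calibrated national model would produce; the
*directions* and the derived arithmetic are the point.

Other examples: `examples/01_synthetic_parameters.py` (parameter file and
life table), `02_single_life_histories.py` (per-woman stage shift under
common random numbers), `04_published_arithmetic.py` (printed-values
mode: e.g. a 4.6/1000 reduction for biennial 50–74 implies NNS 217 per
death averted), `05_participation.py` (70% participation: reduction
7.9 → 5.5 per 1000 offered, NNS unchanged).

There is also a small CLI:

```bash
mammosim synth-params --seed 1 --out params.yaml
mammosim simulate --params params.yaml --regimen biennial_50_74 --n 100000 --out outcomes.json
mammosim compare --regimens all --n 100000 --seed 1 --outdir results/
```

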