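"""Compare screening regimens on one common-random-numbers cohort.

Runs the six built-in regimens on the same simulated women and prints the
mortality comparison and the stage-at-diagnosis distribution.  Because
each woman's disease course is identical across regimens, between-regimen
differences are caused by screening alone.
"""

from mammosim import BUILTIN_REGIMENS, build_report, make_default_params, run_regimens
from mammosim.config import mortality_frame, stage_frame

N = 20_000  # desk-scale; increase for smaller Monte-Carlo error

params = make_default_params(seed=1)
outcomes = run_regimens(params, list(BUILTIN_REGIMENS.values()), N)
reports = build_report(outcomes, baseline="no_screening")

print(f"cohort: {N} women, window ages 40-76, seed {params.seed}\n")
print("Mortality comparison vs no screening (per 1000 women alive at 40):")
print(mortality_frame(reports).to_string(index=False))

print("\nStage at diagnosis per 100,000 women (ages 40-76):")
print(stage_frame(outcomes).to_string())

print("\nReading the tables: deaths per 1000 fall and the early-invasive")
print("fraction rises monotonically with screening intensity — screening")
print("does not prevent cancers (totals rise via earlier and overdetected")
print("diagnoses); it shifts them to earlier, more survivable stages.")
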