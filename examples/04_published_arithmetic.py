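"""Exact outcome arithmetic on published per-regimen levels.

The absolute outcome levels of a calibrated national microsimulation are
not reproducible without its calibration, but every derived statistic —
reductions, relative reduction, NNS, national scaling — follows from the
printed levels by simple arithmetic.  This is the reporting layer's
printed-values mode.
"""

from mammosim import (build_report, mean_ly_per_death_averted, nns_per_death,
                      published_outcomes)

pub = published_outcomes()
reports = build_report(pub, baseline="no_screening")

print("regimen                deaths/1000  reduction  rel.%   NNS/death  NNS/LY")
for name in ("biennial_50_74", "biennial_40_74", "hybrid_40_49a_50_74b",
             "annual_40_74", "annual_40_49"):
    r = reports[name]
    print(f"{name:<22} {r.deaths_per_1000:>10.1f} {r.reduction_per_1000:>9.1f} "
          f"{r.relative_reduction_pct:>6.1f} {r.nns_per_death:>10.1f} "
          f"{r.nns_per_ly:>7.1f}")

annual = reports["annual_40_74"]
print(f"\nannual 40-74: {annual.reduction_per_1000:.1f} deaths averted per 1000 "
      f"women means screening {annual.nns_per_death:.1f} women averts one death;")
print(f"each averted death buys on average "
      f"{mean_ly_per_death_averted(78.9, 7.9):.1f} life years.")
print(f"(cross-check: 1000 / 7.9 = {nns_per_death(7.9):.1f})")
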