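"""Post-diagnosis survival and competing other-cause mortality.

Breast-cancer survival is a stage-specific cure-fraction model: with
probability cure(stage) the woman never dies of breast cancer; otherwise
her breast-cancer death time is exponential with rate(stage), measured
from an *anchor age*.  The anchor is the age the tumor would have
surfaced clinically with no screening (or the screen-detection age when
it never would surface), so earlier screen detection changes only the
stage entering the draw — it never subtracts lead time from survival.
Mortality benefit therefore arises exactly through stage shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import MAX_AGE, LifeTable, SurvivalParams


@dataclass(frozen=True)
class DeathRecord:
    age_at_death: float
    cause: str          # "breast_cancer" | "other"
    life_years_lived: float


def sample_other_cause_death_age(life_table: LifeTable, u) -> float | np.ndarray:
    """Inverse-transform sample of the other-cause death age.

    The discrete life table gives the death-year CDF; a uniform sub-year
    offset is recovered from the residual of the same uniform, so one draw
    yields a continuous age in [0, 110).  Accepts a scalar or an array of
    uniforms.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= 0.0) or np.any(u_arr >= 1.0):
        raise ValueError("u must be in (0, 1)")
    cdf = life_table.death_year_cdf()  # length 111, cdf[-1] == 1
    year = np.searchsorted(cdf, u_arr, side="right") - 1
    year = np.clip(year, 0, MAX_AGE)
    mass = cdf[year + 1] - cdf[year]
    frac = np.where(mass > 0, (u_arr - cdf[year]) / np.where(mass > 0, mass, 1.0), 0.0)
    age = year + frac
    return float(age) if np.isscalar(u) or np.asarray(u).ndim == 0 else age


def sample_bc_death_age(stage_at_dx: str, anchor_age: float,
                        survival: SurvivalParams,
                        u_cure: float, u_time: float) -> float | None:
    """Breast-cancer death age, or None when cured.

    Cured when ``u_cure < cure(stage)``; otherwise death at
    ``anchor_age − ln(u_time)/rate(stage)``.  Using the same
    (u_cure, u_time) pair for a woman under every regimen makes the
    draw monotone in stage: an equal-or-lower stage never produces an
    earlier death.
    """
    if not (0.0 < u_time < 1.0):
        raise ValueError("u_time must be in (0, 1)")
    if u_cure < survival.cure[stage_at_dx]:
        return None
    return anchor_age - math.log(u_time) / survival.rate[stage_at_dx]


def resolve_death(bc_death_age: float | None, other_death_age: float,
                  birth_age: float = 0.0) -> DeathRecord:
    """Combine the two death processes; ties go to other-cause death.

    Histories are truncated at age 109 (a life-table sample may land in
    [109, 110); it is capped here).
    """
    candidates = [(min(other_death_age, float(MAX_AGE)), "other")]
    if bc_death_age is not None and bc_death_age < candidates[0][0]:
        candidates.append((bc_death_age, "breast_cancer"))
    age, cause = min(candidates)
    return DeathRecord(age_at_death=age, cause=cause,
                       life_years_lived=age - birth_age)
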