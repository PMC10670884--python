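"""Cancer natural history: onset, growth, spread and stage assignment.

One woman's unscreened disease course is fully determined here before any
screening logic runs: onset age by inverse-transform sampling of the
age-dependent hazard, Gompertz diameter growth from the invasive onset,
and annual in-situ→invasive, node-spread and distant-spread transitions.
Stage at any age is then a pure function of the trajectory, which is what
lets screening regimens be compared on identical natural histories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import MAX_AGE, StageModel
from .stages import coarse_stage

NEVER = math.inf  # sentinel for events that do not occur


@dataclass(frozen=True)
class Tumor:
    """State of a single primary tumor.

    Ages are in years; events that have not (yet) happened are ``inf``.
    Invariants: onset_age <= invasive_age <= nodal_age <= distant_age
    where finite, d0 < dmax, gamma >= 0.
    """

    onset_age: float
    is_insitu_at_onset: bool
    subtype: str
    gamma: float          # Gompertz growth rate, 1/year
    d0: float             # diameter at invasive onset, mm
    dmax: float           # asymptotic diameter, mm
    invasive_age: float = NEVER
    nodal_age: float = NEVER
    distant_age: float = NEVER

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError(f"gamma must be nonnegative, got {self.gamma}")
        if not self.d0 < self.dmax:
            raise ValueError(f"need d0 < dmax, got {self.d0} >= {self.dmax}")
        if not (self.onset_age <= self.invasive_age <= self.nodal_age <= self.distant_age):
            raise ValueError("event ages must be ordered onset <= invasive <= nodal <= distant")


def sample_onset_age(onset_hazard: np.ndarray, u: float) -> float | None:
    """Invert the piecewise-constant onset hazard at uniform ``u``.

    Returns the (fractional) onset age, or None when the cumulative hazard
    over the whole lifespan never reaches −ln(u) — the woman never
    develops breast cancer.
    """
    if not (0.0 < u < 1.0):
        raise ValueError(f"u must be in (0, 1), got {u}")
    h = np.asarray(onset_hazard, dtype=float)
    if np.any(h < 0):
        raise ValueError("onset hazard rates must be nonnegative")
    target = -math.log(u)
    cum = np.concatenate([[0.0], np.cumsum(h)])  # cumulative hazard at integer ages
    if cum[-1] < target:
        return None
    year = int(np.searchsorted(cum, target, side="left")) - 1
    year = max(year, 0)
    within = (target - cum[year]) / h[year]
    return float(year + within)


def tumor_diameter(tumor: Tumor, t: float) -> float:
    """Diameter (mm) ``t`` years after invasive onset: Gompertz growth.

    d(t) = dmax · (d0/dmax)^exp(−gamma·t); nondecreasing in t, bounded by
    dmax, with d(0) = d0.
    """
    if t < 0:
        raise ValueError(f"t must be nonnegative, got {t}")
    return tumor.dmax * (tumor.d0 / tumor.dmax) ** math.exp(-tumor.gamma * t)


def diameter_at_age(tumor: Tumor, age: float) -> float:
    """Diameter at a given age; 0 before the lesion is invasive."""
    if age < tumor.invasive_age:
        return 0.0
    return tumor_diameter(tumor, age - tumor.invasive_age)


def update_progression(tumor: Tumor, age: float, stage_model: StageModel,
                       insitu_progression_prob: float,
                       u_vec: tuple[float, float, float]) -> Tumor:
    """Apply one year's progression transitions at anniversary ``age``.

    Checks, in order: in-situ→invasive (annual probability), then
    diameter-dependent nodal spread, then distant spread (only once node
    positive).  All events are irreversible.  ``u_vec`` supplies the three
    uniforms (insitu, nodal, distant); all three are always consumed by
    the caller so draw alignment is independent of tumor state.
    """
    u_insitu, u_nodal, u_distant = u_vec
    out = tumor
    if out.invasive_age == NEVER:
        if u_insitu < insitu_progression_prob:
            out = replace(out, invasive_age=age)
        else:
            return out  # still in situ: no size, no spread
    d = diameter_at_age(out, age)
    if out.nodal_age == NEVER:
        if u_nodal < stage_model.nodal(d):
            out = replace(out, nodal_age=age)
        else:
            return out
    if out.distant_age == NEVER and u_distant < stage_model.distant(d):
        out = replace(out, distant_age=age)
    return out


def simulate_progression(tumor: Tumor, stage_model: StageModel,
                         insitu_progression_prob: float,
                         rng: np.random.Generator,
                         max_age: float = MAX_AGE + 1) -> Tumor:
    """Run the annual progression loop from onset to ``max_age``.

    The loop consumes exactly three uniforms per anniversary regardless of
    state, so a tumor's event ages depend only on its own stream — never
    on screening, death or cohort composition.
    """
    tumor = tumor if tumor.is_insitu_at_onset else replace(tumor, invasive_age=tumor.onset_age)
    age = tumor.onset_age + 1.0
    while age <= max_age:
        if tumor.distant_age < NEVER:
            break
        u_vec = tuple(rng.random(3))
        tumor = update_progression(tumor, age, stage_model,
                                   insitu_progression_prob, u_vec)
        age += 1.0
    return tumor


def assign_stage(tumor: Tumor, age: float, stage_model: StageModel) -> str:
    """Stage label at ``age`` from the size/node/distant decision table.

    Stage 0 while not yet invasive; stage 4 once distant spread has
    occurred; otherwise an AJCC-like size/node table with thresholds from
    ``stage_model`` (defaults 20 and 50 mm):

    ==============  =============  =========
    diameter        node-negative  node-positive
    ==============  =============  =========
    <= t1 (20 mm)   1              2A
    t1 < d <= t2    2A             2B
    > t2 (50 mm)    3              3
    ==============  =============  =========
    """
    if age < tumor.onset_age:
        raise ValueError("tumor does not exist yet at this age")
    if tumor.distant_age <= age:
        return "4"
    if age < tumor.invasive_age:
        return "0"
    d = diameter_at_age(tumor, age)
    t1, t2 = stage_model.size_thresholds
    node_positive = tumor.nodal_age <= age
    if d > t2:
        return "3"
    if d > t1:
        return "2B" if node_positive else "2A"
    return "2A" if node_positive else "1"


def coarse_stage_at(tumor: Tumor, age: float, stage_model: StageModel) -> int:
    return coarse_stage(assign_stage(tumor, age, stage_model))
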