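"""Per-woman simulation loop and cohort aggregation.

Each woman's history is simulated under a screening regimen with all
natural-history randomness (other-cause death, onset, tumor attributes,
progression, clinical surfacing, survival uniforms, attendance) drawn
from counter-based streams keyed by ``(base_seed, woman_id, purpose)``.
Those streams are consumed identically under every regimen, and screen
draws are keyed by screen age, so comparing regimens on the same
``(params, base_seed)`` is a common-random-numbers design: differences in
outcomes are caused by the regimen, not by sampling noise, and for nested
schedules the monotone orderings (fewer deaths, earlier stages, more
diagnoses under more screening) hold woman-by-woman.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import rng as _rng
from .detection import (DetectionRecord, ScreeningRegimen, screen_event,
                        scheduled_screen_ages, clinical_surfacing_age)
from .natural_history import (NEVER, Tumor, assign_stage, diameter_at_age,
                              sample_onset_age, simulate_progression)
from .params import MAX_AGE, ParameterSet
from .stages import SUBSTAGES, EARLY_INVASIVE, coarse_stage
from .survival import (DeathRecord, resolve_death, sample_bc_death_age,
                       sample_other_cause_death_age)

_EPS = 1e-12


def _uniform(gen: np.random.Generator) -> float:
    """A uniform draw clipped into the open interval (0, 1)."""
    return min(max(gen.random(), _EPS), 1.0 - _EPS)


@dataclass(frozen=True)
class ReportWindow:
    """Age window within which deaths, life years and diagnoses are tallied.

    Defaults follow the convention of entering reporting at age 40 with a
    36-year observation horizon (deaths after age 76 uncounted); pass
    ``horizon_age=110`` for full-lifetime accounting.
    """

    entry_age: float = 40.0
    horizon_age: float = 76.0

    def __post_init__(self):
        if not self.entry_age < self.horizon_age:
            raise ValueError("entry_age must be below horizon_age")


@dataclass
class LifeHistory:
    woman_id: int
    other_death_age: float
    attends_screening: bool
    tumor: Tumor | None
    detection: DetectionRecord
    death: DeathRecord
    bc_death_age: float | None   # uncensored breast-cancer death age (may exceed other-cause death)
    surfacing_age: float         # age of clinical surfacing absent screening; inf if never


def run_history(params: ParameterSet, regimen: ScreeningRegimen,
                woman_id: int, base_seed: int | None = None,
                ) -> LifeHistory:
    """Simulate one woman under one regimen.

    Within-year event order: other-cause death cuts off everything at the
    sampled death age; tumor growth/progression updates happen on onset
    anniversaries; a scheduled screen (if attending, alive and
    undiagnosed) precedes clinical surfacing in the same year; breast-
    cancer death is resolved after diagnosis or surfacing.
    """
    seed = params.seed if base_seed is None else base_seed

    other_death_age = sample_other_cause_death_age(
        params.life_table, _uniform(_rng.stream(seed, woman_id, _rng.Purpose.MORTALITY)))

    onset_age = sample_onset_age(
        params.onset_hazard, _uniform(_rng.stream(seed, woman_id, _rng.Purpose.ONSET)))

    attend_u = _uniform(_rng.stream(seed, woman_id, _rng.Purpose.ATTENDANCE))
    attends = attend_u < regimen.participation

    tumor: Tumor | None = None
    surfacing_age = NEVER
    u_cure = u_time = None
    # a tumor whose onset is after death can influence nothing; its streams
    # are untouched, which is regimen-independent and hence CRN-safe
    if onset_age is not None and onset_age < min(other_death_age, MAX_AGE + 1):
        tgen = _rng.stream(seed, woman_id, _rng.Purpose.TUMOR)
        u_subtype = tgen.random()
        z_gamma = tgen.standard_normal()
        u_insitu = tgen.random()
        names = sorted(params.subtype_weights)
        cum = np.cumsum([params.subtype_weights[n] for n in names])
        subtype = names[int(np.searchsorted(cum, u_subtype, side="right"))] \
            if u_subtype < cum[-1] else names[-1]
        tumor = Tumor(
            onset_age=onset_age,
            is_insitu_at_onset=u_insitu < params.insitu_fraction,
            subtype=subtype,
            gamma=math.exp(params.growth.log_mean + params.growth.log_sd * z_gamma),
            d0=params.growth.d0,
            dmax=params.growth.dmax,
        )
        tumor = simulate_progression(
            tumor, params.stage_model, params.insitu_progression_prob,
            _rng.stream(seed, woman_id, _rng.Purpose.PROGRESSION))
        surfacing_age = clinical_surfacing_age(
            tumor, params.clinical_detection,
            _uniform(_rng.stream(seed, woman_id, _rng.Purpose.SURFACING)))
        sgen = _rng.stream(seed, woman_id, _rng.Purpose.SURVIVAL)
        u_cure, u_time = _uniform(sgen), _uniform(sgen)

    detection = DetectionRecord()
    schedule = scheduled_screen_ages(regimen)
    screen_detect_age: float | None = None
    if attends and schedule:
        # one row of (u_detect, u_fp, u_biopsy) per age: regimens with
        # nested schedules share draws at shared ages
        draws = _rng.stream(seed, woman_id, _rng.Purpose.SCREEN) \
            .random(3 * (MAX_AGE + 1)).reshape(MAX_AGE + 1, 3)
        for a in schedule:
            if a >= other_death_age or a > MAX_AGE:
                break                      # dead before this screen
            if surfacing_age < a:
                break                      # already diagnosed clinically
            if screen_detect_age is not None:
                break                      # already diagnosed by screen
            detection.n_screens += 1
            u_detect, u_fp, u_biopsy = draws[a]
            detectable = tumor is not None and tumor.onset_age <= a
            outcome = screen_event(
                detectable,
                is_insitu=detectable and a < tumor.invasive_age,
                diameter=diameter_at_age(tumor, a) if detectable else 0.0,
                sens=params.sensitivity,
                fp_recall_rate=params.fp_recall_rate,
                biopsy_given_recall=params.biopsy_given_recall,
                neg_biopsy_given_no_cancer=params.neg_biopsy_given_no_cancer,
                u_detect=u_detect, u_fp=u_fp, u_biopsy=u_biopsy)
            if outcome.detected:
                screen_detect_age = float(a)
            detection.n_fp_recalls += outcome.fp_recall
            detection.n_neg_biopsies += outcome.neg_biopsy

    if screen_detect_age is not None:
        detection.mode = "screen"
        detection.age_at_dx = screen_detect_age
    elif surfacing_age < min(other_death_age, MAX_AGE + 1):
        detection.mode = "clinical"
        detection.age_at_dx = surfacing_age

    bc_death_age: float | None = None
    if detection.mode != "none":
        detection.stage_at_dx = assign_stage(tumor, detection.age_at_dx,
                                             params.stage_model)
        detection.diameter_at_dx = diameter_at_age(tumor, detection.age_at_dx)
        anchor = surfacing_age if surfacing_age < NEVER else detection.age_at_dx
        bc_death_age = sample_bc_death_age(detection.stage_at_dx, anchor,
                                           params.survival, u_cure, u_time)

    death = resolve_death(bc_death_age, other_death_age)
    return LifeHistory(woman_id=woman_id, other_death_age=other_death_age,
                       attends_screening=attends, tumor=tumor,
                       detection=detection, death=death,
                       bc_death_age=bc_death_age, surfacing_age=surfacing_age)


# ---------------------------------------------------------------------------
# Cohort aggregation
# ---------------------------------------------------------------------------

@dataclass
class CohortOutcomes:
    """Aggregates of one regimen over one simulated cohort."""

    regimen: str
    n_women: int
    n_alive_at_entry: int
    window: ReportWindow
    bc_deaths_in_window: int = 0
    total_life_years: float = 0.0        # within the window
    stage_counts: dict[str, int] = field(default_factory=lambda: {s: 0 for s in SUBSTAGES})
    total_cancers: int = 0               # diagnosed within the window
    total_screens: int = 0
    fp_recalls: int = 0
    neg_biopsies: int = 0

    # -- per-capita views ----------------------------------------------------

    @property
    def deaths_per_1000(self) -> float:
        return 1000.0 * self.bc_deaths_in_window / self.n_alive_at_entry

    @property
    def life_years_per_1000(self) -> float:
        return 1000.0 * self.total_life_years / self.n_alive_at_entry

    @property
    def screens_per_woman(self) -> float:
        return self.total_screens / self.n_alive_at_entry

    @property
    def recalls_per_1000(self) -> float:
        return 1000.0 * self.fp_recalls / self.n_alive_at_entry

    @property
    def neg_biopsies_per_1000(self) -> float:
        return 1000.0 * self.neg_biopsies / self.n_alive_at_entry

    def coarse_stage_counts(self) -> dict[int, int]:
        out = {k: 0 for k in range(5)}
        for sub, n in self.stage_counts.items():
            out[coarse_stage(sub)] += n
        return out

    def stage_per_100k(self) -> dict[int, float]:
        scale = 100_000.0 / self.n_alive_at_entry
        return {k: v * scale for k, v in self.coarse_stage_counts().items()}

    @property
    def early_invasive_fraction(self) -> float:
        invasive = self.total_cancers - self.stage_counts["0"]
        if invasive == 0:
            return float("nan")
        early = sum(self.stage_counts[s] for s in EARLY_INVASIVE)
        return early / invasive

    def to_dict(self) -> dict:
        return {
            "regimen": self.regimen,
            "n_women": self.n_women,
            "n_alive_at_entry": self.n_alive_at_entry,
            "window": [self.window.entry_age, self.window.horizon_age],
            "bc_deaths_in_window": self.bc_deaths_in_window,
            "total_life_years": self.total_life_years,
            "stage_counts": dict(self.stage_counts),
            "total_cancers": self.total_cancers,
            "total_screens": self.total_screens,
            "fp_recalls": self.fp_recalls,
            "neg_biopsies": self.neg_biopsies,
            "deaths_per_1000": self.deaths_per_1000,
            "life_years_per_1000": self.life_years_per_1000,
            "screens_per_woman": self.screens_per_woman,
            "recalls_per_1000": self.recalls_per_1000,
            "neg_biopsies_per_1000": self.neg_biopsies_per_1000,
            "stage_per_100k": self.stage_per_100k(),
            "early_invasive_fraction": self.early_invasive_fraction,
        }


def accumulate(outcomes: CohortOutcomes, h: LifeHistory) -> None:
    """Fold one history into the running cohort aggregates."""
    w = outcomes.window
    death_age = h.death.age_at_death
    if death_age < w.entry_age:
        return  # not alive at entry: contributes nothing to the window
    outcomes.n_alive_at_entry += 1
    outcomes.total_life_years += min(death_age, w.horizon_age) - w.entry_age
    if h.death.cause == "breast_cancer" and death_age <= w.horizon_age:
        outcomes.bc_deaths_in_window += 1
    d = h.detection
    if d.mode != "none" and w.entry_age <= d.age_at_dx <= w.horizon_age:
        outcomes.total_cancers += 1
        outcomes.stage_counts[d.stage_at_dx] += 1
    outcomes.total_screens += d.n_screens
    outcomes.fp_recalls += d.n_fp_recalls
    outcomes.neg_biopsies += d.n_neg_biopsies


def run_cohort(params: ParameterSet, regimen: ScreeningRegimen, n_women: int,
               base_seed: int | None = None,
               window: ReportWindow = ReportWindow()) -> CohortOutcomes:
    """Simulate ``n_women`` histories under one regimen and aggregate.

    Deterministic for fixed (params, regimen, n_women, base_seed, window);
    woman ``i``'s natural history is identical across regimens run with
    the same params and seed.
    """
    if n_women < 1:
        raise ValueError("n_women must be at least 1")
    outcomes = CohortOutcomes(regimen=regimen.name, n_women=n_women,
                              n_alive_at_entry=0, window=window)
    for woman_id in range(n_women):
        accumulate(outcomes, run_history(params, regimen, woman_id, base_seed))
    return outcomes


def run_regimens(params: ParameterSet, regimens: list[ScreeningRegimen],
                 n_women: int, base_seed: int | None = None,
                 window: ReportWindow = ReportWindow(),
                 ) -> dict[str, CohortOutcomes]:
    """Run several regimens on the same cohort (common random numbers)."""
    return {r.name: run_cohort(params, r, n_women, base_seed, window)
            for r in regimens}
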