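"""Screening schedules, screen outcomes and clinical surfacing.

Screen detection uses a logistic size-dependent sensitivity (a fixed
constant for in-situ lesions, which carry no meaningful diameter here).
Women without detectable cancer face a constant per-screen false-positive
recall risk, and a recalled woman may receive a (by construction
negative) biopsy.  Clinical surfacing — detection by the woman herself or
at clinical examination — follows a diameter-proportional yearly hazard,
so some slow-growing or late-onset cancers never surface before death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .natural_history import NEVER, Tumor, tumor_diameter
from .params import MAX_AGE, ClinicalDetectionParams, SensitivityParams


@dataclass(frozen=True)
class ScreeningRegimen:
    """A mammography schedule: one or more (start, stop, interval) phases.

    Most regimens are a single arithmetic sequence ``start, start+interval,
    ..., <= stop``; hybrid regimens (e.g. annual in the 40s then biennial
    50–74) concatenate phases.  ``participation`` is the fraction of women
    who attend at all (all-or-none lifetime attendance).
    """

    name: str
    phases: tuple[tuple[int, int, int], ...] = ()
    participation: float = 1.0

    def __post_init__(self):
        for start, stop, interval in self.phases:
            if start > stop:
                raise ValueError(f"{self.name}: start_age {start} > stop_age {stop}")
            if interval < 1:
                raise ValueError(f"{self.name}: interval must be >= 1, got {interval}")
        if not (0.0 <= self.participation <= 1.0):
            raise ValueError(f"{self.name}: participation must be in [0, 1]")

    @classmethod
    def uniform(cls, name: str, start_age: int, stop_age: int, interval: int,
                participation: float = 1.0) -> "ScreeningRegimen":
        return cls(name=name, phases=((start_age, stop_age, interval),),
                   participation=participation)

    @classmethod
    def no_screening(cls) -> "ScreeningRegimen":
        return cls(name="no_screening", phases=())

    @property
    def start_age(self) -> int | None:
        ages = self.screen_ages
        return ages[0] if ages else None

    @property
    def stop_age(self) -> int | None:
        ages = self.screen_ages
        return ages[-1] if ages else None

    @property
    def screen_ages(self) -> tuple[int, ...]:
        return scheduled_screen_ages(self)


def scheduled_screen_ages(regimen: ScreeningRegimen) -> tuple[int, ...]:
    """All scheduled screen ages: per phase, start, start+interval, ... <= stop."""
    ages: set[int] = set()
    for start, stop, interval in regimen.phases:
        ages.update(range(start, stop + 1, interval))
    return tuple(sorted(ages))


#: The named regimens compared throughout: screening offered annually or
#: biennially, starting at 40 or 50, to age 74, plus a 40s-only schedule
#: and the annual-40s/biennial-50s hybrid.
BUILTIN_REGIMENS: dict[str, ScreeningRegimen] = {
    "no_screening": ScreeningRegimen.no_screening(),
    "biennial_50_74": ScreeningRegimen.uniform("biennial_50_74", 50, 74, 2),
    "biennial_40_74": ScreeningRegimen.uniform("biennial_40_74", 40, 74, 2),
    "hybrid_40_49a_50_74b": ScreeningRegimen(
        name="hybrid_40_49a_50_74b", phases=((40, 49, 1), (50, 74, 2))),
    "annual_40_74": ScreeningRegimen.uniform("annual_40_74", 40, 74, 1),
    "annual_40_49": ScreeningRegimen.uniform("annual_40_49", 40, 49, 1),
}


def get_regimen(spec: str) -> ScreeningRegimen:
    """Look up a built-in regimen or parse ``start:stop:interval[:participation]``."""
    if spec in BUILTIN_REGIMENS:
        return BUILTIN_REGIMENS[spec]
    parts = spec.split(":")
    if len(parts) not in (3, 4):
        raise ValueError(
            f"unknown regimen {spec!r}; use one of {sorted(BUILTIN_REGIMENS)} "
            "or START:STOP:INTERVAL[:PARTICIPATION]")
    start, stop, interval = (int(p) for p in parts[:3])
    participation = float(parts[3]) if len(parts) == 4 else 1.0
    return ScreeningRegimen.uniform(spec, start, stop, interval, participation)


def screening_sensitivity(diameter: float, sens: SensitivityParams) -> float:
    """P(screen detects an invasive tumor of this diameter).

    smax / (1 + exp(−k·(d − d50))): monotone nondecreasing in diameter,
    bounded by smax.
    """
    if diameter < 0:
        raise ValueError(f"diameter must be nonnegative, got {diameter}")
    z = -sens.k * (diameter - sens.d50)
    if z > 700:
        return 0.0
    return sens.smax / (1.0 + math.exp(z))


def clinical_surfacing_age(tumor: Tumor, clin: ClinicalDetectionParams,
                           u: float) -> float:
    """First age at which the cumulative surfacing hazard exceeds −ln(u).

    The yearly hazard in the year starting t years after invasive onset is
    c0 · d(t) / dref.  Returns ``inf`` when the cancer never surfaces
    within the lifespan grid (e.g. it never becomes invasive, or it is too
    small/slow before age 110) — such cancers can only be found by
    screening, or never.
    """
    if not (0.0 < u < 1.0):
        raise ValueError(f"u must be in (0, 1), got {u}")
    if tumor.invasive_age == NEVER:
        return NEVER
    target = -math.log(u)
    cum = 0.0
    t = 0.0
    age = tumor.invasive_age
    while age < MAX_AGE + 1:
        cum += clin.c0 * tumor_diameter(tumor, t) / clin.dref
        t += 1.0
        age += 1.0
        if cum >= target:
            return age
    return NEVER


@dataclass
class ScreenOutcome:
    """Result of one attended screen."""

    detected: bool = False
    fp_recall: bool = False
    neg_biopsy: bool = False


def screen_event(cancer_detectable: bool, is_insitu: bool, diameter: float,
                 sens: SensitivityParams, fp_recall_rate: float,
                 biopsy_given_recall: float, neg_biopsy_given_no_cancer: float,
                 u_detect: float, u_fp: float, u_biopsy: float) -> ScreenOutcome:
    """Resolve one attended screen.

    With an undiagnosed cancer present, detection occurs when
    ``u_detect < sensitivity`` (the fixed in-situ constant for in-situ
    lesions).  With no detectable cancer, a false-positive recall occurs
    when ``u_fp < fp_recall_rate`` and the recalled woman receives a
    biopsy when ``u_biopsy < biopsy_given_recall``; that biopsy is
    negative with probability ``neg_biopsy_given_no_cancer`` (1 by
    default: she has no cancer to find).
    """
    out = ScreenOutcome()
    if cancer_detectable:
        p = sens.insitu if is_insitu else screening_sensitivity(diameter, sens)
        out.detected = u_detect < p
        return out
    if u_fp < fp_recall_rate:
        out.fp_recall = True
        if u_biopsy < biopsy_given_recall * neg_biopsy_given_no_cancer:
            out.neg_biopsy = True
    return out


@dataclass
class DetectionRecord:
    """How (and whether) a woman's cancer was found, plus screen counters."""

    mode: str = "none"               # "screen" | "clinical" | "none"
    age_at_dx: float | None = None
    stage_at_dx: str | None = None   # substage label
    diameter_at_dx: float | None = None
    n_screens: int = 0
    n_fp_recalls: int = 0
    n_neg_biopsies: int = 0
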