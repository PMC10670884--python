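"""Derived screening-outcome statistics and regimen comparison reports.

Given per-regimen outcomes — either simulated :class:`~mammosim.engine.
CohortOutcomes` or a table of published per-regimen levels — this module
computes every derived statistic used to compare regimens: absolute and
relative mortality reduction versus no screening, life years saved,
population-level annual deaths averted, number needed to screen (per
death averted and per life year gained), participation-weighted mixtures,
and stage-at-diagnosis distributions per 100,000 women.

The dual input mode exists because the absolute levels of a calibrated
national microsimulation (e.g. 15.7 breast-cancer deaths per 1000
unscreened women) depend on proprietary calibration; the arithmetic that
turns levels into reductions, NNS and weighted mixtures is exact and
testable on the published levels themselves, independently of this
package's synthetic calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .engine import CohortOutcomes
from .stages import EARLY_INVASIVE

# ---------------------------------------------------------------------------
# Elementary outcome arithmetic
# ---------------------------------------------------------------------------


def absolute_reduction(baseline_deaths_per_1000: float,
                       regimen_deaths_per_1000: float) -> float:
    """Deaths averted per 1000 women: baseline minus regimen."""
    if baseline_deaths_per_1000 < 0 or regimen_deaths_per_1000 < 0:
        raise ValueError("death rates must be nonnegative")
    return baseline_deaths_per_1000 - regimen_deaths_per_1000


def relative_reduction(reduction_per_1000: float,
                       baseline_deaths_per_1000: float) -> float:
    """Relative mortality reduction in percent: 100 · reduction / baseline."""
    if baseline_deaths_per_1000 <= 0:
        raise ValueError("baseline death rate must be positive")
    return 100.0 * reduction_per_1000 / baseline_deaths_per_1000


def participation_weighted(screened_value: float, unscreened_value: float,
                           p: float) -> float:
    """Mixture of outcomes for participation fraction p: p·screened + (1−p)·unscreened."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"participation must be in [0, 1], got {p}")
    return p * screened_value + (1.0 - p) * unscreened_value


@dataclass(frozen=True)
class PopulationScale:
    """Cohort-to-nation scaling: women entering the screening ages per year.

    The default corresponds to roughly 235,820 women turning 40 each year
    (Canada); multiply national values by ``us_multiplier`` (population
    ratio, about 8.3) for a US-scale figure.
    """

    women_per_cohort_year: float = 235_820.0
    us_multiplier: float = 8.3

    def __post_init__(self):
        if self.women_per_cohort_year <= 0 or self.us_multiplier <= 0:
            raise ValueError("population scale factors must be positive")


def scale_to_population(reduction_per_1000: float,
                        scale: PopulationScale = PopulationScale(),
                        participation: float = 1.0) -> int:
    """Annual national deaths averted: reduction/1000 · cohort-year size · participation."""
    if reduction_per_1000 < 0:
        raise ValueError("reduction must be nonnegative")
    value = reduction_per_1000 * scale.women_per_cohort_year / 1000.0
    return round(participation_weighted(value, 0.0, participation))


def scale_national(national_value: float, participation: float = 1.0,
                   multiplier: float = 1.0) -> int:
    """Auxiliary mode: apply participation and/or a population ratio to an
    already-scaled national count (e.g. 1862 × 0.7 = 1303)."""
    if national_value < 0:
        raise ValueError("national value must be nonnegative")
    return round(participation_weighted(national_value, 0.0, participation) * multiplier)


def nns_per_death(reduction_per_1000: float) -> float:
    """Women who must be screened to avert one breast-cancer death."""
    if reduction_per_1000 <= 0:
        raise ValueError("no mortality benefit: NNS per death is undefined")
    return 1000.0 / reduction_per_1000


def nns_per_life_year(ly_saved_per_1000: float) -> float:
    """Women who must be screened per life year gained (one decimal)."""
    if ly_saved_per_1000 <= 0:
        raise ValueError("no life years gained: NNS per life year is undefined")
    return round(1000.0 / ly_saved_per_1000, 1)


def mean_ly_per_death_averted(ly_saved_per_1000: float,
                              reduction_per_1000: float) -> float:
    """Mean life years gained by one averted death: LY saved / deaths averted."""
    if reduction_per_1000 <= 0:
        raise ValueError("no deaths averted")
    return ly_saved_per_1000 / reduction_per_1000


def gain_ratio(value_a: float, value_b: float) -> float:
    """Fold change between two regimens' gains (e.g. life years saved)."""
    if value_b == 0:
        raise ValueError("cannot form a ratio against a zero gain")
    return value_a / value_b


# ---------------------------------------------------------------------------
# Stage tables
# ---------------------------------------------------------------------------


def stage_table(outcomes: CohortOutcomes, per: float = 100_000.0) -> dict:
    """Coarse stage counts scaled to ``per`` women, with total and the
    early-invasive (Stage 1 or 2A) fraction from internal substages."""
    scale = per / outcomes.n_alive_at_entry
    coarse = {k: v * scale for k, v in outcomes.coarse_stage_counts().items()}
    return {
        "stage_counts": coarse,
        "total": sum(coarse.values()),
        "early_invasive_fraction": outcomes.early_invasive_fraction,
    }


# ---------------------------------------------------------------------------
# Published per-regimen outcome levels (exact-arithmetic input mode)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrintedOutcomes:
    """Per-regimen outcome levels as printed in a published comparison.

    ``ly_saved_per_1000`` is already relative to the no-screening
    baseline; stage counts are per 100,000 women over a 36-year window and
    the early-invasive fraction is carried as given (its Stage 2A split is
    not recoverable from the coarse rows).
    """

    name: str
    deaths_per_1000: float
    ly_saved_per_1000: float
    screens_per_woman: float = 0.0
    recalls_per_1000: float = 0.0
    neg_biopsies_per_1000: float = 0.0
    stage_per_100k: dict[int, float] = field(default_factory=dict)
    early_invasive_fraction: float | None = None
    #: national annual deaths averted as printed (computed from unrounded
    #: reductions at the source, so not exactly reduction x cohort-year size)
    national_annual_averted: float | None = None

    @property
    def stage_total(self) -> float:
        return sum(self.stage_per_100k.values())


def published_outcomes() -> dict[str, PrintedOutcomes]:
    """Outcome levels reported for the OncoSim-Breast model of the Canadian
    Partnership Against Cancer (1.53 million simulated women born 1975,
    deaths evaluated ages 40–76), used by the exact-arithmetic reporting
    mode and as a scale reference for the synthetic defaults."""
    rows = {
        # name: deaths/1000, LY saved/1000, screens/woman, recalls/1000,
        #       neg biopsies/1000, stage counts per 100k (0..4),
        #       early fraction, national annual deaths averted
        "no_screening": (15.7, 0.0, 0.0, 0.0, 0.0,
                         {0: 403, 1: 2019, 2: 3641, 3: 1417, 4: 545}, 0.54, None),
        "annual_40_49": (12.4, 44.8, 9.3, 660.0, 58.8,
                         {0: 565, 1: 2496, 2: 3400, 3: 1246, 4: 469}, 0.59, 770),
        "biennial_50_74": (11.1, 33.2, 11.6, 641.0, 57.1,
                           {0: 998, 1: 4133, 2: 2977, 3: 878, 4: 354}, 0.72, 1074),
        "biennial_40_74": (9.7, 58.1, 16.3, 959.0, 85.3,
                           {0: 1015, 1: 4334, 2: 2869, 3: 790, 4: 314}, 0.74, 1397),
        "hybrid_40_49a_50_74b": (9.1, 68.3, 20.9, 1236.0, 110.0,
                                 {0: 1042, 1: 4526, 2: 2768, 3: 737, 4: 294}, 0.76, 1538),
        "annual_40_74": (7.8, 78.9, 31.6, 1772.0, 157.7,
                         {0: 1208, 1: 5367, 2: 2299, 3: 503, 4: 231}, 0.82, 1862),
    }
    return {
        name: PrintedOutcomes(name, deaths, ly, screens, recalls, biopsies,
                              dict(stages), frac, national)
        for name, (deaths, ly, screens, recalls, biopsies, stages, frac, national)
        in rows.items()
    }


# ---------------------------------------------------------------------------
# Full comparison reports
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """Baseline-vs-regimen derived statistics for one screening regimen.

    With ``participation`` p < 1, per-cohort-offered quantities (deaths,
    reduction, relative reduction, national deaths averted, screens,
    recalls, biopsies, stage counts) are p-weighted mixtures with the
    baseline; per-actually-screened quantities (life years saved per 1000
    screened, both NNS values) are unchanged, so the algebraic NNS
    identities hold exactly at p = 1.
    """

    regimen: str
    participation: float
    deaths_per_1000: float
    reduction_per_1000: float
    relative_reduction_pct: float
    ly_saved_per_1000: float
    national_annual_averted: int
    nns_per_death: float | None
    nns_per_ly: float | None
    screens_per_woman: float
    recalls_per_1000: float
    neg_biopsies_per_1000: float
    stage_per_100k: dict[int, float]
    early_invasive_fraction: float | None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["stage_per_100k"] = dict(self.stage_per_100k)
        return d


@dataclass(frozen=True)
class _Summary:
    deaths_per_1000: float
    ly_per_1000: float          # level for simulated, saved-vs-baseline for printed
    ly_is_saved: bool
    screens_per_woman: float
    recalls_per_1000: float
    neg_biopsies_per_1000: float
    stage_per_100k: dict[int, float]
    early_invasive_fraction: float | None


def _summarize(o: "CohortOutcomes | PrintedOutcomes") -> _Summary:
    if isinstance(o, CohortOutcomes):
        frac = o.early_invasive_fraction
        return _Summary(o.deaths_per_1000, o.life_years_per_1000, False,
                        o.screens_per_woman, o.recalls_per_1000,
                        o.neg_biopsies_per_1000, o.stage_per_100k(),
                        None if frac != frac else frac)
    return _Summary(o.deaths_per_1000, o.ly_saved_per_1000, True,
                    o.screens_per_woman, o.recalls_per_1000,
                    o.neg_biopsies_per_1000, dict(o.stage_per_100k),
                    o.early_invasive_fraction)


def _weighted_early_fraction(reg: _Summary, base: _Summary, p: float) -> float | None:
    if reg.early_invasive_fraction is None or base.early_invasive_fraction is None:
        return reg.early_invasive_fraction
    inv_r = sum(v for k, v in reg.stage_per_100k.items() if k > 0)
    inv_b = sum(v for k, v in base.stage_per_100k.items() if k > 0)
    if not reg.stage_per_100k or not base.stage_per_100k or p == 1.0:
        return reg.early_invasive_fraction
    early = p * reg.early_invasive_fraction * inv_r \
        + (1 - p) * base.early_invasive_fraction * inv_b
    inv = p * inv_r + (1 - p) * inv_b
    return early / inv if inv > 0 else None


def compare(regimen_outcomes: "CohortOutcomes | PrintedOutcomes",
            baseline_outcomes: "CohortOutcomes | PrintedOutcomes",
            scale: PopulationScale = PopulationScale(),
            participation: float = 1.0) -> ComparisonReport:
    """Build the full derived-statistics report for one regimen vs baseline."""
    reg, base = _summarize(regimen_outcomes), _summarize(baseline_outcomes)
    name = regimen_outcomes.regimen if isinstance(regimen_outcomes, CohortOutcomes) \
        else regimen_outcomes.name

    full_reduction = absolute_reduction(base.deaths_per_1000, reg.deaths_per_1000)
    ly_saved = reg.ly_per_1000 if reg.ly_is_saved \
        else reg.ly_per_1000 - base.ly_per_1000

    p = participation
    deaths = participation_weighted(reg.deaths_per_1000, base.deaths_per_1000, p)
    reduction = absolute_reduction(base.deaths_per_1000, deaths)
    rel = relative_reduction(reduction, base.deaths_per_1000) \
        if base.deaths_per_1000 > 0 else float("nan")
    national = scale_to_population(max(full_reduction, 0.0), scale, p)

    stage = {k: participation_weighted(v, base.stage_per_100k.get(k, 0.0), p)
             for k, v in reg.stage_per_100k.items()}
    return ComparisonReport(
        regimen=name,
        participation=p,
        deaths_per_1000=deaths,
        reduction_per_1000=reduction,
        relative_reduction_pct=rel,
        ly_saved_per_1000=ly_saved,
        national_annual_averted=national,
        nns_per_death=nns_per_death(full_reduction) if full_reduction > 0 else None,
        nns_per_ly=nns_per_life_year(ly_saved) if ly_saved > 0 else None,
        screens_per_woman=participation_weighted(reg.screens_per_woman, base.screens_per_woman, p),
        recalls_per_1000=participation_weighted(reg.recalls_per_1000, base.recalls_per_1000, p),
        neg_biopsies_per_1000=participation_weighted(reg.neg_biopsies_per_1000, base.neg_biopsies_per_1000, p),
        stage_per_100k=stage,
        early_invasive_fraction=_weighted_early_fraction(reg, base, p),
    )


def build_report(outcomes_by_regimen: dict[str, "CohortOutcomes | PrintedOutcomes"],
                 baseline: str = "no_screening",
                 scale: PopulationScale = PopulationScale(),
                 participation: float = 1.0) -> dict[str, ComparisonReport]:
    """One ComparisonReport per non-baseline regimen.

    Accepts simulated CohortOutcomes or PrintedOutcomes (or a mixture);
    raises if the baseline key is missing.
    """
    if baseline not in outcomes_by_regimen:
        raise ValueError(f"baseline regimen {baseline!r} missing from outcomes")
    base = outcomes_by_regimen[baseline]
    return {name: compare(o, base, scale, participation)
            for name, o in outcomes_by_regimen.items() if name != baseline}
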