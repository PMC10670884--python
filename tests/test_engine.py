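import dataclasses
import math

import numpy as np
import pytest

from mammosim import (BUILTIN_REGIMENS, ReportWindow, ScreeningRegimen,
                      run_cohort, run_history, run_regimens)
from conftest import scripted_params, zero_screen_params

ANNUAL = BUILTIN_REGIMENS["annual_40_74"]
BIENNIAL_50 = BUILTIN_REGIMENS["biennial_50_74"]
NONE = BUILTIN_REGIMENS["no_screening"]


def histories_equal_except_screens(a, b) -> bool:
    """Field-for-field equality of two LifeHistory objects, ignoring the
    count of performed screens (screens are performed regardless of their
    sensitivity, so the counter necessarily differs between regimens)."""
    da, db = dataclasses.replace(a.detection, n_screens=0), \
        dataclasses.replace(b.detection, n_screens=0)
    return (a.woman_id == b.woman_id
            and a.other_death_age == b.other_death_age
            and a.attends_screening == b.attends_screening
            and a.tumor == b.tumor
            and da == db
            and a.death == b.death
            and a.bc_death_age == b.bc_death_age
            and a.surfacing_age == b.surfacing_age)


class TestCommonRandomNumbers:
    def test_zero_sensitivity_screening_reproduces_no_screening_histories(
            self, default_params):
        """With smax = 0, in-situ sensitivity 0 and fp rate 0, screening can
        change nothing: each history under the annual regimen equals the
        no-screening history on every field except the screen counter."""
        params = zero_screen_params(default_params)
        for woman_id in range(2000):
            h_none = run_history(params, NONE, woman_id)
            h_ann = run_history(params, ANNUAL, woman_id)
            assert histories_equal_except_screens(h_none, h_ann)

    def test_natural_history_is_regimen_independent(self, default_params):
        """Under full-strength screening the tumor trajectory, other-cause
        death age, surfacing age and attendance are still identical across
        regimens — only detection and its consequences differ."""
        for woman_id in range(2000):
            h_none = run_history(default_params, NONE, woman_id)
            h_ann = run_history(default_params, ANNUAL, woman_id)
            assert h_none.other_death_age == h_ann.other_death_age
            assert h_none.tumor == h_ann.tumor
            assert h_none.surfacing_age == h_ann.surfacing_age
            assert h_none.attends_screening == h_ann.attends_screening


class TestScriptedTrace:
    """Hand-computed history: onset forced just past age 45, invasive at
    onset, gamma = 0.3 exactly, d0 = 5, dmax = 128, no nodal/distant
    spread, no clinical surfacing, screens detect with certainty, no
    other-cause death before 109."""

    def _diameter(self, years):
        return 128.0 * (5.0 / 128.0) ** math.exp(-0.3 * years)

    def test_biennial_50_detects_at_50_at_stage_3(self, traceable_params):
        h = run_history(traceable_params, BIENNIAL_50, woman_id=4)
        assert h.tumor.onset_age == pytest.approx(45.0, abs=1e-6)
        assert h.detection.mode == "screen"
        assert h.detection.age_at_dx == 50.0
        assert h.detection.n_screens == 1
        # d(5) = 128 * (5/128)^exp(-1.5) = 62.0857... mm > 50 mm, node-negative
        assert h.detection.diameter_at_dx == pytest.approx(self._diameter(5.0), abs=1e-6)
        assert h.detection.stage_at_dx == "3"

    def test_annual_40_detects_at_46_at_stage_1(self, traceable_params):
        h = run_history(traceable_params, ANNUAL, woman_id=4)
        assert h.detection.mode == "screen"
        assert h.detection.age_at_dx == 46.0
        # screens at 40..45 happen before onset; the counter includes them
        assert h.detection.n_screens == 7
        # d(1) = 128 * (5/128)^exp(-0.3) = 11.589 mm <= 20 mm, node-negative
        assert h.detection.diameter_at_dx == pytest.approx(self._diameter(1.0), abs=1e-6)
        assert h.detection.stage_at_dx == "1"

    def test_clinical_surfacing_when_unscreened(self):
        params = scripted_params()
        params = dataclasses.replace(
            params,
            clinical_detection=dataclasses.replace(params.clinical_detection,
                                                   c0=100.0)).validate()
        h = run_history(params, NONE, woman_id=4)
        assert h.detection.mode == "clinical"
        assert h.detection.age_at_dx == pytest.approx(46.0, abs=1e-6)
        assert h.surfacing_age == pytest.approx(46.0, abs=1e-6)

    def test_screen_wins_same_year_tie_against_clinical(self):
        """A screen scheduled in the year the tumor would surface counts
        as screen detection (screen precedes surfacing within a year)."""
        params = scripted_params()
        params = dataclasses.replace(
            params,
            clinical_detection=dataclasses.replace(params.clinical_detection,
                                                   c0=100.0)).validate()
        regimen = ScreeningRegimen.uniform("at46", 46, 46, 1)
        h = run_history(params, regimen, woman_id=4)
        assert h.detection.mode == "screen"
        assert h.detection.age_at_dx == 46.0


class TestRunCohort:
    def test_zero_onset_hazard_yields_no_cancers_and_fp_law_recalls(
            self, default_params, immortal_life_table):
        params = dataclasses.replace(
            default_params, onset_hazard=np.zeros(110),
            life_table=immortal_life_table).validate()
        out = run_cohort(params, BIENNIAL_50, 20_000)
        assert out.total_cancers == 0
        assert out.bc_deaths_in_window == 0
        expected = 1000 * 13 * params.fp_recall_rate
        se = 1000 * math.sqrt(13 * 0.055 * 0.945 / 20_000)
        assert abs(out.recalls_per_1000 - expected) < 4 * se

    def test_run_cohort_is_deterministic(self, default_params):
        a = run_cohort(default_params, BIENNIAL_50, 3000)
        b = run_cohort(default_params, BIENNIAL_50, 3000)
        assert a.to_dict() == b.to_dict()

    def test_stage_counts_sum_to_total_cancers(self, default_params):
        out = run_cohort(default_params, ANNUAL, 10_000)
        assert sum(out.stage_counts.values()) == out.total_cancers

    def test_life_years_bounded_by_window_and_one_death_each(self, default_params):
        window = ReportWindow(40.0, 76.0)
        out = run_cohort(default_params, NONE, 10_000, window=window)
        assert out.total_life_years <= 36.0 * out.n_alive_at_entry
        assert out.n_alive_at_entry <= out.n_women

    def test_batch_means_standard_error_is_consistent(self, default_params):
        """Ten independent 10,000-woman batches: the empirical SD of the
        per-batch total-cancer count should agree with the binomial SD
        implied by the pooled cancer rate within a factor of 1.5."""
        batches = [run_cohort(default_params, NONE, 10_000, base_seed=1000 + b)
                   for b in range(10)]
        counts = np.array([b.total_cancers for b in batches], dtype=float)
        alive = np.array([b.n_alive_at_entry for b in batches], dtype=float)
        p_hat = counts.sum() / alive.sum()
        theoretical_sd = math.sqrt(alive.mean() * p_hat * (1 - p_hat))
        empirical_sd = counts.std(ddof=1)
        assert empirical_sd < 1.5 * theoretical_sd
        assert empirical_sd > theoretical_sd / 1.5

    def test_participation_zero_reproduces_no_screening_outcomes(
            self, default_params):
        regimen = ScreeningRegimen.uniform("annual_p0", 40, 74, 1,
                                           participation=0.0)
        none = run_cohort(default_params, NONE, 3000)
        p0 = run_cohort(default_params, regimen, 3000)
        d_none, d_p0 = none.to_dict(), p0.to_dict()
        d_none.pop("regimen"), d_p0.pop("regimen")
        assert d_none == d_p0

    def test_all_or_none_participation_splits_cohort(self, default_params):
        """Participation 0.7 means each woman either attends every screen
        or none: about 70% of women have screens, and attenders' screen
        counts match the full-participation run woman-for-woman."""
        regimen = ScreeningRegimen.uniform("biennial_p07", 50, 74, 2,
                                           participation=0.7)
        n = 4000
        attended, matching = 0, 0
        for woman_id in range(n):
            h = run_history(default_params, regimen, woman_id)
            if h.attends_screening:
                attended += 1
                full = run_history(default_params, BIENNIAL_50, woman_id)
                matching += h.detection.n_screens == full.detection.n_screens
        assert attended == matching  # attenders behave exactly as under p=1
        se = math.sqrt(0.7 * 0.3 / n)
        assert abs(attended / n - 0.7) < 3 * se
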