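import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammosim import (BUILTIN_REGIMENS, absolute_reduction, build_report,
                      compare, gain_ratio, mean_ly_per_death_averted,
                      nns_per_death, nns_per_life_year, participation_weighted,
                      published_outcomes, relative_reduction, run_cohort,
                      scale_national, scale_to_population, stage_table)
from mammosim.reporting import PopulationScale

PUB = published_outcomes()


class TestElementaryArithmetic:
    def test_absolute_reduction_published_rows(self):
        assert absolute_reduction(15.7, 11.1) == pytest.approx(4.6)
        assert absolute_reduction(11.1, 9.7) == pytest.approx(1.4)
        assert absolute_reduction(8.0, 8.0) == 0.0
        with pytest.raises(ValueError):
            absolute_reduction(-1.0, 0.5)

    def test_relative_reduction(self):
        assert relative_reduction(0.0, 15.7) == 0.0
        # printed value 29.10% was computed from unrounded inputs;
        # arithmetic on the rounded inputs gives 29.3%
        assert relative_reduction(4.6, 15.7) == pytest.approx(29.1, abs=0.5)
        assert relative_reduction(2.3, 7.85) == relative_reduction(4.6, 15.7)
        with pytest.raises(ValueError):
            relative_reduction(1.0, 0.0)

    def test_participation_weighting(self):
        assert participation_weighted(7.9, 0.0, 0.7) == pytest.approx(5.5, abs=0.05)
        assert participation_weighted(7.9, 3.0, 1.0) == 7.9
        assert participation_weighted(7.9, 3.0, 0.0) == 3.0
        with pytest.raises(ValueError):
            participation_weighted(1.0, 0.0, 1.2)

    def test_population_scaling(self):
        assert scale_national(1862, participation=0.7) == 1303
        assert scale_national(1862) - scale_national(1074) == 788
        assert scale_to_population(0.0) == 0
        # full-participation national value from the reduction itself
        assert scale_to_population(7.9) == round(7.9 * 235.82)

    def test_nns_per_death(self):
        assert nns_per_death(1000.0) == 1.0
        assert nns_per_death(7.9) == pytest.approx(126.7, abs=0.2)
        with pytest.raises(ValueError):
            nns_per_death(0.0)

    def test_nns_per_life_year(self):
        assert nns_per_life_year(58.1) == 17.2
        assert nns_per_life_year(78.9) == 12.7
        assert nns_per_life_year(1000.0) == 1.0
        with pytest.raises(ValueError):
            nns_per_life_year(-1.0)

    def test_mean_ly_per_death_averted(self):
        assert round(mean_ly_per_death_averted(78.9, 7.9)) == 10
        assert mean_ly_per_death_averted(4.0, 4.0) == 1.0
        assert gain_ratio(58.1, 33.2) == pytest.approx(1.75, abs=0.005)
        with pytest.raises(ValueError):
            mean_ly_per_death_averted(10.0, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(reduction=st.floats(0.1, 900.0))
    def test_nns_identity_is_algebraic(self, reduction):
        assert nns_per_death(reduction) * reduction == pytest.approx(1000.0)

    @settings(derandomize=True, max_examples=100)
    @given(a=st.floats(0.0, 50.0), b=st.floats(0.0, 50.0),
           base=st.floats(0.0, 50.0), p=st.floats(0.0, 1.0))
    def test_participation_weighting_is_linear(self, a, b, base, p):
        """Weighting each regimen column then differencing equals
        differencing then weighting."""
        lhs = participation_weighted(a, base, p) - participation_weighted(b, base, p)
        rhs = p * (a - b)
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestStageTables:
    def test_published_stage_columns_sum_to_printed_totals(self):
        assert PUB["no_screening"].stage_total == 8025
        assert PUB["annual_40_74"].stage_total == 9608
        # this column's printed total (9341) exceeds its printed rows' sum
        # by one — a rounding artifact of the source table
        assert PUB["biennial_50_74"].stage_total == pytest.approx(9341, abs=1)
        assert PUB["biennial_40_74"].stage_total == 9322
        assert PUB["hybrid_40_49a_50_74b"].stage_total == 9367
        assert PUB["annual_40_49"].stage_total == 8176

    def test_simulated_stage_table_scales_and_sums(self, default_params):
        out = run_cohort(default_params, BUILTIN_REGIMENS["biennial_50_74"], 5000)
        table = stage_table(out)
        assert table["total"] == pytest.approx(sum(table["stage_counts"].values()))
        assert table["total"] == pytest.approx(
            out.total_cancers * 100_000 / out.n_alive_at_entry)
        assert 0.0 <= table["early_invasive_fraction"] <= 1.0

    def test_empty_cohort_stage_table_is_all_zeros(self, default_params):
        import dataclasses

        import numpy as np
        params = dataclasses.replace(default_params,
                                     onset_hazard=np.zeros(110)).validate()
        out = run_cohort(params, BUILTIN_REGIMENS["no_screening"], 500)
        table = stage_table(out)
        assert table["total"] == 0.0
        assert all(v == 0.0 for v in table["stage_counts"].values())
        assert math.isnan(table["early_invasive_fraction"])


class TestBuildReport:
    def test_printed_values_mode_reproduces_derived_columns(self):
        reports = build_report(PUB, baseline="no_screening")
        r50 = reports["biennial_50_74"]
        assert r50.reduction_per_1000 == pytest.approx(4.6)
        assert r50.relative_reduction_pct == pytest.approx(29.1, abs=0.5)
        annual = reports["annual_40_74"]
        assert annual.reduction_per_1000 == pytest.approx(7.9)
        assert annual.nns_per_death == pytest.approx(126.7, abs=0.2)
        assert annual.nns_per_ly == 12.7
        assert reports["biennial_40_74"].nns_per_ly == 17.2
        # national column: printed values used unrounded reductions; the
        # propagated rounding bound is 0.1/1000 * 235,820 ~ 24 deaths
        assert annual.national_annual_averted == pytest.approx(1862, abs=24)
        assert r50.national_annual_averted == pytest.approx(1074, abs=24)

    def test_missing_baseline_raises(self):
        with pytest.raises(ValueError, match="baseline"):
            build_report({"annual_40_74": PUB["annual_40_74"]},
                         baseline="no_screening")

    def test_full_participation_report_equals_unadjusted(self):
        full = build_report(PUB, participation=1.0)
        default = build_report(PUB)
        assert {k: v.to_dict() for k, v in full.items()} \
            == {k: v.to_dict() for k, v in default.items()}

    def test_partial_participation_mixes_offered_outcomes_only(self):
        """At 70% participation the per-offered-cohort quantities shrink to
        the 70:30 mixture while per-actually-screened quantities (LY saved
        per 1000 screened, both NNS) are unchanged."""
        p07 = build_report(PUB, participation=0.7)["annual_40_74"]
        p10 = build_report(PUB, participation=1.0)["annual_40_74"]
        assert p07.reduction_per_1000 == pytest.approx(5.53)
        assert p07.relative_reduction_pct == pytest.approx(35.3, abs=0.2)
        assert p07.ly_saved_per_1000 == p10.ly_saved_per_1000
        assert p07.nns_per_death == p10.nns_per_death
        assert p07.nns_per_ly == p10.nns_per_ly
        assert p07.screens_per_woman == pytest.approx(0.7 * 31.6)
        assert p07.recalls_per_1000 == pytest.approx(0.7 * 1772.0)
        assert p07.neg_biopsies_per_1000 == pytest.approx(0.7 * 157.7)

    def test_simulated_mode_is_deterministic(self, default_params):
        regs = [BUILTIN_REGIMENS["no_screening"], BUILTIN_REGIMENS["biennial_50_74"]]
        from mammosim import run_regimens
        a = build_report(run_regimens(default_params, regs, 3000))
        b = build_report(run_regimens(default_params, regs, 3000))
        assert {k: v.to_dict() for k, v in a.items()} \
            == {k: v.to_dict() for k, v in b.items()}

    def test_simulated_mode_nns_identity(self, default_params):
        from mammosim import run_regimens
        regs = [BUILTIN_REGIMENS["no_screening"], BUILTIN_REGIMENS["annual_40_74"]]
        report = build_report(run_regimens(default_params, regs, 20_000))["annual_40_74"]
        assert report.nns_per_death * report.reduction_per_1000 \
            == pytest.approx(1000.0)

    def test_compare_accepts_mixed_input_types(self, default_params):
        sim = run_cohort(default_params, BUILTIN_REGIMENS["biennial_50_74"], 2000)
        report = compare(sim, PUB["no_screening"])
        assert report.regimen == "biennial_50_74"

    def test_us_population_scaling_multiplier(self):
        scale = PopulationScale()
        assert scale_national(1862, multiplier=scale.us_multiplier) \
            == round(1862 * 8.3)
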