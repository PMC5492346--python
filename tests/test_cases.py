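"""Case I/O, flag derivation from weather, classification, and summaries."""

import random
from datetime import date

import pytest

from heatstrain.cases import (
    WorkerCase,
    classify,
    derive_flags,
    load_cases,
    load_reference_cohort,
    round_percent,
    save_cases,
    summarize,
)
from heatstrain.config import AnalysisConfig
from heatstrain.errors import (
    CoverageError,
    EmptyInputError,
    IncompleteCaseError,
    SchemaError,
)
from heatstrain.limits import MetabolicClass
from heatstrain.synthetic import WeatherGenConfig, generate_weather
from heatstrain.wbgt import MeteoSeries


class TestLoadCases:
    def test_reference_cohort_has_47_cases(self, reference_cohort):
        assert len(reference_cohort) == 47

    def test_first_case_fields(self, reference_cohort):
        c = reference_cohort[0]
        assert c.heavy_exertion is True
        assert c.unacclimatized is False
        assert c.age == 41
        assert c.tropical_night is False
        assert c.heat_wave is True
        assert c.wbgt_max == 31.75

    def test_round_trip_identity(self, reference_cohort, tmp_path):
        path = tmp_path / "cases.csv"
        save_cases(reference_cohort, path)
        assert load_cases(path) == reference_cohort

    def test_o_x_flags_accepted(self, tmp_path):
        path = tmp_path / "ox.csv"
        path.write_text(
            "case_id,age,heavy_exertion,unacclimatized,onset_date,"
            "tropical_night,heat_wave,wbgt_max\n"
            "1,41,o,x,,x,o,31.75\n"
        )
        (c,) = load_cases(path)
        assert c.heavy_exertion and not c.unacclimatized and c.heat_wave

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "case_id,age,heavy_exertion,unacclimatized,onset_date,"
            "tropical_night,heat_wave,wbgt_max\n"
        )
        assert load_cases(path) == []

    def test_schema_errors_name_the_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "case_id,age,heavy_exertion,unacclimatized,onset_date,"
            "tropical_night,heat_wave,wbgt_max\n"
            "7,notanage,1,0,,0,1,30.0\n"
        )
        with pytest.raises(SchemaError, match="row 7"):
            load_cases(path)
        path.write_text("case_id,age\n1,41\n")
        with pytest.raises(SchemaError, match="missing columns"):
            load_cases(path)

    def test_checksum_guard(self):
        assert len(load_reference_cohort(verify=True)) == 47


def _hot_weather(seed=0, noise=0.0):
    # onset 2013-07-19 sits in a declared 2-day episode after a tropical night
    cfg = WeatherGenConfig(
        n_days=7,
        heatwave_episodes=[(3, 2, 35.0)],
        tropical_night_nights=[4],
        noise_sd=noise,
        seed=seed,
    )
    return generate_weather(cfg)


ONSET = date(2013, 7, 19)  # day index 4 of the generated week


class TestDeriveFlags:
    def test_hot_scenario_sets_both_flags(self):
        case = WorkerCase("c1", 40, True, False, onset_date=ONSET)
        derived = derive_flags(case, _hot_weather())
        assert derived.heat_wave is True
        assert derived.tropical_night is True
        assert derived.wbgt_max is not None

    def test_cool_scenario_clears_both_flags(self):
        cool = generate_weather(WeatherGenConfig(n_days=7, noise_sd=0.0))
        case = WorkerCase("c1", 40, True, False, onset_date=ONSET)
        derived = derive_flags(case, cool)
        assert derived.heat_wave is False
        assert derived.tropical_night is False

    def test_incomplete_night_window_indeterminate(self):
        weather = _hot_weather()
        # drop the onset morning (00:00-05:59): night coverage falls below 75 %
        kept = tuple(
            o
            for o in weather.observations
            if not (o.timestamp.date() == ONSET and o.timestamp.hour < 6)
        )
        series = MeteoSeries(weather.station_id, kept)
        derived = derive_flags(WorkerCase("c1", 40, True, False, onset_date=ONSET), series)
        assert derived.tropical_night is None
        assert derived.heat_wave is True
        assert derived.wbgt_max is not None

    def test_insufficient_coverage_raises(self):
        weather = _hot_weather()
        case = WorkerCase("c1", 40, True, False, onset_date=date(2013, 7, 16))
        with pytest.raises(CoverageError, match="2013-07-13"):
            derive_flags(case, weather)

    def test_idempotent_given_same_weather(self):
        weather = _hot_weather()
        case = WorkerCase("c1", 40, True, False, onset_date=ONSET)
        once = derive_flags(case, weather)
        assert derive_flags(once, weather) == once

    def test_wider_wbgt_window_never_decreases_max(self):
        weather = _hot_weather()
        case = WorkerCase("c1", 40, True, False, onset_date=ONSET)
        one = derive_flags(case, weather, AnalysisConfig(wbgt_window_days=1))
        three = derive_flags(case, weather, AnalysisConfig(wbgt_window_days=3))
        assert three.wbgt_max >= one.wbgt_max


class TestClassify:
    def test_acclimatized_heavy_below_limit(self, reference_cohort):
        cl = classify(reference_cohort[39])  # heavy, acclimatized, WBGT 23.43
        assert cl.mclass is MetabolicClass.HIGH
        assert cl.limit_c == 25.0
        assert cl.exceeds is False

    def test_light_work_moderate_class(self, reference_cohort):
        cl = classify(reference_cohort[41])  # not heavy, acclimatized, WBGT 32.59
        assert cl.mclass is MetabolicClass.MODERATE
        assert cl.exceeds is True

    def test_extreme_wbgt_always_exceeds(self):
        case = WorkerCase("x", 40, False, True, wbgt_max=50.0)
        assert classify(case).exceeds

    def test_missing_wbgt_rejected(self):
        with pytest.raises(IncompleteCaseError):
            classify(WorkerCase("x", 40, False, True))


class TestSummarize:
    def test_reference_cohort_counts(self, reference_cohort):
        s = summarize(reference_cohort)
        assert s.counts == {
            "heat_wave": 29,
            "tropical_night": 37,
            "unacclimatized": 22,
            "heavy_exertion": 41,
            "exceeds_limit": 45,
        }
        assert s.proportions["heat_wave"] == 61.7
        assert s.proportions["tropical_night"] == 78.7
        assert s.proportions["unacclimatized"] == 46.8
        assert s.proportions["heavy_exertion"] == 87.2
        assert s.proportions["exceeds_limit"] == 95.7

    def test_reference_cohort_age_decades_sum(self, reference_cohort):
        s = summarize(reference_cohort)
        assert sum(s.age_decade_counts.values()) == 47
        assert set(s.age_decade_counts) == {20, 30, 40, 50, 60, 70}

    def test_single_case_all_flags(self):
        case = WorkerCase("only", 35, True, True, tropical_night=True, heat_wave=True, wbgt_max=35.0)
        s = summarize([case])
        assert all(v == 100.0 for v in s.proportions.values())

    def test_permutation_invariance(self, reference_cohort):
        shuffled = list(reference_cohort)
        random.Random(3).shuffle(shuffled)
        assert summarize(shuffled) == summarize(reference_cohort)

    def test_indeterminate_counts_as_false_and_reported(self):
        cases = [
            WorkerCase("a", 40, True, False, tropical_night=None, heat_wave=False, wbgt_max=30.0),
            WorkerCase("b", 40, True, False, tropical_night=True, heat_wave=True, wbgt_max=30.0),
        ]
        s = summarize(cases)
        assert s.counts["tropical_night"] == 1
        assert s.indeterminate["tropical_night"] == 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(EmptyInputError):
            summarize([])

    def test_misaligned_classifications_rejected(self, reference_cohort):
        cls = [classify(c) for c in reference_cohort[:10]]
        with pytest.raises(SchemaError):
            summarize(reference_cohort, cls)


class TestRounding:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(29, 47, 61.7), (45, 47, 95.7), (22, 47, 46.8), (37, 47, 78.7), (41, 47, 87.2),
         (1, 16, 6.3)],  # 6.25 rounds half-up to 6.3
    )
    def test_half_up_one_decimal(self, count, total, expected):
        assert round_percent(count, total) == expected
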