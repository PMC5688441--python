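"""Orchestration: ranking, truncation, grouping views, country filter, and
report integrity."""

import json

import pytest

from mopkit import (
    AgeGroup,
    AnalysisConfig,
    FixtureSpec,
    GroupBy,
    filter_countries,
    generate_profile,
    group_results,
    intervention_impact,
    rank_interventions,
    report_to_dict,
    report_to_frame,
    run_missed_opportunity,
    top_by_age_group,
    top_n,
)
from mopkit.analysis import NO_INTERVENTION, NO_SUMMING_CAVEAT
from mopkit.engine import ImpactResult
from mopkit.errors import ProfileConsistencyError


def _result(intervention_id: str, total: float) -> ImpactResult:
    return ImpactResult(
        intervention_id=intervention_id,
        name=intervention_id,
        delivery_point="community",
        averted_by_cell={},
        averted_by_age_group={g: 0.0 for g in AgeGroup},
        total_averted=total,
    )


def test_rank_descending_with_id_tiebreak():
    results = [_result("d", 5), _result("b", 9), _result("a", 9), _result("c", 1)]
    assert [r.intervention_id for r in rank_interventions(results)] == ["a", "b", "d", "c"]


def test_rank_trivial_cases():
    assert rank_interventions([]) == []
    single = [_result("x", 3.0)]
    assert rank_interventions(single) == single


def test_run_produces_ranked_report(synthetic_profile):
    report = run_missed_opportunity(synthetic_profile)
    totals = [r.total_averted for r in report.all_results]
    assert totals == sorted(totals, reverse=True)
    assert all(r.total_averted > 0 for r in report.results)
    assert NO_SUMMING_CAVEAT in report.warnings


def test_run_rejects_invalid_profile(synthetic_profile):
    broken = synthetic_profile.model_copy(update={"cpr": 0.9, "unmet_need": 0.9})
    with pytest.raises(ProfileConsistencyError):
        run_missed_opportunity(broken)


def test_all_interventions_at_target_rank_alphabetically(synthetic_profile):
    saturated = synthetic_profile.model_copy(
        update={
            "coverage": {k: 0.95 for k in synthetic_profile.coverage},
            "cpr": 0.95,
            "unmet_need": 0.05,
        }
    )
    report = run_missed_opportunity(saturated)
    assert all(r.total_averted == 0.0 for r in report.all_results)
    ids = [r.intervention_id for r in report.all_results]
    assert ids == sorted(ids)
    assert report.results == ()  # zero rows are dropped from the display


def test_higher_burden_intervention_ranks_first(toy_profile):
    # abx addresses 1000 pneumonia deaths; clone "tiny" addresses 100 at the
    # same effectiveness and coverage, so abx must dominate
    abx = toy_profile.catalogue[0]
    tiny = abx.model_copy(
        update={
            "id": "tiny",
            "entries": tuple(
                e.model_copy(update={"cause": "sepsis_pneumonia", "age_group": AgeGroup.NEONATAL})
                for e in abx.entries
            ),
        }
    )
    profile = toy_profile.model_copy(
        update={
            "catalogue": toy_profile.catalogue + (tiny,),
            "coverage": {**toy_profile.coverage, "tiny": toy_profile.coverage["abx"]},
            "deaths": {**toy_profile.deaths, "sepsis_pneumonia": 100.0},
        }
    )
    report = run_missed_opportunity(profile, AnalysisConfig(include_family_planning=False))
    ranked = [r.intervention_id for r in report.all_results]
    assert ranked.index("abx") < ranked.index("tiny")


def test_fp_ranks_first_when_favourable(synthetic_profile):
    profile = synthetic_profile.model_copy(update={"cpr": 0.20, "unmet_need": 0.40})
    report = run_missed_opportunity(profile)
    assert report.results[0].intervention_id == "fp_unmet_need"
    without = run_missed_opportunity(
        profile, AnalysisConfig(include_family_planning=False)
    )
    assert all(r.intervention_id != "fp_unmet_need" for r in without.all_results)


def test_reported_values_equal_solo_engine_runs(synthetic_profile):
    report = run_missed_opportunity(synthetic_profile)
    for result in report.results:
        if result.fp_pathways is not None:
            continue
        solo = intervention_impact(
            synthetic_profile, result.intervention_id, report.config.target_coverage
        )
        assert solo == result


def test_adding_zero_change_intervention_leaves_others_unchanged(toy_profile):
    report = run_missed_opportunity(toy_profile)
    extra = toy_profile.catalogue[0].model_copy(update={"id": "saturated"})
    profile = toy_profile.model_copy(
        update={
            "catalogue": toy_profile.catalogue + (extra,),
            "coverage": {**toy_profile.coverage, "saturated": 0.95},
        }
    )
    report2 = run_missed_opportunity(profile)
    assert {r.intervention_id: r.total_averted for r in report.all_results} == {
        r.intervention_id: r.total_averted
        for r in report2.all_results
        if r.intervention_id != "saturated"
    }


def test_report_exposes_no_grand_total(synthetic_profile):
    payload = report_to_dict(run_missed_opportunity(synthetic_profile))
    assert "total" not in payload and "sum" not in payload
    assert NO_SUMMING_CAVEAT in payload["warnings"]


def test_determinism_byte_identical_reports(synthetic_profile):
    a = report_to_dict(run_missed_opportunity(synthetic_profile))
    b = report_to_dict(run_missed_opportunity(generate_profile(FixtureSpec(seed=1))))
    assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)


def test_profile_not_mutated_by_run(synthetic_profile):
    snapshot = synthetic_profile.model_copy(deep=True)
    run_missed_opportunity(synthetic_profile)
    assert synthetic_profile == snapshot


def test_top_n_truncates_and_retains_full_results():
    profile = generate_profile(FixtureSpec(seed=3, n_interventions=30))
    report = run_missed_opportunity(profile)
    truncated = top_n(report, 20)
    assert len(truncated.results) == 20
    assert truncated.all_results == report.all_results
    assert truncated.results == report.results[:20]
    assert len(top_n(report, 1).results) == 1


def test_top_n_shorter_than_n(toy_profile):
    report = run_missed_opportunity(toy_profile)
    assert top_n(report, 20).results == report.results  # fewer than 20 rows


def test_outcome_grouping_rows_sum_to_totals(synthetic_profile):
    report = run_missed_opportunity(synthetic_profile)
    table = group_results(report, GroupBy.OUTCOME)
    totals = {r.intervention_id: r.total_averted for r in report.results}
    for intervention, row in table.iterrows():
        assert row.sum() == pytest.approx(totals[intervention])


def test_delivery_point_grouping_is_a_partition(synthetic_profile):
    report = run_missed_opportunity(synthetic_profile)
    table = group_results(report, GroupBy.DELIVERY_POINT)
    assert sorted(table["intervention"]) == sorted(
        r.intervention_id for r in report.results
    )
    for _, bucket in table.groupby("delivery_point"):
        ranks = bucket.sort_values("rank_in_group")["total_averted"].tolist()
        assert ranks == sorted(ranks, reverse=True)


def test_cause_grouping_passes_through_single_cause(toy_profile):
    report = run_missed_opportunity(
        toy_profile, AnalysisConfig(include_family_planning=False)
    )
    table = group_results(report, GroupBy.CAUSE)
    row = table.loc["abx"]
    assert row["pneumonia"] == pytest.approx(
        next(r for r in report.results if r.intervention_id == "abx").total_averted
    )
    nonzero = row[row > 0]
    assert list(nonzero.index) == ["pneumonia"]


def test_group_results_rejects_unknown_dimension(synthetic_profile):
    report = run_missed_opportunity(synthetic_profile)
    with pytest.raises(ValueError):
        group_results(report, "flavor")


def test_top_by_age_group_scan(toy_profile):
    report = run_missed_opportunity(
        toy_profile, AnalysisConfig(include_family_planning=False)
    )
    tops = top_by_age_group(report)
    assert tops[AgeGroup.CHILD] == "abx"
    assert tops[AgeGroup.MATERNAL] == "cemoc_ld"
    assert tops[AgeGroup.STILLBIRTH] == "cemoc_ld"
    assert tops[AgeGroup.NEONATAL] == NO_INTERVENTION  # nothing touches it


def test_top_by_age_group_all_zero(synthetic_profile):
    saturated = synthetic_profile.model_copy(
        update={
            "coverage": {k: 0.95 for k in synthetic_profile.coverage},
            "cpr": 0.95,
            "unmet_need": 0.05,
        }
    )
    report = run_missed_opportunity(saturated)
    assert set(top_by_age_group(report).values()) == {NO_INTERVENTION}


def test_filter_countries_boundary_inclusive():
    assert filter_countries({"A": 19.9, "B": 20.0, "C": 85.0}) == ["B", "C"]
    assert filter_countries({}) == []
    assert filter_countries({"A": 5.0, "B": 1.0}, threshold=0) == ["A", "B"]


def test_filter_countries_rejects_negative_u5mr():
    from mopkit.errors import ProfileRangeError

    with pytest.raises(ProfileRangeError):
        filter_countries({"A": -1.0})


def test_report_frame_columns_and_rank(synthetic_profile):
    frame = report_to_frame(run_missed_opportunity(synthetic_profile))
    assert list(frame.columns[:4]) == ["rank", "intervention", "name", "delivery_point"]
    assert frame["rank"].tolist() == list(range(1, len(frame) + 1))
    import numpy as np

    assert np.allclose(
        frame[[g.value for g in AgeGroup]].sum(axis=1), frame["total_averted"]
    )
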