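import datetime as dt

import pytest

from apmonitor import (
    CensusSpec,
    active_caseload,
    apply_sensitivity_exclusions,
    build_cohort,
    dementia_index,
    recent_use_v1,
    recent_use_v2,
)
from apmonitor.cohort import included_members

from conftest import D, make_episodes, make_stream
from oracles import oracle_active, oracle_cohort_included, oracle_dementia_index

CENSUS = D(2018, 6, 28)


def spec(**kw):
    kw.setdefault("census_date", CENSUS)
    return CensusSpec(**kw)


class TestActiveCaseload:
    def test_containment(self):
        eps = make_episodes([("P1", "CMHT-1", "community",
                              CENSUS - dt.timedelta(days=10),
                              CENSUS + dt.timedelta(days=10))])
        assert active_caseload(eps, CENSUS) == {"P1"}

    def test_ends_day_before_census(self):
        eps = make_episodes([("P1", "CMHT-1", "community",
                              D(2018, 1, 1), CENSUS - dt.timedelta(days=1))])
        assert active_caseload(eps, CENSUS) == set()

    def test_open_end_is_ongoing(self):
        eps = make_episodes([("P1", "CMHT-1", "community", D(2018, 1, 1), None)])
        assert active_caseload(eps, CENSUS) == {"P1"}

    def test_starts_on_census(self):
        eps = make_episodes([("P1", "CMHT-1", "community", CENSUS, None)])
        assert active_caseload(eps, CENSUS) == {"P1"}

    def test_matches_day_scan_oracle(self, fixture_bundle, fixture_config):
        for census in fixture_config.census_dates()[::5]:
            assert active_caseload(fixture_bundle.episodes, census) == \
                oracle_active(fixture_bundle.episodes, census)


class TestDementiaIndex:
    def test_earliest_across_sources(self):
        stream = make_stream(dxs=[
            ("P1", D(2018, 2, 1), "F00-F03", "structured"),
            ("P1", D(2018, 1, 15), "F00-F03", "text"),
        ])
        assert dementia_index(stream, "P1", CENSUS) == D(2018, 1, 15)

    def test_event_after_census_absent(self):
        stream = make_stream(dxs=[("P1", D(2018, 7, 1), "F00-F03", "structured")])
        assert dementia_index(stream, "P1", CENSUS) is None

    def test_non_dementia_blocks_ignored(self):
        stream = make_stream(dxs=[("P1", D(2018, 1, 1), "F20-F29", "structured")])
        assert dementia_index(stream, "P1", CENSUS) is None

    def test_matches_oracle_on_fixture(self, fixture_stream, fixture_bundle):
        for pid in fixture_bundle.patients["patient_id"]:
            assert dementia_index(fixture_stream, pid, CENSUS) == \
                oracle_dementia_index(fixture_stream, pid, CENSUS)


class TestRecentUseV1:
    def test_single_mention_inside_window(self):
        stream = make_stream(meds=[("P1", CENSUS - dt.timedelta(days=30),
                                    "risperidone", "mention")])
        flag, evidence = recent_use_v1(stream, "P1", spec(algorithm_version="v1"))
        assert flag and len(evidence) == 1

    def test_boundary_date_included(self):
        stream = make_stream(meds=[("P1", CENSUS - dt.timedelta(days=183),
                                    "risperidone", "mention")])
        flag, _ = recent_use_v1(stream, "P1", spec(algorithm_version="v1"))
        assert flag

    def test_one_day_past_boundary_excluded(self):
        stream = make_stream(meds=[("P1", CENSUS - dt.timedelta(days=184),
                                    "risperidone", "mention")])
        flag, evidence = recent_use_v1(stream, "P1", spec(algorithm_version="v1"))
        assert not flag and evidence == []

    def test_stop_reference_still_counts(self):
        stream = make_stream(meds=[("P1", CENSUS - dt.timedelta(days=5),
                                    "quetiapine", "stop")])
        flag, _ = recent_use_v1(stream, "P1", spec(algorithm_version="v1"))
        assert flag


class TestRecentUseV2:
    def test_single_reference_excluded(self):
        stream = make_stream(meds=[("P1", CENSUS - dt.timedelta(days=30),
                                    "risperidone", "mention")])
        flag, _, reason = recent_use_v2(stream, "P1", spec())
        assert not flag and reason == "single_reference"

    def test_no_references_reason(self):
        stream = make_stream()
        flag, _, reason = recent_use_v2(stream, "P1", spec())
        assert not flag and reason == "no_recent_use"

    def test_stopped_drug_excluded(self):
        stream = make_stream(meds=[
            ("P1", CENSUS - dt.timedelta(days=60), "risperidone", "mention"),
            ("P1", CENSUS - dt.timedelta(days=40), "risperidone", "mention"),
            ("P1", CENSUS - dt.timedelta(days=10), "risperidone", "stop"),
        ])
        flag, evidence, reason = recent_use_v2(stream, "P1", spec())
        assert not flag and reason == "stopped"
        assert len(evidence) == 3  # stop references still count as references

    def test_second_clean_drug_rescues(self):
        stream = make_stream(meds=[
            ("P1", CENSUS - dt.timedelta(days=60), "drugA", "mention"),
            ("P1", CENSUS - dt.timedelta(days=10), "drugA", "stop"),
            ("P1", CENSUS - dt.timedelta(days=50), "drugB", "mention"),
            ("P1", CENSUS - dt.timedelta(days=20), "drugB", "mention"),
        ])
        flag, evidence, reason = recent_use_v2(stream, "P1", spec())
        assert flag and reason == "none" and len(evidence) == 4

    def test_rescue_matches_subset_enumeration(self):
        """Brute-force over every drug's reference subset: a drug survives
        iff none of its in-window references is a stop."""
        refs = [
            ("drugA", "mention"), ("drugA", "stop"),
            ("drugB", "mention"), ("drugB", "mention"),
        ]
        stream = make_stream(meds=[
            ("P1", CENSUS - dt.timedelta(days=30 + i), drug, kind)
            for i, (drug, kind) in enumerate(refs)])
        flag, _, _ = recent_use_v2(stream, "P1", spec())
        surviving = []
        for drug in {d for d, _ in refs}:
            subset = [k for d, k in refs if d == drug]
            if "stop" not in subset and len(subset) >= 1:
                surviving.append(drug)
        assert flag == (len(refs) >= 2 and bool(surviving))

    def test_two_sparse_drugs_pool_to_pass_rule1(self):
        stream = make_stream(meds=[
            ("P1", CENSUS - dt.timedelta(days=30), "drugA", "mention"),
            ("P1", CENSUS - dt.timedelta(days=20), "drugB", "mention"),
        ])
        flag, _, _ = recent_use_v2(stream, "P1", spec())
        assert flag  # pooled counting (the default reading)
        flag_pd, _, reason = recent_use_v2(stream, "P1", spec(rule1_per_drug=True))
        assert not flag_pd and reason == "single_reference"


class TestSensitivityExclusions:
    def base_member(self):
        stream = make_stream(
            meds=[("P1", CENSUS - dt.timedelta(days=30), "risperidone", "mention"),
                  ("P1", CENSUS - dt.timedelta(days=10), "risperidone", "mention")],
            dxs=[("P1", D(2018, 1, 1), "F00-F03", "structured")])
        eps = make_episodes([("P1", "CMHT-1", "community", D(2017, 1, 1), None)])
        return stream, eps

    def _with_extra_dx(self, extra):
        stream, eps = self.base_member()
        meds = [(m.patient_id, m.date, m.drug_name, m.kind)
                for m in stream.medications_for("P1")]
        dxs = [(e.patient_id, e.date, e.icd10_category, e.source)
               for e in stream.diagnoses_for("P1")]
        return make_stream(meds=meds, dxs=dxs + list(extra)), eps

    def test_psychosis_years_before_index(self):
        stream, eps = self._with_extra_dx([("P1", D(2017, 2, 1), "F20-F29", "structured")])
        members = build_cohort(stream, eps, spec(sensitivity_mode=True))
        assert members[0].exclusion_reason == "psychosis_ever"

    def test_other_dx_after_index(self):
        stream, eps = self._with_extra_dx([("P1", D(2018, 3, 1), "other-F", "structured")])
        members = build_cohort(stream, eps, spec(sensitivity_mode=True))
        assert members[0].exclusion_reason == "other_dx_after_index"

    def test_other_dx_before_index_retained(self):
        stream, eps = self._with_extra_dx([("P1", D(2017, 6, 1), "other-F", "structured")])
        members = build_cohort(stream, eps, spec(sensitivity_mode=True))
        assert members[0].included

    def test_other_dx_same_day_as_index_retained(self):
        # "after" is strict: a same-day other-F event does not exclude
        stream, eps = self._with_extra_dx([("P1", D(2018, 1, 1), "other-F", "structured")])
        members = build_cohort(stream, eps, spec(sensitivity_mode=True))
        assert members[0].included

    def test_psychosis_rule_applied_first(self):
        stream, eps = self._with_extra_dx([
            ("P1", D(2017, 2, 1), "F20-F29", "structured"),
            ("P1", D(2018, 3, 1), "other-F", "structured")])
        members = build_cohort(stream, eps, spec(sensitivity_mode=True))
        assert members[0].exclusion_reason == "psychosis_ever"

    def test_only_applies_to_included(self):
        stream, eps = self._with_extra_dx([("P1", D(2017, 2, 1), "F20-F29", "structured")])
        members = build_cohort(stream, eps, spec(algorithm_version="v1"))
        out = apply_sensitivity_exclusions(members, stream, spec())
        assert out[0].exclusion_reason == "psychosis_ever"
        not_active = build_cohort(stream, eps, spec(census_date=D(2016, 6, 28)))
        kept = apply_sensitivity_exclusions(not_active, stream,
                                            spec(census_date=D(2016, 6, 28)))
        assert kept[0].exclusion_reason == "not_active"


class TestBuildCohort:
    def test_not_active_reason(self):
        stream = make_stream(dxs=[("P1", D(2018, 1, 1), "F00-F03", "structured")])
        eps = make_episodes([("P1", "CMHT-1", "community", D(2017, 1, 1),
                              D(2018, 1, 1))])
        members = build_cohort(stream, eps, spec())
        assert len(members) == 1
        assert members[0].exclusion_reason == "not_active"
        assert not members[0].included

    def test_v2_subset_of_v1_every_census(self, fixture_stream, fixture_bundle,
                                          fixture_config):
        for census in fixture_config.census_dates():
            v1 = {m.patient_id for m in included_members(build_cohort(
                fixture_stream, fixture_bundle.episodes,
                spec(census_date=census, algorithm_version="v1")))}
            v2 = {m.patient_id for m in included_members(build_cohort(
                fixture_stream, fixture_bundle.episodes,
                spec(census_date=census, algorithm_version="v2")))}
            assert v2 <= v1

    def test_sensitivity_subset_of_main(self, fixture_stream, fixture_bundle,
                                        fixture_config):
        for census in fixture_config.census_dates()[::4]:
            main = {m.patient_id for m in included_members(build_cohort(
                fixture_stream, fixture_bundle.episodes, spec(census_date=census)))}
            sens = {m.patient_id for m in included_members(build_cohort(
                fixture_stream, fixture_bundle.episodes,
                spec(census_date=census, sensitivity_mode=True)))}
            assert sens <= main

    @pytest.mark.parametrize("version,sensitivity", [
        ("v1", False), ("v2", False), ("v2", True)])
    def test_matches_full_oracle(self, fixture_stream, fixture_bundle,
                                 fixture_config, version, sensitivity):
        for census in fixture_config.census_dates()[::3]:
            got = {m.patient_id for m in included_members(build_cohort(
                fixture_stream, fixture_bundle.episodes,
                spec(census_date=census, algorithm_version=version,
                     sensitivity_mode=sensitivity)))}
            want = oracle_cohort_included(
                fixture_stream, fixture_bundle.episodes, census,
                version=version, sensitivity=sensitivity)
            assert got == want

    def test_every_patient_appears_once(self, fixture_stream, fixture_bundle):
        members = build_cohort(fixture_stream, fixture_bundle.episodes, spec())
        pids = [m.patient_id for m in members]
        assert pids == sorted(set(fixture_bundle.episodes["patient_id"]))
        for m in members:
            assert m.included == (m.exclusion_reason == "none")

    def test_window_shift_invariance(self):
        offset = dt.timedelta(days=37)
        meds = [("P1", CENSUS - dt.timedelta(days=k), "risperidone", "mention")
                for k in (5, 40, 170)]
        dxs = [("P1", D(2018, 1, 3), "F00-F03", "structured"),
               ("P1", D(2018, 2, 1), "other-F", "structured")]
        eps = [("P1", "CMHT-1", "community", D(2017, 1, 1), None)]
        for sens in (False, True):
            base = build_cohort(make_stream(meds=meds, dxs=dxs),
                                make_episodes(eps),
                                spec(sensitivity_mode=sens))
            shifted = build_cohort(
                make_stream(meds=[(p, d + offset, dr, k) for p, d, dr, k in meds],
                            dxs=[(p, d + offset, b, s) for p, d, b, s in dxs]),
                make_episodes([(p, t, s, sd + offset, None) for p, t, s, sd, _ in eps]),
                spec(census_date=CENSUS + offset, sensitivity_mode=sens))
            assert [(m.included, m.exclusion_reason) for m in base] == \
                [(m.included, m.exclusion_reason) for m in shifted]
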