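"""Monitoring-form linkage: completion percentages and the reverse check.

Counting rule: a patient counts as completed at a census when at least one
form of either type is dated inside the closed validity window
``[census - form_validity_days, census]`` (default: the exposure window).
Percentages are rounded half-away-from-zero to one decimal place, matching
the reported style (44.9, 48.5, 60.2, 3.9).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import pandas as pd

from .cohort import CohortMember, active_caseload, active_settings, active_teams, dementia_index
from .config import CensusSpec
from .events import EventStream


def round_pct(numerator: int, denominator: int) -> Optional[float]:
    """100*n/d rounded half-away-from-zero to 1 dp; None when d == 0."""
    if denominator == 0:
        return None
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompletionResult:
    census_date: dt.date
    team_id: str  # "ALL" for the pooled figure
    n_eligible: int
    n_with_form: int
    pct_complete: Optional[float]  # None (absent) when n_eligible == 0


@dataclass(frozen=True)
class ReverseCheckResult:
    census_date: dt.date
    n_dementia_without_algorithm_use: int
    n_with_form: int
    pct: Optional[float]


def _validity_days(spec: CensusSpec, settings: Optional[set[str]]) -> int:
    if spec.setting_specific_validity and settings and "inpatient" in settings:
        return spec.inpatient_validity_days
    return spec.effective_form_validity_days


def form_completed(forms: pd.DataFrame, patient_id: str, spec: CensusSpec,
                   setting: Optional[set[str] | str] = None) -> bool:
    """True iff the patient has any form inside the validity window."""
    if isinstance(setting, str):
        setting = {setting}
    validity = _validity_days(spec, setting)
    lo = spec.census_date - dt.timedelta(days=validity)
    if not len(forms):
        return False
    for rec in forms.itertuples(index=False):
        if rec.patient_id == patient_id and lo <= rec.date <= spec.census_date:
            return True
    return False


def _completed_set(forms: pd.DataFrame, patient_ids: set[str], spec: CensusSpec,
                   settings_by_patient: Optional[dict[str, set[str]]] = None) -> set[str]:
    done = set()
    if not len(forms):
        return done
    for rec in forms.itertuples(index=False):
        if rec.patient_id not in patient_ids or rec.patient_id in done:
            continue
        settings = (settings_by_patient or {}).get(rec.patient_id)
        validity = _validity_days(spec, settings)
        lo = spec.census_date - dt.timedelta(days=validity)
        if lo <= rec.date <= spec.census_date:
            done.add(rec.patient_id)
    return done


def completion_rate(
    members: Iterable[CohortMember],
    forms: pd.DataFrame,
    spec: CensusSpec,
    group_by_team: bool = False,
    episodes: Optional[pd.DataFrame] = None,
) -> list[CompletionResult]:
    """Form-completion percentage, pooled or per team.

    In team mode a patient counts once in every team holding an active
    episode at the census (``episodes`` required); pooled mode counts each
    patient once under team_id "ALL".
    """
    eligible = sorted({m.patient_id for m in members if m.included})
    settings_by_patient = None
    if episodes is not None and spec.setting_specific_validity:
        settings_by_patient = active_settings(episodes, spec.census_date)
    done = _completed_set(forms, set(eligible), spec, settings_by_patient)

    if not group_by_team:
        n = len(eligible)
        k = len(done & set(eligible))
        return [CompletionResult(spec.census_date, "ALL", n, k, round_pct(k, n))]

    if episodes is None:
        raise ValueError("group_by_team=True requires the episodes table")
    teams = active_teams(episodes, spec.census_date)
    by_team: dict[str, list[str]] = {}
    for pid in eligible:
        for team in teams.get(pid, []):
            by_team.setdefault(team, []).append(pid)
    results = []
    for team in sorted(by_team):
        pids = by_team[team]
        k = sum(1 for pid in pids if pid in done)
        results.append(CompletionResult(spec.census_date, team, len(pids), k,
                                        round_pct(k, len(pids))))
    return results


def reverse_check(stream: EventStream, episodes: pd.DataFrame,
                  forms: pd.DataFrame, spec: CensusSpec) -> ReverseCheckResult:
    """Forms completed for dementia patients the algorithm did NOT flag.

    Denominator: active-care patients with a dementia index on or before the
    census whose recent-use rule (same algorithm version as ``spec``) is
    false.  Numerator: those with a completed form in the validity window.
    """
    from .cohort import recent_use_v1, recent_use_v2

    active = active_caseload(episodes, spec.census_date)
    unflagged = set()
    for pid in sorted(active):
        if dementia_index(stream, pid, spec.census_date) is None:
            continue
        if spec.algorithm_version == "v1":
            flag, _ = recent_use_v1(stream, pid, spec)
        else:
            flag, _, _ = recent_use_v2(stream, pid, spec)
        if not flag:
            unflagged.add(pid)
    settings_by_patient = None
    if spec.setting_specific_validity:
        settings_by_patient = active_settings(episodes, spec.census_date)
    done = _completed_set(forms, unflagged, spec, settings_by_patient)
    n, k = len(unflagged), len(done)
    return ReverseCheckResult(spec.census_date, n, k, round_pct(k, n))


def completion_frame(results: Iterable[CompletionResult],
                     spec: CensusSpec) -> pd.DataFrame:
    rows = [(r.census_date.isoformat(), r.team_id, r.n_eligible, r.n_with_form,
             "" if r.pct_complete is None else r.pct_complete,
             spec.algorithm_version, spec.sensitivity_mode) for r in results]
    return pd.DataFrame(rows, columns=[
        "census_date", "team_id", "n_eligible", "n_with_form", "pct_complete",
        "algorithm_version", "sensitivity_mode"])


def reverse_check_frame(results: Iterable[ReverseCheckResult]) -> pd.DataFrame:
    rows = [(r.census_date.isoformat(), r.n_dementia_without_algorithm_use,
             r.n_with_form, "" if r.pct is None else r.pct) for r in results]
    return pd.DataFrame(rows, columns=[
        "census_date", "n_dementia_without_use", "n_with_form", "pct"])
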