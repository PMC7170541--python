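"""Census-date cohort ascertainment.

At each census (the 28th of a month by default) a patient is ascertained
when they (1) hold an active care episode containing the census date,
(2) have a dementia-block diagnosis — structured or text-derived — on or
before the census, and (3) show evidence of recent antipsychotic use inside
the closed lookback window ``[census - window_days, census]``.

Two versions of the recency rule are implemented:

* ``v1`` — any medication reference (of any kind, including stop) inside
  the window qualifies.
* ``v2`` — the refined rule: the pooled in-window reference count must
  reach ``min_references_v2`` (default 2), and any drug carrying an
  in-window stop reference is disqualified; at least one surviving drug
  must retain an in-window reference.

A sensitivity mode additionally removes patients with any psychosis-block
(F20–F29) event up to the census, or any non-dementia F-chapter event
strictly after the index dementia date (psychosis rule applied first).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .config import CensusSpec, ExclusionReason
from .events import EventStream, MedicationReference, events_in_window
from .lexicons import DEMENTIA_BLOCK, PSYCHOSIS_BLOCK


@dataclass
class CohortMember:
    """One patient's ascertainment outcome at one census."""

    patient_id: str
    census_date: dt.date
    dementia_index_date: Optional[dt.date] = None
    antipsychotic_evidence: list[MedicationReference] = field(default_factory=list)
    included: bool = False
    exclusion_reason: ExclusionReason = "none"

    @property
    def n_references_in_window(self) -> int:
        return len(self.antipsychotic_evidence)


def episode_contains(start: dt.date, end: Optional[dt.date], day: dt.date) -> bool:
    """Closed-interval containment; an open end means the episode is ongoing."""
    return start <= day and (end is None or day <= end)


def active_caseload(episodes: pd.DataFrame, census_date: dt.date) -> set[str]:
    """Patients with at least one episode containing the census date."""
    active = set()
    for rec in episodes.itertuples(index=False):
        if episode_contains(rec.start_date, rec.end_date, census_date):
            active.add(rec.patient_id)
    return active


def active_teams(episodes: pd.DataFrame, census_date: dt.date) -> dict[str, list[str]]:
    """patient_id -> sorted team ids holding an active episode at the census."""
    teams: dict[str, set[str]] = {}
    for rec in episodes.itertuples(index=False):
        if episode_contains(rec.start_date, rec.end_date, census_date):
            teams.setdefault(rec.patient_id, set()).add(rec.team_id)
    return {pid: sorted(ts) for pid, ts in teams.items()}


def active_settings(episodes: pd.DataFrame, census_date: dt.date) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for rec in episodes.itertuples(index=False):
        if episode_contains(rec.start_date, rec.end_date, census_date):
            out.setdefault(rec.patient_id, set()).add(rec.setting)
    return out


def dementia_index(stream: EventStream, patient_id: str,
                   census_date: dt.date) -> Optional[dt.date]:
    """Earliest dementia-block event on or before the census, either source."""
    dates = [ev.date for ev in stream.diagnoses_for(patient_id)
             if ev.icd10_category == DEMENTIA_BLOCK and ev.date <= census_date]
    return min(dates) if dates else None


def references_in_window(stream: EventStream, patient_id: str,
                         spec: CensusSpec) -> list[MedicationReference]:
    return events_in_window(stream.medications_for(patient_id),
                            spec.window_start, spec.census_date)


def recent_use_v1(stream: EventStream, patient_id: str,
                  spec: CensusSpec) -> tuple[bool, list[MedicationReference]]:
    """Any in-window reference (stop references included) counts as evidence."""
    evidence = references_in_window(stream, patient_id, spec)
    return bool(evidence), evidence


def recent_use_v2(
    stream: EventStream, patient_id: str, spec: CensusSpec
) -> tuple[bool, list[MedicationReference], ExclusionReason]:
    """Refined rule: minimum reference count, then per-drug stop filter.

    Stop references count toward the reference total before their drug is
    disqualified.  Returns (flag, all in-window references, reason) where
    reason is "none" when the flag is true.
    """
    evidence = references_in_window(stream, patient_id, spec)
    if not evidence:
        return False, evidence, "no_recent_use"
    if spec.rule1_per_drug:
        counts: dict[str, int] = {}
        for ref in evidence:
            counts[ref.drug_name] = counts.get(ref.drug_name, 0) + 1
        enough = max(counts.values()) >= spec.min_references_v2
    else:
        enough = len(evidence) >= spec.min_references_v2
    if not enough:
        return False, evidence, "single_reference"
    stopped_drugs = {ref.drug_name for ref in evidence if ref.kind == "stop"}
    surviving = [ref for ref in evidence if ref.drug_name not in stopped_drugs]
    if not surviving:
        return False, evidence, "stopped"
    return True, evidence, "none"


def apply_sensitivity_exclusions(
    members: Iterable[CohortMember], stream: EventStream, spec: CensusSpec
) -> list[CohortMember]:
    """Secondary-output exclusions applied to included members.

    Psychosis rule first: any F20–F29 event dated on or before the census.
    Then: any non-dementia F-chapter event strictly after the index dementia
    date and on or before the census.
    """
    out = []
    for member in members:
        member = _copy_member(member)
        if member.included:
            events = [ev for ev in stream.diagnoses_for(member.patient_id)
                      if ev.date <= spec.census_date]
            if any(ev.icd10_category == PSYCHOSIS_BLOCK for ev in events):
                member.included = False
                member.exclusion_reason = "psychosis_ever"
            elif member.dementia_index_date is not None and any(
                ev.icd10_category != DEMENTIA_BLOCK
                and ev.date > member.dementia_index_date
                for ev in events
            ):
                member.included = False
                member.exclusion_reason = "other_dx_after_index"
        out.append(member)
    return out


def _copy_member(m: CohortMember) -> CohortMember:
    return CohortMember(
        patient_id=m.patient_id, census_date=m.census_date,
        dementia_index_date=m.dementia_index_date,
        antipsychotic_evidence=list(m.antipsychotic_evidence),
        included=m.included, exclusion_reason=m.exclusion_reason)


def build_cohort(stream: EventStream, episodes: pd.DataFrame,
                 spec: CensusSpec) -> list[CohortMember]:
    """Evaluate every patient in the episode register at one census.

    Rule composition: active care -> dementia prior to census -> recent use
    (v1 or v2) -> optional sensitivity exclusions.  Every evaluated patient
    appears exactly once, sorted by patient_id.
    """
    universe = sorted(set(episodes["patient_id"])) if len(episodes) else []
    active = active_caseload(episodes, spec.census_date)
    members = []
    for pid in universe:
        member = CohortMember(patient_id=pid, census_date=spec.census_date)
        if pid not in active:
            member.exclusion_reason = "not_active"
            members.append(member)
            continue
        member.dementia_index_date = dementia_index(stream, pid, spec.census_date)
        if member.dementia_index_date is None:
            member.exclusion_reason = "no_dementia"
            members.append(member)
            continue
        if spec.algorithm_version == "v1":
            flag, evidence = recent_use_v1(stream, pid, spec)
            reason: ExclusionReason = "none" if flag else "no_recent_use"
        else:
            flag, evidence, reason = recent_use_v2(stream, pid, spec)
        member.antipsychotic_evidence = evidence
        member.included = flag
        member.exclusion_reason = reason
        members.append(member)
    if spec.sensitivity_mode:
        members = apply_sensitivity_exclusions(members, stream, spec)
    return members


def included_members(members: Iterable[CohortMember]) -> list[CohortMember]:
    return [m for m in members if m.included]


def cohort_frame(members: Iterable[CohortMember], spec: CensusSpec) -> pd.DataFrame:
    """The documented cohort.csv schema."""
    rows = [(
        m.census_date.isoformat(), m.patient_id, m.included, m.exclusion_reason,
        m.dementia_index_date.isoformat() if m.dementia_index_date else "",
        m.n_references_in_window, spec.algorithm_version,
        spec.sensitivity_mode, spec.window_days,
    ) for m in members]
    return pd.DataFrame(rows, columns=[
        "census_date", "patient_id", "included", "exclusion_reason",
        "dementia_index_date", "n_references_in_window", "algorithm_version",
        "sensitivity_mode", "window_days"])
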