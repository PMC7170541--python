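"""Unified clinical event stream: diagnosis and medication events from
structured fields and note text, plus forms and episodes passed through."""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import pandas as pd

from .lexicons import DEMENTIA_BLOCK, OTHER_F_BLOCK, PSYCHOSIS_BLOCK

Source = Literal["structured", "text"]
ReferenceKind = Literal["mention", "start", "stop"]

_F_CODE = re.compile(r"^F(\d{2})(\.\d+)?$", re.IGNORECASE)


def classify_icd10(code: str) -> Optional[str]:
    """Map an ICD-10 code to the pipeline's block labels.

    F00-F03 -> dementia block, F20-F29 -> psychosis block, any other
    F-chapter code -> other-F.  Non-F codes are inert (None).
    """
    m = _F_CODE.match(code.strip())
    if not m:
        return None
    n = int(m.group(1))
    if 0 <= n <= 3:
        return DEMENTIA_BLOCK
    if 20 <= n <= 29:
        return PSYCHOSIS_BLOCK
    return OTHER_F_BLOCK


@dataclass(frozen=True, order=True)
class DiagnosisEvent:
    patient_id: str
    date: dt.date
    icd10_category: str  # DEMENTIA_BLOCK | PSYCHOSIS_BLOCK | OTHER_F_BLOCK
    source: Source
    matched_term: str = ""  # surface string; empty for structured events
    provenance_id: str = ""  # note_id for text events, "" for structured

    def __post_init__(self):
        if self.source == "text" and not self.matched_term:
            raise ValueError("text-derived diagnosis requires matched_term")


@dataclass(frozen=True, order=True)
class MedicationReference:
    patient_id: str
    date: dt.date
    drug_name: str  # normalised generic
    kind: ReferenceKind
    note_id: str


def _sort_key(ev):
    source = getattr(ev, "source", "text")
    prov = getattr(ev, "provenance_id", None)
    if prov is None:
        prov = ev.note_id
    return (ev.date, 0 if source == "structured" else 1, prov)


@dataclass
class EventStream:
    """Per-patient, date-sorted event sequences.

    Within a day, structured events precede text events and ties break on
    provenance id, so the stream order is fully deterministic.
    """

    diagnoses: dict[str, list[DiagnosisEvent]] = field(default_factory=dict)
    medications: dict[str, list[MedicationReference]] = field(default_factory=dict)
    forms: pd.DataFrame = field(default_factory=pd.DataFrame)
    episodes: pd.DataFrame = field(default_factory=pd.DataFrame)
    patient_ids: set[str] = field(default_factory=set)

    def add_diagnosis(self, ev: DiagnosisEvent) -> None:
        self.diagnoses.setdefault(ev.patient_id, []).append(ev)
        self.patient_ids.add(ev.patient_id)

    def add_medication(self, ev: MedicationReference) -> None:
        self.medications.setdefault(ev.patient_id, []).append(ev)
        self.patient_ids.add(ev.patient_id)

    def sort(self) -> None:
        for seq in self.diagnoses.values():
            seq.sort(key=_sort_key)
        for seq in self.medications.values():
            seq.sort(key=_sort_key)

    def diagnoses_for(self, patient_id: str) -> list[DiagnosisEvent]:
        return self.diagnoses.get(patient_id, [])

    def medications_for(self, patient_id: str) -> list[MedicationReference]:
        return self.medications.get(patient_id, [])

    def to_events_frame(self) -> pd.DataFrame:
        """Flat export with the documented events.csv schema."""
        rows = []
        for pid in sorted(self.patient_ids):
            merged: list = list(self.diagnoses_for(pid)) + list(self.medications_for(pid))
            merged.sort(key=_sort_key)
            for ev in merged:
                if isinstance(ev, DiagnosisEvent):
                    rows.append((pid, ev.date.isoformat(), "diagnosis",
                                 ev.icd10_category, "", ev.source, ev.provenance_id))
                else:
                    rows.append((pid, ev.date.isoformat(), "medication",
                                 ev.drug_name, ev.kind, "text", ev.note_id))
        return pd.DataFrame(rows, columns=[
            "patient_id", "date", "event_class", "detail", "kind", "source",
            "provenance_id",
        ])


def events_in_window(events: Iterable, start: dt.date, end: dt.date) -> list:
    """Events with date in the closed interval [start, end]."""
    return [ev for ev in events if start <= ev.date <= end]
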