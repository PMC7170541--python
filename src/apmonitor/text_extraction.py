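"""Deterministic lexicon/pattern extraction from clinical note text.

This is an explicit, simpler stand-in for a production clinical NLP stack:
case-insensitive whole-word phrase matching with sentence-local cue
attribution, no parsing, no stemming, no spelling correction.

Attribution rule: a start/stop/negation cue applies to a drug or diagnosis
term in the same sentence within ``ATTRIBUTION_SPAN`` tokens (edge-to-edge
gap, adjacency = 1); the nearest cue wins; on a tie, stop outranks start
outranks plain mention (conservative for exposure).
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, ReferentialIntegrityError
from .events import (
    DiagnosisEvent,
    EventStream,
    MedicationReference,
    classify_icd10,
)
from .lexicons import Lexicons

ATTRIBUTION_SPAN = 5  # max token gap between a cue and its target

_SENTENCE_SPLIT = re.compile(r"[.;\n]")
_TOKEN = re.compile(r"[A-Za-z0-9']+")

# cue-kind precedence on distance ties (lower = stronger)
_PRECEDENCE = {"stop": 0, "start": 1, "negation": 0}


def tokenize(sentence: str) -> list[str]:
    return [t.lower() for t in _TOKEN.findall(sentence)]


def split_sentences(text: str) -> list[str]:
    return [s for s in _SENTENCE_SPLIT.split(text) if s.strip()]


@dataclass(frozen=True)
class _Match:
    start: int  # first token index
    end: int  # last token index (inclusive)
    payload: str  # category / generic / cue kind
    surface: str


def _phrase_index(phrases: Mapping[str, str]) -> dict[str, list[tuple[tuple[str, ...], str]]]:
    """first token -> [(phrase tokens, payload)], longest phrases first."""
    index: dict[str, list[tuple[tuple[str, ...], str]]] = {}
    for phrase, payload in phrases.items():
        toks = tuple(tokenize(phrase))
        if not toks:
            continue
        index.setdefault(toks[0], []).append((toks, payload))
    for cands in index.values():
        cands.sort(key=lambda c: -len(c[0]))
    return index


def _find_matches(tokens: Sequence[str],
                  index: Mapping[str, list[tuple[tuple[str, ...], str]]]) -> list[_Match]:
    out = []
    for i, tok in enumerate(tokens):
        for phrase, payload in index.get(tok, ()):
            j = i + len(phrase)
            if tuple(tokens[i:j]) == phrase:
                out.append(_Match(i, j - 1, payload, " ".join(phrase)))
                break  # longest match at this position wins
    return out


def _gap(a: _Match, b: _Match) -> int:
    """Edge-to-edge token distance; adjacent tokens have gap 1."""
    if a.end < b.start:
        return b.start - a.end
    if b.end < a.start:
        return a.start - b.end
    return 0


def _nearest_cue(target: _Match, cues: Iterable[_Match]) -> Optional[_Match]:
    best: Optional[tuple[int, int, _Match]] = None
    for cue in cues:
        d = _gap(target, cue)
        if d > ATTRIBUTION_SPAN:
            continue
        key = (d, _PRECEDENCE.get(cue.payload, 9))
        if best is None or key < best[:2]:
            best = (*key, cue)
    return best[2] if best else None


class Extractor:
    """Compiled lexicons plus the extraction rules."""

    def __init__(self, lexicons: Lexicons):
        if not lexicons.drug_synonyms or not lexicons.diagnosis_terms:
            raise ConfigurationError("extractor requires non-empty lexicons")
        self.lexicons = lexicons
        term_map = {
            term: block
            for block, terms in lexicons.diagnosis_terms.items()
            for term in terms
        }
        self._dx_index = _phrase_index(term_map)
        self._drug_index = _phrase_index(lexicons.drug_synonyms)
        cue_map: dict[str, str] = {}
        cue_map.update({p: "stop" for p in lexicons.stop_phrases})
        cue_map.update({p: "start" for p in lexicons.start_phrases})
        self._med_cue_index = _phrase_index(cue_map)
        self._neg_index = _phrase_index({p: "negation" for p in lexicons.negation_cues})

    # -- diagnoses ---------------------------------------------------------

    def extract_diagnoses(self, note: Mapping) -> list[DiagnosisEvent]:
        """One event per asserted ICD-10 block per note; negated term
        occurrences are dropped."""
        asserted: dict[str, str] = {}  # block -> first asserted surface term
        for sentence in split_sentences(note["text"]):
            tokens = tokenize(sentence)
            terms = _find_matches(tokens, self._dx_index)
            if not terms:
                continue
            negs = _find_matches(tokens, self._neg_index)
            for term in terms:
                if _nearest_cue(term, negs) is not None:
                    continue
                asserted.setdefault(term.payload, term.surface)
        date = _as_date(note["date"])
        return [
            DiagnosisEvent(
                patient_id=note["patient_id"],
                date=date,
                icd10_category=block,
                source="text",
                matched_term=surface,
                provenance_id=note["note_id"],
            )
            for block, surface in sorted(asserted.items())
        ]

    # -- medication references --------------------------------------------

    def extract_medication_references(self, note: Mapping) -> list[MedicationReference]:
        """One reference per (drug, note); stop outranks start outranks
        mention when a drug is hit more than once."""
        kinds: dict[str, str] = {}
        rank = {"stop": 0, "start": 1, "mention": 2}
        for sentence in split_sentences(note["text"]):
            tokens = tokenize(sentence)
            drugs = _find_matches(tokens, self._drug_index)
            if not drugs:
                continue
            cues = _find_matches(tokens, self._med_cue_index)
            for hit in drugs:
                cue = _nearest_cue(hit, cues)
                kind = cue.payload if cue is not None else "mention"
                prev = kinds.get(hit.payload)
                if prev is None or rank[kind] < rank[prev]:
                    kinds[hit.payload] = kind
        date = _as_date(note["date"])
        return [
            MedicationReference(
                patient_id=note["patient_id"],
                date=date,
                drug_name=drug,
                kind=kind,  # type: ignore[arg-type]
                note_id=note["note_id"],
            )
            for drug, kind in sorted(kinds.items())
        ]

    def extract_note(self, note: Mapping):
        return self.extract_diagnoses(note), self.extract_medication_references(note)


def _as_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def _check_ids(frame: pd.DataFrame, table: str, known: set[str]) -> None:
    for row, pid in enumerate(frame["patient_id"]):
        if pid not in known:
            raise ReferentialIntegrityError(table, row, pid)


def build_event_stream(
    structured_diagnoses: pd.DataFrame,
    notes: Iterable[Mapping],
    forms: pd.DataFrame,
    episodes: pd.DataFrame,
    lexicons: Lexicons,
    patient_ids: Optional[set[str]] = None,
) -> EventStream:
    """Merge structured diagnoses with text-derived events into one stream.

    Duplicate facts across sources are retained with distinct ``source``
    values.  When ``patient_ids`` is given, every table is checked against it
    and an unknown id raises :class:`ReferentialIntegrityError` naming the
    table and row.
    """
    notes = list(notes)
    if patient_ids is not None:
        _check_ids(structured_diagnoses, "diagnoses_structured", patient_ids)
        _check_ids(forms, "forms", patient_ids)
        _check_ids(episodes, "episodes", patient_ids)
        for row, note in enumerate(notes):
            if note["patient_id"] not in patient_ids:
                raise ReferentialIntegrityError("notes", row, note["patient_id"])

    stream = EventStream(forms=forms, episodes=episodes)
    if patient_ids is not None:
        stream.patient_ids |= patient_ids
    stream.patient_ids |= set(episodes.get("patient_id", ()))

    for rec in structured_diagnoses.itertuples(index=False):
        block = classify_icd10(str(rec.icd10_code))
        if block is None:
            continue  # inert code
        stream.add_diagnosis(DiagnosisEvent(
            patient_id=rec.patient_id,
            date=_as_date(rec.date),
            icd10_category=block,
            source="structured",
        ))

    extractor = Extractor(lexicons)
    for note in notes:
        dx_events, med_events = extractor.extract_note(note)
        for ev in dx_events:
            stream.add_diagnosis(ev)
        for ev in med_events:
            stream.add_medication(ev)

    stream.sort()
    return stream
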