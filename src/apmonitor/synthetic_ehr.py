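"""Seeded synthetic EHR bundles with known ground truth.

The generator emulates the monitored caseload: a dementia caseload of which
~32.1% receive antipsychotics, ~19% carry a comorbid psychosis diagnosis,
and a monitoring-form completion probability that ramps linearly across the
monthly censuses (0.22 -> 0.58 by default).

Notes are rendered from fixed sentence templates, not a language model, so
extraction behaviour is exactly analysable; every planted fact is recorded
alongside the note for round-trip scoring.  Ground truth is written to a
separate file that the pipeline proper never reads.

Form completion uses a persistent-adopter model: each patient draws a latent
threshold ``u`` once, and completes a form at every census whose ramp
probability exceeds ``u`` (while eligible).  Because the ramp is
non-decreasing, the fraction of eligible patients with a recent form at
census ``i`` equals the ramp probability at ``i`` exactly, in expectation.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .errors import BundleValidationError, ConfigurationError
from .lexicons import DEMENTIA_BLOCK, PSYCHOSIS_BLOCK, Lexicons, load_lexicons

TEAMS: tuple[tuple[str, str], ...] = (
    ("CMHT-1", "community"),
    ("CMHT-2", "community"),
    ("CMHT-3", "community"),
    ("CMHT-4", "community"),
    ("CHIT-1", "care_home"),
    ("CHIT-2", "care_home"),
    ("WARD-1", "inpatient"),
    ("WARD-2", "inpatient"),
)

DEMENTIA_CODES = ("F00", "F01", "F02", "F03")
PSYCHOSIS_CODES = ("F20", "F22", "F25")
OTHER_F_CODES = ("F31", "F32", "F41")

_DX_TEMPLATES = (
    "Diagnosis of {term} confirmed at memory clinic.",
    "Assessment findings consistent with {term}.",
    "{term} diagnosed following cognitive testing.",
)
_PSYCHOSIS_DX_TEMPLATES = (
    "Long-standing diagnosis of {term} documented.",
    "Past psychiatric history includes {term}.",
)
_MED_START_TEMPLATES = (
    "{phrase} {drug} 0.5mg at night for agitation.",
    "{phrase} {drug} after MDT discussion.",
)
_MED_MENTION_TEMPLATES = (
    "{drug} 0.5mg at night continues.",
    "Medication review: remains on {drug}.",
    "{drug} well tolerated at current dose.",
)
_MED_STOP_TEMPLATES = (
    "{drug} {phrase} due to sedation.",
    "{phrase} {drug} following review of risks.",
)
_NEG_SCREEN_TEMPLATES = (
    "No evidence of {term} on review.",
    "Denies {term} at present.",
)
_NEUTRAL_TEMPLATES = (
    "Seen at home today with carer present.",
    "Routine visit completed, bloods taken.",
    "Attended clinic, physical observations stable.",
    "Care plan discussed with family.",
    "Sleep improved and appetite good.",
)


@dataclass
class NoteState:
    """What a single note must assert; input to :func:`render_note`."""

    patient_id: str
    team_id: str
    note_id: str
    kind: str  # dx_dementia | dx_psychosis | med_start | med_mention | med_stop | neg_screen | neutral
    drug: Optional[str] = None


@dataclass
class Bundle:
    """An in-memory synthetic EHR bundle.

    ``ground_truth`` and ``plants`` are generator-side latent labels; the
    pipeline reads only the other members.
    """

    config: GeneratorConfig
    patients: pd.DataFrame
    episodes: pd.DataFrame
    diagnoses: pd.DataFrame
    notes: list[dict]
    forms: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)
    plants: list[dict] = field(default_factory=list)

    def to_serializable(self) -> dict:
        """Canonical plain-data view used for hashing and round-trips."""
        return {
            "patients": self.patients.astype(str).values.tolist(),
            "episodes": self.episodes.astype(str).values.tolist(),
            "diagnoses": self.diagnoses.astype(str).values.tolist(),
            "notes": self.notes,
            "forms": self.forms.astype(str).values.tolist(),
            "ground_truth": self.ground_truth,
            "plants": self.plants,
        }

    def content_hash(self) -> str:
        blob = json.dumps(self.to_serializable(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _choice(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


def render_note(state: NoteState, date: dt.date, lexicons: Lexicons,
                rng: np.random.Generator) -> tuple[dict, list[dict]]:
    """Render a note from templates and report the facts planted in it."""
    if not lexicons.diagnosis_terms or not lexicons.drug_synonyms:
        raise ConfigurationError("render_note requires non-empty lexicons")
    plants: list[dict] = []
    base = {"note_id": state.note_id, "patient_id": state.patient_id,
            "date": date.isoformat()}
    if state.kind == "dx_dementia":
        term = _choice(rng, lexicons.diagnosis_terms[DEMENTIA_BLOCK])
        text = _choice(rng, _DX_TEMPLATES).format(term=term)
        plants.append({**base, "fact": "diagnosis", "category": DEMENTIA_BLOCK,
                       "negated": False})
    elif state.kind == "dx_psychosis":
        term = _choice(rng, lexicons.diagnosis_terms[PSYCHOSIS_BLOCK])
        text = _choice(rng, _PSYCHOSIS_DX_TEMPLATES).format(term=term)
        plants.append({**base, "fact": "diagnosis", "category": PSYCHOSIS_BLOCK,
                       "negated": False})
    elif state.kind == "med_start":
        phrase = _choice(rng, ("Started", "Commenced", "Initiated"))
        text = _choice(rng, _MED_START_TEMPLATES).format(phrase=phrase, drug=state.drug)
        plants.append({**base, "fact": "medication", "drug": state.drug,
                       "ref_kind": "start"})
    elif state.kind == "med_mention":
        text = _choice(rng, _MED_MENTION_TEMPLATES).format(drug=state.drug)
        plants.append({**base, "fact": "medication", "drug": state.drug,
                       "ref_kind": "mention"})
    elif state.kind == "med_stop":
        tmpl = _choice(rng, _MED_STOP_TEMPLATES)
        phrase = _choice(rng, ("stopped", "discontinued", "ceased")) \
            if tmpl is _MED_STOP_TEMPLATES[0] else \
            _choice(rng, ("Stopped", "Discontinued", "Withdrawn"))
        text = tmpl.format(phrase=phrase, drug=state.drug)
        plants.append({**base, "fact": "medication", "drug": state.drug,
                       "ref_kind": "stop"})
    elif state.kind == "neg_screen":
        term = _choice(rng, lexicons.diagnosis_terms[PSYCHOSIS_BLOCK])
        text = _choice(rng, _NEG_SCREEN_TEMPLATES).format(term=term)
        plants.append({**base, "fact": "diagnosis", "category": PSYCHOSIS_BLOCK,
                       "negated": True})
    elif state.kind == "neutral":
        text = _choice(rng, _NEUTRAL_TEMPLATES)
    else:  # pragma: no cover - internal misuse
        raise ConfigurationError(f"unknown note kind {state.kind!r}")
    note = {"note_id": state.note_id, "patient_id": state.patient_id,
            "date": date.isoformat(), "team_id": state.team_id, "text": text}
    return note, plants


def _days(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Uniform integer in [lo, hi]; degenerate ranges collapse to lo."""
    if hi <= lo:
        return lo
    return lo + int(rng.integers(hi - lo + 1))


def generate_bundle(config: GeneratorConfig,
                    lexicons: Optional[Lexicons] = None) -> Bundle:
    """Generate a complete synthetic bundle; deterministic for a fixed seed."""
    lex = lexicons if lexicons is not None else load_lexicons()
    rng = np.random.default_rng(config.seed)
    start, end = config.start_date, config.end_date
    span = (end - start).days
    censuses = config.census_dates()
    first_census_off = (censuses[0] - start).days

    patients_rows, episode_rows, dx_rows = [], [], []
    notes: list[dict] = []
    plants: list[dict] = []
    ground_truth: dict[str, dict] = {}
    adopter_u: dict[str, float] = {}
    eligibility: dict[str, dict] = {}  # pid -> latent facts reused for forms

    note_counter = 0

    def new_note(pid: str, team: str, kind: str, date: dt.date, drug=None):
        nonlocal note_counter
        state = NoteState(patient_id=pid, team_id=team,
                          note_id=f"N{note_counter:06d}", kind=kind, drug=drug)
        note_counter += 1
        note, planted = render_note(state, date, lex, rng)
        notes.append(note)
        plants.extend(planted)

    for idx in range(config.n_patients):
        pid = f"P{idx:04d}"
        birth_year = 1925 + int(rng.integers(26))
        patients_rows.append((pid, birth_year))

        team, _setting = _choice(rng, TEAMS)
        ep_end: Optional[dt.date] = None
        if rng.random() < config.inactive_rate:
            ep_end = start + dt.timedelta(days=_days(rng, 60, span))
        episode_rows.append((pid, team, _setting, start, ep_end))
        if rng.random() < config.second_team_rate:
            other = _choice(rng, [t for t in TEAMS if t[0] != team])
            episode_rows.append((pid, other[0], other[1], start, None))

        has_dementia = rng.random() < config.dementia_prevalence
        onset: Optional[dt.date] = None
        has_psychosis = False
        post_index_other_dx = False
        exposure: list[tuple[str, dt.date, dt.date]] = []

        if has_dementia:
            onset = start + dt.timedelta(days=_days(rng, 0, max(first_census_off - 1, 0)))
            text_only = rng.random() < config.text_only_dx_fraction
            if text_only:
                new_note(pid, team, "dx_dementia", onset)
            else:
                dx_rows.append((pid, onset, _choice(rng, DEMENTIA_CODES)))
                if rng.random() < 0.4:  # cross-source duplicate
                    new_note(pid, team, "dx_dementia", onset)

            has_psychosis = rng.random() < config.psychosis_comorbidity
            if has_psychosis:
                psy_date = start + dt.timedelta(days=_days(rng, 0, max((onset - start).days - 1, 0)))
                if rng.random() < 0.7:
                    dx_rows.append((pid, psy_date, _choice(rng, PSYCHOSIS_CODES)))
                else:
                    new_note(pid, team, "dx_psychosis", psy_date)

            post_index_other_dx = rng.random() < config.other_dx_rate
            if post_index_other_dx:
                other_off = _days(rng, (onset - start).days + 1, span)
                dx_rows.append((pid, start + dt.timedelta(days=other_off),
                                _choice(rng, OTHER_F_CODES)))

            if rng.random() < config.antipsychotic_prevalence:
                drug = _choice(rng, lex.generics)
                exp_start = onset + dt.timedelta(
                    days=_days(rng, 0, max((end - onset).days - 30, 0)))
                stopped = rng.random() < config.stop_rate
                if stopped:
                    exp_end = exp_start + dt.timedelta(
                        days=_days(rng, 14, (end - exp_start).days))
                else:
                    exp_end = end
                exposure.append((drug, exp_start, exp_end))
                sparse = rng.random() < config.mention_noise
                new_note(pid, team, "med_start", exp_start, drug=drug)
                if not sparse:
                    # same-day anchor keeps >=2 references in any window
                    # overlapping the interval, then ~monthly mentions
                    new_note(pid, team, "med_mention", exp_start, drug=drug)
                    d = exp_start
                    while True:
                        d = d + dt.timedelta(days=28 + _days(rng, 0, 5))
                        if d > exp_end:
                            break
                        new_note(pid, team, "med_mention", d, drug=drug)
                if stopped:
                    new_note(pid, team, "med_stop", exp_end, drug=drug)

        # distractor notes (neutral prose, occasional negated screens)
        n_distract = int(rng.poisson(config.note_rate * span / 30.44))
        for _ in range(n_distract):
            d = start + dt.timedelta(days=_days(rng, 0, span))
            kind = "neg_screen" if rng.random() < config.negation_rate else "neutral"
            new_note(pid, team, kind, d)

        adopter_u[pid] = float(rng.random())
        eligibility[pid] = {
            "team": team, "episode_end": ep_end, "onset": onset,
            "exposure": exposure, "has_dementia": has_dementia,
        }
        ground_truth[pid] = {
            "has_dementia": has_dementia,
            "dementia_onset": onset.isoformat() if onset else None,
            "exposure_intervals": [
                (drug, s.isoformat(), e.isoformat()) for drug, s, e in exposure
            ],
            "has_psychosis": has_psychosis,
            "post_index_other_dx": post_index_other_dx,
        }

    # monitoring forms: persistent adopters complete at every census while
    # ground-truth eligible (dementia + exposure overlapping the window +
    # active episode)
    form_rows = []
    form_counter = 0
    window = dt.timedelta(days=config.exposure_window_days)
    first_form: set[str] = set()
    for ci, census in enumerate(censuses):
        p_complete = config.completion_probability(ci)
        for idx in range(config.n_patients):
            pid = f"P{idx:04d}"
            lat = eligibility[pid]
            if not lat["has_dementia"] or lat["onset"] is None or lat["onset"] > census:
                continue
            if lat["episode_end"] is not None and lat["episode_end"] < census:
                continue
            if not any(s <= census and e >= census - window
                       for _, s, e in lat["exposure"]):
                continue
            if adopter_u[pid] >= p_complete:
                continue
            form_date = census - dt.timedelta(days=_days(rng, 0, 20))
            form_type = "initiation" if pid not in first_form else "review"
            first_form.add(pid)
            form_rows.append((f"F{form_counter:05d}", pid, form_date,
                              form_type, lat["team"]))
            form_counter += 1

    notes.sort(key=lambda n: (n["patient_id"], n["date"], n["note_id"]))
    patients = pd.DataFrame(patients_rows, columns=["patient_id", "birth_year"])
    episodes = pd.DataFrame(episode_rows, columns=[
        "patient_id", "team_id", "setting", "start_date", "end_date"])
    diagnoses = pd.DataFrame(sorted(dx_rows), columns=["patient_id", "date", "icd10_code"])
    forms = pd.DataFrame(form_rows, columns=[
        "form_id", "patient_id", "date", "form_type", "team_id"])
    return Bundle(config=config, patients=patients, episodes=episodes,
                  diagnoses=diagnoses, notes=notes, forms=forms,
                  ground_truth=ground_truth, plants=plants)


# -- serialization ----------------------------------------------------------

_CSV_KW = dict(index=False, lineterminator="\n")


def _iso(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    if isinstance(value, (dt.date, dt.datetime)):
        return value.isoformat()[:10]
    return str(value)


def validate_bundle(bundle: Bundle) -> None:
    """Raise :class:`BundleValidationError` if any date leaves config bounds."""
    lo, hi = bundle.config.start_date, bundle.config.end_date

    def check(date, where):
        if isinstance(date, str):
            date = dt.date.fromisoformat(date)
        if not lo <= date <= hi:
            raise BundleValidationError(
                f"date {date.isoformat()} in {where} outside "
                f"[{lo.isoformat()}, {hi.isoformat()}]")

    for frame, name in ((bundle.diagnoses, "diagnoses_structured"),
                        (bundle.forms, "forms")):
        for d in frame.get("date", ()):
            check(d, name)
    for note in bundle.notes:
        check(note["date"], "notes")
    for rec in bundle.episodes.itertuples(index=False):
        check(rec.start_date, "episodes")
        if rec.end_date is not None and _iso(rec.end_date):
            check(rec.end_date, "episodes")
    ids = list(bundle.patients["patient_id"]) if len(bundle.patients) else []
    if len(set(ids)) != len(ids):
        raise BundleValidationError("duplicate patient_id in patients table")


def write_bundle(bundle: Bundle, output_dir: str | Path) -> list[Path]:
    """Write the documented file set; validates the bundle first."""
    validate_bundle(bundle)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def frame_with_iso_dates(frame: pd.DataFrame, cols) -> pd.DataFrame:
        frame = frame.copy()
        for col in cols:
            if col in frame:
                frame[col] = [_iso(v) for v in frame[col]]
        return frame

    tables = {
        "patients.csv": bundle.patients,
        "episodes.csv": frame_with_iso_dates(bundle.episodes, ["start_date", "end_date"]),
        "diagnoses_structured.csv": frame_with_iso_dates(bundle.diagnoses, ["date"]),
        "forms.csv": frame_with_iso_dates(bundle.forms, ["date"]),
    }
    for name, frame in tables.items():
        path = out / name
        frame.to_csv(path, **_CSV_KW)
        written.append(path)

    notes_path = out / "notes.jsonl"
    with open(notes_path, "w") as fh:
        for note in bundle.notes:
            fh.write(json.dumps(note, sort_keys=True) + "\n")
    written.append(notes_path)

    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(
        {"patients": bundle.ground_truth, "planted_facts": bundle.plants},
        sort_keys=True, indent=1))
    written.append(truth_path)

    cfg_path = out / "config.yaml"
    cfg = bundle.config.model_dump(mode="json")
    import yaml
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    written.append(cfg_path)
    return written


_SCHEMAS = {
    "patients.csv": ["patient_id", "birth_year"],
    "episodes.csv": ["patient_id", "team_id", "setting", "start_date", "end_date"],
    "diagnoses_structured.csv": ["patient_id", "date", "icd10_code"],
    "forms.csv": ["form_id", "patient_id", "date", "form_type", "team_id"],
}


def read_bundle(bundle_dir: str | Path,
                include_ground_truth: bool = False) -> Bundle:
    """Re-read a written bundle.  The pipeline proper must leave
    ``include_ground_truth`` off; truth is test-only."""
    from .config import load_generator_config
    from .errors import MissingInputError, SchemaError

    src = Path(bundle_dir)
    frames = {}
    for name, cols in _SCHEMAS.items():
        path = src / name
        if not path.exists():
            raise MissingInputError(f"missing bundle file: {path}")
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        if list(frame.columns) != cols:
            raise SchemaError(
                f"{name}: expected columns {cols}, found {list(frame.columns)}")
        frames[name] = frame

    def parse_date(s: str):
        try:
            return dt.date.fromisoformat(s)
        except ValueError as exc:
            raise SchemaError(f"unparseable date {s!r}") from exc

    patients = frames["patients.csv"]
    patients["birth_year"] = patients["birth_year"].astype(int)
    episodes = frames["episodes.csv"]
    episodes["start_date"] = episodes["start_date"].map(parse_date)
    episodes["end_date"] = episodes["end_date"].map(
        lambda s: parse_date(s) if s else None)
    diagnoses = frames["diagnoses_structured.csv"]
    if len(diagnoses):
        diagnoses["date"] = diagnoses["date"].map(parse_date)
    forms = frames["forms.csv"]
    if len(forms):
        forms["date"] = forms["date"].map(parse_date)

    notes_path = src / "notes.jsonl"
    if not notes_path.exists():
        raise MissingInputError(f"missing bundle file: {notes_path}")
    notes = [json.loads(line) for line in notes_path.read_text().splitlines() if line]

    config = load_generator_config(src / "config.yaml")
    ground_truth, plants = {}, []
    if include_ground_truth:
        raw = json.loads((src / "ground_truth.json").read_text())
        ground_truth, plants = raw["patients"], raw["planted_facts"]
    return Bundle(config=config, patients=patients, episodes=episodes,
                  diagnoses=diagnoses, notes=notes, forms=forms,
                  ground_truth=ground_truth, plants=plants)
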