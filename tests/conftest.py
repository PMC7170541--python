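import datetime as dt

import pandas as pd
import pytest

from apmonitor import (
    DiagnosisEvent,
    EventStream,
    GeneratorConfig,
    MedicationReference,
    generate_bundle,
    load_lexicons,
)
from apmonitor.reporting import stream_from_bundle

EPISODE_COLS = ["patient_id", "team_id", "setting", "start_date", "end_date"]
FORM_COLS = ["form_id", "patient_id", "date", "form_type", "team_id"]


def D(y, m, d):
    return dt.date(y, m, d)


def make_episodes(rows):
    """rows: (patient_id, team_id, setting, start_date, end_date|None)"""
    return pd.DataFrame(rows, columns=EPISODE_COLS)


def make_forms(rows):
    """rows: (patient_id, date) or full 5-tuples"""
    full = []
    for i, row in enumerate(rows):
        if len(row) == 2:
            full.append((f"F{i:04d}", row[0], row[1], "review", "CMHT-1"))
        else:
            full.append(row)
    return pd.DataFrame(full, columns=FORM_COLS)


def make_stream(meds=(), dxs=(), episodes=None, forms=None):
    """meds: (pid, date, drug, kind); dxs: (pid, date, block, source)."""
    stream = EventStream(
        forms=forms if forms is not None else make_forms([]),
        episodes=episodes if episodes is not None else make_episodes([]),
    )
    for i, (pid, date, drug, kind) in enumerate(meds):
        stream.add_medication(
            MedicationReference(pid, date, drug, kind, f"N{i:04d}"))
    for i, (pid, date, block, source) in enumerate(dxs):
        stream.add_diagnosis(DiagnosisEvent(
            pid, date, block, source,
            matched_term="term" if source == "text" else "",
            provenance_id=f"T{i:04d}" if source == "text" else ""))
    stream.sort()
    return stream


@pytest.fixture(scope="session")
def lex():
    return load_lexicons()


@pytest.fixture(scope="session")
def fixture_config():
    return GeneratorConfig(n_patients=50, seed=11)


@pytest.fixture(scope="session")
def fixture_bundle(fixture_config):
    return generate_bundle(fixture_config)


@pytest.fixture(scope="session")
def fixture_stream(fixture_bundle):
    return stream_from_bundle(fixture_bundle)


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free bundle: every planted fact is recoverable."""
    return generate_bundle(GeneratorConfig(
        n_patients=60, seed=5, mention_noise=0.0, stop_rate=0.0,
        negation_rate=0.0))


@pytest.fixture(scope="session")
def clean_stream(clean_bundle):
    return stream_from_bundle(clean_bundle)
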