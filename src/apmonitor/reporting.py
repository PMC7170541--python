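"""End-to-end orchestration: monthly reports, trend series, PDSA variant
comparison and human-readable team feedback."""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .cohort import build_cohort, cohort_frame, included_members
from .config import CensusSpec, census_range
from .forms import (
    CompletionResult,
    completion_frame,
    completion_rate,
    reverse_check,
    reverse_check_frame,
)
from .lexicons import Lexicons, load_lexicons
from .synthetic_ehr import Bundle, read_bundle
from .text_extraction import build_event_stream

log = logging.getLogger("apmonitor")

_CSV_KW = dict(index=False, lineterminator="\n")


@dataclass(frozen=True)
class TrendPoint:
    census_date: dt.date
    pct_main: Optional[float]
    pct_sensitivity: Optional[float]
    n_main: int
    n_sensitivity: int


@dataclass
class TrendSeries:
    points: list[TrendPoint]
    algorithm_version: str
    window_days: int

    def frame(self) -> pd.DataFrame:
        rows = [(p.census_date.isoformat(),
                 "" if p.pct_main is None else p.pct_main,
                 "" if p.pct_sensitivity is None else p.pct_sensitivity,
                 p.n_main, p.n_sensitivity) for p in self.points]
        return pd.DataFrame(rows, columns=[
            "census_date", "pct_main", "pct_sensitivity", "n_main",
            "n_sensitivity"])


@dataclass(frozen=True)
class VariantStage:
    label: str
    n_eligible: int
    n_with_form: int
    pct: Optional[float]
    exclusion_tally: dict[str, int] = field(default_factory=dict, hash=False)


@dataclass(frozen=True)
class VariantComparison:
    """The three-stage cascade at one census: v1 baseline, the
    reference/stop refinement, then the sensitivity exclusions."""

    census_date: dt.date
    stages: tuple[VariantStage, VariantStage, VariantStage]

    def __post_init__(self):
        ns = [s.n_eligible for s in self.stages]
        assert ns == sorted(ns, reverse=True), "cascade denominators must be non-increasing"


def stream_from_bundle(bundle: Bundle, lexicons: Optional[Lexicons] = None):
    lex = lexicons if lexicons is not None else load_lexicons()
    return build_event_stream(
        bundle.diagnoses, bundle.notes, bundle.forms, bundle.episodes, lex,
        patient_ids=set(bundle.patients["patient_id"]) if len(bundle.patients) else set(),
    )


def _spec_for(config: dict, census: dt.date, **overrides) -> CensusSpec:
    params = dict(config)
    params.update(overrides)
    params["census_date"] = census
    return CensusSpec(**params)


def run_monthly(
    bundle_dir: str | Path,
    census_start: str,
    census_end: str,
    spec_params: Optional[dict] = None,
    out_dir: Optional[str | Path] = None,
    lexicons: Optional[Lexicons] = None,
) -> dict[str, pd.DataFrame]:
    """Run the whole pipeline over every monthly census in the span.

    Returns (and optionally writes) cohort.csv, completion.csv,
    reverse_check.csv and trend.csv contents.  Deterministic given inputs.
    """
    bundle = read_bundle(bundle_dir)
    stream = stream_from_bundle(bundle, lexicons)
    params = spec_params or {}
    censuses = census_range(census_start, census_end)

    if not len(bundle.patients):
        log.info("empty bundle: zero censuses processed")
        empty_spec = _spec_for(params, censuses[0])
        outputs = {
            "cohort.csv": cohort_frame([], empty_spec),
            "completion.csv": completion_frame([], empty_spec),
            "reverse_check.csv": reverse_check_frame([]),
            "trend.csv": TrendSeries([], empty_spec.algorithm_version,
                                     empty_spec.window_days).frame(),
        }
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            for name, frame in outputs.items():
                frame.to_csv(out / name, **_CSV_KW)
        return outputs

    cohort_frames, completion_frames, reverse_rows, trend_points = [], [], [], []
    for census in censuses:
        spec_main = _spec_for(params, census, sensitivity_mode=False)
        spec_sens = _spec_for(params, census, sensitivity_mode=True)

        members = build_cohort(stream, bundle.episodes, spec_main)
        tally: dict[str, int] = {}
        for m in members:
            tally[m.exclusion_reason] = tally.get(m.exclusion_reason, 0) + 1
        log.info("census %s: %d evaluated, %d included, exclusions %s",
                 census, len(members), sum(m.included for m in members), tally)
        cohort_frames.append(cohort_frame(members, spec_main))

        pooled = completion_rate(members, bundle.forms, spec_main)[0]
        per_team = completion_rate(members, bundle.forms, spec_main,
                                   group_by_team=True, episodes=bundle.episodes)
        completion_frames.append(
            completion_frame([pooled] + per_team, spec_main))

        members_sens = build_cohort(stream, bundle.episodes, spec_sens)
        pooled_sens = completion_rate(members_sens, bundle.forms, spec_sens)[0]

        reverse_rows.append(reverse_check(stream, bundle.episodes, bundle.forms,
                                          spec_main))
        trend_points.append(TrendPoint(
            census, pooled.pct_complete, pooled_sens.pct_complete,
            pooled.n_eligible, pooled_sens.n_eligible))

    some_spec = _spec_for(params, censuses[0])
    trend = TrendSeries(trend_points, some_spec.algorithm_version,
                        some_spec.window_days)
    outputs = {
        "cohort.csv": pd.concat(cohort_frames, ignore_index=True)
        if cohort_frames else cohort_frame([], some_spec),
        "completion.csv": pd.concat(completion_frames, ignore_index=True)
        if completion_frames else completion_frame([], some_spec),
        "reverse_check.csv": reverse_check_frame(reverse_rows),
        "trend.csv": trend.frame(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in outputs.items():
            frame.to_csv(out / name, **_CSV_KW)
    return outputs


def compare_variants(
    bundle_dir: str | Path,
    census_date: dt.date,
    spec_params: Optional[dict] = None,
    lexicons: Optional[Lexicons] = None,
) -> VariantComparison:
    """Three-stage cascade at one census: v1, v2 (reference/stop filters),
    v2 + sensitivity exclusions.  Denominators are non-increasing; the
    percentages themselves may move either way."""
    bundle = read_bundle(bundle_dir)
    stream = stream_from_bundle(bundle, lexicons)
    params = dict(spec_params or {})
    params.pop("algorithm_version", None)
    params.pop("sensitivity_mode", None)

    stages = []
    for label, version, sensitivity in (
        ("v1", "v1", False),
        ("v2_reference_stop", "v2", False),
        ("v2_sensitivity", "v2", True),
    ):
        spec = _spec_for(params, census_date, algorithm_version=version,
                         sensitivity_mode=sensitivity)
        members = build_cohort(stream, bundle.episodes, spec)
        tally: dict[str, int] = {}
        for m in members:
            if not m.included:
                tally[m.exclusion_reason] = tally.get(m.exclusion_reason, 0) + 1
        pooled = completion_rate(members, bundle.forms, spec)[0]
        log.info("variant %s at %s: %d eligible, exclusions %s",
                 label, census_date, pooled.n_eligible, tally)
        stages.append(VariantStage(label, pooled.n_eligible, pooled.n_with_form,
                                   pooled.pct_complete, tally))
    return VariantComparison(census_date, tuple(stages))


def render_report(results: list[CompletionResult], census_date: dt.date,
                  spec: CensusSpec) -> str:
    """Stable, human-readable team feedback summary for one census."""
    lines = [
        f"Antipsychotic monitoring report — census {census_date.isoformat()}",
        f"algorithm={spec.algorithm_version}  window_days={spec.window_days}  "
        f"form_validity_days={spec.effective_form_validity_days}  "
        f"sensitivity={'on' if spec.sensitivity_mode else 'off'}",
        "-" * 72,
    ]
    for r in sorted(results, key=lambda r: (r.team_id != "ALL", r.team_id)):
        if r.n_eligible == 0:
            lines.append(f"{r.team_id:<10} no eligible patients")
        else:
            lines.append(
                f"{r.team_id:<10} eligible={r.n_eligible:<4d} "
                f"forms={r.n_with_form:<4d} completion={r.pct_complete:.1f}%")
    return "\n".join(lines) + "\n"
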