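"""Lexicon loading for the rule-based extractor.

Lexicons are plain YAML shipped as package data (``data/lexicons.yaml``) and
can be replaced wholesale by pointing :func:`load_lexicons` at another file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError

DEMENTIA_BLOCK = "F00-F03"
PSYCHOSIS_BLOCK = "F20-F29"
OTHER_F_BLOCK = "other-F"

DIAGNOSIS_BLOCKS = (DEMENTIA_BLOCK, PSYCHOSIS_BLOCK, OTHER_F_BLOCK)


@dataclass(frozen=True)
class Lexicons:
    """Surface-form dictionaries driving extraction.

    Attributes
    ----------
    diagnosis_terms:
        ICD-10 block label -> list of surface terms asserting that block.
    drug_synonyms:
        surface form (generic or brand) -> normalised generic name.
    generics:
        the configured antipsychotic generic names, in file order.
    start_phrases, stop_phrases, negation_cues:
        contextual cue phrases (may be multi-word).
    """

    diagnosis_terms: dict[str, list[str]]
    drug_synonyms: dict[str, str]
    generics: tuple[str, ...]
    start_phrases: tuple[str, ...]
    stop_phrases: tuple[str, ...]
    negation_cues: tuple[str, ...]
    source: str = field(default="package", compare=False)

    def __post_init__(self):
        for name in ("diagnosis_terms", "drug_synonyms", "start_phrases",
                     "stop_phrases", "negation_cues"):
            if not getattr(self, name):
                raise ConfigurationError(f"lexicon field {name!r} is empty")


def _build(raw: dict, source: str) -> Lexicons:
    try:
        dx = {str(k): [str(t).lower() for t in v]
              for k, v in raw["diagnosis_terms"].items()}
        drugs = raw["antipsychotics"]
    except KeyError as exc:  # pragma: no cover - config authoring error
        raise ConfigurationError(f"lexicon file missing section {exc}") from exc
    synonyms: dict[str, str] = {}
    for generic, brands in drugs.items():
        generic = str(generic).lower()
        synonyms[generic] = generic
        for brand in brands or []:
            synonyms[str(brand).lower()] = generic
    return Lexicons(
        diagnosis_terms=dx,
        drug_synonyms=synonyms,
        generics=tuple(str(g).lower() for g in drugs),
        start_phrases=tuple(str(p).lower() for p in raw.get("start_phrases", [])),
        stop_phrases=tuple(str(p).lower() for p in raw.get("stop_phrases", [])),
        negation_cues=tuple(str(p).lower() for p in raw.get("negation_cues", [])),
        source=source,
    )


def load_lexicons(path: str | Path | None = None) -> Lexicons:
    """Load lexicons from ``path``, or the packaged defaults when omitted."""
    if path is None:
        text = (resources.files("apmonitor") / "data" / "lexicons.yaml").read_text()
        return _build(yaml.safe_load(text), source="package")
    path = Path(path)
    return _build(yaml.safe_load(path.read_text()), source=str(path))
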