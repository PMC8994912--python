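"""Code maps: diagnosis/procedure codes -> complication and comorbidity classes.

Hospital registers record ICD-10 diagnosis codes and national operation codes
in mixed dialects (with or without the dot, mixed case). A code map assigns a
code to a class when any of the class's patterns equals the normalized code or
is a prefix of it — the convention used by national register chapter lists.

Two maps are used downstream:

* a complication map over the six diabetes complication classes
  (cerebrovascular, cardiovascular, nephropathy, foot disorder, eye,
  neurological), which drives episode construction, and
* a comorbidity map over a modified Charlson grouping: HIV/AIDS,
  hemiplegia/paraplegia and "diabetes without complications" are dropped,
  the two liver classes are merged into ``any_chronic_liver_disease`` and the
  two malignancy classes into ``any_malignancy``; "diabetes with chronic
  complications" is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

COMPLICATION_CLASSES: tuple[str, ...] = (
    "cerebrovascular",
    "cardiovascular",
    "nephropathy",
    "foot_disorder",
    "eye",
    "neurological",
)

#: Modified Charlson comorbidity classes (see module docstring).
COMORBIDITY_CLASSES: tuple[str, ...] = (
    "myocardial_infarction",
    "congestive_heart_failure",
    "peripheral_vascular_disease",
    "cerebrovascular_disease",
    "dementia",
    "chronic_pulmonary_disease",
    "rheumatological_disease",
    "peptic_ulcer_disease",
    "any_chronic_liver_disease",
    "diabetes_with_chronic_complications",
    "moderate_or_severe_renal_disease",
    "any_malignancy",
)

#: Charlson classes deliberately absent from the comorbidity map.
EXCLUDED_CHARLSON_CLASSES: tuple[str, ...] = (
    "hiv_aids",
    "hemiplegia_paraplegia",
    "diabetes_without_complications",
)


class CodeMapError(ValueError):
    """Raised for schema or validation problems in a code-map config."""


def normalize_code(code: str) -> str:
    """Uppercase and strip the ICD-10 dot so register dialects compare equal."""
    return code.strip().upper().replace(".", "")


@dataclass(frozen=True)
class PatternMap:
    """Mapping class name -> tuple of normalized code patterns.

    A pattern matches a code when it equals the normalized code or is a
    prefix of it.
    """

    entries: dict[str, tuple[str, ...]]

    #: expected class universe; subclasses override
    required_classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = set(self.required_classes or self.entries)
        got = set(self.entries)
        unknown = got - required
        if unknown:
            raise CodeMapError(
                f"unknown class name(s) {sorted(unknown)}; "
                f"expected classes: {sorted(required)}"
            )
        missing = required - got
        if missing:
            raise CodeMapError(f"missing class(es): {sorted(missing)}")
        for cls, patterns in self.entries.items():
            seen: set[str] = set()
            for p in patterns:
                if not isinstance(p, str) or not p.strip():
                    raise CodeMapError(f"empty/non-string pattern under {cls!r}")
                norm = normalize_code(p)
                if norm in seen:
                    raise CodeMapError(f"duplicate pattern {p!r} under {cls!r}")
                seen.add(norm)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def classify(self, code: str) -> set[str]:
        """Classes whose pattern list matches *code* (exact or prefix)."""
        if not code or not str(code).strip():
            raise ValueError("code must be a non-empty string")
        norm = normalize_code(str(code))
        hits: set[str] = set()
        for cls, patterns in self.entries.items():
            for p in patterns:
                if norm.startswith(normalize_code(p)):
                    hits.add(cls)
                    break
        return hits


def _normalized(entries: dict) -> dict[str, tuple[str, ...]]:
    return {
        str(cls): tuple(normalize_code(str(p)) for p in (patterns or []))
        for cls, patterns in entries.items()
    }


@dataclass(frozen=True)
class CodeMap(PatternMap):
    """Complication-class code map over the six complication classes."""

    required_classes: tuple[str, ...] = COMPLICATION_CLASSES


@dataclass(frozen=True)
class ComorbidityMap(PatternMap):
    """Modified Charlson comorbidity code map."""

    required_classes: tuple[str, ...] = COMORBIDITY_CLASSES

    def __post_init__(self) -> None:
        present_excluded = set(self.entries) & set(EXCLUDED_CHARLSON_CLASSES)
        if present_excluded:
            raise CodeMapError(
                f"excluded Charlson class(es) present: {sorted(present_excluded)}"
            )
        super().__post_init__()


def classify_code(code: str, pattern_map: PatternMap) -> set[str]:
    """Classify *code* under *pattern_map*; unmatched codes give an empty set."""
    return pattern_map.classify(code)


def load_code_maps(config_path: str | Path) -> tuple[CodeMap, ComorbidityMap]:
    """Load and validate complication and comorbidity maps from a YAML config.

    The config has two top-level sections, ``complication_codes`` and
    ``comorbidity_codes``, each mapping a class name to a list of code
    patterns (exact codes or prefixes).
    """
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(f"code-map config not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise CodeMapError(f"config {path} is not a mapping")
    for section in ("complication_codes", "comorbidity_codes"):
        if section not in raw:
            raise CodeMapError(f"config {path} missing section {section!r}")
    code_map = CodeMap(entries=_normalized(raw["complication_codes"]))
    comorbidity_map = ComorbidityMap(entries=_normalized(raw["comorbidity_codes"]))
    for name, pmap in (("complication", code_map), ("comorbidity", comorbidity_map)):
        counts = {cls: len(pats) for cls, pats in pmap.entries.items()}
        logger.info("%s map loaded: %d patterns (%s)", name, sum(counts.values()), counts)
    return code_map, comorbidity_map


def default_synthetic_maps() -> tuple[CodeMap, ComorbidityMap]:
    """Transparent mnemonic code maps for the synthetic registry.

    Complication codes start with a three-letter class mnemonic (``CER0``,
    ``CAR0``, ...) and comorbidity codes with ``CM_<class>``, so synthetic
    fixtures are self-documenting. Real register code lists drop in via
    :func:`load_code_maps` without code changes.
    """
    code_map = CodeMap(
        entries={
            "cerebrovascular": ("CER",),
            "cardiovascular": ("CAR",),
            "nephropathy": ("NEP",),
            "foot_disorder": ("FOO",),
            "eye": ("EYE",),
            "neurological": ("NEU",),
        }
    )
    comorbidity_map = ComorbidityMap(
        entries={cls: (normalize_code(f"CM{i:02d}"),) for i, cls in enumerate(COMORBIDITY_CLASSES)}
    )
    return code_map, comorbidity_map
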