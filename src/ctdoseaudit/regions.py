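"""Protocol-to-region classification and the fixed-region failure mode.

Commercial monitoring systems have been observed to stamp the body region
of the *last* series of a study onto every series of that study.  For
multi-region examinations (e.g. head + chest in one visit) this inflates
the DLP-to-ED conversion of the low-factor series.  :func:`emulate_fixed_region`
reproduces exactly that behaviour so the bias can be quantified downstream.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError, NoDiagnosticSeriesError
from .records import SeriesRegion, StudyAlias, StudyRecord


# ---------------------------------------------------------------------------
# Alias rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AliasRule:
    """Case-insensitive regex over the protocol name; first match wins."""

    pattern: str
    alias: SeriesRegion

    def matches(self, protocol_name: str) -> bool:
        return re.search(self.pattern, protocol_name, re.IGNORECASE) is not None


@dataclass(frozen=True)
class AliasRuleSet:
    rules: tuple[AliasRule, ...]
    fallback: SeriesRegion = SeriesRegion.UNDEFINED

    def __post_init__(self) -> None:
        if not self.rules:
            raise ConfigError("AliasRuleSet requires at least one rule")

    @classmethod
    def from_file(cls, path: str | Path) -> "AliasRuleSet":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "AliasRuleSet":
        rules = tuple(
            AliasRule(pattern=r["pattern"], alias=SeriesRegion(r["alias"]))
            for r in raw["rules"]
        )
        fallback = SeriesRegion(raw.get("fallback", "undefined"))
        return cls(rules=rules, fallback=fallback)

    def to_mapping(self) -> dict:
        return {
            "rules": [{"pattern": r.pattern, "alias": r.alias.value} for r in self.rules],
            "fallback": self.fallback.value,
        }


def classify_protocol(protocol_name: str, rules: AliasRuleSet) -> SeriesRegion:
    """Deterministic first-match classification; unmatched -> fallback."""
    for rule in rules.rules:
        if rule.matches(protocol_name):
            return rule.alias
    return rules.fallback


# ---------------------------------------------------------------------------
# Study-level alias derivation
# ---------------------------------------------------------------------------

#: series-level region -> study-level alias.  ``trunk`` has no study-level
#: counterpart; it is attributed to ``abdomen`` (its dose-dominant section).
SERIES_TO_STUDY_ALIAS: dict[SeriesRegion, StudyAlias] = {
    SeriesRegion.HEAD: StudyAlias.HEAD,
    SeriesRegion.NECK: StudyAlias.NECK,
    SeriesRegion.CHEST: StudyAlias.CHEST,
    SeriesRegion.ABDOMEN_PELVIS: StudyAlias.ABDOMEN,
    SeriesRegion.TRUNK: StudyAlias.ABDOMEN,
    SeriesRegion.UNDEFINED: StudyAlias.UNDEFINED,
}


def derive_study_alias(
    study: StudyRecord,
    alias_map: Mapping[SeriesRegion, StudyAlias] | None = None,
) -> tuple[StudyAlias, bool]:
    """Derive the study-level alias from the study's diagnostic series.

    Scouts never vote.  If all diagnostic series agree on one region the
    study alias is that region (mapped through ``alias_map``); otherwise the
    study is flagged multi-region and the alias follows the series with the
    largest DLP.

    Returns ``(study_alias, multi_region)``.
    """
    alias_map = alias_map or SERIES_TO_STUDY_ALIAS
    diagnostic = study.diagnostic_series()
    if not diagnostic:
        raise NoDiagnosticSeriesError(
            f"study {study.study_id}: no diagnostic series"
        )
    regions = {s.series_region for s in diagnostic}
    if len(regions) == 1:
        return alias_map[next(iter(regions))], False
    dominant = max(diagnostic, key=lambda s: s.dlp)
    return alias_map[dominant.series_region], True


# ---------------------------------------------------------------------------
# Fixed-region emulation
# ---------------------------------------------------------------------------

def emulate_fixed_region(
    study: StudyRecord, *, use_trailing_scout: bool = False
) -> StudyRecord:
    """Return a copy in which every series carries one fixed region.

    The fixed region is that of the last diagnostic (non-scout) series,
    matching the observed failure mode; ``use_trailing_scout=True`` switches
    to the literally-last series, scout or not.  The input is untouched and
    the operation is idempotent.
    """
    if not study.series:
        raise ValueError(f"study {study.study_id}: empty series list")
    if use_trailing_scout:
        anchor = study.series[-1]
    else:
        diagnostic = study.diagnostic_series()
        anchor = diagnostic[-1] if diagnostic else study.series[-1]
    fixed = anchor.series_region
    new_series = [
        dataclasses.replace(s, series_region=fixed) for s in study.series
    ]
    return study.replace_series(new_series)


# ---------------------------------------------------------------------------
# Default rule table (user-overridable; dumpable via the CLI)
# ---------------------------------------------------------------------------

DEFAULT_ALIAS_RULES = AliasRuleSet(
    rules=(
        # order matters: compound regions before their parts
        AliasRule(r"polytrauma|trunk|chest.?abdomen.?pelvis|\bCAP\b", SeriesRegion.TRUNK),
        AliasRule(r"abdomen.{0,3}pelvis|abdo.?pelv|\bTAP\b", SeriesRegion.ABDOMEN_PELVIS),
        AliasRule(r"head|brain|skull|cranial|cranium", SeriesRegion.HEAD),
        AliasRule(r"sinus|facial|orbit|temporal bone|sella", SeriesRegion.HEAD),
        AliasRule(r"cervical|neck|carotid|larynx|thyroid", SeriesRegion.NECK),
        AliasRule(r"chest|thorax|thoracic|lung|HRCT|pulmo", SeriesRegion.CHEST),
        AliasRule(r"cardiac|coronar|heart", SeriesRegion.CHEST),
        AliasRule(r"abdomen|abdo|liver|pancrea|kidney|renal|urogra",
                  SeriesRegion.ABDOMEN_PELVIS),
        AliasRule(r"pelvis|pelvic|bladder|prostate", SeriesRegion.ABDOMEN_PELVIS),
        AliasRule(r"colono|entero", SeriesRegion.ABDOMEN_PELVIS),
    ),
    fallback=SeriesRegion.UNDEFINED,
)
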