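"""Recoding fine-grained cause-of-death labels onto a condensed common list.

Hospital diagnoses and physician VA coding use fine ICD-10-style labels,
while probabilistic interpreters work with a short list of broad categories.
Before any agreement statistic can be computed, all three methods' labels
must be recoded onto one shared "condensed common list".  This module
provides that recoding: a validated source-label -> category map, a built-in
map implementing the standard merges (asthma/bronchitis into chronic
respiratory diseases; rabies/tetanus/bare sepsis into other acute
infections; stroke/hypertension/heart conditions into cardiovascular
diseases; shigellosis/gastroenteritis/diarrheas into diarrhea/
gastroenteritis; pneumonia kept with sepsis as pneumonia/sepsis; TB kept
distinct from HIV), and CSV import/export.

Matching is exact on case-folded, trimmed labels — no fuzzy matching, so
every recode is auditable.  Unmapped labels fall into a configurable default
category with a logged warning rather than aborting a batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .cohort import INDETERMINATE, CauseList

logger = logging.getLogger(__name__)

#: A 35-entry condensed common cause list in the style of probabilistic VA
#: interpreters' adult short lists.  Synthetic stand-in assembled for this
#: package: it contains every category the recoding rules above target, padded
#: with the usual broad adult groups (maternal, injuries, chronic diseases).
CONDENSED_COMMON_LIST = CauseList((
    "HIV/AIDS-related death",
    "tuberculosis (pulmonary)",
    "malaria",
    "meningitis",
    "diarrhea/gastroenteritis",
    "pneumonia/sepsis",
    "other acute infections",
    "cardiovascular diseases",
    "diabetes",
    "chronic respiratory diseases",
    "liver diseases",
    "renal diseases",
    "digestive diseases (other)",
    "neoplasms",
    "anemia",
    "malnutrition",
    "sickle cell disease",
    "epilepsy",
    "mental/neurological disorders",
    "endocrine/metabolic (other)",
    "other chronic diseases",
    "maternal: hemorrhage",
    "maternal: sepsis",
    "maternal: eclampsia",
    "maternal: obstructed labor",
    "maternal: abortion-related",
    "other maternal causes",
    "road traffic accident",
    "other accidents",
    "drowning",
    "suicide",
    "homicide/violence",
    "other injuries",
    "other infectious diseases",
    "other and unspecified",
))

DEFAULT_CATEGORY = "other and unspecified"


def _norm(label: str) -> str:
    return label.strip().casefold()


@dataclass
class CauseMap:
    """Source label (case-insensitive, trimmed) -> condensed category."""

    entries: dict[str, str]
    cause_list: CauseList = CONDENSED_COMMON_LIST
    default_category: str = DEFAULT_CATEGORY

    def __post_init__(self) -> None:
        if self.default_category not in self.cause_list:
            raise ValueError(
                f"default category {self.default_category!r} not in cause list"
            )
        bad = {t for t in self.entries.values() if t not in self.cause_list}
        if bad:
            raise ValueError(f"map targets not in cause list: {sorted(bad)}")
        self.entries = {_norm(k): v for k, v in self.entries.items()}
        self._canonical = {_norm(c): c for c in self.cause_list}

    def __len__(self) -> int:
        return len(self.entries)


def recode(label: str, cmap: CauseMap) -> str:
    """Map a source label to its condensed category (total function).

    Already-condensed labels and ``indeterminate`` pass through unchanged;
    anything unrecognised lands in the map's default category with a warning.
    Idempotent by construction.
    """
    if not label or not label.strip():
        raise ValueError("cannot recode an empty label")
    key = _norm(label)
    if key == INDETERMINATE:
        return INDETERMINATE
    if key in cmap.entries:
        return cmap.entries[key]
    if key in cmap._canonical:
        return cmap._canonical[key]
    logger.warning("unmapped cause label %r -> %r", label, cmap.default_category)
    return cmap.default_category


def recode_series(labels, cmap: CauseMap) -> pd.Series:
    """Vector version of :func:`recode` for assignment columns."""
    s = pd.Series(labels)
    return s.map(lambda x: recode(x, cmap))


def load_cause_map(
    path,
    cause_list: CauseList = CONDENSED_COMMON_LIST,
    default_category: str = DEFAULT_CATEGORY,
) -> CauseMap:
    """Load and validate a two-column ``source_label,condensed_category`` CSV.

    Duplicate rows with a consistent target are deduplicated with a warning;
    duplicates with conflicting targets are a hard error naming the label, as
    is any target absent from the cause list.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["source_label", "condensed_category"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    entries: dict[str, str] = {}
    for line, (src, tgt) in enumerate(
        zip(df["source_label"], df["condensed_category"]), start=2
    ):
        key = _norm(src)
        if not key:
            raise ValueError(f"{path}:{line}: empty source label")
        if tgt not in cause_list:
            raise ValueError(
                f"{path}:{line}: target {tgt!r} is not a condensed category"
            )
        if key in entries:
            if entries[key] != tgt:
                raise ValueError(
                    f"{path}:{line}: source {src!r} maps to both "
                    f"{entries[key]!r} and {tgt!r}"
                )
            logger.warning("%s:%d: duplicate mapping for %r ignored", path, line, src)
            continue
        entries[key] = tgt
    return CauseMap(entries, cause_list, default_category)


def save_cause_map(cmap: CauseMap, path) -> None:
    """Export a cause map in the two-column CSV format."""
    pd.DataFrame(
        sorted(cmap.entries.items()), columns=["source_label", "condensed_category"]
    ).to_csv(path, index=False)


def builtin_default_map(
    cause_list: CauseList = CONDENSED_COMMON_LIST,
    default_category: str = DEFAULT_CATEGORY,
) -> CauseMap:
    """The standard merges applied before comparing COD assignment methods.

    Covers the recodes a hospital or physician label set needs to land on the
    condensed common list; users extend it with their own CSV for fuller
    label inventories.  TB stays its own category, distinct from HIV.
    """
    rules = {
        # chronic respiratory
        "asthma": "chronic respiratory diseases",
        "bronchitis": "chronic respiratory diseases",
        "chronic bronchitis": "chronic respiratory diseases",
        "chronic obstructive pulmonary disease": "chronic respiratory diseases",
        "copd": "chronic respiratory diseases",
        "emphysema": "chronic respiratory diseases",
        # acute infections without a category of their own; bare sepsis
        # (without pneumonia) belongs here, not in pneumonia/sepsis
        "rabies": "other acute infections",
        "tetanus": "other acute infections",
        "sepsis": "other acute infections",
        "septicemia": "other acute infections",
        "septicaemia": "other acute infections",
        # cardiovascular merge
        "stroke": "cardiovascular diseases",
        "hypertension": "cardiovascular diseases",
        "heart failure": "cardiovascular diseases",
        "ischemic heart disease": "cardiovascular diseases",
        "ischaemic heart disease": "cardiovascular diseases",
        "myocardial infarction": "cardiovascular diseases",
        "rheumatic heart disease": "cardiovascular diseases",
        "cardiac arrest": "cardiovascular diseases",
        "heart conditions": "cardiovascular diseases",
        # one broad diarrheal category
        "shigellosis": "diarrhea/gastroenteritis",
        "gastroenteritis": "diarrhea/gastroenteritis",
        "bloody diarrhea": "diarrhea/gastroenteritis",
        "bloody diarrhoea": "diarrhea/gastroenteritis",
        "nonbloody diarrhea": "diarrhea/gastroenteritis",
        "nonbloody diarrhoea": "diarrhea/gastroenteritis",
        "dysentery": "diarrhea/gastroenteritis",
        "cholera": "diarrhea/gastroenteritis",
        # pneumonia stays pooled with sepsis
        "pneumonia": "pneumonia/sepsis",
        "pneumonia/sepsis": "pneumonia/sepsis",
        # common synonyms for the retained fine categories
        "tuberculosis": "tuberculosis (pulmonary)",
        "tb": "tuberculosis (pulmonary)",
        "pulmonary tuberculosis": "tuberculosis (pulmonary)",
        "hiv": "HIV/AIDS-related death",
        "aids": "HIV/AIDS-related death",
        "hiv/aids": "HIV/AIDS-related death",
        "diabetes mellitus": "diabetes",
        "leukemia": "neoplasms",
        "cancer of the cervix": "neoplasms",
        "liver cirrhosis": "liver diseases",
        "alcoholic liver disease": "liver diseases",
        "renal failure": "renal diseases",
    }
    return CauseMap(rules, cause_list, default_category)
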