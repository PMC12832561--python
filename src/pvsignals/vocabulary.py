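"""PT -> SOC hierarchy and label dictionaries.

MedDRA-style vocabularies group specific adverse-event Preferred Terms (PT)
under System Organ Classes (SOC).  MedDRA itself is licensed, so the package
ships a small fixture vocabulary covering the terms exercised by the
roflumilast case study and accepts any user-supplied two-column table.
Label dictionaries record which PTs appear in the FDA label or the Canadian
product monograph; a positive signal absent from both is an unexpected
(novel) signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)

UNMAPPED_SOC = "unmapped"

_DATA = Path(__file__).parent / "data"


def _norm(s: str) -> str:
    return " ".join(str(s).split()).strip().lower()


class Agency(str, Enum):
    FDA = "fda"
    CANADA = "canada"


class Labeledness(str, Enum):
    LABELED = "labeled"
    UNLABELED = "unlabeled"


@dataclass(frozen=True)
class EventVocabulary:
    """An immutable PT -> SOC map; every PT belongs to exactly one SOC."""

    pt_to_soc: Mapping[str, str]

    @property
    def soc_set(self) -> frozenset[str]:
        return frozenset(self.pt_to_soc.values())

    def __contains__(self, pt: str) -> bool:
        return _norm(pt) in self.pt_to_soc


@dataclass(frozen=True)
class LabelDictionary:
    """Labeled adverse-event terms for one regulatory agency.

    ``synonym_map`` canonicalizes variant spellings (e.g. US "diarrhea" to
    the MedDRA "diarrhoea") before the exact-match lookup; every synonym
    target must itself be usable as a canonical PT.
    """

    agency: Agency
    labeled_terms: frozenset[str]
    synonym_map: Mapping[str, str] = field(default_factory=dict)

    def canonicalize(self, pt: str) -> str:
        s = _norm(pt)
        return self.synonym_map.get(s, s)

    def is_labeled(self, pt: str) -> bool:
        return self.canonicalize(pt) in self.labeled_terms


def load_vocabulary(path: str | Path) -> EventVocabulary:
    """Load a two-column (PT, SOC) delimited table.

    PTs are normalized to trimmed lower case; duplicate PT rows with the
    same SOC are tolerated, conflicting duplicates raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: vocabulary needs two columns (PT, SOC)")
    if len(df) == 0:
        raise ValueError(f"{path}: vocabulary file is empty")
    mapping: dict[str, str] = {}
    for pt, soc in zip(df.iloc[:, 0], df.iloc[:, 1]):
        pt_n, soc_n = _norm(pt), _norm(soc)
        if not pt_n:
            continue
        if pt_n in mapping and mapping[pt_n] != soc_n:
            raise ValueError(f"conflicting SOC for PT {pt_n!r}: "
                             f"{mapping[pt_n]!r} vs {soc_n!r}")
        mapping[pt_n] = soc_n
    return EventVocabulary(pt_to_soc=mapping)


def load_fixture_vocabulary() -> EventVocabulary:
    """The vocabulary shipped with the package (~50 PTs)."""
    return load_vocabulary(_DATA / "fixture_vocabulary.tsv")


def map_pt_to_soc(vocab: EventVocabulary, pt: str) -> str:
    """SOC for a PT; unknown PTs map to the reserved SOC ``unmapped``."""
    soc = vocab.pt_to_soc.get(_norm(pt))
    if soc is None:
        log.debug("PT %r not in vocabulary", pt)
        return UNMAPPED_SOC
    return soc


def load_label_dictionaries(
    terms_path: str | Path | None = None,
    synonyms_path: str | Path | None = None,
) -> dict[Agency, LabelDictionary]:
    """Load the shipped (or user-supplied) label dictionaries.

    The terms table has columns (term, agency); the synonym table
    (variant, canonical) is shared by all agencies.
    """
    terms_path = terms_path or _DATA / "labeled_terms.tsv"
    synonyms_path = synonyms_path or _DATA / "synonyms.tsv"
    terms = pd.read_csv(terms_path, sep="\t", dtype=str, keep_default_na=False)
    syn = pd.read_csv(synonyms_path, sep="\t", dtype=str, keep_default_na=False)
    synonym_map = {_norm(v): _norm(c) for v, c in zip(syn["variant"], syn["canonical"])}
    out: dict[Agency, LabelDictionary] = {}
    for agency in Agency:
        labeled = frozenset(
            _norm(t) for t, a in zip(terms["term"], terms["agency"])
            if _norm(a) == agency.value
        )
        out[agency] = LabelDictionary(agency=agency, labeled_terms=labeled,
                                      synonym_map=synonym_map)
    return out


def classify_labeledness(
    pt: str, label_dicts: Iterable[LabelDictionary]
) -> dict[Agency, Labeledness]:
    """Per-agency labeled/unlabeled classification of one PT.

    Exact match after synonym canonicalization; pure in its inputs.
    """
    return {
        d.agency: Labeledness.LABELED if d.is_labeled(pt) else Labeledness.UNLABELED
        for d in label_dicts
    }
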