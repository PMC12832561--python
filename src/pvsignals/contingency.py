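"""2x2 contingency tables for drug-event pairs.

Disproportionality statistics compare how often an event is reported with
the target drug against the rest of the database.  For an event ``e``::

                    event e    other events
    target drug        a            b
    other drugs        c            d

The counting unit is the report (case): a report contributes at most once
per PT, and once per SOC even when several of its PTs share that SOC.
The margins a+b (target total) and a+b+c+d = N (database total) are the
same for every event at a given level.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

from .report_store import SafetyReport
from .vocabulary import UNMAPPED_SOC, EventVocabulary, map_pt_to_soc


class Level(str, Enum):
    PT = "pt"
    SOC = "soc"


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 counts for one drug-event pair."""

    event_name: str
    level: Level
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("cells must be non-negative integers")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Independence-expected count E = (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n_total


def _report_terms(report: SafetyReport, level: Level,
                  vocab: EventVocabulary | None) -> set[str]:
    if level is Level.PT:
        return set(report.events)
    assert vocab is not None
    return {map_pt_to_soc(vocab, pt) for pt in report.events}


def build_table(
    target_reports: Sequence[SafetyReport],
    background_reports: Sequence[SafetyReport],
    event: str,
    level: Level = Level.PT,
    vocab: EventVocabulary | None = None,
) -> ContingencyTable:
    """Build the 2x2 table for one event at PT or SOC level.

    ``target_reports`` and ``background_reports`` must be disjoint report
    sets.  At SOC level the event must be a SOC present in the vocabulary
    (or the reserved ``unmapped`` class).
    """
    event = " ".join(str(event).split()).lower()
    if level is Level.SOC:
        if vocab is None:
            raise ValueError("SOC level requires a vocabulary")
        if event != UNMAPPED_SOC and event not in vocab.soc_set:
            raise ValueError(f"unknown SOC {event!r}")
    a = sum(1 for r in target_reports if event in _report_terms(r, level, vocab))
    c = sum(1 for r in background_reports if event in _report_terms(r, level, vocab))
    return ContingencyTable(event_name=event, level=level, a=a,
                            b=len(target_reports) - a,
                            c=c, d=len(background_reports) - c)


def build_all(
    target_reports: Sequence[SafetyReport],
    background_reports: Sequence[SafetyReport],
    level: Level = Level.PT,
    vocab: EventVocabulary | None = None,
    min_count: int = 1,
) -> list[ContingencyTable]:
    """Tables for every event with a >= min_count among target reports.

    Sorted by ``a`` descending, event name ascending, so selection of the
    top-k most frequent events is a deterministic prefix of the result.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    a_counts: dict[str, int] = {}
    for r in target_reports:
        for t in _report_terms(r, level, vocab):
            a_counts[t] = a_counts.get(t, 0) + 1
    c_counts: dict[str, int] = {}
    for r in background_reports:
        for t in _report_terms(r, level, vocab):
            c_counts[t] = c_counts.get(t, 0) + 1
    n_t, n_b = len(target_reports), len(background_reports)
    tables = [
        ContingencyTable(event_name=e, level=level, a=a, b=n_t - a,
                         c=c_counts.get(e, 0), d=n_b - c_counts.get(e, 0))
        for e, a in a_counts.items() if a >= min_count
    ]
    tables.sort(key=lambda t: (-t.a, t.event_name))
    return tables


def pair_tables_for_prior(
    reports: Sequence[SafetyReport], min_count: int = 1
) -> list[ContingencyTable]:
    """(drug, PT) tables over the whole store, for empirical-Bayes prior fitting.

    Each report is attributed to its first suspect drug entry (primary
    suspect preferred).  The gamma-Poisson shrinker's prior must be fitted
    on the full event universe of the database, not just the target drug's
    events, so this enumerates every observed drug-PT pair.
    """
    from .report_store import Role

    pairs: dict[tuple[str, str], int] = {}
    drug_tot: dict[str, int] = {}
    pt_tot: dict[str, int] = {}
    n = len(reports)
    for r in reports:
        drug = None
        for role in (Role.PRIMARY_SUSPECT, Role.SUSPECT, Role.SECONDARY_SUSPECT):
            drug = next((d.name_normalized for d in r.drugs if d.role is role), None)
            if drug:
                break
        if drug is None:
            drug = r.drugs[0].name_normalized if r.drugs else "unknown"
        drug_tot[drug] = drug_tot.get(drug, 0) + 1
        for pt in r.events:
            pairs[(drug, pt)] = pairs.get((drug, pt), 0) + 1
            pt_tot[pt] = pt_tot.get(pt, 0) + 1
    out = []
    for (drug, pt), a in sorted(pairs.items()):
        if a < min_count:
            continue
        b = drug_tot[drug] - a
        c = pt_tot[pt] - a
        out.append(ContingencyTable(event_name=f"{drug}::{pt}", level=Level.PT,
                                    a=a, b=b, c=c, d=n - a - b - c))
    return out


def pair_cells_from_counts(counts, reports_per_drug):
    """2x2 cell arrays for every (drug, event) pair of a count matrix.

    ``counts[d, e]`` is the number of reports of drug ``d`` containing
    event ``e`` and ``reports_per_drug[d]`` the drug's report total.
    Returns float arrays (a, b, c, d) of the same shape as ``counts``,
    with margins conserved against the database total.
    """
    import numpy as np

    counts = np.asarray(counts, dtype=float)
    row = np.asarray(reports_per_drug, dtype=float)[:, None]
    col = counts.sum(axis=0, keepdims=True)
    n = row.sum()
    a = counts
    return a, row - a, col - a, n - row - col + a


def tables_to_frame(tables: Sequence[ContingencyTable]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"event": t.event_name, "level": t.level.value,
          "a": t.a, "b": t.b, "c": t.c, "d": t.d} for t in tables],
        columns=["event", "level", "a", "b", "c", "d"])


def write_tables(tables: Sequence[ContingencyTable], path: str | Path) -> None:
    tables_to_frame(tables).to_csv(path, sep="\t", index=False)
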