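"""Within-drug subgroup comparisons and co-medication sensitivity analysis.

Subgroup analysis asks, among reports of the target drug only, whether an
event is reported disproportionately in one stratum (e.g. females) versus
another (males).  For each event the 2x2 table crosses event-vs-other-events
with target-vs-control stratum; the stratified ("adjusted") ROR uses the
same Woolf interval as the database-wide ROR, a two-sided p-value comes
from the Yates chi-square (Fisher's exact test when any expected cell is
below 5), and p-values across the event list are corrected by the
Benjamini-Hochberg false-discovery-rate procedure.  adj_ror > 1 means the
event is relatively more reported in the target stratum.

The sensitivity reanalysis drops reports that also mention commonly
co-administered bronchodilator products (formoterol and its dual/triple
combinations by default) and reruns the unchanged signal pipeline on the
remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .report_store import SafetyReport, _norm
from .signal_stats import ror_arrays

log = logging.getLogger(__name__)

DEFAULT_TOP_K_EVENTS = 50

#: report attribute accessors for the supported stratum variables
STRATUM_ACCESSORS: dict[str, Callable[[SafetyReport], str]] = {
    "gender": lambda r: r.gender.value,
    "age_band": lambda r: r.age_band(),
    "route": lambda r: r.route.value,
}


@dataclass(frozen=True)
class SubgroupResult:
    event_name: str
    stratum_variable: str
    target_label: str
    control_label: str
    a: int  # target stratum, with event
    b: int  # target stratum, without
    c: int  # control stratum, with event
    d: int  # control stratum, without
    adj_ror: float
    ci: tuple[float, float]
    corrected: bool
    p: float
    p_adj: float


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pair_p_value(a: int, b: int, c: int, d: int) -> float:
    """Two-sided p: Fisher exact if any expected cell < 5, else Yates chi2."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    if n == 0:
        return 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected < 5).any():
        return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return float(stats.chi2_contingency(table, correction=True)[1])


def top_events(reports: Sequence[SafetyReport], k: int = DEFAULT_TOP_K_EVENTS) -> list[str]:
    """The k most frequent PTs (report-level counts; ties alphabetical)."""
    counts: dict[str, int] = {}
    for r in reports:
        for e in r.events:
            counts[e] = counts.get(e, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [e for e, _ in ranked[:k]]


def subgroup_ror(
    drug_reports: Sequence[SafetyReport],
    stratum_variable: str,
    target: str,
    control: str,
    events: Sequence[str] | None = None,
    top_k: int = DEFAULT_TOP_K_EVENTS,
) -> list[SubgroupResult]:
    """Stratified ROR with BH-adjusted p-values for each event.

    ``stratum_variable`` is one of gender / age_band / route; reports whose
    stratum value is neither ``target`` nor ``control`` (including missing)
    are excluded.  ``events`` defaults to the top-k most frequent PTs among
    the included reports.
    """
    if stratum_variable not in STRATUM_ACCESSORS:
        raise ValueError(f"unknown stratum variable {stratum_variable!r}")
    accessor = STRATUM_ACCESSORS[stratum_variable]
    tgt = [r for r in drug_reports if accessor(r) == target]
    ctl = [r for r in drug_reports if accessor(r) == control]
    if not tgt or not ctl:
        raise ValueError(f"empty stratum: {target}={len(tgt)}, {control}={len(ctl)}")
    if events is None:
        events = top_events([*tgt, *ctl], k=top_k)

    rows = []
    for event in events:
        e = _norm(event)
        a = sum(1 for r in tgt if e in r.events)
        c = sum(1 for r in ctl if e in r.events)
        b, d = len(tgt) - a, len(ctl) - c
        ror, lo, hi, corr = ror_arrays(a, b, c, d)
        rows.append((e, a, b, c, d, float(ror), float(lo), float(hi), bool(corr),
                     _pair_p_value(a, b, c, d)))
    p_adj = fdr_adjust([row[9] for row in rows])
    return [
        SubgroupResult(
            event_name=e, stratum_variable=stratum_variable,
            target_label=target, control_label=control,
            a=a, b=b, c=c, d=d, adj_ror=ror, ci=(lo, hi), corrected=corr,
            p=p, p_adj=float(q))
        for (e, a, b, c, d, ror, lo, hi, corr, p), q in zip(rows, p_adj)
    ]


def load_default_comedications() -> list[str]:
    """Default co-medication exclusion list: long-acting beta-2 agonists and
    their dual/triple combination products."""
    path = Path(__file__).parent / "data" / "comedications.tsv"
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def exclude_comedications(drug_reports: Sequence[SafetyReport],
                          comed_names: Sequence[str]) -> list[SafetyReport]:
    """Drop reports mentioning any co-medication in any drug role.

    Matching mirrors drug-query selection: case-insensitive substring on
    product name and active ingredient, so combination products match on
    any component name.  Monotone: output is a subset of the input.
    """
    if not comed_names:
        raise ValueError("co-medication list must be nonempty")
    names = [_norm(n) for n in comed_names]
    kept = [r for r in drug_reports
            if not any(d.matches_name(names) for d in r.drugs)]
    log.info("sensitivity exclusion: %d of %d reports dropped",
             len(drug_reports) - len(kept), len(drug_reports))
    return kept


def results_to_frame(results: Sequence[SubgroupResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"event": r.event_name, "stratum": r.stratum_variable,
          "target": r.target_label, "control": r.control_label,
          "a": r.a, "b": r.b, "c": r.c, "d": r.d,
          "adj_ror": r.adj_ror, "ci_lo": r.ci[0], "ci_hi": r.ci[1],
          "p": r.p, "p_adj": r.p_adj} for r in results])
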