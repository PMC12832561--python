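"""Reference tables from the roflumilast dual-database case study.

The package ships two small published summaries of the roflumilast FAERS
analysis (2011 Q1 - 2024 Q4): the demographic marginals of the 2,962
deduplicated reports, and the SOC-level signal-strength table (case
numbers and the four disproportionality statistics with their interval
bounds for all 26 system organ classes).  The raw regulatory extracts
behind them are not redistributable, so these tables serve as fixed
inputs for verifying the summarizer, the contingency bookkeeping, and the
signal-classification rules against known printed outputs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .signal_stats import (DEFAULT_CRITERIA, SignalCriteria, SignalResult,
                           classify_signal)

_DATA = Path(__file__).parent / "data"


def load_reference_soc_table() -> pd.DataFrame:
    """SOC-level signal statistics of the case study (26 rows).

    Columns: soc, n (case number), ror/ror_lo/ror_hi, prr, chi2,
    ebgm/ebgm05, ic/ic025.
    """
    return pd.read_csv(_DATA / "reference_soc_signals.tsv", sep="\t")


def load_reference_marginals() -> pd.DataFrame:
    """Demographic marginal counts (variable, category, count) of the
    case study's deduplicated report set."""
    return pd.read_csv(_DATA / "reference_demographics.tsv", sep="\t")


def classify_reference_socs(
    criteria: SignalCriteria = DEFAULT_CRITERIA,
) -> list[SignalResult]:
    """Apply the positivity criteria to the printed SOC statistics.

    The printed statistics are taken as direct inputs (no recomputation is
    possible without the raw extracts); each row becomes a
    :class:`SignalResult` whose flags follow from the classification rules
    alone.
    """
    out = []
    for row in load_reference_soc_table().itertuples(index=False):
        r = SignalResult(
            event_name=row.soc, level="soc", n=int(row.n),
            ror=float(row.ror), ror_lo=float(row.ror_lo), ror_hi=float(row.ror_hi),
            ror_corrected=False, prr=float(row.prr), chi2=float(row.chi2),
            ic=float(row.ic), ic025=float(row.ic025),
            ebgm=float(row.ebgm), ebgm05=float(row.ebgm05))
        out.append(classify_signal(r, criteria))
    return out
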