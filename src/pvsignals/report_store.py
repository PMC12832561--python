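"""Normalized spontaneous-report model and FAERS/CVARD ingestion.

Spontaneous adverse-event databases (FAERS, Canada Vigilance) distribute
quarterly delimited text extracts: a demographics table defines the report
universe and child tables (drugs, reactions, indications, therapy dates)
join on the report identifier.  This module reads those dialects into a
single normalized :class:`SafetyReport` model, selects reports for a query
drug and role, collapses longitudinal case versions to the most recent
report, strips indication/noise terms from event lists, and summarizes the
demographics of a cleaned store.

All downstream analysis consumes only the normalized model, so the two
source dialects (and the synthetic generator) are interchangeable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

LBS_TO_KG = 0.45359237

# ---------------------------------------------------------------------------
# Errors


class FormatError(ValueError):
    """A source file is missing a required column or is otherwise malformed."""


class EmptyStoreError(ValueError):
    """An operation that needs at least one report received none."""


# ---------------------------------------------------------------------------
# Dates

@dataclass(frozen=True, order=False)
class PartialDate:
    """A calendar date of year, year-month, or full day precision.

    FAERS dates are YYYY, YYYYMM or YYYYMMDD numeric strings; CVARD dates
    are ISO strings that may omit the day.  Comparison uses the zero-padded
    numeric form, so partial dates order before any fuller date in the same
    period.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.month is None and self.day is not None:
            raise ValueError("day without month")
        if not (1900 <= self.year <= 2200):
            raise ValueError(f"implausible year {self.year}")
        if self.month is not None and not (1 <= self.month <= 12):
            raise ValueError(f"invalid month {self.month}")
        if self.day is not None and not (1 <= self.day <= 31):
            raise ValueError(f"invalid day {self.day}")

    @property
    def full_precision(self) -> bool:
        return self.day is not None

    def sort_key(self) -> str:
        return f"{self.year:04d}{self.month or 0:02d}{self.day or 0:02d}"

    def to_ordinal(self) -> int:
        """Proleptic ordinal; full-precision dates only."""
        import datetime

        if not self.full_precision:
            raise ValueError("partial date has no ordinal")
        return datetime.date(self.year, self.month, self.day).toordinal()

    def isoformat(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"

    @classmethod
    def parse(cls, raw: str | None) -> "PartialDate | None":
        """Parse a FAERS numeric (YYYY[MM[DD]]) or ISO (YYYY[-MM[-DD]]) date.

        Returns None for empty/unparseable input.
        """
        if raw is None:
            return None
        s = str(raw).strip().replace("-", "")
        if not s or not s.isdigit():
            return None
        try:
            if len(s) == 4:
                return cls(int(s))
            if len(s) == 6:
                return cls(int(s[:4]), int(s[4:6]))
            if len(s) == 8:
                return cls(int(s[:4]), int(s[4:6]), int(s[6:8]))
        except ValueError:
            return None
        return None


# ---------------------------------------------------------------------------
# Enums and records


class Role(str, Enum):
    PRIMARY_SUSPECT = "primary_suspect"
    SECONDARY_SUSPECT = "secondary_suspect"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"
    SUSPECT = "suspect"  # CVARD's undifferentiated suspect role


class Gender(str, Enum):
    MALE = "male"
    FEMALE = "female"
    MISSING = "missing"


class RouteGroup(str, Enum):
    ORAL = "oral"
    TOPICAL = "topical"
    OTHER = "other"
    MISSING = "missing"


class Reporter(str, Enum):
    HCP = "healthcare_professional"
    CONSUMER = "consumer"
    OTHER = "other"
    MISSING = "missing"


class SourceDb(str, Enum):
    FAERS = "faers"
    CVARD = "cvard"


FAERS_ROLE_CODES = {
    "PS": Role.PRIMARY_SUSPECT,
    "SS": Role.SECONDARY_SUSPECT,
    "C": Role.CONCOMITANT,
    "I": Role.INTERACTING,
}

CVARD_ROLE_CODES = {
    "suspect": Role.SUSPECT,
    "concomitant": Role.CONCOMITANT,
    "interacting": Role.INTERACTING,
}

# FAERS occupation codes: MD physician, PH pharmacist, RN nurse, OT other
# health professional, HP health professional, CN consumer, LW lawyer.
OCCP_CODES = {
    "MD": Reporter.HCP,
    "PH": Reporter.HCP,
    "RN": Reporter.HCP,
    "OT": Reporter.HCP,
    "HP": Reporter.HCP,
    "CN": Reporter.CONSUMER,
    "LW": Reporter.OTHER,
}


def _norm(s: str | None) -> str:
    return "" if s is None else " ".join(str(s).split()).strip().lower()


@dataclass(frozen=True)
class DrugEntry:
    """One drug row of a report."""

    name_raw: str
    name_normalized: str
    role: Role
    ingredient: str = ""  # normalized active-ingredient string (FAERS PROD_AI)
    route_raw: str | None = None
    start_date: PartialDate | None = None

    def __post_init__(self) -> None:
        if not self.name_normalized:
            raise ValueError("empty normalized drug name")

    def matches_name(self, names: Iterable[str]) -> bool:
        """Case-insensitive substring match on product name or ingredient."""
        for n in names:
            n = _norm(n)
            if n and (n in self.name_normalized or n in self.ingredient):
                return True
        return False


@dataclass(frozen=True)
class DrugQuery:
    """A drug of interest: generic plus trade names, with accepted roles."""

    generic_names: frozenset[str]
    trade_names: frozenset[str] = frozenset()
    role_filter: frozenset[Role] = frozenset({Role.PRIMARY_SUSPECT, Role.SUSPECT})

    def __post_init__(self) -> None:
        if not (self.generic_names | self.trade_names):
            raise ValueError("query has no names")

    @property
    def names(self) -> frozenset[str]:
        return frozenset(_norm(n) for n in (self.generic_names | self.trade_names))


ROFLUMILAST_QUERY = DrugQuery(
    generic_names=frozenset({"roflumilast"}),
    trade_names=frozenset({"daliresp", "daxas", "zoryve"}),
)


@dataclass
class SafetyReport:
    """One (version of a) spontaneous adverse-event report."""

    report_key: str
    case_key: str
    receipt_date: PartialDate | None
    source_db: SourceDb
    gender: Gender = Gender.MISSING
    age_years: float | None = None
    weight_kg: float | None = None
    route: RouteGroup = RouteGroup.MISSING
    reporter: Reporter = Reporter.MISSING
    country: str | None = None
    event_date: PartialDate | None = None
    drugs: list[DrugEntry] = field(default_factory=list)
    events: list[str] = field(default_factory=list)
    indications: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("negative age")
        if self.weight_kg is not None and self.weight_kg <= 0:
            raise ValueError("non-positive weight")
        # events are case-report sets: one row per distinct PT
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(_norm(e), None)
        self.events = [e for e in seen if e]

    def age_band(self) -> str:
        if self.age_years is None:
            return "missing"
        if self.age_years < 18:
            return "<18"
        if self.age_years < 65:
            return "18-64"
        return ">=65"

    def weight_band(self) -> str:
        if self.weight_kg is None:
            return "missing"
        if self.weight_kg < 50:
            return "<50"
        if self.weight_kg <= 100:
            return "50-100"
        return ">100"


# ---------------------------------------------------------------------------
# Route normalization


def _load_route_map() -> dict[str, str]:
    path = Path(__file__).parent / "data" / "route_map.tsv"
    df = pd.read_csv(path, sep="\t")
    return {_norm(r): n for r, n in zip(df["raw"], df["normalized"])}


_ROUTE_MAP: dict[str, str] | None = None


def normalize_route(raw: str | None) -> RouteGroup:
    """Map a free-text administration route to {oral, topical, other, missing}.

    Unknown non-empty strings map to ``other``; absent values to ``missing``.
    """
    global _ROUTE_MAP
    if _ROUTE_MAP is None:
        _ROUTE_MAP = _load_route_map()
    s = _norm(raw)
    if not s or s == "unknown":
        return RouteGroup.MISSING
    return RouteGroup(_ROUTE_MAP.get(s, "other"))


def _report_route(drugs: Sequence[DrugEntry]) -> RouteGroup:
    """Report-level route: the first suspect entry with a known route wins."""
    suspect_roles = (Role.PRIMARY_SUSPECT, Role.SUSPECT, Role.SECONDARY_SUSPECT)
    for want_suspect in (True, False):
        for d in drugs:
            if want_suspect != (d.role in suspect_roles):
                continue
            r = normalize_route(d.route_raw)
            if r is not RouteGroup.MISSING:
                return r
    return RouteGroup.MISSING


# ---------------------------------------------------------------------------
# Unit conversion


def convert_age_to_years(value: str | float | None, code: str | None) -> float | None:
    """Convert a FAERS AGE/AGE_COD pair to years.

    DEC decades, YR years, MON months, WK weeks, DY days, HR hours.
    Unparseable values/codes, non-positive results and ages over 120 years
    are treated as missing.
    """
    try:
        v = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None
    if math.isnan(v) or v < 0:
        return None
    factors = {
        "DEC": 10.0,
        "YR": 1.0,
        "MON": 1 / 12.0,
        "WK": 7 / 365.25,
        "DY": 1 / 365.25,
        "HR": 1 / 8760.0,
    }
    code = (code or "YR").strip().upper()
    if code not in factors:
        return None
    years = v * factors[code]
    if years > 120:
        return None
    return years


def convert_weight_to_kg(value: str | float | None, code: str | None) -> float | None:
    """Convert a FAERS WT/WT_COD pair to kilograms (LBS x 0.45359237)."""
    try:
        v = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None
    if math.isnan(v) or v <= 0:
        return None
    factors = {"KG": 1.0, "KGS": 1.0, "LBS": LBS_TO_KG, "LB": LBS_TO_KG, "GMS": 1e-3}
    code = (code or "KG").strip().upper()
    if code not in factors:
        return None
    return v * factors[code]


# ---------------------------------------------------------------------------
# FAERS parsing


def _read_delimited(path: str | Path, sep: str, required: Sequence[str],
                    aliases: Mapping[str, Sequence[str]] | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, engine="python")
    df.columns = [c.strip().upper() for c in df.columns]
    if aliases:
        # legacy schemas (pre-2014Q3) use different column names
        for canonical, alts in aliases.items():
            if canonical not in df.columns:
                for alt in alts:
                    if alt in df.columns:
                        df = df.rename(columns={alt: canonical})
                        break
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col}")
    return df


def _drop_orphans(df: pd.DataFrame, universe: set[str], table: str) -> pd.DataFrame:
    mask = df["PRIMARYID"].isin(universe)
    n_dropped = int((~mask).sum())
    if n_dropped:
        log.info("%s: dropped %d rows without a DEMO parent", table, n_dropped)
    return df[mask]


def parse_faers_quarter(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    indi_path: str | Path | None = None,
    ther_path: str | Path | None = None,
) -> list[SafetyReport]:
    """Parse one quarter of FAERS-style '$'-delimited ASCII tables.

    DEMO defines the report universe (one SafetyReport per row); DRUG, REAC,
    INDI and THER rows attach by PRIMARYID, and child rows without a DEMO
    parent are dropped (count logged).  Ages and weights are converted to
    years and kilograms; unparseable codes become missing.
    """
    demo = _read_delimited(
        demo_path, "$", ["PRIMARYID", "CASEID", "FDA_DT"],
        aliases={"SEX": ["GNDR_COD"], "PRIMARYID": ["ISR"], "CASEID": ["CASE"]},
    )
    if len(demo) == 0:
        raise EmptyStoreError(f"{Path(demo_path).name}: DEMO table is empty")
    drug = _read_delimited(
        drug_path, "$", ["PRIMARYID", "ROLE_COD", "DRUGNAME"],
        aliases={"DRUG_SEQ": ["DSG_DRUG_SEQ"]},
    )
    reac = _read_delimited(reac_path, "$", ["PRIMARYID", "PT"])
    indi = (
        _read_delimited(indi_path, "$", ["PRIMARYID", "INDI_PT"])
        if indi_path is not None else None
    )
    ther = (
        _read_delimited(ther_path, "$", ["PRIMARYID", "START_DT"],
                        aliases={"DSG_DRUG_SEQ": ["DRUG_SEQ"]})
        if ther_path is not None else None
    )

    universe = set(demo["PRIMARYID"])
    drug = _drop_orphans(drug, universe, "DRUG")
    reac = _drop_orphans(reac, universe, "REAC")
    if indi is not None:
        indi = _drop_orphans(indi, universe, "INDI")
    if ther is not None:
        ther = _drop_orphans(ther, universe, "THER")

    # therapy start dates keyed by (report, drug sequence)
    starts: dict[tuple[str, str], PartialDate] = {}
    if ther is not None and "DSG_DRUG_SEQ" in ther.columns:
        for pid, seq, dt in zip(ther["PRIMARYID"], ther["DSG_DRUG_SEQ"], ther["START_DT"]):
            d = PartialDate.parse(dt)
            if d is not None:
                starts.setdefault((pid, str(seq)), d)

    drugs_by_report: dict[str, list[DrugEntry]] = {}
    for row in drug.itertuples(index=False):
        pid = row.PRIMARYID
        name = str(row.DRUGNAME).strip()
        if not name:
            continue
        seq = str(getattr(row, "DRUG_SEQ", "")) if hasattr(row, "DRUG_SEQ") else ""
        role = FAERS_ROLE_CODES.get(str(row.ROLE_COD).strip().upper(), Role.CONCOMITANT)
        entry = DrugEntry(
            name_raw=name,
            name_normalized=_norm(name),
            role=role,
            ingredient=_norm(getattr(row, "PROD_AI", "")),
            route_raw=(str(getattr(row, "ROUTE", "")).strip() or None),
            start_date=starts.get((pid, seq)),
        )
        drugs_by_report.setdefault(pid, []).append(entry)

    events_by_report: dict[str, list[str]] = {}
    for pid, pt in zip(reac["PRIMARYID"], reac["PT"]):
        if str(pt).strip():
            events_by_report.setdefault(pid, []).append(str(pt))

    indi_by_report: dict[str, list[str]] = {}
    if indi is not None:
        for pid, pt in zip(indi["PRIMARYID"], indi["INDI_PT"]):
            s = _norm(pt)
            if s and s not in ("product used for unknown indication",):
                lst = indi_by_report.setdefault(pid, [])
                if s not in lst:
                    lst.append(s)

    gender_map = {"M": Gender.MALE, "F": Gender.FEMALE}
    reports: list[SafetyReport] = []
    for row in demo.itertuples(index=False):
        pid = row.PRIMARYID
        entries = drugs_by_report.get(pid, [])
        reports.append(SafetyReport(
            report_key=str(pid),
            case_key=str(row.CASEID),
            receipt_date=PartialDate.parse(row.FDA_DT),
            source_db=SourceDb.FAERS,
            gender=gender_map.get(str(getattr(row, "SEX", "")).strip().upper(),
                                  Gender.MISSING),
            age_years=convert_age_to_years(getattr(row, "AGE", None),
                                           getattr(row, "AGE_COD", None)),
            weight_kg=convert_weight_to_kg(getattr(row, "WT", None),
                                           getattr(row, "WT_COD", None)),
            route=_report_route(entries),
            reporter=OCCP_CODES.get(str(getattr(row, "OCCP_COD", "")).strip().upper(),
                                    Reporter.MISSING if not str(getattr(row, "OCCP_COD", "")).strip()
                                    else Reporter.OTHER),
            country=(_norm(getattr(row, "REPORTER_COUNTRY", "")) or None),
            event_date=PartialDate.parse(getattr(row, "EVENT_DT", None)),
            drugs=entries,
            events=events_by_report.get(pid, []),
            indications=indi_by_report.get(pid, []),
        ))
    return reports


# ---------------------------------------------------------------------------
# CVARD parsing

CVARD_GENDER = {"male": Gender.MALE, "m": Gender.MALE,
                "female": Gender.FEMALE, "f": Gender.FEMALE}
CVARD_REPORTER = {
    "physician": Reporter.HCP, "pharmacist": Reporter.HCP,
    "other health professional": Reporter.HCP, "health professional": Reporter.HCP,
    "consumer": Reporter.CONSUMER, "consumer or other non health professional": Reporter.CONSUMER,
    "lawyer": Reporter.OTHER, "other": Reporter.OTHER,
}


def parse_cvard_extract(paths: Mapping[str, str | Path] | str | Path,
                        sep: str = "\t") -> list[SafetyReport]:
    """Parse a Canada Vigilance-style extract into the normalized model.

    ``paths`` is either a directory containing ``reports.tsv``, ``drugs.tsv``
    and ``reactions.tsv``, or a mapping with keys ``reports``, ``drugs``,
    ``reactions``.  The reports table defines the universe (REPORT_ID,
    DATRECEIVED, GENDER_ENG, AGE, AGE_UNIT_ENG, WEIGHT, WEIGHT_UNIT_ENG,
    REPORTER_TYPE_ENG, EVENT_DATE, COUNTRY); drugs carry DRUGNAME,
    DRUGINVOLV_ENG (Suspect/Concomitant), ROUTEADMIN_ENG and
    THERAPY_START_DATE; reactions carry PT_NAME_ENG.  Dates are ISO and may
    be partial (``2013-05``).
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {"reports": base / "reports.tsv", "drugs": base / "drugs.tsv",
                 "reactions": base / "reactions.tsv"}
    rep = _read_delimited(paths["reports"], sep, ["REPORT_ID", "DATRECEIVED"])
    if len(rep) == 0:
        raise EmptyStoreError("CVARD reports table is empty")
    drg = _read_delimited(paths["drugs"], sep, ["REPORT_ID", "DRUGNAME", "DRUGINVOLV_ENG"])
    rxn = _read_delimited(paths["reactions"], sep, ["REPORT_ID", "PT_NAME_ENG"])

    universe = set(rep["REPORT_ID"])
    drg = drg[drg["REPORT_ID"].isin(universe)]
    rxn = rxn[rxn["REPORT_ID"].isin(universe)]

    drugs_by_report: dict[str, list[DrugEntry]] = {}
    for row in drg.itertuples(index=False):
        name = str(row.DRUGNAME).strip()
        if not name:
            continue
        role = CVARD_ROLE_CODES.get(_norm(row.DRUGINVOLV_ENG), Role.CONCOMITANT)
        drugs_by_report.setdefault(row.REPORT_ID, []).append(DrugEntry(
            name_raw=name,
            name_normalized=_norm(name),
            role=role,
            ingredient=_norm(getattr(row, "ACTIVE_INGREDIENT_NAME", "")),
            route_raw=(str(getattr(row, "ROUTEADMIN_ENG", "")).strip() or None),
            start_date=PartialDate.parse(getattr(row, "THERAPY_START_DATE", None)),
        ))

    events_by_report: dict[str, list[str]] = {}
    for rid, pt in zip(rxn["REPORT_ID"], rxn["PT_NAME_ENG"]):
        if str(pt).strip():
            events_by_report.setdefault(rid, []).append(str(pt))

    reports: list[SafetyReport] = []
    for row in rep.itertuples(index=False):
        rid = row.REPORT_ID
        entries = drugs_by_report.get(rid, [])
        reports.append(SafetyReport(
            report_key=str(rid),
            case_key=str(getattr(row, "CASE_ID", rid) or rid),
            receipt_date=PartialDate.parse(row.DATRECEIVED),
            source_db=SourceDb.CVARD,
            gender=CVARD_GENDER.get(_norm(getattr(row, "GENDER_ENG", "")), Gender.MISSING),
            age_years=convert_age_to_years(
                getattr(row, "AGE", None),
                {"years": "YR", "months": "MON", "weeks": "WK", "days": "DY",
                 "decades": "DEC", "hours": "HR"}.get(
                    _norm(getattr(row, "AGE_UNIT_ENG", "years")), "YR")),
            weight_kg=convert_weight_to_kg(
                getattr(row, "WEIGHT", None),
                {"kilograms": "KG", "pounds": "LBS"}.get(
                    _norm(getattr(row, "WEIGHT_UNIT_ENG", "kilograms")), "KG")),
            route=_report_route(entries),
            reporter=CVARD_REPORTER.get(_norm(getattr(row, "REPORTER_TYPE_ENG", "")),
                                        Reporter.MISSING),
            country=(_norm(getattr(row, "COUNTRY", "")) or None),
            event_date=PartialDate.parse(getattr(row, "EVENT_DATE", None)),
            drugs=entries,
            events=events_by_report.get(rid, []),
            indications=[],
        ))
    return reports


# ---------------------------------------------------------------------------
# Selection, deduplication, exclusion


def select_drug_reports(reports: Sequence[SafetyReport], query: DrugQuery) -> list[SafetyReport]:
    """Reports with >=1 drug entry matching the query names in an accepted role.

    Matching is a case-insensitive substring test against both the product
    name and the active-ingredient field, so combination products containing
    a queried ingredient match.
    """
    names = query.names
    out = []
    for r in reports:
        for d in r.drugs:
            if d.role in query.role_filter and d.matches_name(names):
                out.append(r)
                break
    return out


def _report_key_rank(key: str) -> tuple[int, int | str]:
    # numeric report keys compare by value; non-numeric fall back to string
    k = key.strip()
    return (0, int(k)) if k.isdigit() else (1, k)


def deduplicate(reports: Sequence[SafetyReport]) -> list[SafetyReport]:
    """Collapse case versions: keep the latest receipt date per case id.

    Ties on receipt date keep the larger report key (numeric comparison for
    numeric keys).  Output is sorted by case key, so the operation is
    deterministic and idempotent.
    """
    best: dict[str, SafetyReport] = {}
    for r in reports:
        cur = best.get(r.case_key)
        if cur is None:
            best[r.case_key] = r
            continue
        new_k = (r.receipt_date.sort_key() if r.receipt_date else "",
                 _report_key_rank(r.report_key))
        cur_k = (cur.receipt_date.sort_key() if cur.receipt_date else "",
                 _report_key_rank(cur.report_key))
        if new_k > cur_k:
            best[r.case_key] = r
    return [best[k] for k in sorted(best)]


def load_default_exclusions() -> set[str]:
    """Default event-term exclusion list: indications for the query drug and
    terms unrelated to drug therapy (off label use, medication error, ...)."""
    path = Path(__file__).parent / "data" / "exclusion_terms.tsv"
    return {_norm(line) for line in path.read_text().splitlines() if line.strip()}


def exclude_noise_terms(reports: Sequence[SafetyReport],
                        exclusion_terms: Iterable[str]) -> list[SafetyReport]:
    """Remove excluded PTs from every event list; drop reports left empty.

    Matching is case-insensitive exact PT match.  Counts of removed terms
    and dropped reports are logged.
    """
    excl = {_norm(t) for t in exclusion_terms}
    removed: dict[str, int] = {}
    out: list[SafetyReport] = []
    n_dropped = 0
    for r in reports:
        kept = []
        for e in r.events:
            if e in excl:
                removed[e] = removed.get(e, 0) + 1
            else:
                kept.append(e)
        if not kept:
            n_dropped += 1
            continue
        out.append(replace(r, events=kept) if len(kept) != len(r.events) else r)
    if removed:
        log.info("excluded %d event mentions across %d terms; dropped %d empty reports",
                 sum(removed.values()), len(removed), n_dropped)
    return out


# ---------------------------------------------------------------------------
# Demographic summary


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (2.345 -> 2.35 at 2 digits), as printed tables use."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_demographics(reports: Sequence[SafetyReport], top_k: int = 5) -> pd.DataFrame:
    """Count/percentage table over gender, age band, route, weight band,
    reporter, top-k indications, countries and receipt years.

    Percentages are of the total report count, rounded half-up to one
    decimal.  Requires a non-empty (deduplicated) store.
    """
    if not reports:
        raise EmptyStoreError("cannot summarize an empty store")
    n = len(reports)

    def count_rows(variable: str, values: Iterable[str],
                   order: Sequence[str] | None = None, k: int | None = None):
        counts: dict[str, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        if order is not None:
            items = [(c, counts.get(c, 0)) for c in order]
        else:
            items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            if k is not None:
                items = items[:k]
        return [
            {"variable": variable, "category": c, "count": m,
             "percent": round_half_up(100.0 * m / n)}
            for c, m in items
        ]

    rows: list[dict] = []
    rows += count_rows("gender", (r.gender.value for r in reports),
                       order=["male", "female", "missing"])
    rows += count_rows("age_band", (r.age_band() for r in reports),
                       order=["<18", "18-64", ">=65", "missing"])
    rows += count_rows("route", (r.route.value for r in reports),
                       order=["oral", "topical", "other", "missing"])
    rows += count_rows("weight_band", (r.weight_band() for r in reports),
                       order=["<50", "50-100", ">100", "missing"])
    rows += count_rows("reporter", (r.reporter.value for r in reports),
                       order=["healthcare_professional", "consumer", "other", "missing"])
    rows += count_rows(
        "indication",
        (r.indications[0] if r.indications else "missing" for r in reports), k=top_k)
    rows += count_rows("country", (r.country or "missing" for r in reports), k=top_k)
    rows += count_rows(
        "year",
        (str(r.receipt_date.year) if r.receipt_date else "missing" for r in reports),
        k=top_k)
    return pd.DataFrame(rows, columns=["variable", "category", "count", "percent"])


# ---------------------------------------------------------------------------
# Normalized store serialization (reports.tsv / drugs.tsv / events.tsv)


def _fmt_num(x: float | None) -> str:
    if x is None:
        return ""
    return f"{x:g}"


def write_store(reports: Sequence[SafetyReport], out_dir: str | Path) -> None:
    """Serialize a store as three TSV tables.

    ``reports.tsv``: report_key, case_key, receipt_date, source_db, gender,
    age_years, weight_kg, route, reporter, country, event_date.
    ``drugs.tsv``: report_key, name_raw, role, ingredient, route_raw,
    start_date.  ``events.tsv``: report_key, kind (event|indication), term.
    Dates are ISO at their recorded precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def iso(d: PartialDate | None) -> str:
        return d.isoformat() if d else ""

    pd.DataFrame([
        {"report_key": r.report_key, "case_key": r.case_key,
         "receipt_date": iso(r.receipt_date), "source_db": r.source_db.value,
         "gender": r.gender.value, "age_years": _fmt_num(r.age_years),
         "weight_kg": _fmt_num(r.weight_kg), "route": r.route.value,
         "reporter": r.reporter.value, "country": r.country or "",
         "event_date": iso(r.event_date)}
        for r in reports
    ]).to_csv(out / "reports.tsv", sep="\t", index=False)

    pd.DataFrame([
        {"report_key": r.report_key, "name_raw": d.name_raw, "role": d.role.value,
         "ingredient": d.ingredient, "route_raw": d.route_raw or "",
         "start_date": iso(d.start_date)}
        for r in reports for d in r.drugs
    ], columns=["report_key", "name_raw", "role", "ingredient", "route_raw",
                "start_date"]).to_csv(out / "drugs.tsv", sep="\t", index=False)

    pd.DataFrame(
        [{"report_key": r.report_key, "kind": "event", "term": e}
         for r in reports for e in r.events]
        + [{"report_key": r.report_key, "kind": "indication", "term": t}
           for r in reports for t in r.indications],
        columns=["report_key", "kind", "term"],
    ).to_csv(out / "events.tsv", sep="\t", index=False)


def read_store(in_dir: str | Path) -> list[SafetyReport]:
    """Inverse of :func:`write_store`; round-trips a normalized store."""
    base = Path(in_dir)
    rep = pd.read_csv(base / "reports.tsv", sep="\t", dtype=str, keep_default_na=False)
    drg = pd.read_csv(base / "drugs.tsv", sep="\t", dtype=str, keep_default_na=False)
    evt = pd.read_csv(base / "events.tsv", sep="\t", dtype=str, keep_default_na=False)

    drugs_by_report: dict[str, list[DrugEntry]] = {}
    for row in drg.itertuples(index=False):
        drugs_by_report.setdefault(row.report_key, []).append(DrugEntry(
            name_raw=row.name_raw, name_normalized=_norm(row.name_raw),
            role=Role(row.role), ingredient=row.ingredient,
            route_raw=row.route_raw or None,
            start_date=PartialDate.parse(row.start_date.replace("-", "")) if row.start_date else None,
        ))
    ev_by_report: dict[str, list[str]] = {}
    ind_by_report: dict[str, list[str]] = {}
    for row in evt.itertuples(index=False):
        target = ev_by_report if row.kind == "event" else ind_by_report
        target.setdefault(row.report_key, []).append(row.term)

    out = []
    for row in rep.itertuples(index=False):
        out.append(SafetyReport(
            report_key=row.report_key, case_key=row.case_key,
            receipt_date=PartialDate.parse(row.receipt_date.replace("-", "")) if row.receipt_date else None,
            source_db=SourceDb(row.source_db), gender=Gender(row.gender),
            age_years=float(row.age_years) if row.age_years else None,
            weight_kg=float(row.weight_kg) if row.weight_kg else None,
            route=RouteGroup(row.route), reporter=Reporter(row.reporter),
            country=row.country or None,
            event_date=PartialDate.parse(row.event_date.replace("-", "")) if row.event_date else None,
            drugs=drugs_by_report.get(row.report_key, []),
            events=ev_by_report.get(row.report_key, []),
            indications=ind_by_report.get(row.report_key, []),
        ))
    return out
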