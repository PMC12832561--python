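"""FAERS-shaped synthetic report generator with known ground truth.

The regulatory extracts behind a real pharmacovigilance study cannot be
bundled, so this module simulates a spontaneous-report database whose
structure matches what the pipeline ingests: case-versioned duplicate
reports, demographic marginals with realistic missingness (about half of
ages and nearly three quarters of weights missing, as in the roflumilast
FAERS case study), a drug-event multinomial background with planted
relative-risk signals, indication-term contamination of event lists, and
Weibull-distributed onset dates for a configurable fraction of reports.

Every draw comes from one seeded generator, so runs are fully
reproducible, and a ground-truth manifest records the planted pairs and
injected duplicates for later verification.  ``pair_report_counts`` exposes
the same drug/event assignment draw as a count matrix without building
report objects, which keeps large calibration studies (hundreds of
replicates at 1e5 reports) cheap; both paths consume the generator state
identically, so their counts agree exactly for a given seed.
"""

from __future__ import annotations

import datetime
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .report_store import (DrugEntry, Gender, PartialDate, Reporter, Role,
                           RouteGroup, SafetyReport, SourceDb)
from .vocabulary import EventVocabulary

log = logging.getLogger(__name__)

#: demographic marginals matching the case study's report mix
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "gender": {"male": 0.457, "female": 0.412, "missing": 0.131},
    "age_band": {"<18": 0.002, "18-64": 0.133, ">=65": 0.349, "missing": 0.516},
    "route": {"oral": 0.895, "topical": 0.077, "other": 0.028},
    "weight_band": {"<50": 0.030, "50-100": 0.214, ">100": 0.026, "missing": 0.730},
    "reporter": {"healthcare_professional": 0.302, "consumer": 0.359,
                 "other": 0.232, "missing": 0.107},
}


def drug_name(i: int) -> str:
    return f"drug_{i:03d}"


def event_name(i: int) -> str:
    return f"pt_{i:03d}"


def synthetic_vocabulary(n_events: int, n_socs: int = 10) -> EventVocabulary:
    """A synthetic PT -> SOC map assigning PTs to SOCs round-robin."""
    return EventVocabulary(pt_to_soc={
        event_name(i): f"soc_{i % n_socs:02d}" for i in range(n_events)})


@dataclass
class SyntheticConfig:
    """Full parameterization of the synthetic report store.

    Defaults emulate the study conditions of the roflumilast case study:
    events per report average 2.9 (truncated Poisson, min 1), onset times
    follow an early-failure Weibull (shape 0.8, scale 30 days) and are
    recorded for ~16.7% of reports, and demographic marginals carry the
    heavy missingness typical of spontaneous reports.
    """

    n_reports: int = 10_000
    n_drugs: int = 10
    n_events: int = 200
    background_event_probs: np.ndarray | None = None  # default: Zipf-like
    drug_probs: np.ndarray | None = None              # default: uniform
    planted_signals: list[tuple[int, int, float]] = field(default_factory=list)
    events_per_report_mean: float = 2.9
    demographics: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_DEMOGRAPHICS)
    duplicate_rate: float = 0.10
    tto_weibull_scale: float = 30.0
    tto_weibull_shape: float = 0.8
    tto_fraction_with_dates: float = 0.167
    indication_terms: list[str] = field(default_factory=lambda: [
        "chronic obstructive pulmonary disease", "psoriasis"])
    indication_contamination_rate: float = 0.05
    seed: int = 0

    def validation_errors(self) -> list[str]:
        errs = []
        if self.n_reports < 1:
            errs.append("n_reports must be >= 1")
        if self.n_drugs < 1 or self.n_events < 1:
            errs.append("n_drugs and n_events must be >= 1")
        for drug, event, rr in self.planted_signals:
            if not (0 <= drug < self.n_drugs and 0 <= event < self.n_events):
                errs.append(f"planted signal ({drug},{event}) out of range")
            if rr <= 0:
                errs.append(f"relative_risk must be > 0, got {rr}")
        if self.events_per_report_mean <= 1:
            errs.append("events_per_report_mean must exceed the truncation floor 1")
        if not 0 <= self.duplicate_rate < 1:
            errs.append("duplicate_rate must lie in [0, 1)")
        if not 0 <= self.tto_fraction_with_dates <= 1:
            errs.append("tto_fraction_with_dates must lie in [0, 1]")
        if self.tto_weibull_scale <= 0 or self.tto_weibull_shape <= 0:
            errs.append("Weibull parameters must be positive")
        if not 0 <= self.indication_contamination_rate <= 1:
            errs.append("indication_contamination_rate must lie in [0, 1]")
        for var, marg in self.demographics.items():
            probs = np.array(list(marg.values()), dtype=float)
            if (probs < 0).any() or (probs > 1).any() or abs(probs.sum() - 1) > 1e-6:
                errs.append(f"demographic marginal {var!r} is not a distribution")
        for name, vec in (("background_event_probs", self.background_event_probs),
                          ("drug_probs", self.drug_probs)):
            if vec is not None:
                v = np.asarray(vec, dtype=float)
                if (v < 0).any() or abs(v.sum() - 1) > 1e-6:
                    errs.append(f"{name} is not a probability vector")
        return errs

    def event_probs(self) -> np.ndarray:
        if self.background_event_probs is not None:
            return np.asarray(self.background_event_probs, dtype=float)
        # Zipf-like background: a few frequent PTs, a long tail
        w = 1.0 / np.arange(1, self.n_events + 1)
        return w / w.sum()

    def drug_probabilities(self) -> np.ndarray:
        if self.drug_probs is not None:
            return np.asarray(self.drug_probs, dtype=float)
        return np.full(self.n_drugs, 1.0 / self.n_drugs)


def _truncated_poisson_rate(mean: float) -> float:
    """Rate lambda such that a zero-truncated Poisson has the given mean."""
    f = lambda lam: lam / -math.expm1(-lam) - mean
    return optimize.brentq(f, 1e-9, 10 * mean)


def _draw_assignments(config: SyntheticConfig, rng: np.random.Generator):
    """Drug index and distinct event set per report (shared sampling core).

    Events are drawn with replacement from the (per-drug, RR-tilted)
    background distribution and uniquified, matching the report-level
    counting unit.  Returns (drug_idx, unique pair codes report*K+event).
    """
    n, n_events = config.n_reports, config.n_events
    drug_idx = rng.choice(config.n_drugs, size=n, p=config.drug_probabilities())
    lam = _truncated_poisson_rate(config.events_per_report_mean)
    k = rng.poisson(lam, size=n)
    while True:  # zero-truncation by redraw
        zero = k == 0
        if not zero.any():
            break
        k[zero] = rng.poisson(lam, size=int(zero.sum()))

    base = config.event_probs()
    tilts: dict[int, np.ndarray] = {}
    for drug, event, rr in config.planted_signals:
        p = tilts.get(drug, base.copy())
        p[event] *= rr
        tilts[drug] = p
    pair_codes = []
    for d in range(config.n_drugs):
        mask = drug_idx == d
        if not mask.any():
            continue
        p = tilts.get(d, base)
        p = p / p.sum()
        kk = k[mask]
        draws = rng.choice(n_events, size=int(kk.sum()), p=p)
        report_ids = np.repeat(np.flatnonzero(mask), kk)
        pair_codes.append(np.unique(report_ids.astype(np.int64) * n_events + draws))
    codes = np.concatenate(pair_codes) if pair_codes else np.empty(0, dtype=np.int64)
    return drug_idx, np.sort(codes)


def pair_report_counts(config: SyntheticConfig,
                       rng: np.random.Generator | None = None):
    """Report-level (drug, event) count matrix without building reports.

    Returns ``(counts, reports_per_drug)`` where ``counts[d, e]`` is the
    number of reports assigned to drug ``d`` whose event set contains
    event ``e``.  Consumes generator state exactly as :func:`generate`
    does for the same draw, so the two paths agree for a given seed.
    """
    errs = config.validation_errors()
    if errs:
        raise ValueError("invalid SyntheticConfig: " + "; ".join(errs))
    if rng is None:
        rng = np.random.default_rng(config.seed)
    drug_idx, codes = _draw_assignments(config, rng)
    counts = np.zeros((config.n_drugs, config.n_events), dtype=np.int64)
    report_of = (codes // config.n_events).astype(np.int64)
    event_of = (codes % config.n_events).astype(np.int64)
    np.add.at(counts, (drug_idx[report_of], event_of), 1)
    reports_per_drug = np.bincount(drug_idx, minlength=config.n_drugs)
    return counts, reports_per_drug


_BAND_AGE = {"<18": (2, 17), "18-64": (18, 64), ">=65": (65, 90)}
_BAND_WT = {"<50": (35.0, 49.5), "50-100": (50.0, 100.0), ">100": (100.5, 140.0)}
_ROUTE_RAW = {"oral": "Oral", "topical": "Topical", "other": "OTHER"}
_EPOCH = datetime.date(2011, 1, 1)
_WINDOW_DAYS = (datetime.date(2024, 12, 31) - _EPOCH).days


def _date_from_offset(offset: int) -> PartialDate:
    d = _EPOCH + datetime.timedelta(days=int(offset))
    return PartialDate(d.year, d.month, d.day)


def generate(config: SyntheticConfig) -> tuple[list[SafetyReport], dict]:
    """Draw a raw (pre-deduplication) report store plus ground-truth manifest.

    Reports are independent: drug assignment is multinomial, event lists
    come from the RR-tilted background, demographics from the configured
    marginals.  A ``duplicate_rate`` fraction of cases is emitted twice —
    the clone differs only in report key and a later receipt date, so
    deduplication must recover exactly the original case set.  The manifest
    records planted pairs, duplicated case keys, and the case universe.
    """
    errs = config.validation_errors()
    if errs:
        raise ValueError("invalid SyntheticConfig: " + "; ".join(errs))
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    drug_idx, codes = _draw_assignments(config, rng)
    events_by_report: dict[int, list[str]] = {}
    for code in codes:
        events_by_report.setdefault(int(code) // config.n_events, []).append(
            event_name(int(code) % config.n_events))

    def draw_marginal(var: str) -> np.ndarray:
        marg = config.demographics[var]
        cats = list(marg)
        probs = np.array([marg[c] for c in cats], dtype=float)
        return np.array(cats, dtype=object)[rng.choice(len(cats), size=n, p=probs / probs.sum())]

    gender = draw_marginal("gender")
    age_band = draw_marginal("age_band")
    route = draw_marginal("route")
    weight_band = draw_marginal("weight_band")
    reporter = draw_marginal("reporter")

    receipt_offsets = rng.integers(0, _WINDOW_DAYS + 1, size=n)
    has_tto = rng.random(n) < config.tto_fraction_with_dates
    tto_days = np.ceil(config.tto_weibull_scale *
                       rng.weibull(config.tto_weibull_shape, size=n)).astype(int)
    tto_days = np.maximum(tto_days, 1)
    start_offsets = rng.integers(0, _WINDOW_DAYS - 3700, size=n)
    has_indication = rng.random(n) < 0.5
    indication_pick = rng.integers(0, max(len(config.indication_terms), 1), size=n)
    contaminate = rng.random(n) < config.indication_contamination_rate

    ages = np.zeros(n)
    weights = np.zeros(n)
    for band, (lo, hi) in _BAND_AGE.items():
        m = age_band == band
        ages[m] = rng.integers(lo, hi + 1, size=int(m.sum()))
    for band, (lo, hi) in _BAND_WT.items():
        m = weight_band == band
        weights[m] = np.round(rng.uniform(lo, hi, size=int(m.sum())), 1)

    reports: list[SafetyReport] = []
    for i in range(n):
        d = int(drug_idx[i])
        evs = events_by_report.get(i, [event_name(0)])
        inds: list[str] = []
        if config.indication_terms and has_indication[i]:
            inds = [config.indication_terms[int(indication_pick[i]) % len(config.indication_terms)]]
        if config.indication_terms and contaminate[i]:
            term = config.indication_terms[int(indication_pick[i]) % len(config.indication_terms)]
            if term not in evs:
                evs = [*evs, term]
        start = _date_from_offset(start_offsets[i]) if has_tto[i] else None
        event_date = (_date_from_offset(start_offsets[i] + tto_days[i])
                      if has_tto[i] else None)
        entry = DrugEntry(
            name_raw=drug_name(d).upper(), name_normalized=drug_name(d),
            role=Role.PRIMARY_SUSPECT, ingredient=drug_name(d),
            route_raw=_ROUTE_RAW.get(str(route[i])), start_date=start)
        reports.append(SafetyReport(
            report_key=str(100_000_000 + 10 * i),
            case_key=f"C{i:08d}",
            receipt_date=_date_from_offset(receipt_offsets[i]),
            source_db=SourceDb.FAERS,
            gender=Gender(str(gender[i])),
            age_years=float(ages[i]) if age_band[i] != "missing" else None,
            weight_kg=float(weights[i]) if weight_band[i] != "missing" else None,
            route=RouteGroup(str(route[i])) if route[i] != "missing" else RouteGroup.MISSING,
            reporter=Reporter(str(reporter[i])),
            country="united states",
            event_date=event_date,
            drugs=[entry],
            events=evs,
            indications=inds,
        ))

    # duplicate case versions: exact clones except report key / receipt date
    n_dup = int(round(config.duplicate_rate * n))
    dup_cases = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], int)
    duplicates = []
    for i in sorted(int(j) for j in dup_cases):
        orig = reports[i]
        offset = min(int(receipt_offsets[i]) + 90, _WINDOW_DAYS)
        dup = SafetyReport(
            report_key=str(100_000_000 + 10 * i + 1),
            case_key=orig.case_key,
            receipt_date=_date_from_offset(offset),
            source_db=orig.source_db, gender=orig.gender,
            age_years=orig.age_years, weight_kg=orig.weight_kg,
            route=orig.route, reporter=orig.reporter, country=orig.country,
            event_date=orig.event_date, drugs=list(orig.drugs),
            events=list(orig.events), indications=list(orig.indications))
        duplicates.append(dup)

    manifest = {
        "planted_signals": [(drug_name(d), event_name(e), rr)
                            for d, e, rr in config.planted_signals],
        "case_keys": [r.case_key for r in reports],
        "duplicated_case_keys": [d.case_key for d in duplicates],
        "n_cases": n,
        "seed": config.seed,
    }
    return [*reports, *duplicates], manifest


# ---------------------------------------------------------------------------
# FAERS fixture emission (inverse of report_store.parse_faers_quarter)


def write_faers_fixture(reports: Sequence[SafetyReport], out_dir: str | Path) -> dict[str, Path]:
    """Emit DEMO/DRUG/REAC/INDI/THER in the '$'-delimited quarterly dialect.

    The emitted files parse back (via ``parse_faers_quarter``) to a store
    equal to the input, which is the round-trip property the tests hold.
    """
    if not reports:
        raise ValueError("empty store")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def faers_date(d: PartialDate | None) -> str:
        if d is None:
            return ""
        s = f"{d.year:04d}"
        if d.month is not None:
            s += f"{d.month:02d}"
            if d.day is not None:
                s += f"{d.day:02d}"
        return s

    gender_code = {Gender.MALE: "M", Gender.FEMALE: "F", Gender.MISSING: ""}
    occp_code = {Reporter.HCP: "MD", Reporter.CONSUMER: "CN",
                 Reporter.OTHER: "LW", Reporter.MISSING: ""}
    role_code = {v: k for k, v in
                 {"PS": Role.PRIMARY_SUSPECT, "SS": Role.SECONDARY_SUSPECT,
                  "C": Role.CONCOMITANT, "I": Role.INTERACTING}.items()}

    demo_rows, drug_rows, reac_rows, indi_rows, ther_rows = [], [], [], [], []
    for r in reports:
        demo_rows.append({
            "PRIMARYID": r.report_key, "CASEID": r.case_key,
            "FDA_DT": faers_date(r.receipt_date),
            "AGE": "" if r.age_years is None else f"{r.age_years:g}",
            "AGE_COD": "" if r.age_years is None else "YR",
            "SEX": gender_code[r.gender],
            "WT": "" if r.weight_kg is None else f"{r.weight_kg:g}",
            "WT_COD": "" if r.weight_kg is None else "KG",
            "OCCP_COD": occp_code[r.reporter],
            "REPORTER_COUNTRY": r.country or "",
            "EVENT_DT": faers_date(r.event_date),
        })
        for seq, d in enumerate(r.drugs, start=1):
            drug_rows.append({
                "PRIMARYID": r.report_key, "DRUG_SEQ": seq,
                "ROLE_COD": role_code.get(d.role, "PS"),
                "DRUGNAME": d.name_raw, "PROD_AI": d.ingredient.upper(),
                "ROUTE": d.route_raw or ""})
            if d.start_date is not None:
                ther_rows.append({"PRIMARYID": r.report_key, "DSG_DRUG_SEQ": seq,
                                  "START_DT": faers_date(d.start_date)})
        for e in r.events:
            reac_rows.append({"PRIMARYID": r.report_key, "PT": e})
        for t in r.indications:
            indi_rows.append({"PRIMARYID": r.report_key, "INDI_DRUG_SEQ": 1,
                              "INDI_PT": t})

    paths = {}
    for name, rows, cols in (
        ("DEMO", demo_rows, ["PRIMARYID", "CASEID", "FDA_DT", "AGE", "AGE_COD",
                             "SEX", "WT", "WT_COD", "OCCP_COD",
                             "REPORTER_COUNTRY", "EVENT_DT"]),
        ("DRUG", drug_rows, ["PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME",
                             "PROD_AI", "ROUTE"]),
        ("REAC", reac_rows, ["PRIMARYID", "PT"]),
        ("INDI", indi_rows, ["PRIMARYID", "INDI_DRUG_SEQ", "INDI_PT"]),
        ("THER", ther_rows, ["PRIMARYID", "DSG_DRUG_SEQ", "START_DT"]),
    ):
        path = out / f"{name}.txt"
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="$", index=False)
        paths[name] = path
    return paths


def build_reference_marginals_store(
    marginals_path: str | Path | None = None) -> list[SafetyReport]:
    """Deterministic store whose demographic marginals match a count table.

    Reads a (variable, category, count) TSV — the shipped file carries the
    roflumilast FAERS report mix — and assigns each attribute column-wise
    in blocks, so every marginal is reproduced exactly.  Used to exercise
    the demographic summarizer against known printed percentages.
    """
    if marginals_path is None:
        marginals_path = Path(__file__).parent / "data" / "reference_demographics.tsv"
    df = pd.read_csv(marginals_path, sep="\t", dtype={"count": int})
    by_var: dict[str, list[tuple[str, int]]] = {}
    for row in df.itertuples(index=False):
        by_var.setdefault(row.variable, []).append((str(row.category), int(row.count)))
    totals = {v: sum(c for _, c in cats) for v, cats in by_var.items()}
    if len(set(totals.values())) != 1:
        raise ValueError(f"marginal totals disagree: {totals}")
    n = next(iter(totals.values()))

    def expand(var: str) -> list[str]:
        out: list[str] = []
        for cat, cnt in by_var[var]:
            out.extend([cat] * cnt)
        return out

    gender = expand("gender")
    age_band = expand("age_band")
    route = expand("route")
    weight = expand("weight_band")
    reporter = expand("reporter")
    indication = expand("indication")
    country = expand("country")
    year = expand("year")

    band_age = {"<18": 10.0, "18-64": 45.0, ">=65": 72.0}
    band_wt = {"<50": 45.0, "50-100": 70.0, ">100": 110.0}
    reports = []
    for i in range(n):
        reports.append(SafetyReport(
            report_key=str(200_000_000 + i), case_key=f"R{i:07d}",
            receipt_date=PartialDate(int(year[i]), 6, 15),
            source_db=SourceDb.FAERS,
            gender=Gender(gender[i]),
            age_years=band_age.get(age_band[i]),
            weight_kg=band_wt.get(weight[i]),
            route=RouteGroup(route[i]),
            reporter=Reporter(reporter[i]),
            country=None if country[i] == "missing" else country[i],
            drugs=[DrugEntry(name_raw="ROFLUMILAST", name_normalized="roflumilast",
                             role=Role.PRIMARY_SUSPECT, ingredient="roflumilast")],
            events=["diarrhoea"],
            indications=[] if indication[i] == "missing" else [indication[i]],
        ))
    return reports
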