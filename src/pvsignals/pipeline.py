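"""Pipeline orchestration and publication-style tabular outputs.

``run_pipeline`` executes the full analysis in order — ingest, deduplicate,
select the query drug, strip noise terms, build contingency tables, compute
the four disproportionality statistics with labeledness, characterize
time-to-onset, run subgroup comparisons and the co-medication sensitivity
reanalysis — writing one TSV per stage plus a log of record counts at every
step, so the report flow can be audited like a screening diagram.
``render_tables`` reformats those outputs in the style of a publication:
statistics to two decimals, intervals in parentheses, positivity markers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import contingency, report_store, signal_stats, subgroup_sensitivity, tto_weibull
from .report_store import (DrugQuery, Role, SafetyReport, round_half_up)
from .vocabulary import (Agency, classify_labeledness, load_fixture_vocabulary,
                         load_label_dictionaries, load_vocabulary)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Either ``store_dir`` (a normalized store) or ``faers_dirs`` (quarter
    directories containing DEMO/DRUG/REAC/INDI/THER .txt files) must be
    set.  The resolved config is written beside the outputs of every run.
    """

    out_dir: str
    store_dir: str | None = None
    faers_dirs: list[str] = field(default_factory=list)
    vocabulary_path: str | None = None  # None -> shipped fixture vocabulary
    generic_names: list[str] = field(default_factory=lambda: ["roflumilast"])
    trade_names: list[str] = field(default_factory=lambda: ["daliresp", "daxas", "zoryve"])
    role_filter: list[str] = field(default_factory=lambda: ["primary_suspect", "suspect"])
    exclusion_terms: list[str] | None = None  # None -> shipped defaults
    min_count: int = 1
    top_k_events: int = 50
    forest_min_count: int = 30
    comedications: list[str] | None = None  # None -> shipped defaults
    tto_cap_days: int = tto_weibull.DEFAULT_TTO_CAP_DAYS
    subgroups: list[dict] = field(default_factory=lambda: [
        {"variable": "gender", "target": "female", "control": "male"},
        {"variable": "age_band", "target": ">=65", "control": "18-64"},
        {"variable": "route", "target": "oral", "control": "topical"},
    ])
    seed: int = 20110401  # quarter the drug entered the pharmacovigilance window

    def validate(self) -> None:
        if not self.store_dir and not self.faers_dirs:
            raise ValueError("config must set store_dir or faers_dirs")
        if self.store_dir and not Path(self.store_dir).exists():
            raise ValueError(f"store_dir does not exist: {self.store_dir}")
        for d in self.faers_dirs:
            if not Path(d).exists():
                raise ValueError(f"faers dir does not exist: {d}")
        if self.vocabulary_path is not None and not Path(self.vocabulary_path).exists():
            raise ValueError(f"vocabulary path does not exist: {self.vocabulary_path}")
        if not (self.generic_names or self.trade_names):
            raise ValueError("drug query is empty")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")

    def query(self) -> DrugQuery:
        return DrugQuery(
            generic_names=frozenset(self.generic_names),
            trade_names=frozenset(self.trade_names),
            role_filter=frozenset(Role(r) for r in self.role_filter),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the exit message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _signals_frame(results: Sequence[signal_stats.SignalResult],
                   label_dicts=None) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "event": r.event_name, "level": r.level, "n": r.n,
            "ror": r.ror, "ror_lo": r.ror_lo, "ror_hi": r.ror_hi,
            "prr": r.prr, "chi2": r.chi2, "ic": r.ic, "ic025": r.ic025,
            "ebgm": r.ebgm, "ebgm05": r.ebgm05,
            "flag_ror": r.flags.get("ror", False),
            "flag_prr": r.flags.get("prr", False),
            "flag_bcpnn": r.flags.get("bcpnn", False),
            "flag_mgps": r.flags.get("mgps", False),
            "positive_any": r.positive_any, "positive_all": r.positive_all,
        }
        if label_dicts is not None and r.level == "pt":
            lab = classify_labeledness(r.event_name, label_dicts.values())
            row["fda_label"] = lab[Agency.FDA].value
            row["canada_label"] = lab[Agency.CANADA].value
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage in order; returns the output directory.

    Any stage failure raises :class:`StageError` naming the stage, which
    the CLI converts to a nonzero exit status.
    """
    config.validate()  # before any ingestion
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: list[tuple[str, int]] = []

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S"))
    root = logging.getLogger("pvsignals")
    root.addHandler(handler)
    try:
        return _run_stages(config, out, counts)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_stages(config: PipelineConfig, out: Path,
                counts: list[tuple[str, int]]) -> Path:
    vocab = (load_vocabulary(config.vocabulary_path) if config.vocabulary_path
             else load_fixture_vocabulary())
    label_dicts = load_label_dictionaries()

    def run_stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError(name, exc) from exc

    def ingest() -> list[SafetyReport]:
        if config.store_dir:
            return report_store.read_store(config.store_dir)
        reports: list[SafetyReport] = []
        for d in config.faers_dirs:
            base = Path(d)
            reports.extend(report_store.parse_faers_quarter(
                base / "DEMO.txt", base / "DRUG.txt", base / "REAC.txt",
                base / "INDI.txt" if (base / "INDI.txt").exists() else None,
                base / "THER.txt" if (base / "THER.txt").exists() else None))
        return reports

    store = run_stage("ingest", ingest)
    counts.append(("raw_reports", len(store)))

    deduped = run_stage("deduplicate", lambda: report_store.deduplicate(store))
    counts.append(("deduplicated", len(deduped)))

    selected = run_stage("select", lambda: report_store.select_drug_reports(
        deduped, config.query()))
    target_keys = {r.report_key for r in selected}
    background = [r for r in deduped if r.report_key not in target_keys]
    counts.append(("target_selected", len(selected)))

    def exclude_noise():
        excl = (set(config.exclusion_terms) if config.exclusion_terms is not None
                else report_store.load_default_exclusions())
        return (report_store.exclude_noise_terms(selected, excl),
                report_store.exclude_noise_terms(background, excl))

    target, bg = run_stage("exclude_noise", exclude_noise)
    counts.append(("target_after_exclusions", len(target)))
    counts.append(("background_after_exclusions", len(bg)))

    def demographics():
        df = report_store.summarize_demographics(target)
        df.to_csv(out / "demographics.tsv", sep="\t", index=False)
        return df

    run_stage("demographics", demographics)

    def signals():
        prior_tables = contingency.pair_tables_for_prior([*target, *bg])
        mgps_priors = (signal_stats.fit_mgps_priors(prior_tables, seed=config.seed)
                       if len(prior_tables) >= 50 else None)
        out_frames = {}
        for level in (contingency.Level.PT, contingency.Level.SOC):
            tables = contingency.build_all(target, bg, level, vocab,
                                           min_count=config.min_count)
            results = signal_stats.compute_signals(tables, mgps_priors)
            df = _signals_frame(results, label_dicts if level is contingency.Level.PT else None)
            df.to_csv(out / f"signals_{level.value}.tsv", sep="\t", index=False)
            out_frames[level.value] = (tables, results, df)
        return out_frames, mgps_priors

    signal_frames, mgps_priors = run_stage("signals", signals)
    counts.append(("pt_events", len(signal_frames["pt"][0])))
    counts.append(("soc_events", len(signal_frames["soc"][0])))

    def tto():
        records = tto_weibull.extract_tto(target, config.query(),
                                          cap_days=config.tto_cap_days)
        if not records:
            log.warning("no usable TTO records; skipping Weibull stage")
            return None
        summary = tto_weibull.tto_summary(records)
        summary["bins"].to_csv(out / "tto_summary.tsv", sep="\t", index=False)
        tto_weibull.cumulative_incidence(records).to_csv(
            out / "cumulative_incidence.tsv", sep="\t", index=False)
        try:
            fit = tto_weibull.weibull_fit(records)
        except ValueError as exc:
            log.warning("Weibull fit unavailable: %s", exc)
            return summary
        pd.DataFrame([{
            "scale_alpha": fit.scale_alpha, "scale_lo": fit.scale_ci[0],
            "scale_hi": fit.scale_ci[1], "shape_beta": fit.shape_beta,
            "shape_lo": fit.shape_ci[0], "shape_hi": fit.shape_ci[1],
            "n": fit.n, "failure_class": fit.failure_class.value,
            "median_tto": summary["median"], "iqr_lo": summary["iqr"][0],
            "iqr_hi": summary["iqr"][1],
        }]).to_csv(out / "weibull.tsv", sep="\t", index=False)
        return summary

    run_stage("tto", tto)

    def subgroups():
        for sg in config.subgroups:
            try:
                res = subgroup_sensitivity.subgroup_ror(
                    target, sg["variable"], sg["target"], sg["control"],
                    top_k=config.top_k_events)
            except ValueError as exc:
                log.warning("subgroup %s skipped: %s", sg["variable"], exc)
                continue
            subgroup_sensitivity.results_to_frame(res).to_csv(
                out / f"subgroup_{sg['variable']}.tsv", sep="\t", index=False)

    run_stage("subgroups", subgroups)

    def sensitivity():
        comeds = (config.comedications if config.comedications is not None
                  else subgroup_sensitivity.load_default_comedications())
        kept = subgroup_sensitivity.exclude_comedications(target, comeds)
        counts.append(("sensitivity_reports", len(kept)))
        tables = contingency.build_all(kept, bg, contingency.Level.PT, vocab,
                                       min_count=config.min_count)
        results = signal_stats.compute_signals(tables, mgps_priors)
        df = _signals_frame(results, label_dicts)
        df.insert(0, "analysis", "sensitivity")
        df.to_csv(out / "sensitivity_signals_pt.tsv", sep="\t", index=False)

    run_stage("sensitivity", sensitivity)

    pd.DataFrame(counts, columns=["stage", "n_reports"]).to_csv(
        out / "flow_counts.tsv", sep="\t", index=False)
    config.to_yaml(out / "resolved_config.yaml")
    for name, n in counts:
        log.info("flow count %s = %d", name, n)
    return out


# ---------------------------------------------------------------------------
# Publication-style rendering


def _fmt(x: float, nd: int = 2) -> str:
    if pd.isna(x):
        return ""
    if x == float("inf"):
        return "inf"
    return f"{round_half_up(float(x), nd):.{nd}f}"


def render_tables(out_dir: str | Path, forest_min_count: int = 30) -> list[Path]:
    """Format pipeline outputs as publication-style tables.

    Writes a demographics table, a SOC signal-strength table with interval
    parentheses and positivity markers (one ``*`` per positive algorithm),
    a PT forest table restricted to positive PTs with at least
    ``forest_min_count`` reports, and one formatted table per subgroup.
    """
    out = Path(out_dir)
    written: list[Path] = []

    demo_path = out / "demographics.tsv"
    if demo_path.exists():
        df = pd.read_csv(demo_path, sep="\t")
        df["case_proportion"] = df["percent"].map(lambda p: f"{p:.1f}%")
        p = out / "table_demographics.tsv"
        df[["variable", "category", "count", "case_proportion"]].to_csv(
            p, sep="\t", index=False)
        written.append(p)

    soc_path = out / "signals_soc.tsv"
    if soc_path.exists():
        df = pd.read_csv(soc_path, sep="\t")
        rows = []
        for r in df.itertuples(index=False):
            mark = lambda flag: "*" if flag else ""
            rows.append({
                "soc": r.event, "case_number": r.n,
                "ror_ci": f"{_fmt(r.ror)} ({_fmt(r.ror_lo)}, {_fmt(r.ror_hi)}){mark(r.flag_ror)}",
                "prr_chi2": f"{_fmt(r.prr)} ({_fmt(r.chi2)}){mark(r.flag_prr)}",
                "ebgm_ebgm05": f"{_fmt(r.ebgm)} ({_fmt(r.ebgm05)}){mark(r.flag_mgps)}",
                "ic_ic025": f"{_fmt(r.ic)} ({_fmt(r.ic025)}){mark(r.flag_bcpnn)}",
                "n_positive_algorithms": int(r.flag_ror) + int(r.flag_prr)
                + int(r.flag_bcpnn) + int(r.flag_mgps),
            })
        p = out / "table_soc_signals.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written.append(p)

    pt_path = out / "signals_pt.tsv"
    if pt_path.exists():
        df = pd.read_csv(pt_path, sep="\t")
        sel = df[(df["positive_any"]) & (df["n"] >= forest_min_count)].copy()
        sel["ror_ci"] = [
            f"{_fmt(r.ror)} ({_fmt(r.ror_lo)}, {_fmt(r.ror_hi)})"
            for r in sel.itertuples(index=False)]
        cols = ["event", "n", "ror_ci"]
        if "fda_label" in sel.columns:
            cols += ["fda_label", "canada_label"]
        p = out / "table_pt_forest.tsv"
        sel[cols].to_csv(p, sep="\t", index=False)
        written.append(p)

    for sub in sorted(out.glob("subgroup_*.tsv")):
        df = pd.read_csv(sub, sep="\t")
        df["adj_ror_ci"] = [
            f"{_fmt(r.adj_ror)} ({_fmt(r.ci_lo)}, {_fmt(r.ci_hi)})"
            for r in df.itertuples(index=False)]
        df["significant"] = df["p_adj"] < 0.05
        p = out / f"table_{sub.stem}.tsv"
        df[["event", "target", "control", "a", "b", "c", "d",
            "adj_ror_ci", "p", "p_adj", "significant"]].to_csv(
            p, sep="\t", index=False)
        written.append(p)
    return written
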