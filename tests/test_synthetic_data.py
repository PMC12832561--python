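"""Generator ground truth: duplicates, round trips, planted signals."""

from __future__ import annotations

import numpy as np
import pytest

from pvsignals.contingency import pair_cells_from_counts
from pvsignals.report_store import (deduplicate, parse_faers_quarter,
                                    select_drug_reports, DrugQuery, Role)
from pvsignals.signal_stats import ror_arrays
from pvsignals.synthetic_data import (SyntheticConfig, build_reference_marginals_store,
                                      drug_name, generate, pair_report_counts,
                                      synthetic_vocabulary, write_faers_fixture)


def test_invalid_config_lists_offending_fields():
    cfg = SyntheticConfig(n_reports=0, duplicate_rate=1.5,
                          planted_signals=[(99, 0, -2.0)])
    errs = cfg.validation_errors()
    text = "; ".join(errs)
    assert "n_reports" in text and "duplicate_rate" in text
    assert "out of range" in text and "relative_risk" in text
    with pytest.raises(ValueError, match="n_reports"):
        generate(cfg)


def test_duplicates_deduplicate_back_to_case_set():
    cfg = SyntheticConfig(n_reports=100, duplicate_rate=0.2, seed=21)
    reports, manifest = generate(cfg)
    assert len(reports) == 120  # raw store carries the clones
    deduped = deduplicate(reports)
    assert len(deduped) == 100
    assert {r.case_key for r in deduped} == set(manifest["case_keys"])
    assert len(manifest["duplicated_case_keys"]) == 20
    # clones win the dedup (later receipt date) but differ only in key/date
    by_case = {r.case_key: r for r in reports[:100]}
    for r in deduped:
        orig = by_case[r.case_key]
        assert r.events == orig.events and r.drugs == orig.drugs


def test_faers_fixture_round_trip(tmp_path):
    cfg = SyntheticConfig(n_reports=100, duplicate_rate=0.15, seed=4)
    reports, _ = generate(cfg)
    paths = write_faers_fixture(reports, tmp_path)
    back = parse_faers_quarter(paths["DEMO"], paths["DRUG"], paths["REAC"],
                               paths["INDI"], paths["THER"])
    assert sorted(back, key=lambda r: r.report_key) == \
        sorted(reports, key=lambda r: r.report_key)
    # DEMO row count equals the raw (pre-dedup) record count
    demo_lines = paths["DEMO"].read_text().strip().splitlines()
    assert len(demo_lines) - 1 == len(reports)


def test_partial_dates_serialize_truncated(tmp_path):
    from pvsignals.report_store import PartialDate

    reports, _ = generate(SyntheticConfig(n_reports=3, duplicate_rate=0, seed=0))
    reports[0].receipt_date = PartialDate(2013, 5)
    paths = write_faers_fixture(reports, tmp_path)
    demo = paths["DEMO"].read_text().splitlines()
    assert "$201305$" in demo[1]
    back = parse_faers_quarter(paths["DEMO"], paths["DRUG"], paths["REAC"],
                               paths["INDI"], paths["THER"])
    key = reports[0].report_key
    got = next(r for r in back if r.report_key == key)
    assert got.receipt_date == PartialDate(2013, 5)
    assert not got.receipt_date.full_precision


def test_count_path_matches_report_path():
    """pair_report_counts and generate draw identical event assignments."""
    cfg = SyntheticConfig(n_reports=400, n_drugs=4, n_events=30,
                          planted_signals=[(1, 2, 4.0)], seed=9)
    counts, per_drug = pair_report_counts(cfg)
    reports, _ = generate(cfg)
    recount = np.zeros_like(counts)
    for r in reports[:cfg.n_reports]:
        d = int(r.drugs[0].name_normalized.split("_")[1])
        for e in r.events:
            if e.startswith("pt_"):
                recount[d, int(e.split("_")[1])] += 1
    assert (counts == recount).all()
    assert per_drug.sum() == cfg.n_reports


def test_planted_signal_ror_near_truth():
    """RR=5 at background 0.01 in 50k reports lands near the planted effect."""
    probs = np.full(100, 0.01)  # uniform background, each event at 1%
    cfg = SyntheticConfig(n_reports=50_000, n_drugs=10, n_events=100,
                          background_event_probs=probs,
                          planted_signals=[(0, 5, 5.0)], duplicate_rate=0.0,
                          seed=2024)
    counts, per_drug = pair_report_counts(cfg)
    a, b, c, d = pair_cells_from_counts(counts, per_drug)
    ror, _, _, _ = ror_arrays(a[0, 5], b[0, 5], c[0, 5], d[0, 5])
    assert 3.5 <= float(ror) <= 7.0


def test_indication_contamination_and_exclusion():
    cfg = SyntheticConfig(n_reports=2000, indication_contamination_rate=0.3,
                          duplicate_rate=0.0, seed=6)
    reports, _ = generate(cfg)
    contaminated = sum(1 for r in reports
                       if any(t in r.events for t in cfg.indication_terms))
    assert 0.2 < contaminated / len(reports) < 0.4
    from pvsignals.report_store import exclude_noise_terms

    cleaned = exclude_noise_terms(reports, set(cfg.indication_terms))
    assert all(t not in r.events for r in cleaned for t in cfg.indication_terms)


def test_demographic_marginals_land_near_targets():
    reports, _ = generate(SyntheticConfig(n_reports=5000, duplicate_rate=0, seed=13))
    frac_male = np.mean([r.gender.value == "male" for r in reports])
    frac_age_missing = np.mean([r.age_years is None for r in reports])
    frac_wt_missing = np.mean([r.weight_kg is None for r in reports])
    assert frac_male == pytest.approx(0.457, abs=0.03)
    assert frac_age_missing == pytest.approx(0.516, abs=0.03)
    assert frac_wt_missing == pytest.approx(0.730, abs=0.03)


def test_reference_marginals_store_is_exact():
    reports = build_reference_marginals_store()
    assert len(reports) == 2962
    assert sum(1 for r in reports if r.gender.value == "male") == 1354
    assert sum(1 for r in reports if r.weight_kg is None) == 2162


def test_synthetic_vocabulary_covers_events():
    vocab = synthetic_vocabulary(25, n_socs=5)
    assert len(vocab.pt_to_soc) == 25
    assert len(vocab.soc_set) == 5


def test_generated_store_selectable_by_query():
    reports, _ = generate(SyntheticConfig(n_reports=300, n_drugs=3, seed=1))
    q = DrugQuery(generic_names=frozenset({drug_name(0)}),
                  role_filter=frozenset({Role.PRIMARY_SUSPECT}))
    sel = select_drug_reports(reports, q)
    assert 0 < len(sel) < len(reports)
    assert all(any(d.name_normalized == drug_name(0) for d in r.drugs) for r in sel)
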