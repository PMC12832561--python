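"""Ingestion, selection, deduplication, exclusion and demographics."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignals.report_store import (
    DrugQuery, EmptyStoreError, FormatError, Gender, PartialDate, Role,
    RouteGroup, convert_age_to_years, convert_weight_to_kg, deduplicate,
    exclude_noise_terms, parse_cvard_extract, parse_faers_quarter, read_store,
    round_half_up, select_drug_reports, summarize_demographics, write_store,
)

from conftest import make_report, write_faers_files


# ---------------------------------------------------------------------------
# unit conversion


@pytest.mark.parametrize("value,code,expected", [
    (780, "MON", 65.0),          # months to years
    (65, "YR", 65.0),
    (6.5, "DEC", 65.0),          # decades scale by ten
    (8760, "HR", 1.0),
    (130, "YR", None),           # >120 years: implausible, treated missing
    ("", "YR", None),
    ("abc", "YR", None),
    (50, "LIGHTYEARS", None),    # unknown unit code
])
def test_age_conversion(value, code, expected):
    got = convert_age_to_years(value, code)
    assert got == pytest.approx(expected) if expected is not None else got is None


@pytest.mark.parametrize("value,code,expected", [
    (154, "LBS", 154 * 0.45359237),
    (70, "KG", 70.0),
    (70000, "GMS", 70.0),
    (-5, "KG", None),
    ("", "KG", None),
])
def test_weight_conversion(value, code, expected):
    got = convert_weight_to_kg(value, code)
    assert got == pytest.approx(expected) if expected is not None else got is None


# ---------------------------------------------------------------------------
# partial dates


def test_partial_date_precision_and_order():
    full = PartialDate.parse("20130518")
    ym = PartialDate.parse("201305")
    y = PartialDate.parse("2013")
    assert full.full_precision and not ym.full_precision and not y.full_precision
    assert y.sort_key() < ym.sort_key() < full.sort_key()
    assert PartialDate.parse("2013-05") == ym  # ISO partial form
    assert PartialDate.parse("") is None
    assert PartialDate.parse("201313") is None  # invalid month


# ---------------------------------------------------------------------------
# FAERS parsing


def test_parse_faers_joins_children(tmp_path):
    paths = write_faers_files(
        tmp_path,
        demo=[{"PRIMARYID": "1", "CASEID": "C1", "FDA_DT": "20130101",
               "AGE": "780", "AGE_COD": "MON", "SEX": "M",
               "WT": "154", "WT_COD": "LBS", "OCCP_COD": "MD"},
              {"PRIMARYID": "2", "CASEID": "C2", "FDA_DT": "20130201",
               "SEX": "F"}],
        drug=[{"PRIMARYID": "1", "DRUG_SEQ": "1", "ROLE_COD": "PS",
               "DRUGNAME": "DALIRESP", "PROD_AI": "ROFLUMILAST", "ROUTE": "Oral"},
              {"PRIMARYID": "2", "DRUG_SEQ": "1", "ROLE_COD": "SS",
               "DRUGNAME": "ROFLUMILAST"}],
        reac=[{"PRIMARYID": "1", "PT": "Diarrhoea"},
              {"PRIMARYID": "1", "PT": "Nausea"},
              {"PRIMARYID": "2", "PT": "Headache"},
              {"PRIMARYID": "999", "PT": "Orphan row"}],
        ther=[{"PRIMARYID": "1", "DSG_DRUG_SEQ": "1", "START_DT": "20130101"}],
    )
    reports = parse_faers_quarter(paths["DEMO"], paths["DRUG"], paths["REAC"],
                                  ther_path=paths["THER"])
    assert [len(r.events) for r in reports] == [2, 1]
    r1 = reports[0]
    assert r1.age_years == pytest.approx(65.0)
    assert r1.weight_kg == pytest.approx(69.85, abs=0.01)
    assert r1.events == ["diarrhoea", "nausea"]  # normalized PTs
    assert r1.route is RouteGroup.ORAL
    assert r1.drugs[0].start_date == PartialDate(2013, 1, 1)
    assert r1.drugs[0].role is Role.PRIMARY_SUSPECT


def test_parse_faers_missing_column_names_file_and_column(tmp_path):
    paths = write_faers_files(
        tmp_path,
        demo=[{"PRIMARYID": "1", "CASEID": "C1"}],
        demo_cols=["PRIMARYID", "CASEID"],  # no FDA_DT
        drug=[], reac=[])
    with pytest.raises(FormatError, match="DEMO.txt.*FDA_DT"):
        parse_faers_quarter(paths["DEMO"], paths["DRUG"], paths["REAC"])


def test_parse_faers_empty_demo_errors(tmp_path):
    paths = write_faers_files(tmp_path, demo=[], drug=[], reac=[])
    with pytest.raises(EmptyStoreError):
        parse_faers_quarter(paths["DEMO"], paths["DRUG"], paths["REAC"])


def test_parse_cvard(tmp_path):
    import pandas as pd

    pd.DataFrame([
        {"REPORT_ID": "10", "DATRECEIVED": "2013-05", "GENDER_ENG": "Female",
         "AGE": "70", "AGE_UNIT_ENG": "Years"},
        {"REPORT_ID": "11", "DATRECEIVED": "2014-01-02"},
    ]).to_csv(tmp_path / "reports.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"REPORT_ID": "10", "DRUGNAME": "DAXAS", "DRUGINVOLV_ENG": "Suspect"},
        {"REPORT_ID": "11", "DRUGNAME": "DAXAS", "DRUGINVOLV_ENG": "Concomitant"},
    ]).to_csv(tmp_path / "drugs.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"REPORT_ID": "10", "PT_NAME_ENG": "Dyspnoea"},
        {"REPORT_ID": "10", "PT_NAME_ENG": "Cough"},
        {"REPORT_ID": "11", "PT_NAME_ENG": "Headache"},
    ]).to_csv(tmp_path / "reactions.tsv", sep="\t", index=False)

    reports = parse_cvard_extract(tmp_path)
    assert [len(r.events) for r in reports] == [2, 1]
    assert reports[0].drugs[0].role is Role.SUSPECT
    assert reports[1].drugs[0].role is Role.CONCOMITANT
    # partial receipt date keeps year-month with day-precision false
    assert reports[0].receipt_date == PartialDate(2013, 5)
    assert not reports[0].receipt_date.full_precision


# ---------------------------------------------------------------------------
# selection


def test_select_matches_trade_name_and_role(roflumilast_query):
    included = make_report(drug="DALIRESP", role=Role.PRIMARY_SUSPECT)
    wrong_role = make_report(report_key="2", case_key="C2",
                             drug="ROFLUMILAST", role=Role.SECONDARY_SUSPECT)
    assert select_drug_reports([included, wrong_role], roflumilast_query) == [included]

    conc_only = DrugQuery(generic_names=frozenset({"roflumilast"}),
                          role_filter=frozenset({Role.CONCOMITANT}))
    assert select_drug_reports([included], conc_only) == []


def test_select_matches_ingredient_of_combination_product(roflumilast_query):
    combo = make_report(drug="SOME COMBO PRODUCT")
    combo.drugs[0] = combo.drugs[0].__class__(
        name_raw="COMBO", name_normalized="combo", role=Role.PRIMARY_SUSPECT,
        ingredient="roflumilast\\other", route_raw=None, start_date=None)
    assert select_drug_reports([combo], roflumilast_query) == [combo]


def test_select_monotone_in_role_filter():
    reports = [make_report(report_key=str(i), case_key=f"C{i}", role=role)
               for i, role in enumerate([Role.PRIMARY_SUSPECT, Role.CONCOMITANT,
                                         Role.SUSPECT])]
    small = DrugQuery(generic_names=frozenset({"roflumilast"}),
                      role_filter=frozenset({Role.PRIMARY_SUSPECT}))
    big = DrugQuery(generic_names=frozenset({"roflumilast"}),
                    role_filter=frozenset({Role.PRIMARY_SUSPECT, Role.CONCOMITANT}))
    sel_small = select_drug_reports(reports, small)
    sel_big = select_drug_reports(reports, big)
    assert set(r.report_key for r in sel_small) <= set(r.report_key for r in sel_big)
    assert all(r in reports for r in sel_big)


# ---------------------------------------------------------------------------
# deduplication


def test_dedup_keeps_latest_version_and_breaks_ties_by_key():
    v1 = make_report(report_key="5", case_key="100", receipt="20130101")
    v2 = make_report(report_key="6", case_key="100", receipt="20130301")
    assert deduplicate([v1, v2]) == [v2]
    assert deduplicate([v2, v1]) == [v2]  # input order irrelevant

    t1 = make_report(report_key="5", case_key="100", receipt="20130101")
    t2 = make_report(report_key="9", case_key="100", receipt="20130101")
    assert deduplicate([t1, t2])[0].report_key == "9"


@settings(deadline=None, max_examples=50)
@given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 3), st.integers(0, 20)),
                max_size=30))
def test_dedup_idempotent_and_never_grows(triples):
    reports = [make_report(report_key=str(100 + i), case_key=f"C{case}",
                           receipt=f"201301{1 + day:02d}")
               for i, (case, day, _) in enumerate(triples)]
    once = deduplicate(reports)
    assert len(once) <= len(reports)
    assert deduplicate(once) == once
    assert len(once) == len({r.case_key for r in reports})


# ---------------------------------------------------------------------------
# noise-term exclusion


def test_exclusions_strip_terms_and_drop_empty_reports():
    r1 = make_report(events=("diarrhoea", "off label use"))
    r2 = make_report(report_key="2", case_key="C2", events=("psoriasis",))
    out = exclude_noise_terms([r1, r2], {"off label use", "psoriasis"})
    assert len(out) == 1 and out[0].events == ["diarrhoea"]
    # empty exclusion set is the identity
    assert exclude_noise_terms([r1, r2], set()) == [r1, r2]


# ---------------------------------------------------------------------------
# demographics


def test_percent_rounding_one_third():
    reports = [make_report(report_key=str(i), case_key=f"C{i}",
                           gender=Gender.MALE if i == 0 else Gender.FEMALE)
               for i in range(3)]
    df = summarize_demographics(reports)
    male = df[(df.variable == "gender") & (df.category == "male")]
    assert male["percent"].iloc[0] == 33.3


def test_percentages_sum_to_100_per_variable():
    from pvsignals.synthetic_data import SyntheticConfig, generate

    reports, _ = generate(SyntheticConfig(n_reports=500, seed=3))
    df = summarize_demographics(deduplicate(reports))
    for var in ["gender", "age_band", "route", "weight_band", "reporter"]:
        total = df[df.variable == var]["percent"].sum()
        assert total == pytest.approx(100.0, abs=0.2)


def test_summarize_empty_store_errors():
    with pytest.raises(EmptyStoreError):
        summarize_demographics([])


@pytest.mark.parametrize("x,nd,expected", [
    (2.345, 2, 2.35), (2.344, 2, 2.34), (0.05, 1, 0.1), (33.3333, 1, 33.3),
])
def test_round_half_up(x, nd, expected):
    assert round_half_up(x, nd) == expected


# ---------------------------------------------------------------------------
# store round trip


def test_store_round_trip(tmp_path):
    from pvsignals.synthetic_data import SyntheticConfig, generate

    reports, _ = generate(SyntheticConfig(n_reports=50, duplicate_rate=0.1, seed=11))
    write_store(reports, tmp_path)
    assert read_store(tmp_path) == reports
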