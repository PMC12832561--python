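"""Shared fixtures: handcrafted report stores and FAERS file writers."""

from __future__ import annotations

from pathlib import Path

import pytest

from pvsignals.report_store import (DrugEntry, DrugQuery, Gender, PartialDate,
                                    Reporter, Role, RouteGroup, SafetyReport,
                                    SourceDb)


def make_report(report_key="1001", case_key="C1", receipt="20130301",
                drug="ROFLUMILAST", role=Role.PRIMARY_SUSPECT,
                events=("diarrhoea",), indications=(), gender=Gender.MALE,
                age=70.0, route_raw="Oral", start=None, event_date=None,
                **kw) -> SafetyReport:
    """One-line SafetyReport factory for hand-built fixtures."""
    entry = DrugEntry(name_raw=drug, name_normalized=drug.lower(), role=role,
                      ingredient=drug.lower(), route_raw=route_raw,
                      start_date=PartialDate.parse(start))
    from pvsignals.report_store import _report_route

    return SafetyReport(
        report_key=report_key, case_key=case_key,
        receipt_date=PartialDate.parse(receipt), source_db=SourceDb.FAERS,
        gender=gender, age_years=age, route=_report_route([entry]),
        reporter=Reporter.CONSUMER, country="united states",
        event_date=PartialDate.parse(event_date),
        drugs=[entry], events=list(events), indications=list(indications), **kw)


@pytest.fixture
def roflumilast_query() -> DrugQuery:
    return DrugQuery(generic_names=frozenset({"roflumilast"}),
                     trade_names=frozenset({"daliresp", "daxas", "zoryve"}),
                     role_filter=frozenset({Role.PRIMARY_SUSPECT}))


def write_faers_files(tmp_path: Path, demo, drug, reac, indi=None, ther=None,
                      demo_cols=None) -> dict[str, Path]:
    """Write '$'-delimited FAERS tables from lists of row dicts."""
    import pandas as pd

    paths = {}
    for name, rows, default_cols in (
        ("DEMO", demo, demo_cols or ["PRIMARYID", "CASEID", "FDA_DT", "AGE",
                                     "AGE_COD", "SEX", "WT", "WT_COD",
                                     "OCCP_COD", "REPORTER_COUNTRY", "EVENT_DT"]),
        ("DRUG", drug, ["PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME",
                        "PROD_AI", "ROUTE"]),
        ("REAC", reac, ["PRIMARYID", "PT"]),
        ("INDI", indi, ["PRIMARYID", "INDI_DRUG_SEQ", "INDI_PT"]),
        ("THER", ther, ["PRIMARYID", "DSG_DRUG_SEQ", "START_DT"]),
    ):
        if rows is None:
            continue
        path = tmp_path / f"{name}.txt"
        pd.DataFrame(rows, columns=default_cols).fillna("").to_csv(
            path, sep="$", index=False)
        paths[name] = path
    return paths
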