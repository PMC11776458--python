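"""Cohort rules: windows, washout, incident/prevalent status, case filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abivr import (
    build_exposure_table,
    case_count_filter,
    count_ab_in_window,
    define_incident_outcomes,
    filter_analysis_set,
)


def rx(*rows):
    return pd.DataFrame(rows, columns=["person_id", "date", "atc_code"])


def subjects(*rows):
    return pd.DataFrame(rows, columns=["person_id", "birth_date", "sex"])


# ---------------------------------------------------------------- window


def test_window_and_washout_worked_example():
    records = rx(
        ("p1", "2010-05-03", "J01CA04"),
        ("p1", "2004-12-31", "J01FA10"),
        ("p1", "2014-09-15", "J01MA02"),
    )
    count, washout = count_ab_in_window(records, "p1", "2015-01-01")
    assert count == 1  # only the 2010 course; 2004 predates the window
    assert washout is True  # 2014-09-15 inside the final 6 months


def test_unknown_person_yields_zero_without_washout():
    records = rx(("p1", "2010-05-03", "J01CA04"))
    assert count_ab_in_window(records, "ghost", "2015-01-01") == (0, False)


def test_washout_flag_ignores_non_antibiotics_but_prefix_filter_counts():
    records = rx(
        ("p1", "2014-10-01", "A02BC01"),  # not an antibiotic
        ("p1", "2012-01-01", "J01FA09"),
        ("p1", "2012-02-01", "J01CA04"),
    )
    count, washout = count_ab_in_window(records, "p1", "2015-01-01", atc_prefix="J01FA")
    assert (count, washout) == (1, False)
    # subclass prefix narrows the count but washout still scans all J01*
    records2 = pd.concat([records, rx(("p1", "2014-12-01", "J01CA04"))])
    count2, washout2 = count_ab_in_window(records2, "p1", "2015-01-01", atc_prefix="J01FA")
    assert (count2, washout2) == (1, True)


def test_same_day_same_code_counts_once():
    records = rx(
        ("p1", "2012-03-04", "J01CA04"),
        ("p1", "2012-03-04", "J01CA04"),
        ("p1", "2012-03-04", "J01FA09"),
    )
    count, _ = count_ab_in_window(records, "p1", "2015-01-01")
    assert count == 2


def _brute_count(records, person, index, years_back, washout_months, prefix):
    index = pd.Timestamp(index)
    start = index - pd.DateOffset(years=years_back)
    cutoff = index - pd.DateOffset(months=washout_months)
    seen = set()
    count, washout = 0, False
    for _, r in records.iterrows():
        if r["person_id"] != person:
            continue
        d = pd.Timestamp(r["date"])
        key = (d, r["atc_code"])
        if key in seen:
            continue
        seen.add(key)
        if r["atc_code"].startswith(prefix) and start <= d < cutoff:
            count += 1
        if r["atc_code"].startswith("J01") and cutoff <= d < index:
            washout = True
    return count, washout


def test_boundary_dates_match_bruteforce_filter():
    # 12 records across the exact window boundaries
    dates = [
        "2005-01-01", "2004-12-31", "2005-01-02", "2014-07-01", "2014-06-30",
        "2014-07-02", "2014-12-31", "2015-01-01", "2010-01-01", "2012-06-15",
        "2005-06-30", "2014-11-30",
    ]
    records = rx(*[("p1", d, "J01AA02") for d in dates])
    got = count_ab_in_window(records, "p1", "2015-01-01")
    assert got == _brute_count(records, "p1", "2015-01-01", 10, 6, "J01")
    assert got == (6, True)  # 6 in [2005-01-01, 2014-07-01), washout hit


# ---------------------------------------------------------------- exposure table


def test_exposure_table_subclass_counts():
    subj = subjects(("p1", "1980-06-01", "female"))
    records = rx(
        ("p1", "2010-01-01", "J01CR02"),
        ("p1", "2011-01-01", "J01CR05"),
        ("p1", "2012-01-01", "J01FA09"),
        ("p1", "2013-01-01", "J01CC01"),
    )
    out = build_exposure_table(records, subj, "2015-01-01")
    row = out.iloc[0]
    assert row["n_ab_total"] == 4
    assert row["n_ab_J01CR"] == 2
    assert row["n_ab_J01FA"] == 1
    assert row["n_ab_J01MA"] == 0
    assert not row["washout_violation"] and row["eligible"]
    assert row["age_at_index"] == 34  # birthday not yet reached on Jan 1


def test_washout_violation_makes_ineligible():
    subj = subjects(("p1", "1980-06-01", "male"))
    records = rx(("p1", "2014-12-01", "J01CA04"))
    out = build_exposure_table(records, subj, "2015-01-01")
    assert out.iloc[0]["washout_violation"]
    assert not out.iloc[0]["eligible"]


def test_empty_prescriptions_gives_all_zero():
    subj = subjects(("p1", "1980-06-01", "male"), ("p2", "1990-01-01", "female"))
    out = build_exposure_table(rx(), subj, "2015-01-01")
    assert (out["n_ab_total"] == 0).all()
    assert (~out["washout_violation"]).all()


def test_duplicate_subject_rejected():
    subj = subjects(("p1", "1980-06-01", "male"), ("p1", "1981-01-01", "male"))
    with pytest.raises(ValueError, match="duplicate"):
        build_exposure_table(rx(), subj, "2015-01-01")


def test_per_person_index_dates():
    subj = subjects(("p1", "1980-06-01", "male"), ("p2", "1980-06-01", "female"))
    records = rx(("p1", "2016-01-15", "J01CA04"), ("p2", "2016-01-15", "J01CA04"))
    idx = pd.Series(
        pd.to_datetime(["2015-01-01", "2018-01-01"]), index=["p1", "p2"]
    )
    out = build_exposure_table(records, subj, idx).set_index("person_id")
    assert out.loc["p1", "n_ab_total"] == 0  # after p1's index date
    assert out.loc["p2", "n_ab_total"] == 1  # in p2's window


# ---------------------------------------------------------------- analysis filters


def _exposure_row(pid, age, n_ab, eligible=True, sex="female", sub=0):
    return {
        "person_id": pid, "n_ab_total": n_ab, "n_ab_J01CR": sub,
        "n_ab_J01FA": 0, "n_ab_J01MA": 0, "washout_violation": not eligible,
        "age_at_index": age, "sex": sex, "eligible": eligible,
    }


def test_age_and_cap_bounds_inclusive():
    exp = pd.DataFrame([
        _exposure_row("a", 51, 3),
        _exposure_row("b", 50, 5),
        _exposure_row("c", 23, 0),
        _exposure_row("d", 22, 0),
        _exposure_row("e", 40, 6),
        _exposure_row("f", 40, 2, eligible=False),
    ])
    kept = set(filter_analysis_set(exp)["person_id"])
    assert kept == {"b", "c"}


def test_subclass_instrument_caps_subclass_count():
    exp = pd.DataFrame([
        _exposure_row("a", 30, 8, sub=2),
        _exposure_row("b", 30, 3, sub=6),
    ])
    kept = set(filter_analysis_set(exp, instrument="J01CR")["person_id"])
    assert kept == {"a"}  # cap applies to the subclass count, not the total


def test_widening_filters_is_monotone():
    rng = np.random.default_rng(0)
    exp = pd.DataFrame([
        _exposure_row(f"p{i}", int(rng.integers(18, 95)), int(rng.integers(0, 14)),
                      eligible=bool(rng.random() < 0.9))
        for i in range(300)
    ])
    narrow = set(filter_analysis_set(exp)["person_id"])
    wide = set(filter_analysis_set(exp, min_age=23, max_age=89, max_ab=10)["person_id"])
    assert narrow <= wide


def test_empty_analysis_set_warns_not_raises():
    exp = pd.DataFrame([_exposure_row("a", 99, 0)])
    with pytest.warns(UserWarning, match="empty"):
        out = filter_analysis_set(exp)
    assert out.empty


# ---------------------------------------------------------------- outcomes


def dx(*rows):
    return pd.DataFrame(rows, columns=["person_id", "date", "icd10_code"])


def test_incident_prevalent_censored_partition():
    subj = subjects(
        ("p1", "1980-01-01", "f"), ("p2", "1980-01-01", "f"),
        ("p3", "1980-01-01", "f"), ("p4", "1980-01-01", "f"),
    )
    diag = dx(
        ("p1", "2013-06-01", "K58.0"),   # prevalent
        ("p2", "2016-03-10", "K58.9"),   # incident
        ("p3", "2023-05-01", "K58"),     # after follow-up end -> ignored
    )
    out = define_incident_outcomes(diag, subj, {"ibs": ["K58"]})
    status = out.set_index("person_id")["status"]
    assert status["p1"] == "prevalent_excluded"
    assert status["p2"] == "incident"
    assert status["p3"] == "censored_nonevent"
    assert status["p4"] == "censored_nonevent"
    # partition is exhaustive and exclusive
    assert len(out) == 4 and out["status"].isin(
        ["incident", "prevalent_excluded", "censored_nonevent"]
    ).all()


def test_gap_mode_reclassifies_early_incidence_as_prevalent():
    subj = subjects(("p2", "1980-01-01", "f"))
    diag = dx(("p2", "2016-03-10", "K58.9"))
    no_gap = define_incident_outcomes(diag, subj, {"ibs": ["K58"]}, gap_years=0)
    with_gap = define_incident_outcomes(diag, subj, {"ibs": ["K58"]}, gap_years=5)
    assert no_gap.iloc[0]["status"] == "incident"
    assert with_gap.iloc[0]["status"] == "prevalent_excluded"


def test_prefix_matching_spans_subcodes():
    subj = subjects(("p1", "1980-01-01", "f"))
    diag = dx(("p1", "2016-01-01", "K58.32"))
    out = define_incident_outcomes(diag, subj, {"ibs": ["K58"]})
    assert out.iloc[0]["status"] == "incident"


def test_empty_disease_codes_rejected():
    subj = subjects(("p1", "1980-01-01", "f"))
    with pytest.raises(ValueError):
        define_incident_outcomes(dx(), subj, {})


def test_case_count_filter_boundary():
    frames = []
    for disease, n_inc in [("rare", 49), ("common", 50)]:
        frames.append(pd.DataFrame({
            "person_id": [f"{disease}{i}" for i in range(n_inc)],
            "disease": disease,
            "status": "incident",
            "first_date": pd.NaT,
        }))
    outcomes = pd.concat(frames, ignore_index=True)
    assert case_count_filter(outcomes) == ["common"]
    tally = (outcomes["status"] == "incident").groupby(outcomes["disease"]).sum()
    assert tally["rare"] == 49 and tally["common"] == 50


def test_case_count_filter_respects_analysis_set():
    outcomes = pd.DataFrame({
        "person_id": [f"p{i}" for i in range(60)],
        "disease": "d",
        "status": "incident",
        "first_date": pd.NaT,
    })
    assert case_count_filter(outcomes) == ["d"]
    assert case_count_filter(outcomes, persons=[f"p{i}" for i in range(40)]) == []


# ---------------------------------------------------------------- properties


@given(
    washout_months=st.integers(min_value=0, max_value=6),
    n_records=st.integers(min_value=0, max_value=25),
    seed=st.integers(min_value=0, max_value=10_000),
)
@settings(max_examples=40)
def test_longer_washout_never_increases_count(washout_months, n_records, seed):
    rng = np.random.default_rng(seed)
    days = rng.integers(1, 4200, size=n_records)
    records = rx(*[
        ("p", str(pd.Timestamp("2015-01-01") - pd.Timedelta(days=int(d))), "J01AA02")
        for d in days
    ])
    count_w, _ = count_ab_in_window(records, "p", "2015-01-01",
                                    washout_months=washout_months)
    count_0, _ = count_ab_in_window(records, "p", "2015-01-01", washout_months=0)
    assert count_w <= count_0


def test_washout_exclusions_verifiable_by_rescan(midsize_study):
    tables = midsize_study.sample1
    subj = tables["subjects"]
    exp = build_exposure_table(tables["prescriptions"], subj, "2015-01-01")
    flagged = exp.loc[exp["washout_violation"], "person_id"]
    rx_all = tables["prescriptions"].copy()
    rx_all["date"] = pd.to_datetime(rx_all["date"])
    lo, hi = pd.Timestamp("2014-07-01"), pd.Timestamp("2015-01-01")
    recent = rx_all[(rx_all["date"] >= lo) & (rx_all["date"] < hi)
                    & rx_all["atc_code"].str.startswith("J01")]
    assert set(flagged) == set(recent["person_id"])
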