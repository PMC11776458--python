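"""Instrument and outcome construction from EHR-style tables.

The instrument is the per-person count of antibiotic prescriptions (ATC
J01*) in the window from 10 years to 6 months before an index date; anyone
with a J01 prescription inside the final 6 months (the washout) is flagged
and excluded. Outcomes are incident-disease indicators: first occurrence of
a configured ICD-10 code during follow-up, with pre-follow-up (prevalent)
cases excluded and an optional gap mode that additionally treats the first
years of follow-up as prevalent.

Window conventions: courses are counted over the half-open interval
[index - years_back, index - washout_months) and the washout is
[index - washout_months, index); one prescription record is one course,
with same-day duplicates of the same ATC code deduplicated.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "INSTRUMENT_COLUMNS",
    "SUBCLASS_PREFIXES",
    "count_ab_in_window",
    "build_exposure_table",
    "filter_analysis_set",
    "define_incident_outcomes",
    "case_count_filter",
]

ATC_ANTIBIOTIC_PREFIX = "J01"
SUBCLASS_PREFIXES = ("J01CR", "J01FA", "J01MA")
INSTRUMENT_COLUMNS = {
    "total": "n_ab_total",
    "J01CR": "n_ab_J01CR",
    "J01FA": "n_ab_J01FA",
    "J01MA": "n_ab_J01MA",
}

_STATUS_INCIDENT = "incident"
_STATUS_PREVALENT = "prevalent_excluded"
_STATUS_CENSORED = "censored_nonevent"


def _check_window(years_back, washout_months):
    if years_back <= washout_months / 12.0:
        raise ValueError("years_back must exceed washout_months/12")


def _offsets(index_dates, years_back, washout_months):
    """Per-date (window_start, washout_start) using calendar offsets."""
    idx = pd.DatetimeIndex(index_dates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", pd.errors.PerformanceWarning)
        start = idx - pd.DateOffset(years=int(years_back))
        cutoff = idx - pd.DateOffset(months=int(washout_months))
    return start, cutoff


def _dedup(prescriptions):
    return prescriptions.drop_duplicates(["person_id", "date", "atc_code"])


def count_ab_in_window(prescriptions, person_id, index_date, years_back=10,
                       washout_months=6, atc_prefix=ATC_ANTIBIOTIC_PREFIX):
    """Count one person's antibiotic courses in the analysis window.

    Returns ``(count, washout_violation)`` where ``count`` is the number of
    deduplicated records whose ATC code starts with ``atc_prefix`` and whose
    date falls in [index - years_back, index - washout_months), and
    ``washout_violation`` is True iff any J01* record (regardless of
    ``atc_prefix``) falls in [index - washout_months, index). An unknown
    person yields ``(0, False)``.
    """
    _check_window(years_back, washout_months)
    index_date = pd.Timestamp(index_date)
    rows = prescriptions[prescriptions["person_id"] == person_id]
    if rows.empty:
        return 0, False
    rows = rows.assign(date=pd.to_datetime(rows["date"]))
    rows = _dedup(rows)
    (start,), (cutoff,) = _offsets([index_date], years_back, washout_months)
    dates = rows["date"]
    atc = rows["atc_code"].astype(str)
    in_window = (dates >= start) & (dates < cutoff) & atc.str.startswith(atc_prefix)
    in_washout = (dates >= cutoff) & (dates < index_date) & atc.str.startswith(ATC_ANTIBIOTIC_PREFIX)
    return int(in_window.sum()), bool(in_washout.any())


def build_exposure_table(prescriptions, subjects, index_dates, years_back=10,
                         washout_months=6):
    """Per-subject antibiotic counts (total and per subclass) and flags.

    Parameters
    ----------
    prescriptions : DataFrame with person_id, date, atc_code
    subjects : DataFrame with person_id, birth_date (sex carried if present)
    index_dates : scalar date, or mapping/Series person_id -> date

    Returns one row per subject: ``n_ab_total`` (all J01*), per-subclass
    counts, ``washout_violation``, ``age_at_index`` (completed years) and
    ``eligible`` (= no washout violation; age/cap filters come later).
    """
    _check_window(years_back, washout_months)
    if subjects["person_id"].duplicated().any():
        dups = subjects.loc[subjects["person_id"].duplicated(), "person_id"].iloc[0]
        raise ValueError(f"duplicate person_id in subjects: {dups!r}")

    pid = subjects["person_id"].to_numpy()
    if isinstance(index_dates, (pd.Series, dict)):
        idx = pd.Series(index_dates).reindex(pid)
        if idx.isna().any():
            missing = pid[idx.isna().to_numpy()][0]
            raise ValueError(f"missing index date for person {missing!r}")
        idx = pd.to_datetime(idx)
    else:
        idx = pd.Series(pd.Timestamp(index_dates), index=pid)
    idx.index = pid

    counts = pd.DataFrame(
        0, index=pid,
        columns=["n_ab_total", *(f"n_ab_{p}" for p in SUBCLASS_PREFIXES)],
    )
    washout = pd.Series(False, index=pid)

    rx = prescriptions.loc[prescriptions["person_id"].isin(pid)].copy()
    if not rx.empty:
        rx["date"] = pd.to_datetime(rx["date"])
        rx = _dedup(rx)
        rx_idx = idx.loc[rx["person_id"]].to_numpy()
        uniq = pd.DatetimeIndex(pd.unique(idx))
        start_u, cutoff_u = _offsets(uniq, years_back, washout_months)
        start = pd.Series(start_u, index=uniq).loc[pd.DatetimeIndex(rx_idx)].to_numpy()
        cutoff = pd.Series(cutoff_u, index=uniq).loc[pd.DatetimeIndex(rx_idx)].to_numpy()

        dates = rx["date"].to_numpy()
        atc = rx["atc_code"].astype(str)
        is_ab = atc.str.startswith(ATC_ANTIBIOTIC_PREFIX).to_numpy()
        in_window = (dates >= start) & (dates < cutoff)
        in_washout = (dates >= cutoff) & (dates < rx_idx)

        grp = rx["person_id"]
        tot = pd.Series(np.where(in_window & is_ab, 1, 0)).groupby(grp.to_numpy()).sum()
        counts.loc[tot.index, "n_ab_total"] = tot
        for prefix in SUBCLASS_PREFIXES:
            sub = atc.str.startswith(prefix).to_numpy()
            c = pd.Series(np.where(in_window & sub, 1, 0)).groupby(grp.to_numpy()).sum()
            counts.loc[c.index, f"n_ab_{prefix}"] = c
        w = pd.Series(in_washout & is_ab).groupby(grp.to_numpy()).any()
        washout.loc[w.index] = w

    birth = pd.to_datetime(subjects["birth_date"])
    idx_arr = pd.DatetimeIndex(idx.to_numpy())
    before_birthday = (idx_arr.month < birth.dt.month.to_numpy()) | (
        (idx_arr.month == birth.dt.month.to_numpy())
        & (idx_arr.day < birth.dt.day.to_numpy())
    )
    age = idx_arr.year - birth.dt.year.to_numpy() - before_birthday.astype(int)

    out = pd.DataFrame({"person_id": pid})
    for col in counts.columns:
        out[col] = counts[col].to_numpy()
    out["washout_violation"] = washout.to_numpy()
    out["age_at_index"] = age
    if "sex" in subjects.columns:
        out["sex"] = subjects["sex"].to_numpy()
    out["eligible"] = ~out["washout_violation"]
    return out


def filter_analysis_set(exposure, min_age=23, max_age=50, max_ab=5,
                        instrument="total", sex=None):
    """Apply the eligibility filters: washout, age bounds, usage cap.

    Bounds are inclusive. The usage cap applies to the count of the chosen
    instrument (so a subclass instrument is capped on its own count), while
    the washout flag always reflects all J01* usage.
    """
    if min_age > max_age:
        raise ValueError("min_age must not exceed max_age")
    if max_ab < 0:
        raise ValueError("max_ab must be >= 0")
    col = INSTRUMENT_COLUMNS[instrument]
    mask = (
        exposure["eligible"]
        & exposure["age_at_index"].between(min_age, max_age)
        & (exposure[col] <= max_ab)
    )
    if sex is not None and sex != "all":
        mask &= exposure["sex"] == sex
    subset = exposure.loc[mask].copy()
    if subset.empty:
        warnings.warn("analysis set is empty after filtering", stacklevel=2)
    return subset


def define_incident_outcomes(diagnoses, subjects, disease_codes,
                             followup_start="2015-01-01",
                             followup_end="2022-12-31", gap_years=0):
    """Classify each person x disease as incident / prevalent / censored.

    ``disease_codes`` maps disease name -> list of ICD-10 prefixes (prefix
    match, so "K58" matches "K58.0"). A person is *incident* iff their first
    matching diagnosis falls in (followup_start + gap_years, followup_end];
    *prevalent_excluded* iff it falls on or before followup_start +
    gap_years; otherwise *censored_nonevent*. Diagnoses after the end of
    follow-up are ignored entirely (right censoring).
    """
    if not disease_codes:
        raise ValueError("disease_codes must name at least one disease")
    fs = pd.Timestamp(followup_start)
    fe = pd.Timestamp(followup_end)
    if fs >= fe:
        raise ValueError("followup_start must precede followup_end")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", pd.errors.PerformanceWarning)
        gap_cut = fs + pd.DateOffset(years=int(gap_years))

    dx = diagnoses.copy()
    dx["date"] = pd.to_datetime(dx["date"])
    dx = dx[dx["date"] <= fe]
    codes = dx["icd10_code"].astype(str)

    pid = subjects["person_id"].to_numpy()
    frames = []
    for disease, prefixes in disease_codes.items():
        hit = codes.str.startswith(tuple(str(p) for p in prefixes))
        first = dx.loc[hit].groupby("person_id")["date"].min().reindex(pid)
        status = np.where(
            first.isna(),
            _STATUS_CENSORED,
            np.where(first <= gap_cut, _STATUS_PREVALENT, _STATUS_INCIDENT),
        )
        frames.append(
            pd.DataFrame(
                {
                    "person_id": pid,
                    "disease": disease,
                    "status": status,
                    "first_date": first.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def case_count_filter(outcomes, min_cases=50, persons=None):
    """Diseases with at least ``min_cases`` incident cases in the analysis set."""
    oc = outcomes
    if persons is not None:
        oc = oc[oc["person_id"].isin(set(persons))]
    tallies = (
        oc.loc[oc["status"] == _STATUS_INCIDENT].groupby("disease").size()
    )
    order = list(dict.fromkeys(outcomes["disease"]))
    return [d for d in order if tallies.get(d, 0) >= min_cases]
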