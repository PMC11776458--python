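"""End-to-end orchestration: raw tables -> cohorts -> panel estimates.

Thin glue over :mod:`cohort`, :mod:`mbfeat` and :mod:`ivcore` implementing
the two-sample design: a fixed follow-up start date indexes the outcome
cohort, per-person microbiome collection dates index the microbiome cohort,
and the same eligibility filters (washout, age bounds, usage cap) are
applied to both before estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from . import cohort, ivcore, mbfeat

__all__ = ["PanelSettings", "build_analysis_exposure", "run_ab_ivr"]


@dataclass(frozen=True)
class PanelSettings:
    """Analysis settings shared by both samples.

    Defaults are the main-analysis conditions: ages 23-50 inclusive, at
    most 5 courses of the instrument antibiotics, 6-month washout, total
    J01* usage as instrument, follow-up 2015-01-01..2022-12-31, at least
    50 incident cases per disease, FDR threshold 0.05.
    """

    min_age: int = 23
    max_age: int = 50
    max_ab: int = 5
    gap_years: int = 0
    instrument: str = "total"
    transform: str = "none"  # none | int
    sex_filter: str = "all"  # all | female | male
    min_cases: int = 50
    fdr_alpha: float = 0.05
    ci_multiplier: float = 1.96
    weak_z_threshold: float = 2.0
    years_back: int = 10
    washout_months: int = 6
    followup_start: str = "2015-01-01"
    followup_end: str = "2022-12-31"
    sample1_index_date: str = "2015-01-01"
    covariates: tuple = ()


def _index_dates_for(tables, settings, default_date):
    subjects = tables["subjects"]
    if "index_date" in subjects.columns:
        return pd.Series(
            pd.to_datetime(subjects["index_date"]).to_numpy(),
            index=subjects["person_id"].to_numpy(),
        )
    return pd.Timestamp(default_date)


def build_analysis_exposure(tables, settings: PanelSettings, default_index_date=None):
    """Exposure table for one sample with all eligibility filters applied."""
    default_date = default_index_date or settings.sample1_index_date
    exposure = cohort.build_exposure_table(
        tables["prescriptions"],
        tables["subjects"],
        _index_dates_for(tables, settings, default_date),
        years_back=settings.years_back,
        washout_months=settings.washout_months,
    )
    return cohort.filter_analysis_set(
        exposure,
        min_age=settings.min_age,
        max_age=settings.max_age,
        max_ab=settings.max_ab,
        instrument=settings.instrument,
        sex=None if settings.sex_filter == "all" else settings.sex_filter,
    )


def prepare_microbiome(tables, analysis_exposure, settings: PanelSettings):
    """log P/B features for the microbiome-cohort analysis set."""
    mb = mbfeat.compute_log_pb(tables["genus_abundance"])
    mb = mb[mb["person_id"].isin(set(analysis_exposure["person_id"]))].copy()
    if settings.transform == "int":
        mb["log_pb"] = mbfeat.rank_inverse_normal(mb["log_pb"].to_numpy())
    elif settings.transform != "none":
        raise ValueError(f"unknown transform {settings.transform!r}")
    return mb


def run_ab_ivr(sample1_tables, sample2_tables, disease_codes,
               settings: PanelSettings = None, diseases=None,
               pseudo_outcomes=None) -> pd.DataFrame:
    """Run the full AB-IVR panel on raw two-sample tables.

    ``pseudo_outcomes``, when given, replaces the EHR-derived outcome table
    (used for null calibration with randomly generated disease indicators);
    ``disease_codes`` may then be empty.
    """
    settings = settings or PanelSettings()
    analysis1 = build_analysis_exposure(sample1_tables, settings)
    analysis2 = build_analysis_exposure(sample2_tables, settings)
    mb = prepare_microbiome(sample2_tables, analysis2, settings)

    if pseudo_outcomes is not None:
        outcomes = pseudo_outcomes
    else:
        outcomes = cohort.define_incident_outcomes(
            sample1_tables["diagnoses"],
            sample1_tables["subjects"],
            disease_codes,
            followup_start=settings.followup_start,
            followup_end=settings.followup_end,
            gap_years=settings.gap_years,
        )
    return ivcore.run_disease_panel(
        mb,
        analysis2,
        analysis1,
        outcomes,
        diseases=diseases,
        instrument=settings.instrument,
        covariates=list(settings.covariates) or None,
        min_cases=settings.min_cases,
        ci_multiplier=settings.ci_multiplier,
        weak_z_threshold=settings.weak_z_threshold,
    )
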