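"""Sensitivity suite: null calibration and the scenario grid.

Null calibration replaces the EHR outcomes with pseudo-disease indicators
drawn independently of everything else (one Bernoulli column per target
prevalence, 2.5%..97.5% in steps of 2.5% = 39 columns) and checks that the
panel declares at most the nominal 5% of them significant.

The scenario grid reruns the panel under perturbed eligibility and
modelling choices - wider age range (23-89), higher usage cap (10), a
5-year incidence gap, each antibiotic subclass as instrument, the
inverse-normal-transformed exposure, and sex strata - mirroring the
robustness checks a causal claim should survive.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ivcore import PANEL_COLUMNS
from .pipeline import PanelSettings, run_ab_ivr

__all__ = [
    "DEFAULT_PROBABILITIES",
    "CalibrationResult",
    "ScenarioSpec",
    "default_scenario_grid",
    "make_pseudo_outcomes",
    "null_calibration",
    "run_sensitivity_grid",
    "write_report",
    "scenario_seed",
]

# 2.5% .. 97.5% in steps of 2.5% -> 39 pseudo-disease prevalences.
DEFAULT_PROBABILITIES = tuple(np.round(np.arange(1, 40) * 0.025, 4))


def scenario_seed(master_seed: int, name: str) -> int:
    """Stable per-scenario sub-seed (< 2^31) derived from a master seed."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of one pseudo-disease null-calibration run."""

    n_pseudo: int
    probabilities: tuple
    n_significant_fdr: int
    n_significant_nominal: int
    proportion_fdr: float
    proportion_nominal: float
    alpha: float
    seed: int
    results: pd.DataFrame = field(repr=False, compare=False)


@dataclass(frozen=True)
class ScenarioSpec:
    """One row of the sensitivity grid: a named set of panel settings."""

    name: str
    min_age: int = 23
    max_age: int = 50
    max_ab: int = 5
    gap_years: int = 0
    instrument: str = "total"
    transform: str = "none"
    sex_filter: str = "all"

    def to_settings(self, base: PanelSettings) -> PanelSettings:
        return replace(
            base,
            min_age=self.min_age,
            max_age=self.max_age,
            max_ab=self.max_ab,
            gap_years=self.gap_years,
            instrument=self.instrument,
            transform=self.transform,
            sex_filter=self.sex_filter,
        )


def default_scenario_grid():
    """The standard robustness grid around the main analysis settings."""
    return [
        ScenarioSpec("main"),
        ScenarioSpec("age_23_89", max_age=89),
        ScenarioSpec("ab_cap_10", max_ab=10),
        ScenarioSpec("gap_5y", gap_years=5),
        ScenarioSpec("instrument_J01CR", instrument="J01CR"),
        ScenarioSpec("instrument_J01FA", instrument="J01FA"),
        ScenarioSpec("instrument_J01MA", instrument="J01MA"),
        ScenarioSpec("int_transform", transform="int"),
        ScenarioSpec("female", sex_filter="female"),
        ScenarioSpec("male", sex_filter="male"),
        ScenarioSpec("male_23_89", sex_filter="male", max_age=89),
    ]


def make_pseudo_outcomes(person_ids, probabilities=None, seed=0) -> pd.DataFrame:
    """Independent Bernoulli pseudo-disease columns, one per probability.

    Each pseudo-disease is drawn independently of every exposure and of the
    other columns, so any association the panel finds is a false positive.
    Output uses the standard outcome-table layout (no prevalent rows,
    ``first_date`` absent).
    """
    probs = DEFAULT_PROBABILITIES if probabilities is None else tuple(probabilities)
    probs_arr = np.asarray(probs, dtype=float)
    if np.any(probs_arr <= 0) or np.any(probs_arr >= 1):
        raise ValueError("pseudo-disease probabilities must lie strictly in (0, 1)")
    pid = np.asarray(person_ids)
    rng = np.random.default_rng(seed)
    frames = []
    for p in probs_arr:
        y = rng.random(pid.size) < p
        frames.append(
            pd.DataFrame(
                {
                    "person_id": pid,
                    "disease": f"pseudo_{100 * p:.1f}pct",
                    "status": np.where(y, "incident", "censored_nonevent"),
                    "first_date": pd.NaT,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def null_calibration(sample1_tables, sample2_tables, settings=None, seed=0,
                     alpha=0.05, probabilities=None) -> CalibrationResult:
    """Run the full panel on pseudo-outcomes and tally significance rates.

    ``proportion_fdr`` is the fraction of estimated pseudo-diseases with
    FDR-adjusted p <= alpha (the pass criterion is <= alpha, expected 0);
    ``proportion_nominal`` uses the unadjusted p-values and should track
    the nominal level under correct calibration.
    """
    settings = settings or PanelSettings()
    probs = DEFAULT_PROBABILITIES if probabilities is None else tuple(probabilities)
    pseudo = make_pseudo_outcomes(
        sample1_tables["subjects"]["person_id"].to_numpy(), probs, seed=seed
    )
    panel = run_ab_ivr(
        sample1_tables, sample2_tables, disease_codes=None,
        settings=settings, pseudo_outcomes=pseudo,
    )
    ok = panel[panel["status"] == "ok"]
    n_fdr = int((ok["p_fdr"] <= alpha).sum())
    n_nom = int((ok["p"] <= alpha).sum())
    denom = max(len(ok), 1)
    return CalibrationResult(
        n_pseudo=len(probs),
        probabilities=tuple(probs),
        n_significant_fdr=n_fdr,
        n_significant_nominal=n_nom,
        proportion_fdr=n_fdr / denom,
        proportion_nominal=n_nom / denom,
        alpha=alpha,
        seed=seed,
        results=panel,
    )


def run_sensitivity_grid(sample1_tables, sample2_tables, disease_codes,
                         scenarios=None, base_settings=None) -> pd.DataFrame:
    """Rerun the panel under every scenario; tidy one-row-per-disease output.

    A scenario whose filters empty an analysis set is reported with status
    ``skipped:empty_analysis_set`` rather than raising.
    """
    scenarios = scenarios if scenarios is not None else default_scenario_grid()
    if not scenarios:
        raise ValueError("scenario list is empty")
    base = base_settings or PanelSettings()
    pieces = []
    for spec in scenarios:
        settings = spec.to_settings(base)
        try:
            with np.errstate(all="ignore"):
                panel = run_ab_ivr(sample1_tables, sample2_tables,
                                   disease_codes, settings=settings)
        except ValueError:
            panel = pd.DataFrame(
                [{"disease": d, "instrument": settings.instrument,
                  "status": "skipped:empty_analysis_set"}
                 for d in disease_codes]
            )
            for col in PANEL_COLUMNS:
                if col not in panel.columns:
                    panel[col] = np.nan
            panel = panel[PANEL_COLUMNS]
        panel.insert(0, "scenario", spec.name)
        pieces.append(panel)
    return pd.concat(pieces, ignore_index=True)


def write_report(results: pd.DataFrame, calibration, out_dir) -> dict:
    """Write the tidy results TSV, calibration summary and a forest figure.

    Returns a dict of written paths. File content is deterministic for
    fixed inputs.
    """
    import json
    import pathlib

    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if results is None or len(results) == 0:
        raise ValueError("results table is empty")
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    results_path = out / "results.tsv"
    results.to_csv(results_path, sep="\t", index=False, float_format="%.10g")
    paths["results"] = results_path

    if calibration is not None:
        cal_path = out / "calibration.tsv"
        calibration.results.to_csv(cal_path, sep="\t", index=False, float_format="%.10g")
        summary = {
            "n_pseudo": calibration.n_pseudo,
            "alpha": calibration.alpha,
            "n_significant_fdr": calibration.n_significant_fdr,
            "n_significant_nominal": calibration.n_significant_nominal,
            "proportion_fdr": calibration.proportion_fdr,
            "proportion_nominal": calibration.proportion_nominal,
            "seed": calibration.seed,
        }
        sum_path = out / "calibration_summary.json"
        sum_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        paths["calibration"] = cal_path
        paths["calibration_summary"] = sum_path
    else:
        note = out / "calibration_summary.json"
        note.write_text(json.dumps({"calibration": "skipped"}) + "\n")
        paths["calibration_summary"] = note

    ok = results[results["status"] == "ok"]
    fig_path = out / "forest.png"
    if len(ok):
        labels = (
            ok["disease"].astype(str)
            + (" | " + ok["scenario"].astype(str) if "scenario" in ok.columns else "")
        )
        ypos = np.arange(len(ok))[::-1]
        height = max(2.0, 0.32 * len(ok) + 1.2)
        fig, ax = plt.subplots(figsize=(7, height))
        ax.errorbar(
            ok["beta_d_mb"], ypos,
            xerr=[ok["beta_d_mb"] - ok["ci_low"], ok["ci_high"] - ok["beta_d_mb"]],
            fmt="o", color="#2c3e50", ecolor="#7f8c8d", capsize=2, markersize=4,
        )
        ax.axvline(0.0, color="#c0392b", lw=0.8, ls="--")
        ax.set_yticks(ypos)
        ax.set_yticklabels(labels, fontsize=7)
        ax.set_xlabel("causal effect of log P/B ratio (95% CI)")
        fig.tight_layout()
        fig.savefig(fig_path, dpi=150, metadata={"Software": None})
        plt.close(fig)
        paths["figure"] = fig_path
    return paths
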