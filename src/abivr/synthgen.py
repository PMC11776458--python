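"""Synthetic two-sample biobank generator.

Produces paired EHR-style table sets with the statistical structure the
AB-IVR estimator assumes: a large outcome cohort ("sample 1", disease
follow-up recorded) and a small, disjoint microbiome cohort ("sample 2",
genus-level relative abundances recorded), linked only through a shared
generative model in which cumulative antibiotic usage shifts the log
Prevotella/Bacteroides ratio additively, and incident disease risk depends
on that ratio through a logistic model.

Violation knobs (confounding, a direct instrument->outcome path, and a
disease->usage feedback loop) allow stress-testing the estimator when the
instrumental-variable assumptions fail.
"""

from __future__ import annotations

import dataclasses
import numbers
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "ScenarioError",
    "DiseaseSpec",
    "SimScenario",
    "SimulatedStudy",
    "simulate_two_samples",
    "simulate_log_pb",
]

AB_CLASS_NAMES = ("J01CR", "J01FA", "J01MA", "other")

# Representative ATC codes drawn per antibiotic subclass when emitting
# prescription rows. "other" pools the remaining J01 families.
_ATC_POOLS = {
    "J01CR": ("J01CR02", "J01CR05"),
    "J01FA": ("J01FA09", "J01FA10", "J01FA06"),
    "J01MA": ("J01MA02", "J01MA06", "J01MA12"),
    "other": ("J01CA04", "J01DB05", "J01DC02", "J01EE01", "J01XE01"),
}

_FILLER_GENERA = (
    "Faecalibacterium", "Roseburia", "Alistipes", "Blautia", "Bifidobacterium",
    "Ruminococcus", "Akkermansia", "Eubacterium", "Dorea", "Coprococcus",
    "Parabacteroides", "Oscillibacter", "Dialister", "Collinsella",
    "Streptococcus", "Lachnospira", "Butyrivibrio", "Odoribacter",
)

# Prescription dates are drawn as whole-day offsets before the index date.
# The in-window band [190, 3640] sits strictly inside the 10-year/6-month
# counting window for every calendar index date, and the washout band
# [1, 175] sits strictly inside the 6-month washout, so generated courses
# never straddle a window boundary regardless of month lengths.
_WINDOW_OFFSET_DAYS = (190, 3640)
_WASHOUT_OFFSET_DAYS = (1, 175)


class ScenarioError(ValueError):
    """A scenario field violates its invariant."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"invalid scenario field {field_name!r}: {message}")


@dataclass(frozen=True)
class DiseaseSpec:
    """One simulated disease: target incidence and causal log-odds slope.

    ``causal_beta`` is the change in log-odds of incident disease per unit
    log P/B ratio; ``baseline_prevalence`` is the marginal incidence the
    intercept is calibrated to.
    """

    name: str
    icd10_code: str
    baseline_prevalence: float
    causal_beta: float


DEFAULT_DISEASES = (
    DiseaseSpec("irritable_bowel_syndrome", "K58", 0.05, -0.5),
    DiseaseSpec("migraine", "G43", 0.06, -0.3),
    DiseaseSpec("depression", "F32", 0.08, 0.0),
)


@dataclass(frozen=True)
class SimScenario:
    """All knobs of the two-sample generator.

    Defaults encode the confounding-free study conditions: disjoint cohorts
    of 50,000 (outcome) and 2,500 (microbiome) subjects, an overdispersed
    long-tailed 10-year antibiotic count, near-independent subclass usage,
    a bimodal (enterotype-mixture) baseline log P/B ratio, and a shared
    additive usage effect on log P/B.
    """

    n_sample1: int = 50_000
    n_sample2: int = 2_500
    seed: int = 0
    # Negative-binomial total course count: mean, gamma shape (dispersion;
    # larger = closer to Poisson), and a hard truncation cap.
    ab_count_mean: float = 3.0
    ab_count_dispersion: float = 3.0
    ab_count_max: int = 30
    # Per-course allocation probabilities for (J01CR, J01FA, J01MA, other).
    class_split: tuple = (0.15, 0.15, 0.10, 0.60)
    washout_prob: float = 0.10
    # Two-component Gaussian mixture for the baseline log P/B ratio.
    enterotype_weights: tuple = (0.7, 0.3)
    enterotype_means: tuple = (-2.0, 1.0)
    enterotype_sds: tuple = (1.0, 1.0)
    pb_noise_sd: float = 0.25
    # Additive change in log P/B per course; scalar (shared across classes)
    # or a length-4 sequence aligned with AB_CLASS_NAMES.
    ab_effect: object = -0.3
    disease_specs: tuple = DEFAULT_DISEASES
    prevalent_frac: float = 0.02
    confounder_strength: float = 0.0
    direct_effect: float = 0.0
    feedback_strength: float = 0.0
    age_range: tuple = (18, 89)
    sex_ratio: float = 0.6  # proportion female
    index_date_sample1: str = "2015-01-01"
    mb_collection_window: tuple = ("2017-11-01", "2020-07-31")
    followup_start: str = "2015-01-01"
    followup_end: str = "2022-12-31"

    # ------------------------------------------------------------------ #
    def validate(self) -> "SimScenario":
        if not (isinstance(self.n_sample1, numbers.Integral) and self.n_sample1 > 0):
            raise ScenarioError("n_sample1", "must be a positive integer")
        if not (isinstance(self.n_sample2, numbers.Integral) and self.n_sample2 > 0):
            raise ScenarioError("n_sample2", "must be a positive integer")
        if self.ab_count_mean <= 0:
            raise ScenarioError("ab_count_mean", "must be > 0")
        if self.ab_count_dispersion <= 0:
            raise ScenarioError("ab_count_dispersion", "must be > 0")
        if self.ab_count_max < 0:
            raise ScenarioError("ab_count_max", "must be >= 0")
        split = np.asarray(self.class_split, dtype=float)
        if split.shape != (len(AB_CLASS_NAMES),):
            raise ScenarioError("class_split", f"needs {len(AB_CLASS_NAMES)} entries")
        if np.any(split < 0) or np.any(split > 1):
            raise ScenarioError("class_split", "probabilities must lie in [0, 1]")
        if abs(split.sum() - 1.0) > 1e-9:
            raise ScenarioError("class_split", "must sum to 1 within 1e-9")
        for name in ("washout_prob", "sex_ratio", "prevalent_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(name, "must lie in [0, 1]")
        w = np.asarray(self.enterotype_weights, dtype=float)
        mu = np.asarray(self.enterotype_means, dtype=float)
        sd = np.asarray(self.enterotype_sds, dtype=float)
        if not (w.shape == mu.shape == sd.shape) or w.ndim != 1 or w.size < 1:
            raise ScenarioError("enterotype_mix", "weights/means/sds must be equal-length vectors")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ScenarioError("enterotype_weights", "must be non-negative and sum to 1")
        if np.any(sd <= 0):
            raise ScenarioError("enterotype_sds", "must be > 0")
        if self.pb_noise_sd < 0:
            raise ScenarioError("pb_noise_sd", "must be >= 0")
        eff = np.atleast_1d(np.asarray(self.ab_effect, dtype=float))
        if eff.size not in (1, len(AB_CLASS_NAMES)):
            raise ScenarioError("ab_effect", "must be scalar or one value per subclass")
        if not self.disease_specs:
            raise ScenarioError("disease_specs", "at least one disease is required")
        seen = set()
        for spec in self.disease_specs:
            if not 0.0 < spec.baseline_prevalence < 1.0:
                raise ScenarioError("disease_specs", f"{spec.name}: baseline_prevalence must be in (0, 1)")
            if spec.name in seen:
                raise ScenarioError("disease_specs", f"duplicate disease name {spec.name!r}")
            seen.add(spec.name)
        lo, hi = self.age_range
        if not (0 < lo <= hi):
            raise ScenarioError("age_range", "must satisfy 0 < min <= max")
        if self.feedback_strength < 0:
            raise ScenarioError("feedback_strength", "must be >= 0")
        return self

    # ------------------------------------------------------------------ #
    def ab_effect_vector(self) -> np.ndarray:
        eff = np.atleast_1d(np.asarray(self.ab_effect, dtype=float))
        if eff.size == 1:
            return np.repeat(eff, len(AB_CLASS_NAMES))
        return eff

    def disease_codes(self) -> dict:
        """Disease-name -> ICD-10 prefix list mapping for cohort building."""
        return {d.name: [d.icd10_code] for d in self.disease_specs}

    @classmethod
    def from_dict(cls, cfg: dict) -> "SimScenario":
        cfg = dict(cfg)
        if "disease_specs" in cfg:
            cfg["disease_specs"] = tuple(
                d if isinstance(d, DiseaseSpec) else DiseaseSpec(**d)
                for d in cfg["disease_specs"]
            )
        for key in ("class_split", "enterotype_weights", "enterotype_means",
                    "enterotype_sds", "age_range", "mb_collection_window"):
            if key in cfg and isinstance(cfg[key], list):
                cfg[key] = tuple(cfg[key])
        return cls(**cfg).validate()

    @classmethod
    def from_yaml(cls, path) -> "SimScenario":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls.from_dict(cfg)


# ---------------------------------------------------------------------- #
@dataclass
class SimulatedStudy:
    """Output bundle of :func:`simulate_two_samples`.

    ``sample1``/``sample2`` hold the standard input tables (as written to
    disk); ``truth1``/``truth2`` hold the latent per-person generative state
    (true course counts, latent log P/B, confounder) for validation only and
    are never written by :meth:`write`.
    """

    sample1: dict
    sample2: dict
    truth1: pd.DataFrame
    truth2: pd.DataFrame
    scenario: SimScenario

    def write(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        for name, tables in (("sample1", self.sample1), ("sample2", self.sample2)):
            sub = out / name
            sub.mkdir(parents=True, exist_ok=True)
            for tname, df in tables.items():
                frame = df.copy()
                for col in frame.columns:
                    if pd.api.types.is_datetime64_any_dtype(frame[col]):
                        frame[col] = frame[col].dt.strftime("%Y-%m-%d")
                frame.to_csv(sub / f"{tname}.tsv", sep="\t", index=False)
        with open(out / "diseases.yaml", "w") as fh:
            yaml.safe_dump(self.scenario.disease_codes(), fh, sort_keys=True)


def simulate_log_pb(n_ab_by_class, scenario: SimScenario, rng,
                    confounder=None, disease_onset=None) -> np.ndarray:
    """Draw log P/B ratios given per-person antibiotic course counts.

    value = enterotype-mixture draw
            + sum_class ab_effect[class] * count[class]
            + confounder_strength * confounder
            - feedback_strength * disease_onset
            + N(0, pb_noise_sd)

    Parameters
    ----------
    n_ab_by_class : array of shape (n, 4) or (n,)
        Course counts per subclass (columns ordered as ``AB_CLASS_NAMES``);
        a 1-D array is treated as total counts under a shared effect.
    """
    counts = np.asarray(n_ab_by_class)
    if np.any(counts < 0):
        raise ValueError("antibiotic course counts must be non-negative")
    if counts.ndim == 1:
        counts = counts[:, None]
        effects = np.array([float(np.mean(scenario.ab_effect_vector()))])
        if np.ptp(scenario.ab_effect_vector()) > 0:
            raise ValueError("per-class ab_effect requires per-class counts")
    elif counts.ndim == 2 and counts.shape[1] == len(AB_CLASS_NAMES):
        effects = scenario.ab_effect_vector()
    else:
        raise ValueError("n_ab_by_class must have shape (n,) or (n, 4)")
    n = counts.shape[0]

    w = np.asarray(scenario.enterotype_weights, dtype=float)
    mu = np.asarray(scenario.enterotype_means, dtype=float)
    sd = np.asarray(scenario.enterotype_sds, dtype=float)
    comp = rng.choice(w.size, size=n, p=w)
    value = rng.normal(mu[comp], sd[comp])
    value = value + counts @ effects
    if confounder is not None:
        value = value + scenario.confounder_strength * np.asarray(confounder, dtype=float)
    if disease_onset is not None:
        value = value - scenario.feedback_strength * np.asarray(disease_onset, dtype=float)
    if scenario.pb_noise_sd > 0:
        value = value + rng.normal(0.0, scenario.pb_noise_sd, size=n)
    return value


def simulate_two_samples(scenario: SimScenario) -> SimulatedStudy:
    """Generate the paired outcome and microbiome cohorts.

    Person-id sets of the two samples are disjoint by construction. All
    randomness flows from ``scenario.seed`` through per-table substreams, so
    repeated calls are byte-identical.
    """
    scenario.validate()
    root = np.random.SeedSequence(scenario.seed)
    ss1, ss2 = root.spawn(2)
    s1_tables, truth1 = _simulate_sample(scenario, scenario.n_sample1, "S1", ss1, kind="outcome")
    s2_tables, truth2 = _simulate_sample(scenario, scenario.n_sample2, "S2", ss2, kind="microbiome")
    return SimulatedStudy(s1_tables, s2_tables, truth1, truth2, scenario)


# ---------------------------------------------------------------------- #
# internals

def _simulate_sample(scenario, n, prefix, seedseq, kind):
    rng_demo, rng_counts, rng_pb, rng_rx, rng_dx, rng_genus = (
        np.random.default_rng(s) for s in seedseq.spawn(6)
    )
    person_id = np.array([f"{prefix}_{i:06d}" for i in range(n)])

    if kind == "outcome":
        index_dates = pd.Series(
            np.full(n, np.datetime64(scenario.index_date_sample1)), index=person_id
        )
    else:
        w0, w1 = (pd.Timestamp(d) for d in scenario.mb_collection_window)
        span = (w1 - w0).days
        offs = rng_demo.integers(0, span + 1, size=n)
        index_dates = pd.Series(w0 + pd.to_timedelta(offs, unit="D"), index=person_id)

    lo, hi = scenario.age_range
    ages = rng_demo.integers(lo, hi + 1, size=n)
    # Birth placed so that the completed age at the index date equals the
    # drawn age; the 5..360-day margin keeps calendar wobble from flipping it.
    extra = rng_demo.uniform(5.0, 360.0, size=n)
    birth = (
        pd.DatetimeIndex(index_dates.values)
        - pd.to_timedelta(np.round(ages * 365.2425 + extra), unit="D")
    ).normalize()
    sex = np.where(rng_demo.random(n) < scenario.sex_ratio, "female", "male")
    confounder = rng_demo.normal(0.0, 1.0, size=n)

    # Latent pre-index disease onset drives the feedback loop: extra courses
    # and a shifted microbiome before follow-up starts.
    onset_by_disease = {}
    any_onset = np.zeros(n, dtype=bool)
    if scenario.feedback_strength > 0:
        for spec in scenario.disease_specs:
            o = rng_counts.random(n) < spec.baseline_prevalence
            onset_by_disease[spec.name] = o
            any_onset |= o
    else:
        for spec in scenario.disease_specs:
            onset_by_disease[spec.name] = np.zeros(n, dtype=bool)

    k = scenario.ab_count_dispersion
    lam = rng_counts.gamma(k, scenario.ab_count_mean / k, size=n)
    lam = lam * np.exp(scenario.confounder_strength * confounder)
    total = rng_counts.poisson(lam)
    if scenario.feedback_strength > 0:
        total = total + rng_counts.poisson(scenario.feedback_strength, size=n) * any_onset
    total = np.minimum(total, scenario.ab_count_max)
    class_counts = rng_counts.multinomial(total, np.asarray(scenario.class_split, dtype=float))

    log_pb_true = simulate_log_pb(
        class_counts, scenario, rng_pb, confounder=confounder, disease_onset=any_onset
    )

    prescriptions = _make_prescriptions(scenario, person_id, class_counts, index_dates, rng_rx)
    subjects = pd.DataFrame(
        {
            "person_id": person_id,
            "birth_date": birth,
            "sex": sex,
            "index_date": pd.DatetimeIndex(index_dates.values),
        }
    )

    tables = {"subjects": subjects, "prescriptions": prescriptions}
    if kind == "outcome":
        tables["diagnoses"] = _make_diagnoses(
            scenario, person_id, total, log_pb_true, confounder, onset_by_disease, rng_dx
        )
    else:
        tables["genus_abundance"] = _make_genus_table(person_id, log_pb_true, rng_genus)

    truth = pd.DataFrame(
        {
            "person_id": person_id,
            "age": ages,
            "sex": sex,
            "confounder": confounder,
            "any_onset": any_onset,
            "n_ab_total_true": total,
            "log_pb_true": log_pb_true,
        }
    )
    for j, cname in enumerate(AB_CLASS_NAMES):
        truth[f"n_ab_{cname}_true"] = class_counts[:, j]
    return tables, truth


def _make_prescriptions(scenario, person_id, class_counts, index_dates, rng):
    lo, hi = _WINDOW_OFFSET_DAYS
    pieces = []
    for j, cname in enumerate(AB_CLASS_NAMES):
        reps = class_counts[:, j]
        m = int(reps.sum())
        if m == 0:
            continue
        pid = np.repeat(person_id, reps)
        idx = np.repeat(index_dates.values, reps)
        offs = rng.integers(lo, hi + 1, size=m)
        atc = rng.choice(_ATC_POOLS[cname], size=m)
        pieces.append(pd.DataFrame({"person_id": pid, "_idx": idx, "_off": offs, "atc_code": atc}))

    # Washout violators get one extra course inside the 6-month washout.
    wlo, whi = _WASHOUT_OFFSET_DAYS
    wmask = rng.random(person_id.size) < scenario.washout_prob
    mw = int(wmask.sum())
    if mw:
        cls = rng.choice(len(AB_CLASS_NAMES), size=mw, p=np.asarray(scenario.class_split, dtype=float))
        atc = np.array([rng.choice(_ATC_POOLS[AB_CLASS_NAMES[c]]) for c in cls])
        pieces.append(
            pd.DataFrame(
                {
                    "person_id": person_id[wmask],
                    "_idx": index_dates.values[wmask],
                    "_off": rng.integers(wlo, whi + 1, size=mw),
                    "atc_code": atc,
                }
            )
        )
    if not pieces:
        return pd.DataFrame(columns=["person_id", "date", "atc_code"])

    rx = pd.concat(pieces, ignore_index=True)
    # Redraw offsets until each person's course dates are distinct, so that
    # same-day-same-code deduplication downstream cannot drop real courses.
    for _ in range(20):
        dup = rx.duplicated(["person_id", "_off"], keep="first")
        if not dup.any():
            break
        rx.loc[dup, "_off"] = rng.integers(lo, hi + 1, size=int(dup.sum()))
    rx["date"] = pd.DatetimeIndex(rx["_idx"]) - pd.to_timedelta(rx["_off"], unit="D")
    rx = rx[["person_id", "date", "atc_code"]].sort_values(
        ["person_id", "date", "atc_code"], kind="mergesort"
    )
    return rx.reset_index(drop=True)


def _calibrated_intercept(eta, target):
    if np.ptp(eta) == 0:
        return float(logit(target) - eta[0])
    f = lambda b0: expit(b0 + eta).mean() - target
    return brentq(f, -40.0, 40.0, xtol=1e-12)


def _make_diagnoses(scenario, person_id, total, log_pb, confounder, onset_by_disease, rng):
    fs = pd.Timestamp(scenario.followup_start)
    fe = pd.Timestamp(scenario.followup_end)
    n_follow = (fe - fs).days  # incident offsets drawn in [1, n_follow]
    rows = []
    n = person_id.size
    for spec in scenario.disease_specs:
        eta = (
            spec.causal_beta * log_pb
            + scenario.confounder_strength * confounder
            + scenario.direct_effect * total
        )
        b0 = _calibrated_intercept(eta, spec.baseline_prevalence)
        diseased = rng.random(n) < expit(b0 + eta)

        prevalent = rng.random(n) < scenario.prevalent_frac
        if prevalent.any():
            offs = rng.integers(1, 3651, size=int(prevalent.sum()))
            rows.append(
                pd.DataFrame(
                    {
                        "person_id": person_id[prevalent],
                        "date": fs - pd.to_timedelta(offs, unit="D"),
                        "icd10_code": spec.icd10_code,
                    }
                )
            )
        onset = onset_by_disease[spec.name]
        if onset.any():
            # Undiagnosed pre-existing disease surfaces early in follow-up.
            offs = rng.integers(1, 1826, size=int(onset.sum()))
            rows.append(
                pd.DataFrame(
                    {
                        "person_id": person_id[onset],
                        "date": fs + pd.to_timedelta(offs, unit="D"),
                        "icd10_code": spec.icd10_code,
                    }
                )
            )
        inc = diseased & ~onset
        if inc.any():
            offs = rng.integers(1, n_follow + 1, size=int(inc.sum()))
            rows.append(
                pd.DataFrame(
                    {
                        "person_id": person_id[inc],
                        "date": fs + pd.to_timedelta(offs, unit="D"),
                        "icd10_code": spec.icd10_code,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=["person_id", "date", "icd10_code"])
    dx = pd.concat(rows, ignore_index=True)
    dx = dx.sort_values(["person_id", "date", "icd10_code"], kind="mergesort")
    return dx.reset_index(drop=True)


def _make_genus_table(person_id, log_pb, rng, detection_limit=0.01):
    """MetaPhlAn-style wide genus table (rows sum to 100, percent units).

    Prevotella and Bacteroides split a Beta-distributed share of each row
    according to exp(log_pb); filler genera share the remainder via a
    sparse symmetric Dirichlet. Values below the detection limit are zeroed
    and rows renormalized (the P/B ratio is invariant to renormalization).
    """
    n = person_id.size
    share = rng.beta(5.0, 5.0, size=n)
    r = np.exp(log_pb)
    prev = 100.0 * share * r / (1.0 + r)
    bact = 100.0 * share / (1.0 + r)
    filler = rng.dirichlet(np.full(len(_FILLER_GENERA), 0.3), size=n)
    filler = 100.0 * (1.0 - share)[:, None] * filler

    mat = np.column_stack([prev, bact, filler])
    mat[mat < detection_limit] = 0.0
    mat = 100.0 * mat / mat.sum(axis=1, keepdims=True)
    cols = ["Prevotella", "Bacteroides", *_FILLER_GENERA]
    out = pd.DataFrame(mat, columns=cols)
    out.insert(0, "person_id", person_id)
    return out
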