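"""Synthetic EHR cohort generator.

Emulates a biobank-style cohort in which participants carry genomic risk
factors (a monogenic familial-hypercholesterolemia-style carrier flag and a
standardized polygenic risk score), develop coronary heart disease with an
age-dependent Gompertz baseline hazard and multiplicative (proportional-
hazards) genetic/sex effects, and leave behind a fragmented billing-code
stream: encounters arrive as a Poisson process inside observation windows,
some participants have a long gap splitting their record in two, some have a
spurious "backfilled" code at an early age, and self-reported disease status
is an imperfect (sensitivity/specificity) reflection of the truth.

Ground truth (latent onset ages, true case status) is written separately from
the observable tables so downstream phenotyping, segmentation, and modelling
stages can be validated against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

DAYS_PER_YEAR = 365.25

#: toy code vocabulary used by the simulator; matches the packaged default CodeSet
GENERIC_CODE = ("Z00", "ICD10", "diagnosis")
MI_CODE = ("I21", "ICD10", "diagnosis")
PCI_CODE = ("92920", "CPT4", "procedure")
CABG_CODE = ("33533", "CPT4", "procedure")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Ages are in years unless suffixed ``_days``. Hazard parameters refer to
    the Gompertz baseline h0(t) = a * exp(b * t) with t age in years.
    """

    n_participants: int = 5000
    n_sites: int = 10
    seed: int = 0
    monogenic_prevalence: float = 0.006
    prs_high_quantile: float = 0.95
    female_fraction: float = 0.674
    # baseline cumulative incidence by 75 ~= 0.13 for an unexposed female
    gompertz_a: float = 2.0e-5
    gompertz_b: float = 0.085
    log_hr_monogenic: float = math.log(1.85)
    log_hr_prs_high: float = math.log(2.0)
    log_hr_male: float = math.log(1.7)
    # age at first EHR record (truncated normal)
    ehr_entry_age_mean: float = 40.0
    ehr_entry_age_sd: float = 15.0
    ehr_entry_age_min: float = 1.0
    ehr_entry_age_max: float = 70.0
    # age at study enrollment, independent of the EHR stream
    enrollment_age_mean: float = 51.2
    enrollment_age_sd: float = 14.9
    enrollment_age_min: float = 18.0
    enrollment_age_max: float = 90.0
    encounter_rate: float = 5.0  # generic codes per person-year inside windows
    fragmentation_prob: float = 0.45
    gap_threshold_years: float = 1.5
    gap_excess_mean_years: float = 5.5  # gap length = threshold + Exp(mean)
    artifact_prob: float = 0.10
    artifact_age_min: float = 2.0
    artifact_age_max: float = 15.0
    selfreport_sensitivity: float = 0.60
    selfreport_specificity: float = 0.98
    survey_response_prob: float = 0.97
    admin_censor_age: float = 85.0
    min_adult_age: float = 18.0
    # mix of emitted CHD sub-phenotypes (MI, PCI, CABG)
    subphenotype_mix: tuple = (0.5, 0.3, 0.2)

    def validate(self) -> None:
        probs = {
            "monogenic_prevalence": self.monogenic_prevalence,
            "prs_high_quantile": self.prs_high_quantile,
            "female_fraction": self.female_fraction,
            "fragmentation_prob": self.fragmentation_prob,
            "artifact_prob": self.artifact_prob,
            "selfreport_sensitivity": self.selfreport_sensitivity,
            "selfreport_specificity": self.selfreport_specificity,
            "survey_response_prob": self.survey_response_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.gompertz_a <= 0:
            raise ValueError("gompertz_a must be positive")
        if self.encounter_rate <= 0:
            raise ValueError("encounter_rate must be positive")
        if self.admin_censor_age <= self.ehr_entry_age_mean:
            raise ValueError("admin_censor_age must exceed mean EHR entry age")
        if self.n_participants <= 0 or self.n_sites <= 0:
            raise ValueError("n_participants and n_sites must be positive")
        if abs(sum(self.subphenotype_mix) - 1.0) > 1e-9:
            raise ValueError("subphenotype_mix must sum to 1")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "subphenotype_mix" in raw:
            raw["subphenotype_mix"] = tuple(raw["subphenotype_mix"])
        return cls(**raw)


@dataclass
class TruthRecord:
    """Ground truth for one participant (never read by analysis modules)."""

    participant_id: str
    true_onset_age: Optional[float]  # years; None if no lifetime onset
    true_chd: bool
    monogenic: bool
    prs_standardized: float
    high_prs: bool
    sex: str  # {"female", "male"}
    site: str
    enrollment_age: float
    component: Optional[str] = None  # {"mi", "pci", "cabg"} for true cases


def simulate_onset_age(
    monogenic: bool,
    high_prs: bool,
    sex: str,
    config: SimConfig,
    uniform_draw: float,
) -> Optional[float]:
    """Invert the Gompertz proportional-hazards cumulative hazard.

    With baseline h0(t) = a·exp(b·t) and rate multiplier
    r = exp(sum of applicable log hazard ratios), the onset age solving
    H(T) = -log(U) is T = (1/b)·log(1 - b·log(U)/(a·r)); b = 0 falls back to
    the exponential closed form -log(U)/(a·r). Returns ``None`` when no onset
    occurs within a lifetime (argument of the log non-positive, possible for
    b < 0) or when T exceeds the administrative censoring age.
    """
    if not 0.0 < uniform_draw < 1.0:
        raise ValueError("uniform_draw must be in (0, 1)")
    if config.gompertz_a <= 0:
        raise ValueError("gompertz_a must be positive")
    a, b = config.gompertz_a, config.gompertz_b
    r = math.exp(
        (config.log_hr_monogenic if monogenic else 0.0)
        + (config.log_hr_prs_high if high_prs else 0.0)
        + (config.log_hr_male if sex == "male" else 0.0)
    )
    neg_log_u = -math.log(uniform_draw)
    if b == 0.0:
        t = neg_log_u / (a * r)
    else:
        arg = 1.0 + b * neg_log_u / (a * r)
        if arg <= 0.0:
            return None
        t = math.log(arg) / b
    if t > config.admin_censor_age:
        return None
    return t


def _onset_ages_vectorized(
    rate_multiplier: np.ndarray, u: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Vectorized inverse-cumulative-hazard draw; NaN where no onset."""
    a, b = config.gompertz_a, config.gompertz_b
    neg_log_u = -np.log(u)
    if b == 0.0:
        t = neg_log_u / (a * rate_multiplier)
    else:
        arg = 1.0 + b * neg_log_u / (a * rate_multiplier)
        t = np.where(arg > 0.0, np.log(np.maximum(arg, 1e-300)) / b, np.nan)
    return np.where(t <= config.admin_censor_age, t, np.nan)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    if sd == 0.0:
        return np.full(size, min(max(mean, lo), hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=size)
    return mean + sd * stats.norm.ppf(u)


def simulate_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the latent cohort: exposures, covariates, and true onset ages."""
    n = config.n_participants
    pid = np.array([f"P{i:06d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    site = np.array([f"site_{i:02d}" for i in rng.integers(0, config.n_sites, n)])
    monogenic = rng.random(n) < config.monogenic_prevalence
    prs = rng.standard_normal(n)
    # fixed externally-calibrated cut-off: theoretical normal quantile
    threshold = stats.norm.ppf(config.prs_high_quantile)
    high_prs = prs >= threshold
    enroll = _truncated_normal(
        rng,
        config.enrollment_age_mean,
        config.enrollment_age_sd,
        config.enrollment_age_min,
        config.enrollment_age_max,
        n,
    )
    log_r = (
        config.log_hr_monogenic * monogenic
        + config.log_hr_prs_high * high_prs
        + config.log_hr_male * (sex == "male")
    )
    u = rng.uniform(1e-12, 1.0, size=n)
    onset = _onset_ages_vectorized(np.exp(log_r), u, config)
    true_chd = ~np.isnan(onset)
    component = np.full(n, "", dtype=object)
    n_cases = int(true_chd.sum())
    if n_cases:
        component[true_chd] = rng.choice(
            ["mi", "pci", "cabg"], size=n_cases, p=list(config.subphenotype_mix)
        )
    return pd.DataFrame(
        {
            "participant_id": pid,
            "true_onset_age": onset,
            "true_chd": true_chd,
            "monogenic": monogenic,
            "prs_standardized": prs,
            "high_prs": high_prs,
            "sex": sex,
            "site": site,
            "enrollment_age": enroll,
            "component": component,
        }
    )


def _years_to_days(age_years) -> int:
    return int(round(age_years * DAYS_PER_YEAR))


def emit_billing_stream(truth: TruthRecord, config: SimConfig, rng: np.random.Generator) -> list:
    """Emit one participant's billing records as a list of dicts.

    Observation windows are built by optionally splitting [entry, admin_censor]
    with a long gap (> the segmentation threshold); generic codes arrive as a
    homogeneous Poisson process inside windows; CHD codes are emitted at the
    true onset age when the onset falls inside a window; with probability
    ``artifact_prob`` a single spurious early code precedes the true entry.
    Ages are reported at day resolution.
    """
    entry = float(
        _truncated_normal(
            rng,
            config.ehr_entry_age_mean,
            config.ehr_entry_age_sd,
            config.ehr_entry_age_min,
            config.ehr_entry_age_max,
            1,
        )[0]
    )
    censor = config.admin_censor_age
    if entry >= censor:
        raise ValueError("empty observation window: entry age at/after admin censoring")
    windows = [(entry, censor)]
    if rng.random() < config.fragmentation_prob and censor - entry > 1.0:
        gap = config.gap_threshold_years + rng.exponential(config.gap_excess_mean_years)
        split = rng.uniform(entry + 0.5, censor - 0.5)
        if split + gap < censor - 0.1:
            windows = [(entry, split), (split + gap, censor)]
        else:
            windows = [(entry, split)]

    rows = []

    def add(age_years, code_tuple):
        code, system, kind = code_tuple
        rows.append(
            {
                "participant_id": truth.participant_id,
                "code": code,
                "code_system": system,
                "record_kind": kind,
                "age_days": _years_to_days(age_years),
            }
        )

    for w0, w1 in windows:
        k = rng.poisson(config.encounter_rate * (w1 - w0))
        for age in rng.uniform(w0, w1, size=k):
            add(age, GENERIC_CODE)
    if not rows:
        add(entry, GENERIC_CODE)  # every participant has at least one encounter

    onset = truth.true_onset_age
    if onset is not None and any(w0 <= onset <= w1 for w0, w1 in windows):
        if truth.component == "mi":
            add(onset, MI_CODE)
            delta_days = int(rng.integers(0, 6))  # second code within the 5-day window
            add(onset + delta_days / DAYS_PER_YEAR, MI_CODE)
        elif truth.component == "cabg":
            add(onset, CABG_CODE)
        else:
            add(onset, PCI_CODE)

    if rng.random() < config.artifact_prob:
        age = rng.uniform(config.artifact_age_min, config.artifact_age_max)
        add(age, GENERIC_CODE)  # backfilled artifact followed by a long gap
    return rows


def simulate_self_report(true_chd: bool, config: SimConfig, rng: np.random.Generator) -> bool:
    """Misclassified survey answer: P(+|case)=sensitivity, P(+|non-case)=1-specificity."""
    if true_chd:
        return bool(rng.random() < config.selfreport_sensitivity)
    return bool(rng.random() < 1.0 - config.selfreport_specificity)


def simulate_cohort(config: SimConfig) -> dict:
    """Generate the full cohort.

    Returns ``{"participants": ..., "billing": ..., "truth": ...}`` DataFrames.
    All randomness flows from ``config.seed`` through named substreams so the
    output is bit-identical for a fixed seed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    truth_rng, billing_rng, survey_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    truth = simulate_truth(config, truth_rng)

    billing_rows = []
    for row in truth.itertuples(index=False):
        rec = TruthRecord(
            participant_id=row.participant_id,
            true_onset_age=None if np.isnan(row.true_onset_age) else float(row.true_onset_age),
            true_chd=bool(row.true_chd),
            monogenic=bool(row.monogenic),
            prs_standardized=float(row.prs_standardized),
            high_prs=bool(row.high_prs),
            sex=row.sex,
            site=row.site,
            enrollment_age=float(row.enrollment_age),
            component=row.component or None,
        )
        billing_rows.extend(emit_billing_stream(rec, config, billing_rng))
    billing = pd.DataFrame(billing_rows)
    billing = billing.sort_values(["participant_id", "age_days"], kind="mergesort").reset_index(
        drop=True
    )

    n = config.n_participants
    responded = survey_rng.random(n) < config.survey_response_prob
    u_report = survey_rng.random(n)
    pos_prob = np.where(
        truth["true_chd"], config.selfreport_sensitivity, 1.0 - config.selfreport_specificity
    )
    sr_chd = u_report < pos_prob
    # sub-phenotype answers: true cases report their true component; false
    # positives endorse a random component half the time (survey skip logic:
    # sub-answers only exist for self-reported CHD)
    comp = truth["component"].to_numpy()
    fp_mask = sr_chd & ~truth["true_chd"].to_numpy()
    fp_component = np.full(n, "", dtype=object)
    if fp_mask.sum():
        draw = survey_rng.random(int(fp_mask.sum()))
        picks = survey_rng.choice(["mi", "pci", "cabg"], size=int(fp_mask.sum()),
                                  p=list(config.subphenotype_mix))
        fp_component[fp_mask] = np.where(draw < 0.5, picks, "")
    reported_comp = np.where(truth["true_chd"].to_numpy(), comp, fp_component)

    def sub_flag(name):
        return sr_chd & (reported_comp == name)

    participants = pd.DataFrame(
        {
            "participant_id": truth["participant_id"],
            "sex": truth["sex"],
            "site": truth["site"],
            "enrollment_age_years": truth["enrollment_age"],
            "monogenic": truth["monogenic"],
            "prs_standardized": truth["prs_standardized"],
            "high_prs": truth["high_prs"],
            "selfreport_chd": pd.array(np.where(responded, sr_chd, None), dtype="boolean"),
            "selfreport_mi": pd.array(np.where(responded, sub_flag("mi"), None), dtype="boolean"),
            "selfreport_pci": pd.array(np.where(responded, sub_flag("pci"), None), dtype="boolean"),
            "selfreport_cabg": pd.array(np.where(responded, sub_flag("cabg"), None), dtype="boolean"),
        }
    )
    return {"participants": participants, "billing": billing, "truth": truth}


def write_cohort(tables: dict, out_dir) -> dict:
    """Write participants.csv / billing.csv / truth.csv; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("participants", "billing", "truth"):
        p = out / f"{name}.csv"
        tables[name].to_csv(p, index=False)
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# Direct generators for estimator validation (parameter recovery)
# ---------------------------------------------------------------------------

def simulate_binary_risk_cohort(
    n: int,
    seed: int,
    baseline_risk: float = 0.02,
    log_rr_high_prs: float = math.log(2.0),
    log_rr_monogenic: float = math.log(1.8),
    log_rr_male: float = math.log(1.5),
    config: Optional[SimConfig] = None,
) -> pd.DataFrame:
    """Binary outcome under a multiplicative-risk (log-link) model.

    P(Y=1) = baseline_risk · exp(sum of applicable log relative risks), so the
    true RR of each exposure is known exactly — the ground truth against which
    the modified-Poisson estimator is validated.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    site = np.array([f"site_{i:02d}" for i in rng.integers(0, config.n_sites, n)])
    monogenic = rng.random(n) < config.monogenic_prevalence
    prs = rng.standard_normal(n)
    high_prs = prs >= stats.norm.ppf(config.prs_high_quantile)
    enroll = _truncated_normal(
        rng, config.enrollment_age_mean, config.enrollment_age_sd,
        config.enrollment_age_min, config.enrollment_age_max, n,
    )
    obs_years = rng.uniform(2.0, 30.0, size=n)
    p = baseline_risk * np.exp(
        log_rr_high_prs * high_prs
        + log_rr_monogenic * monogenic
        + log_rr_male * (sex == "male")
    )
    if p.max() >= 1.0:
        raise ValueError("risk model exceeds probability 1; lower baseline_risk")
    y = rng.random(n) < p
    return pd.DataFrame(
        {
            "monogenic": monogenic,
            "high_prs": high_prs,
            "sex": sex,
            "site": site,
            "enrollment_age_years": enroll,
            "obs_years": obs_years,
            "outcome": y,
        }
    )


def simulate_survival_cohort(
    n: int,
    seed: int,
    config: Optional[SimConfig] = None,
    left_truncate: bool = True,
) -> pd.DataFrame:
    """Left-truncated survival data from the Gompertz PH generator.

    Entry ages follow the EHR entry-age distribution; subjects whose onset
    precedes entry are never observed (the truncation mechanism itself).
    Exit is onset or a censoring age uniform between entry and the
    administrative limit. True log hazard ratios come from ``config``.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    site = np.array([f"site_{i:02d}" for i in rng.integers(0, config.n_sites, n)])
    monogenic = rng.random(n) < config.monogenic_prevalence
    prs = rng.standard_normal(n)
    high_prs = prs >= stats.norm.ppf(config.prs_high_quantile)
    log_r = (
        config.log_hr_monogenic * monogenic
        + config.log_hr_prs_high * high_prs
        + config.log_hr_male * (sex == "male")
    )
    u = rng.uniform(1e-12, 1.0, size=n)
    onset = _onset_ages_vectorized(np.exp(log_r), u, config)
    onset = np.where(np.isnan(onset), np.inf, onset)
    if left_truncate:
        entry = _truncated_normal(
            rng, config.ehr_entry_age_mean, config.ehr_entry_age_sd,
            config.ehr_entry_age_min, config.ehr_entry_age_max, n,
        )
    else:
        entry = np.zeros(n)
    censor = rng.uniform(entry, config.admin_censor_age)
    exit_age = np.minimum(onset, censor)
    event = onset <= censor
    observed = exit_age > entry  # onset before entry ⇒ truncated away
    df = pd.DataFrame(
        {
            "entry_age_years": entry,
            "exit_age_years": exit_age,
            "event": event,
            "monogenic": monogenic,
            "high_prs": high_prs,
            "sex": sex,
            "sex_male": sex == "male",
            "site": site,
        }
    )
    return df.loc[observed].reset_index(drop=True)
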