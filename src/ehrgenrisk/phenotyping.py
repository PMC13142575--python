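"""Rule-based CHD phenotyping from billing codes, and survey harmonization.

The EHR algorithm targets "hard" coronary heart disease: myocardial
infarction (at least two MI diagnosis codes within a 5-day window) and
coronary revascularization (at least one CABG or PCI procedure code). Onset
is the earliest of the component onsets. Self-reported status comes from
baseline survey questions, harmonized onto the same sub-phenotypes, and a
combined definition takes the union of the two sources.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

BILLING_COLUMNS = ["participant_id", "code", "code_system", "record_kind", "age_days"]


def normalize_code(code: str) -> str:
    """Trim, uppercase, and strip dots (ICD dialects differ in dot usage)."""
    return str(code).strip().upper().replace(".", "")


@dataclass(frozen=True)
class CodeSet:
    """Billing-code definitions of the three CHD components.

    Members are sets of ``(code_system, code)`` pairs with codes normalized.
    """

    mi_diagnosis: frozenset
    cabg_procedure: frozenset
    pci_procedure: frozenset

    def __post_init__(self):
        sets = [self.mi_diagnosis, self.cabg_procedure, self.pci_procedure]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("component code sets must be pairwise disjoint")

    @staticmethod
    def _norm(pairs) -> frozenset:
        return frozenset((str(sys_).strip(), normalize_code(code)) for sys_, code in pairs)

    @classmethod
    def from_dict(cls, d: dict) -> "CodeSet":
        def pairs(key):
            return cls._norm((e["code_system"], e["code"]) for e in d.get(key, []))

        return cls(
            mi_diagnosis=pairs("mi_diagnosis"),
            cabg_procedure=pairs("cabg_procedure"),
            pci_procedure=pairs("pci_procedure"),
        )

    @classmethod
    def from_yaml(cls, path) -> "CodeSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_codeset() -> CodeSet:
    """Toy code set matching the simulator's vocabulary.

    Real-data use requires supplying the study's full ICD/CPT lists as config.
    """
    return CodeSet.from_dict(
        {
            "mi_diagnosis": [
                {"code_system": "ICD10", "code": "I21"},
                {"code_system": "ICD9", "code": "410"},
            ],
            "cabg_procedure": [
                {"code_system": "CPT4", "code": "33533"},
                {"code_system": "ICD10PCS", "code": "0210"},
            ],
            "pci_procedure": [
                {"code_system": "CPT4", "code": "92920"},
                {"code_system": "ICD10PCS", "code": "02703ZZ"},
            ],
        }
    )


def _match_mask(records: pd.DataFrame, pairs: frozenset, kind: str) -> np.ndarray:
    keys = list(
        zip(
            records["code_system"].astype(str).str.strip(),
            records["code"].map(normalize_code),
        )
    )
    in_set = np.fromiter((k in pairs for k in keys), dtype=bool, count=len(keys))
    return in_set & (records["record_kind"].to_numpy() == kind)


def detect_mi(
    records: pd.DataFrame, codeset: CodeSet, window_days: int = 5
) -> tuple[bool, Optional[int]]:
    """Two MI diagnosis codes within ``window_days`` of each other.

    Positive iff two distinct MI-diagnosis records differ in age by at most
    the window (same-day distinct records qualify); onset is the earlier age
    of the earliest qualifying pair. Order- and duplicate-invariant.
    """
    if window_days < 0:
        raise ValueError("window_days must be non-negative")
    if records.empty:
        return False, None
    ages = np.sort(records.loc[_match_mask(records, codeset.mi_diagnosis, "diagnosis"),
                               "age_days"].to_numpy())
    if ages.size < 2:
        return False, None
    close = np.diff(ages) <= window_days
    if not close.any():
        return False, None
    return True, int(ages[int(np.argmax(close))])


def detect_procedure(records: pd.DataFrame, codes: frozenset) -> tuple[bool, Optional[int]]:
    """At least one matching procedure code; first age is the minimum match."""
    if records.empty:
        return False, None
    ages = records.loc[_match_mask(records, codes, "procedure"), "age_days"]
    if ages.empty:
        return False, None
    return True, int(ages.min())


def classify_chd(records: pd.DataFrame, codeset: CodeSet, window_days: int = 5) -> dict:
    """Combine MI / CABG / PCI detection into a PhenotypeResult dict.

    ``chd`` holds iff any component holds; onset is the minimum component onset.
    """
    mi, mi_age = detect_mi(records, codeset, window_days)
    cabg, cabg_age = detect_procedure(records, codeset.cabg_procedure)
    pci, pci_age = detect_procedure(records, codeset.pci_procedure)
    onsets = [a for a in (mi_age, cabg_age, pci_age) if a is not None]
    pid = records["participant_id"].iloc[0] if len(records) else None
    return {
        "participant_id": pid,
        "mi": mi,
        "pci": pci,
        "cabg": cabg,
        "chd": mi or pci or cabg,
        "onset_age_days": min(onsets) if onsets else None,
    }


def phenotype_cohort(
    billing: pd.DataFrame, codeset: CodeSet, window_days: int = 5
) -> pd.DataFrame:
    """Vectorized `classify_chd` over a whole billing table.

    Returns one row per participant present in ``billing``.
    """
    if billing.empty:
        return pd.DataFrame(
            columns=["participant_id", "mi", "pci", "cabg", "chd", "onset_age_days"]
        )
    df = billing.copy()
    mi_mask = _match_mask(df, codeset.mi_diagnosis, "diagnosis")
    cabg_mask = _match_mask(df, codeset.cabg_procedure, "procedure")
    pci_mask = _match_mask(df, codeset.pci_procedure, "procedure")

    def first_match(mask):
        sub = df.loc[mask]
        return sub.groupby("participant_id")["age_days"].min()

    # MI: earliest qualifying pair among sorted MI ages per participant
    mi_sub = df.loc[mi_mask, ["participant_id", "age_days"]].sort_values(
        ["participant_id", "age_days"], kind="mergesort"
    )
    mi_onsets = {}
    for pid, grp in mi_sub.groupby("participant_id", sort=False):
        ages = grp["age_days"].to_numpy()
        if ages.size < 2:
            continue
        close = np.diff(ages) <= window_days
        if close.any():
            mi_onsets[pid] = int(ages[int(np.argmax(close))])
    mi_onsets = pd.Series(mi_onsets, dtype="float64")

    cabg_onsets = first_match(cabg_mask)
    pci_onsets = first_match(pci_mask)

    pids = df["participant_id"].drop_duplicates().sort_values()
    out = pd.DataFrame({"participant_id": pids}).set_index("participant_id")
    out["mi_onset"] = mi_onsets
    out["cabg_onset"] = cabg_onsets
    out["pci_onset"] = pci_onsets
    out["mi"] = out["mi_onset"].notna()
    out["cabg"] = out["cabg_onset"].notna()
    out["pci"] = out["pci_onset"].notna()
    out["chd"] = out[["mi", "pci", "cabg"]].any(axis=1)
    out["onset_age_days"] = out[["mi_onset", "cabg_onset", "pci_onset"]].min(axis=1)
    return (
        out.reset_index()[["participant_id", "mi", "pci", "cabg", "chd", "onset_age_days"]]
    )


def harmonize_self_report(survey: pd.DataFrame) -> pd.DataFrame:
    """Map baseline-survey answers to a SelfReportStatus table.

    Expected columns (boolean, possibly missing): ``currently_have``,
    ``had_in_past``, ``heart_attack``, ``bypass_surgery``, ``stenting``.
    CHD is positive if either CHD question is positive; sub-phenotypes map
    heart attack → MI, bypass surgery → CABG, stenting → PCI and can only be
    positive when CHD is positive (survey skip logic). A participant with
    both CHD answers missing has missing CHD status.
    """
    cur = survey["currently_have"].astype("boolean")
    past = survey["had_in_past"].astype("boolean")
    chd = (cur.fillna(False) | past.fillna(False)).astype("boolean")
    chd[cur.isna() & past.isna()] = pd.NA

    def sub(col):
        flag = survey[col].astype("boolean").fillna(False)
        return (flag & chd.fillna(False)).astype("boolean")

    return pd.DataFrame(
        {
            "participant_id": survey["participant_id"],
            "chd": chd,
            "mi": sub("heart_attack"),
            "cabg": sub("bypass_surgery"),
            "pci": sub("stenting"),
        }
    )


def combine_cases(ehr_chd: pd.Series, sr_chd: pd.Series) -> pd.Series:
    """Union case definition: positive iff either source is positive.

    Missing self-report counts as negative for the union.
    """
    ehr = ehr_chd.astype("boolean").fillna(False)
    sr = sr_chd.astype("boolean").fillna(False)
    return (ehr | sr).astype(bool)
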