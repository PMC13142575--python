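"""Cross-source case-status agreement statistics.

Cross-tabulates EHR-algorithm and self-reported case status (overall and by
sub-phenotype) and computes overall agreement, positive (case-level)
agreement, per-source discordance rates, and Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ContingencyTable:
    both_pos: int
    both_neg: int
    ehr_only: int
    sr_only: int

    def __post_init__(self):
        for v in (self.both_pos, self.both_neg, self.ehr_only, self.sr_only):
            if v < 0:
                raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.both_pos + self.both_neg + self.ehr_only + self.sr_only


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round-half-up to match conventional printed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def cross_tabulate(
    ehr_status: pd.Series,
    sr_status: pd.Series,
    restrict_to: str = "both_available",
    sr_chd: pd.Series | None = None,
) -> ContingencyTable:
    """Cross-tabulate two per-participant status series (aligned on index).

    ``restrict_to="both_available"`` drops participants with missing
    self-report; ``restrict_to="self_reported_cases"`` additionally restricts
    to participants with self-reported CHD (``sr_chd``), the denominator used
    for sub-phenotype tables.
    """
    ehr = ehr_status.astype("boolean")
    sr = sr_status.astype("boolean")
    keep = sr.notna() & ehr.notna()
    if restrict_to == "self_reported_cases":
        if sr_chd is None:
            raise ValueError("restrict_to='self_reported_cases' requires sr_chd")
        keep &= sr_chd.astype("boolean").fillna(False)
    elif restrict_to != "both_available":
        raise ValueError(f"unknown restriction {restrict_to!r}")
    e = ehr[keep].astype(bool).to_numpy()
    s = sr[keep].astype(bool).to_numpy()
    return ContingencyTable(
        both_pos=int((e & s).sum()),
        both_neg=int((~e & ~s).sum()),
        ehr_only=int((e & ~s).sum()),
        sr_only=int((~e & s).sum()),
    )


def overall_agreement(t: ContingencyTable) -> float:
    """Proportion of participants classified identically by both sources."""
    if t.total == 0:
        raise ValueError("empty contingency table")
    return (t.both_pos + t.both_neg) / t.total


def positive_agreement(t: ContingencyTable) -> float:
    """Agreement among participants positive by at least one source."""
    denom = t.both_pos + t.ehr_only + t.sr_only
    if denom == 0:
        raise ValueError("no positive participants in either source")
    return t.both_pos / denom


def discordance_rates(t: ContingencyTable) -> tuple[float | None, float | None]:
    """(share of self-report positives missed by EHR, and vice versa).

    A zero marginal makes the corresponding rate undefined (returned as None).
    """
    sr_marginal = t.both_pos + t.sr_only
    ehr_marginal = t.both_pos + t.ehr_only
    sr_missed = t.sr_only / sr_marginal if sr_marginal else None
    ehr_missed = t.ehr_only / ehr_marginal if ehr_marginal else None
    return sr_missed, ehr_missed


def cohens_kappa(t: ContingencyTable) -> float:
    """Chance-corrected agreement (companion statistic, reported alongside)."""
    n = t.total
    if n == 0:
        raise ValueError("empty contingency table")
    po = (t.both_pos + t.both_neg) / n
    p_ehr = (t.both_pos + t.ehr_only) / n
    p_sr = (t.both_pos + t.sr_only) / n
    pe = p_ehr * p_sr + (1 - p_ehr) * (1 - p_sr)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def _table_dict(t: ContingencyTable) -> dict:
    d = {
        "both_pos": t.both_pos,
        "both_neg": t.both_neg,
        "ehr_only": t.ehr_only,
        "sr_only": t.sr_only,
        "total": t.total,
        "overall_agreement_pct": round_half_up(100 * overall_agreement(t)),
        "kappa": cohens_kappa(t),
    }
    pos_denom = t.both_pos + t.ehr_only + t.sr_only
    d["positive_agreement_pct"] = (
        round_half_up(100 * positive_agreement(t)) if pos_denom else None
    )
    sr_missed, ehr_missed = discordance_rates(t)
    d["sr_pos_missed_by_ehr_pct"] = (
        round_half_up(100 * sr_missed) if sr_missed is not None else None
    )
    d["ehr_pos_missed_by_sr_pct"] = (
        round_half_up(100 * ehr_missed) if ehr_missed is not None else None
    )
    for cell in ("both_pos", "both_neg", "ehr_only", "sr_only"):
        d[f"{cell}_pct"] = round_half_up(100 * d[cell] / t.total) if t.total else None
    return d


def agreement_report(ehr_pheno: pd.DataFrame, self_report: pd.DataFrame) -> dict:
    """Build the full agreement report (counts and percentages).

    ``ehr_pheno`` has boolean columns mi/pci/cabg/chd; ``self_report`` has
    nullable-boolean columns chd/mi/pci/cabg. Both are indexed (or keyed) by
    participant_id; participants missing from either table are aligned as
    missing. The overall CHD table is restricted to participants with both
    sources available, sub-phenotype tables to self-reported CHD cases.
    """
    e = ehr_pheno.set_index("participant_id") if "participant_id" in ehr_pheno else ehr_pheno
    s = (
        self_report.set_index("participant_id")
        if "participant_id" in self_report
        else self_report
    )
    idx = e.index.union(s.index)
    e = e.reindex(idx)
    s = s.reindex(idx)
    sr_chd = s["chd"]
    report = {
        "n_ehr": int(e["chd"].notna().sum()),
        "n_survey": int(sr_chd.notna().sum()),
        "ehr_cases": int(e["chd"].fillna(False).astype(bool).sum()),
        "sr_cases": int(sr_chd.fillna(False).astype(bool).sum()),
    }
    report["ehr_prevalence_pct"] = round_half_up(100 * report["ehr_cases"] / report["n_ehr"])
    report["sr_prevalence_pct"] = round_half_up(100 * report["sr_cases"] / report["n_survey"])
    report["chd"] = _table_dict(
        cross_tabulate(e["chd"], sr_chd, restrict_to="both_available")
    )
    for sub in ("mi", "pci", "cabg"):
        report[sub] = _table_dict(
            cross_tabulate(
                e[sub], s[sub], restrict_to="self_reported_cases", sr_chd=sr_chd
            )
        )
    return report
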