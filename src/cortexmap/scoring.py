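"""Semiquantitative neuropathology scoring and cohort summaries.

Encodes the scoring system used to stage Alzheimer's disease neuropathologic
change (ADNC) in tumor-adjacent cortex:

* cortical tumor-cell infiltration graded low / medium / high from the
  nonneuronal cell fraction (medium ≈ 1:1 neurons to nonneuronal cells,
  high > 70% nonneuronal);
* CERAD neuritic plaque score 0 / A / B / C (0 = no neuritic plaques, i.e.
  diffuse plaques only; A = 1–3 per high-power field; B = 5–10; C = > 20;
  unassigned gap counts map to the nearest boundary);
* ADNC category from the deposit flags: AT (parenchymal Abeta + pTau),
  T (pTau only), A (parenchymal Abeta only), vascular_only, none;
* a combined severity score adding the 0–3 ranks of the Braak & Braak group
  and the CERAD score;
* APP expression (absent/sparse/moderate/abundant) and diffuse axonal
  injury (absent/sparse/moderate/frequent) scales;
* cohort prevalence tables with half-up integer display rounding;
* Cohen's kappa for inter-rater agreement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "SeverityScore",
    "BRAAK_RANK",
    "CERAD_RANK",
    "ADNC_SET",
    "grade_infiltration",
    "cerad_score",
    "classify_adnc",
    "combined_severity",
    "score_app",
    "score_dai",
    "cohort_prevalence",
    "adnc_prevalence",
    "percent_round_half_up",
    "cohens_kappa",
]

BRAAK_RANK = {"0": 0, "I-II": 1, "III-IV": 2, "V-VI": 3}
CERAD_RANK = {"0": 0, "A": 1, "B": 2, "C": 3}
ADNC_SET = ("AT", "T", "A")  # vascular_only optionally included


@dataclass
class PatientRecord:
    """One patient's semiquantitative scores and demographics."""

    patient_id: str
    age: float
    sex: str = "NA"
    lobe: str = "NA"
    hemisphere: str = "NA"
    adnc_category: str = "none"
    cerad: str = "NA"
    braak_group: str = "NA"
    caa_vessel: bool = False
    caa_capillary: bool = False
    infiltration: str = "low"
    app_tumor: str = "absent"
    app_neuron: str = "absent"
    dai: str = "absent"
    survival_days: float | None = None
    mgmt_methylated: bool | None = None

    def __post_init__(self):
        if not 0.0 <= self.age <= 120.0:
            raise ValueError(f"age must lie in [0, 120], got {self.age}")
        if self.adnc_category == "none" and self.cerad not in ("0", "NA"):
            raise ValueError("category 'none' requires CERAD in {0, NA}")


@dataclass(frozen=True)
class SeverityScore:
    """Ordinal ADNC severity: Braak-group rank + CERAD rank, range 0–6."""

    braak_rank: int
    cerad_rank: int

    @property
    def value(self) -> int:
        return self.braak_rank + self.cerad_rank


def grade_infiltration(neuron_count: int, nonneuron_count: int) -> str:
    """Low / medium / high cortical tumor-cell infiltration.

    High: nonneuronal fraction > 0.70. Medium: fraction in [0.45, 0.70]
    (operationalizing "approximately 1:1"). Low otherwise.
    """
    if neuron_count < 0 or nonneuron_count < 0:
        raise ValueError("counts must be >= 0")
    total = neuron_count + nonneuron_count
    if total == 0:
        raise ValueError("cannot grade infiltration with zero cells")
    frac = nonneuron_count / total
    if frac > 0.70:
        return "high"
    if frac >= 0.45:
        return "medium"
    return "low"


def cerad_score(neuritic_per_hpf: float, diffuse_present: bool = False) -> str:
    """CERAD neuritic plaque score.

    0 with no neuritic plaques (diffuse plaques alone stay 0); A for 1–3 per
    high-power field; B for 5–10; C above 20. The unassigned gaps map to the
    nearest boundary (4 → A, 11–19 → B).
    """
    if neuritic_per_hpf < 0:
        raise ValueError(f"plaque count must be >= 0, got {neuritic_per_hpf}")
    if neuritic_per_hpf == 0:
        return "0"
    if neuritic_per_hpf <= 4:
        return "A"
    if neuritic_per_hpf < 20:
        return "B"
    return "C"


def classify_adnc(abeta_parenchymal: bool, ptau: bool, abeta_vascular: bool = False) -> str:
    """ADNC category from the three deposit flags."""
    if abeta_parenchymal and ptau:
        return "AT"
    if ptau:
        return "T"
    if abeta_parenchymal:
        return "A"
    if abeta_vascular:
        return "vascular_only"
    return "none"


def combined_severity(braak_group: str, cerad: str) -> SeverityScore | None:
    """Rank-sum severity of the two staging systems; NA input yields None."""
    if braak_group in (None, "NA") or cerad in (None, "NA"):
        warnings.warn("combined_severity: NA input yields NA output", stacklevel=2)
        return None
    if braak_group not in BRAAK_RANK:
        raise ValueError(f"unknown Braak group {braak_group!r}")
    if cerad not in CERAD_RANK:
        raise ValueError(f"unknown CERAD score {cerad!r}")
    return SeverityScore(BRAAK_RANK[braak_group], CERAD_RANK[cerad])


def score_app(fraction_positive_percent: float) -> str:
    """APP expression scale: absent < 1%, sparse 1–5%, moderate 10–30%,
    abundant > 50% (gap percentages map to the nearest boundary)."""
    f = fraction_positive_percent
    if f < 0 or f > 100:
        raise ValueError(f"percentage must lie in [0, 100], got {f}")
    if f < 1:
        return "absent"
    if f <= 7.5:  # 1–5% band plus its nearest-boundary gap share
        return "sparse"
    if f <= 40:  # 10–30% band plus its gap share
        return "moderate"
    return "abundant"


def score_dai(spheroids_per_hpf_hotspot: float) -> str:
    """Diffuse axonal injury: APP-positive axonal spheroids per high-power
    field in hot spots (sparse 1–10, moderate 10–30, frequent > 30)."""
    n = spheroids_per_hpf_hotspot
    if n < 0:
        raise ValueError(f"spheroid count must be >= 0, got {n}")
    if n < 1:
        return "absent"
    if n <= 10:
        return "sparse"
    if n <= 30:
        return "moderate"
    return "frequent"


def percent_round_half_up(fraction: float) -> int:
    """Display rounding of a fraction to integer percent, half away from zero
    (22/205 → 11%)."""
    return int(math.floor(100.0 * fraction + 0.5))


def cohort_prevalence(records: pd.DataFrame, column: str = "adnc_category") -> pd.DataFrame:
    """Count and percent of each level of a categorical column.

    Returns one row per observed level with ``count``, ``fraction`` (raw)
    and ``percent`` (half-up integer, for display), sorted by count
    descending.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty cohort table")
    n = len(records)
    counts = records[column].value_counts()
    return pd.DataFrame(
        {
            "category": counts.index,
            "count": counts.to_numpy(),
            "fraction": counts.to_numpy() / n,
            "percent": [percent_round_half_up(c / n) for c in counts.to_numpy()],
        }
    ).reset_index(drop=True)


def adnc_prevalence(records: pd.DataFrame, include_vascular: bool = False) -> dict:
    """Overall ADNC prevalence.

    A record counts as ADNC-positive if it carries an explicit boolean
    ``adnc`` column set True, otherwise if its ``adnc_category`` is in
    {AT, T, A} (plus ``vascular_only`` when ``include_vascular``).
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty cohort table")
    if "adnc" in records.columns:
        flag = records["adnc"].astype(bool)
    else:
        cats = ADNC_SET + (("vascular_only",) if include_vascular else ())
        flag = records["adnc_category"].isin(cats)
    n = len(records)
    k = int(flag.sum())
    return {"count": k, "n": n, "fraction": k / n, "percent": percent_round_half_up(k / n)}


def cohens_kappa(rater1, rater2) -> float:
    """Cohen's kappa for two categorical rating vectors.

    κ = (p_o − p_e) / (1 − p_e) with chance agreement p_e from the product
    of marginals. Perfect agreement returns 1 even when p_e = 1 (both raters
    constant and identical, warned); two constant but different raters are a
    degenerate chance-level case and return 0 with a warning.
    """
    r1 = np.asarray(rater1)
    r2 = np.asarray(rater2)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("rating vectors must be 1-D and of equal length")
    n = len(r1)
    if n < 2:
        raise ValueError("need at least 2 ratings")
    cats = np.union1d(r1, r2)
    p_o = float(np.mean(r1 == r2))
    p1 = np.array([np.mean(r1 == c) for c in cats])
    p2 = np.array([np.mean(r2 == c) for c in cats])
    p_e = float(p1 @ p2)
    if p_o == 1.0:
        if p_e == 1.0:
            warnings.warn(
                "both raters constant and identical: kappa defined as 1", stacklevel=2
            )
        return 1.0
    if p_e == 1.0:  # unreachable when p_o < 1, kept for clarity
        warnings.warn("degenerate chance agreement p_e = 1", stacklevel=2)
        return 0.0
    if p_e == 0.0 and p_o == 0.0:
        warnings.warn(
            "raters constant but different: degenerate table, kappa set to 0", stacklevel=2
        )
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)
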