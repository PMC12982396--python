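"""Corrected basophil-activity scoring and responder classification.

The central quantity is the corrected activity readout. For a challenged
sample, with all fractions normalized to CD45+ leukocytes:

    b  total (intact) basophil fraction
    c  CD63++ basophil fraction
    m  missing-basophil fraction = max(b_reference - b_challenged, 0),
       the drop in total basophils relative to the matched unchallenged
       sample of the same culture arm

    A = (c + m) / (b + m)

Strongly activated basophils can leave the standard scatter gate entirely;
adding the lost fraction to both numerator and denominator counts them as
activated instead of silently shrinking the basophil pool. Fold changes:

    fc_allergen = A(ALG) / [c(CTRL)/b(CTRL)]       (allergen response)
    bat_fc      = A(ALG_OMA) / A(ALG)              (omalizumab response)

each arm's m computed against its own unchallenged sample (CTRL for the
untreated arm, OMA for the omalizumab arm). A lower BAT Fc means a better
in vitro response to omalizumab. BAT positivity uses the clinical convention
(> 5% CD63++ among basophils under allergen); exclusion applies the
positivity filter first and a Tukey-hinge IQR outlier rule on the remaining
BAT Fc values second.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .gating import PopulationCounts
from .synthetic import Condition

logger = logging.getLogger(__name__)

#: Clinical BAT positivity cutoff: > 5% of basophils CD63++ under allergen.
BAT_POSITIVITY_CUTOFF = 0.05

#: Unchallenged reference condition per culture arm.
ARMS: dict[str, tuple[Condition, Condition]] = {
    "untreated": (Condition.CTRL, Condition.ALG),
    "omalizumab": (Condition.OMA, Condition.ALG_OMA),
}


class ScoringError(ValueError):
    """Raised on inconsistent condition summaries."""


@dataclass(frozen=True)
class ConditionSummary:
    """CD45-normalized basophil fractions of one condition.

    ``b``: intact-basophil fraction of CD45+ leukocytes; ``c``: CD63++
    fraction of CD45+ leukocytes; ``p63 = c/b`` is the CD63++ fraction of
    basophils (the clinical readout). Invalid samples (no CD45+ events) carry
    ``valid=False`` and NaN fractions.
    """

    condition: Condition
    b: float
    c: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and not (0.0 <= self.c <= self.b <= 1.0):
            raise ScoringError(
                f"{self.condition.value}: need 0 <= c <= b <= 1, got "
                f"c={self.c}, b={self.b}"
            )

    @property
    def p63(self) -> float:
        """CD63++ fraction of basophils; NaN when b = 0 (degenerate)."""
        if not self.valid or self.b == 0:
            return float("nan")
        return self.c / self.b


@dataclass(frozen=True)
class ActivityResult:
    """Corrected-activity quantities of one culture arm."""

    arm: str                  # "untreated" | "omalizumab"
    m: float                  # missing-basophil fraction of CD45+
    A_challenged: float       # corrected activity of the challenged sample
    A_reference: float        # uncorrected activity (c/b) of the unchallenged one
    valid: bool = True


@dataclass(frozen=True)
class ResponseProfile:
    """Per-donor response readouts and bookkeeping flags."""

    donor_id: str
    fc_allergen: float = float("nan")
    bat_fc: float = float("nan")
    positive_bat: bool = False
    excluded: str = "none"            # none | nonreactive | outlier
    responder_class: str = "unassigned"  # better | poor_non | unassigned
    valid: bool = True

    @property
    def included(self) -> bool:
        return self.valid and self.excluded == "none"


def condition_summaries(
    counts: Mapping[Condition | str, PopulationCounts]
) -> dict[Condition, ConditionSummary]:
    """Condition summaries from the gated counts of all four conditions.

    b = n_basophil_intact / n_cd45 and c = n_cd63pos / n_cd45; altered-scatter
    events deliberately do not enter b or c — they surface only through the
    missing-basophil term m, which compares b across conditions.
    """
    out: dict[Condition, ConditionSummary] = {}
    for condition in (Condition.CTRL, Condition.OMA, Condition.ALG,
                      Condition.ALG_OMA):
        key = condition if condition in counts else condition.value
        if key not in counts:
            raise ScoringError(f"missing condition: {condition.value}")
        pc = counts[key]
        if pc.n_cd45 == 0:
            logger.warning("condition %s has no CD45+ events; flagged invalid",
                           condition.value)
            out[condition] = ConditionSummary(condition, float("nan"),
                                              float("nan"), valid=False)
        else:
            out[condition] = ConditionSummary(
                condition,
                b=pc.n_basophil_intact / pc.n_cd45,
                c=pc.n_cd63pos / pc.n_cd45,
            )
    return out


def missing_basophils(ref: ConditionSummary, challenged: ConditionSummary) -> float:
    """Missing-basophil fraction m = max(ref.b - challenged.b, 0).

    ``ref`` and ``challenged`` must belong to the same culture arm
    (CTRL vs ALG, or OMA vs ALG_OMA). Negative loss clamps to zero: missing
    basophils are defined as a decrease.
    """
    pairs = set(ARMS.values())
    if (ref.condition, challenged.condition) not in pairs:
        raise ScoringError(
            f"arm mismatch: {ref.condition.value} is not the unchallenged "
            f"reference of {challenged.condition.value}"
        )
    return max(ref.b - challenged.b, 0.0)


def corrected_activity(challenged: ConditionSummary, m: float) -> float:
    """A = (c + m) / (b + m); NaN (flagged by caller) when b + m = 0."""
    if m < 0:
        raise ScoringError("m must be >= 0")
    denom = challenged.b + m
    if denom == 0:
        return float("nan")
    return (challenged.c + m) / denom


def activity_results(
    summaries: Mapping[Condition, ConditionSummary]
) -> dict[str, ActivityResult]:
    """Corrected activity of both arms from the four condition summaries."""
    out: dict[str, ActivityResult] = {}
    for arm, (ref_cond, chall_cond) in ARMS.items():
        ref, chall = summaries[ref_cond], summaries[chall_cond]
        if not (ref.valid and chall.valid):
            out[arm] = ActivityResult(arm, float("nan"), float("nan"),
                                      float("nan"), valid=False)
            continue
        m = missing_basophils(ref, chall)
        a = corrected_activity(chall, m)
        out[arm] = ActivityResult(arm, m, a, ref.p63,
                                  valid=not math.isnan(a) and not math.isnan(ref.p63))
    return out


def response_profile(
    donor_id: str, summaries: Mapping[Condition, ConditionSummary]
) -> ResponseProfile:
    """Fold changes and BAT positivity for one donor.

    The allergen-response denominator is the control sample's uncorrected
    activity c/b; the control has m = 0 by construction, so corrected and
    uncorrected coincide there.
    """
    arms = activity_results(summaries)
    unt, oma = arms["untreated"], arms["omalizumab"]
    if not (unt.valid and oma.valid):
        return ResponseProfile(donor_id, valid=False)
    if unt.A_reference == 0 or unt.A_challenged == 0:
        logger.warning("donor %s: zero reference or challenged activity; "
                       "profile flagged invalid", donor_id)
        return ResponseProfile(donor_id, valid=False)
    p63_alg = summaries[Condition.ALG].p63
    return ResponseProfile(
        donor_id=donor_id,
        fc_allergen=unt.A_challenged / unt.A_reference,
        bat_fc=oma.A_challenged / unt.A_challenged,
        positive_bat=bool(p63_alg > BAT_POSITIVITY_CUTOFF),
    )


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def tukey_hinges(values: Sequence[float]) -> tuple[float, float]:
    """Tukey hinges H1, H3: medians of the lower/upper halves of the sorted
    data, with both halves including the overall median when n is odd."""
    s = np.sort(np.asarray(values, dtype=float))
    n = s.size
    if n < 2:
        raise ScoringError("tukey_hinges: need at least 2 values")
    half = n // 2 + 1 if n % 2 else n // 2
    return float(np.median(s[:half])), float(np.median(s[-half:]))


def tukey_fences(values: Sequence[float], k: float = 1.5) -> tuple[float, float]:
    """Outlier fences [H1 - k*IQR, H3 + k*IQR] with hinge-based IQR."""
    h1, h3 = tukey_hinges(values)
    iqr = h3 - h1
    return h1 - k * iqr, h3 + k * iqr


def apply_exclusions(
    profiles: Sequence[ResponseProfile],
    min_for_outlier_rule: int = 4,
) -> tuple[list[ResponseProfile], list[dict]]:
    """Flag non-reactive donors, then Tukey BAT-Fc outliers.

    Order is fixed: the > 5% CD63++ positivity filter runs first, and the
    Tukey-hinge IQR rule runs on the BAT Fc values of the remaining donors
    only, so non-reactive samples never enter the IQR computation. With fewer
    than ``min_for_outlier_rule`` remaining values the outlier step is
    skipped with a warning. Returns the updated profiles and an audit trail
    (one record per donor with its inclusion decision).
    """
    out = list(profiles)
    audit: list[dict] = []

    for i, p in enumerate(out):
        if not p.valid:
            audit.append({"donor_id": p.donor_id, "decision": "invalid",
                          "rule": "invalid_counts"})
        elif not p.positive_bat:
            out[i] = replace(p, excluded="nonreactive",
                             responder_class="unassigned")
            audit.append({"donor_id": p.donor_id, "decision": "excluded",
                          "rule": "bat_positivity_5pct"})

    remaining = [(i, p) for i, p in enumerate(out) if p.included]
    if len(remaining) < min_for_outlier_rule:
        logger.warning("only %d reactive donors; Tukey outlier step skipped",
                       len(remaining))
    else:
        lo, hi = tukey_fences([p.bat_fc for _, p in remaining])
        for i, p in remaining:
            if not (lo <= p.bat_fc <= hi):
                out[i] = replace(p, excluded="outlier",
                                 responder_class="unassigned")
                audit.append({"donor_id": p.donor_id, "decision": "excluded",
                              "rule": "tukey_iqr", "fences": [lo, hi],
                              "bat_fc": p.bat_fc})

    for p in out:
        if p.included:
            audit.append({"donor_id": p.donor_id, "decision": "included",
                          "rule": "none"})
    return out, audit


# ---------------------------------------------------------------------------
# responder classification
# ---------------------------------------------------------------------------

def classify_rank_split(
    profiles: Sequence[ResponseProfile]
) -> list[ResponseProfile]:
    """Rank included donors by BAT Fc and split into two groups.

    Lower half (stronger blockade) = ``better``; upper half = ``poor_non``.
    For odd n the median donor goes to ``poor_non`` (conservative toward
    non-response); ties break by donor_id. Excluded donors stay unassigned.
    """
    out = list(profiles)
    included = [(i, p) for i, p in enumerate(out) if p.included]
    order = sorted(included, key=lambda ip: (ip[1].bat_fc, ip[1].donor_id))
    n_better = len(order) // 2
    for rank, (i, p) in enumerate(order):
        label = "better" if rank < n_better else "poor_non"
        out[i] = replace(p, responder_class=label)
    return out


def classify_margin(
    profiles: Sequence[ResponseProfile], margin: float = 0.6
) -> list[ResponseProfile]:
    """Classify included donors against a fixed BAT-Fc margin.

    ``better`` iff bat_fc < margin; the boundary value itself goes to
    ``poor_non`` (conservative). The default 0.6 is the midpoint separating
    the two rank-split groups of a discovery-scale cohort.
    """
    if margin <= 0:
        raise ScoringError("margin must be > 0")
    out = list(profiles)
    for i, p in enumerate(out):
        if p.included:
            label = "better" if p.bat_fc < margin else "poor_non"
            out[i] = replace(p, responder_class=label)
    return out


def profiles_table(profiles: Sequence[ResponseProfile]):
    """Tidy per-donor table of response profiles."""
    import pandas as pd

    return pd.DataFrame([{
        "donor_id": p.donor_id,
        "fc_allergen": p.fc_allergen,
        "bat_fc": p.bat_fc,
        "positive_bat": p.positive_bat,
        "excluded": p.excluded,
        "responder_class": p.responder_class,
        "valid": p.valid,
    } for p in profiles])
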