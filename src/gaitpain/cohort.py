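"""Per-person analytic variables for the walking-pain analysis.

Turns a participant table (per-knee walking-pain ratings, per-exam KL
grades, covariates) plus a speed-filtered gait-feature table into the
analysis table used by variable selection and the association models:

* a binary outcome (no pain vs mild unilateral pain while walking), with
  bilateral-pain participants excluded and moderate-or-worse unilateral
  pain set missing;
* a 3-category outcome that keeps the moderate/severe unilateral group;
* a radiographic osteoarthritis count (knees with KL grade >= 2, 0-2),
  back-filling a missing current KL grade from the most recent prior exam;
* standardized continuous variables.

Every drop or exclusion is counted in a flow log so the final sample is
fully accounted for.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "PAIN_LEVELS",
    "build_pain_outcomes",
    "build_roa_status",
    "assemble_analysis_table",
    "CONTINUOUS_VARIABLES",
]

log = logging.getLogger(__name__)

PAIN_LEVELS = ("none", "mild", "moderate", "severe", "extreme")

#: severities grouped as "moderate or severe" for the 3-category outcome;
#: "extreme" is grouped there too (configurable via the functions below).
_MODSEV_LEVELS = ("moderate", "severe", "extreme")

#: continuous variables standardized in the analysis table
CONTINUOUS_VARIABLES = ("age", "bmi", "cesd")


def build_pain_outcomes(
    participants: pd.DataFrame, modsev_levels: tuple[str, ...] = _MODSEV_LEVELS
) -> pd.DataFrame:
    """Derive the 2- and 3-category walking-pain outcomes per participant.

    Returns a frame indexed like the input with columns ``outcome2``
    (``no_pain`` / ``mild_unilateral`` / NaN), ``outcome3`` (``no_pain`` /
    ``mild_unilateral`` / ``modsev_unilateral`` / NaN) and ``pain_flow``
    (``no_pain`` / ``mild`` / ``modsev`` / ``excluded_bilateral`` /
    ``dropped_missing``).  Bilateral pain excludes the participant from
    both outcomes; a missing rating on either knee drops the record;
    moderate-or-worse unilateral pain is missing for ``outcome2`` only.
    """
    left = participants["pain_walking_left"]
    right = participants["pain_walking_right"]

    def level_ok(s: pd.Series) -> pd.Series:
        return s.isin(PAIN_LEVELS)

    bad = ~(level_ok(left) & level_ok(right))
    left_pain = left.isin(PAIN_LEVELS[1:])
    right_pain = right.isin(PAIN_LEVELS[1:])

    flow = pd.Series("no_pain", index=participants.index, dtype=object)
    flow[bad] = "dropped_missing"
    bilateral = left_pain & right_pain & ~bad
    flow[bilateral] = "excluded_bilateral"
    unilateral = (left_pain ^ right_pain) & ~bad
    severity = left.where(left_pain, right)
    mild = unilateral & (severity == "mild")
    modsev = unilateral & severity.isin(modsev_levels)
    flow[mild] = "mild"
    flow[modsev] = "modsev"

    outcome2 = pd.Series(np.nan, index=participants.index, dtype=object)
    outcome2[flow == "no_pain"] = "no_pain"
    outcome2[flow == "mild"] = "mild_unilateral"
    outcome3 = pd.Series(np.nan, index=participants.index, dtype=object)
    outcome3[flow == "no_pain"] = "no_pain"
    outcome3[flow == "mild"] = "mild_unilateral"
    outcome3[flow == "modsev"] = "modsev_unilateral"

    n_dropped = int(bad.sum())
    if n_dropped:
        log.info("dropped %d participants with missing pain ratings", n_dropped)
    return pd.DataFrame(
        {"outcome2": outcome2, "outcome3": outcome3, "pain_flow": flow}
    )


def _backfill_kl(current: pd.Series, priors: list[pd.Series]) -> pd.Series:
    """Current KL grade, back-filled from the most recent prior exam."""
    filled = current.copy()
    for prior in priors:  # priors ordered most recent first
        filled = filled.where(filled.notna(), prior)
    return filled


def build_roa_status(participants: pd.DataFrame) -> pd.Series:
    """Number of knees with radiographic OA (KL grade >= 2): 0, 1 or 2.

    A knee's current KL grade, when missing (including knees no longer
    x-rayed after replacement), is back-filled with the most recent prior
    non-missing grade.  A knee that stays unresolved after back-fill makes
    the count missing, with a logged notice.
    """
    counts = pd.Series(0.0, index=participants.index)
    unresolved = pd.Series(False, index=participants.index)
    for knee in ("left", "right"):
        current = participants[f"kl_{knee}_current"].copy()
        tkr_col = f"tkr_{knee}"
        if tkr_col in participants.columns:
            current = current.mask(participants[tkr_col].fillna(False).astype(bool))
        priors = [
            participants[c]
            for c in (f"kl_{knee}_prior1", f"kl_{knee}_prior2")
            if c in participants.columns
        ]
        filled = _backfill_kl(current, priors)
        unresolved |= filled.isna()
        counts += (filled >= 2).astype(float)
    counts[unresolved] = np.nan
    n_bad = int(unresolved.sum())
    if n_bad:
        log.info("%d participants with unresolvable KL grades; roa_count missing", n_bad)
    return counts.rename("roa_count")


def standardize(column: pd.Series) -> pd.Series:
    """Z-score a column over its non-missing values (sample sd)."""
    sd = column.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ConfigError(f"cannot standardize constant column '{column.name}'")
    return (column - column.mean()) / sd


def assemble_analysis_table(
    participants: pd.DataFrame,
    features: pd.DataFrame,
    standardize_continuous: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Join outcomes, covariates and gait features into the analysis table.

    The feature table is expected to be speed-filtered already.  The join
    is inner on ``id``; continuous gait features and covariates are
    z-scored over the joined sample.  Returns the table and a flow log
    dictionary accounting for every input participant.
    """
    if participants["id"].duplicated().any() or features["id"].duplicated().any():
        raise ConfigError("duplicate participant ids")
    outcomes = build_pain_outcomes(participants)
    roa = build_roa_status(participants)
    base = pd.concat(
        [participants[["id", "age", "sex", "race_site", "bmi", "cesd"]], outcomes, roa],
        axis=1,
    )
    merged = base.merge(features, on="id", how="inner", validate="one_to_one")

    flow = {
        "n_participants": int(len(participants)),
        "n_with_features": int(len(merged)),
        "n_missing_features": int(len(participants) - len(merged)),
        "n_no_pain": int((merged["pain_flow"] == "no_pain").sum()),
        "n_mild_unilateral": int((merged["pain_flow"] == "mild").sum()),
        "n_modsev_unilateral": int((merged["pain_flow"] == "modsev").sum()),
        "n_excluded_bilateral": int((merged["pain_flow"] == "excluded_bilateral").sum()),
        "n_dropped_missing_pain": int((merged["pain_flow"] == "dropped_missing").sum()),
    }
    analysis = merged[~merged["pain_flow"].isin(["excluded_bilateral", "dropped_missing"])].copy()
    flow["n_analysis"] = int(len(analysis))

    if standardize_continuous:
        feature_cols = [c for c in features.columns if c != "id"]
        for col in list(feature_cols) + list(CONTINUOUS_VARIABLES):
            if analysis[col].notna().sum() >= 2 and analysis[col].std(ddof=1) > 0:
                analysis[col] = standardize(analysis[col])
    analysis = analysis.reset_index(drop=True)
    return analysis, flow
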