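"""The CRC lifestyle index: a nine-component 0-4 risk-factor score.

The index condenses nine lifestyle and anthropometric risk factors for
colorectal cancer into a single score.  Each component earns 0, 0.5 or 1
point for not meeting, partially meeting or meeting a target cut-off:

==========================  =========  ==============  =========
Component                   0 points   0.5 points      1 point
==========================  =========  ==============  =========
BMI (kg/m2)                 >= 30      25 - < 30       < 25
WC women (cm)               >= 88      80 - < 88       < 80
WC men (cm)                 >= 102     94 - < 102      < 94
Height (sex-specific)       tertile 3  tertile 2       tertile 1
Leisure-time activity       inactive   moderate        active
Whole grains (g/day)        < 45       45 - < 90       >= 90
Dairy products (g/day)      < 200      200 - < 400     >= 400
Red/processed meat (g/wk)   red > 350  red <= 350 and  red <= 350 and
                            or proc    proc 21 - <100  proc <= 21
                            >= 100
Alcohol, 100% (g/day)       > 20       > 0 - <= 20     0
==========================  =========  ==============  =========

BMI and WC points are averaged into one body-fatness score (BMI alone if
the WC column is absent from the whole dataset), and the four dietary
points are averaged into one dietary score, so the total - body fatness +
height + activity + diet - ranges from 0 to 4.  Higher points indicate a
lower-risk lifestyle.

Two boundary conventions favour the participant: processed meat of
exactly 21 g/week earns the full point, and tied heights fall in the
lower (shorter, higher-scoring) tertile.  Participants with a missing
value in any present scoring column are rejected, mirroring the
exclusion-based handling of the source cohorts.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import MissingDataError, StratumTooSmallError, ValidationError

logger = logging.getLogger(__name__)

SEXES = ("woman", "man")
ACTIVITY_LEVELS = ("inactive", "moderate", "active")

#: Columns compute_index consumes, besides the optional "wc".
REQUIRED_COLUMNS = (
    "sex", "bmi", "height", "activity",
    "whole_grains", "dairy", "red_meat", "processed_meat", "alcohol",
)

_ACTIVITY_POINTS = {"inactive": 0.0, "moderate": 0.5, "active": 1.0}


def _check_nonnegative(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(np.isnan(arr)):
        raise MissingDataError(f"missing {name} value")
    if np.any(arr < 0):
        raise ValidationError(f"{name} must be non-negative")
    return arr


def score_component(component: str, value, sex: str | None = None):
    """Score one index component; returns points in {0, 0.5, 1}.

    ``sex`` is required for waist circumference (sex-specific cut-offs).
    Accepts scalars or arrays for the quantitative components.
    """
    if component == "bmi":
        v = _check_nonnegative("bmi", value)
        return np.where(v >= 30, 0.0, np.where(v >= 25, 0.5, 1.0))[()]
    if component == "wc":
        v = _check_nonnegative("wc", value)
        sex_arr = np.asarray(sex)
        if np.any(~np.isin(sex_arr, SEXES)):
            raise ValidationError(f"sex must be one of {SEXES}")
        hi = np.where(sex_arr == "man", 102.0, 88.0)
        lo = np.where(sex_arr == "man", 94.0, 80.0)
        return np.where(v >= hi, 0.0, np.where(v >= lo, 0.5, 1.0))[()]
    if component == "whole_grains":
        v = _check_nonnegative("whole_grains", value)
        return np.where(v >= 90, 1.0, np.where(v >= 45, 0.5, 0.0))[()]
    if component == "dairy":
        v = _check_nonnegative("dairy", value)
        return np.where(v >= 400, 1.0, np.where(v >= 200, 0.5, 0.0))[()]
    if component == "alcohol":
        v = _check_nonnegative("alcohol", value)
        return np.where(v > 20, 0.0, np.where(v > 0, 0.5, 1.0))[()]
    if component == "activity":
        arr = np.asarray(value)
        if np.any(~np.isin(arr, ACTIVITY_LEVELS)):
            raise ValidationError(
                f"activity must be one of {ACTIVITY_LEVELS}, got {value!r}")
        if arr.ndim == 0:
            return _ACTIVITY_POINTS[str(arr)]
        return np.array([_ACTIVITY_POINTS[a] for a in arr])
    raise ValidationError(f"unknown component {component!r}")


def score_meat(red_g_per_week, processed_g_per_week):
    """Score the combined red/processed-meat component.

    Full point: red <= 350 g/week and processed <= 21 g/week (the
    boundary 21 g/week counts as meeting the target).  Half point: red
    <= 350 and processed < 100.  Otherwise zero.
    """
    red = _check_nonnegative("red_meat", red_g_per_week)
    proc = _check_nonnegative("processed_meat", processed_g_per_week)
    full = (red <= 350) & (proc <= 21)
    half = (red <= 350) & (proc < 100)
    return np.where(full, 1.0, np.where(half, 0.5, 0.0))[()]


def score_height(heights, sexes) -> np.ndarray:
    """Sex-specific tertile scoring of height.

    Within each sex the empirical 1/3 and 2/3 quantiles define the
    tertiles; the shortest tertile earns 1 point, the middle 0.5, the
    tallest 0.  Heights exactly at a cut point fall in the lower tertile.
    """
    heights = _check_nonnegative("height", heights)
    sexes = np.asarray(sexes)
    if heights.shape != sexes.shape:
        raise ValidationError("heights and sexes must have equal length")
    points = np.full(heights.shape, np.nan)
    for sex in np.unique(sexes):
        mask = sexes == sex
        if mask.sum() < 3:
            raise StratumTooSmallError(
                f"sex stratum {sex!r} has {mask.sum()} members (< 3)")
        h = heights[mask]
        q1, q2 = np.quantile(h, [1 / 3, 2 / 3])
        points[mask] = np.where(h <= q1, 1.0, np.where(h <= q2, 0.5, 0.0))
    return points


def compute_index(table: pd.DataFrame) -> pd.DataFrame:
    """Score every participant of a phenotype table.

    Returns a DataFrame indexed like ``table`` with per-component points,
    the body-fatness and dietary sub-scores, and the total (0-4).  If the
    ``wc`` column is absent from the dataset entirely, body fatness falls
    back to the BMI points alone; per-row missing values in present
    columns raise :class:`MissingDataError`.
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"phenotype table lacks columns {missing_cols}")
    for col in REQUIRED_COLUMNS + (("wc",) if "wc" in table.columns else ()):
        if table[col].isna().any():
            bad = list(table.index[table[col].isna()])
            raise MissingDataError(
                f"missing {col!r} for participants {bad[:5]} "
                "(participants with missing scoring data are excluded, "
                "not imputed)")

    sex = table["sex"].to_numpy()
    if np.any(~np.isin(sex, SEXES)):
        raise ValidationError(f"sex must be one of {SEXES}")

    out = pd.DataFrame(index=table.index)
    out["bmi_pts"] = score_component("bmi", table["bmi"].to_numpy())
    if "wc" in table.columns:
        out["wc_pts"] = score_component("wc", table["wc"].to_numpy(), sex)
        out["body_fatness"] = (out["bmi_pts"] + out["wc_pts"]) / 2
    else:
        logger.info("compute_index: WC column absent, "
                    "body fatness based on BMI alone")
        out["wc_pts"] = np.nan
        out["body_fatness"] = out["bmi_pts"]
    out["height_pts"] = score_height(table["height"].to_numpy(), sex)
    out["activity_pts"] = score_component(
        "activity", table["activity"].to_numpy())
    out["whole_grain_pts"] = score_component(
        "whole_grains", table["whole_grains"].to_numpy())
    out["dairy_pts"] = score_component("dairy", table["dairy"].to_numpy())
    out["meat_pts"] = score_meat(table["red_meat"].to_numpy(),
                                 table["processed_meat"].to_numpy())
    out["alcohol_pts"] = score_component(
        "alcohol", table["alcohol"].to_numpy())
    out["dietary_score"] = out[
        ["whole_grain_pts", "dairy_pts", "meat_pts", "alcohol_pts"]
    ].mean(axis=1)
    out["total"] = (out["body_fatness"] + out["height_pts"]
                    + out["activity_pts"] + out["dietary_score"])
    out["quintile"] = assign_quintiles(out["total"].to_numpy())
    return out


def assign_quintiles(scores) -> np.ndarray:
    """Split scores into cohort-specific quintiles (1 = lowest).

    Participants are ranked by score with stable order and split into
    five near-equal groups; all participants sharing a score value are
    assigned the quintile of the first of them in rank order, so tied
    values never straddle a quintile boundary (which is why observed
    quintile sizes can be unequal).
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 5:
        raise ValidationError("need at least 5 participants for quintiles")
    if np.any(np.isnan(scores)):
        raise MissingDataError("missing scores in quintile assignment")
    order = np.argsort(scores, kind="stable")
    provisional = np.empty(n, dtype=int)
    provisional[order] = np.arange(n) * 5 // n + 1
    # collapse ties onto the quintile of their first occurrence
    labels = provisional.copy()
    first_of_value: dict[float, int] = {}
    for pos in order:
        v = scores[pos]
        if v in first_of_value:
            labels[pos] = first_of_value[v]
        else:
            first_of_value[v] = labels[pos]
    if len(np.unique(labels)) == 1:
        warnings.warn("degenerate quintiles: all scores tied", stacklevel=2)
    return labels
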