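"""Purchase-derived phenotypes and survey dichotomization.

From a traffic-light-labeled cafeteria transaction log, derives per
participant:

* quality — the Healthy Purchasing Score: labeled purchases weighted green=1,
  yellow=0.5, red=0, expressed as a percentage (0-100);
* quantity — total, food, and beverage item counts over the 3-month baseline
  window;
* timing — the median across days of the first food purchase inside the
  breakfast (06:00-10:00) and lunch (11:00-14:00) windows, in minutes since
  midnight.

Survey frequency categories are dichotomized: meal skipping to never vs ≥1
day/week; home-prepared meals to <3 vs ≥3 days/week.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COLOR_WEIGHTS = {"green": 1.0, "yellow": 0.5, "red": 0.0}
BREAKFAST_WINDOW = (360, 600)   # 06:00-10:00 inclusive, minutes since midnight
LUNCH_WINDOW = (660, 840)       # 11:00-14:00 inclusive
BASELINE_DAYS = 91

_SKIP_MAP = {"Never": 0, "1-2 days": 1, "3-4 days": 1, "5-6 days": 1, "Every day": 1}
_HOME_MAP = {"Never": 0, "1-2 days": 0, "3-4 days": 1, "5-6 days": 1, "Every day": 1}

SURVEY_BINARIES = {
    "skip_breakfast": ("skips_breakfast", "skip"),
    "skip_lunch": ("skips_lunch", "skip"),
    "skip_dinner": ("skips_dinner", "skip"),
    "home_breakfast": ("prepares_breakfast_home", "home"),
    "home_lunch": ("prepares_lunch_home", "home"),
    "home_dinner": ("prepares_dinner_home", "home"),
}


def healthy_purchasing_score(transactions: pd.DataFrame) -> float:
    """Healthy Purchasing Score (percent) over labeled transactions.

    ``100 × mean(color weight)`` over green/yellow/red items; unlabeled
    items are excluded from numerator and denominator.  Returns NaN when no
    labeled transaction exists (the participant is excluded from the quality
    analysis).
    """
    colors = transactions["color"].astype(str)
    labeled = colors.isin(COLOR_WEIGHTS)
    if not labeled.any():
        return float("nan")
    w = colors[labeled].map(COLOR_WEIGHTS)
    return float(100.0 * w.mean())


def purchase_counts(transactions: pd.DataFrame):
    """(total, food, beverage) item counts; label-independent."""
    food = int((transactions["item_class"] == "food").sum())
    bev = int((transactions["item_class"] == "beverage").sum())
    return food + bev, food, bev


def meal_time_median(transactions: pd.DataFrame, meal: str,
                     food_only: bool = True) -> float:
    """Median daily first-purchase time for one meal, minutes since midnight.

    Per calendar day, the earliest food purchase inside the meal window
    (inclusive bounds) is taken; the phenotype is the median of those daily
    first times over days with at least one qualifying purchase.  NaN when no
    day qualifies.  ``food_only=False`` admits beverages as well.
    """
    if meal == "breakfast":
        lo, hi = BREAKFAST_WINDOW
    elif meal == "lunch":
        lo, hi = LUNCH_WINDOW
    else:
        raise ValueError(f"unknown meal '{meal}' (expected 'breakfast' or 'lunch')")
    tx = transactions
    if food_only:
        tx = tx[tx["item_class"] == "food"]
    if len(tx) == 0:
        return float("nan")
    ts = pd.to_datetime(tx["timestamp"])
    minutes = ts.dt.hour * 60 + ts.dt.minute
    inwin = (minutes >= lo) & (minutes <= hi)
    if not inwin.any():
        return float("nan")
    firsts = minutes[inwin].groupby(ts[inwin].dt.date).min()
    return float(np.median(firsts.to_numpy(float)))


def dichotomize_survey(value: str, kind: str) -> int:
    """Dichotomize one five-category survey response.

    ``kind='skip'``: Never → 0 (daily eater), anything else → 1 (skipper).
    ``kind='home'``: Never or 1-2 days → 0 (<3 home meals/week), else → 1.
    """
    norm = str(value).strip().replace("–", "-").replace("—", "-")
    mapping = {"skip": _SKIP_MAP, "home": _HOME_MAP}.get(kind)
    if mapping is None:
        raise ValueError(f"unknown survey kind '{kind}'")
    if norm not in mapping:
        raise ValueError(f"unrecognized survey category: '{value}'")
    return mapping[norm]


def baseline_window(transactions: pd.DataFrame, enrollment_date) -> pd.DataFrame:
    """Restrict a transaction log to the 91 days strictly before enrollment.

    Keeps records with enrollment − 91 days ≤ date < enrollment (purchases on
    the enrollment day itself are excluded).
    """
    enroll = pd.Timestamp(enrollment_date).normalize()
    ts = pd.to_datetime(transactions["timestamp"])
    lo = enroll - pd.Timedelta(days=BASELINE_DAYS)
    keep = (ts >= lo) & (ts < enroll)
    return transactions.loc[keep]


def derive_phenotypes(transactions: pd.DataFrame, survey: pd.DataFrame,
                      covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-participant phenotype table from raw logs and surveys.

    One row per participant of the covariate table, with the quality,
    quantity, and timing outcomes (transactions first restricted to each
    participant's baseline window) and the six dichotomized survey
    behaviours.  Vectorized over the whole log; the per-participant
    functions in this module define the same reductions one participant at
    a time.
    """
    cov = covariates.set_index("participant_id")
    survey_idx = survey.set_index("participant_id")
    orphans = survey_idx.index.difference(cov.index)
    if len(orphans):
        raise ValueError(f"survey participants absent from covariates: "
                         f"{list(orphans[:5])}")

    tx = transactions.copy()
    ts = pd.to_datetime(tx["timestamp"])
    enroll = pd.to_datetime(cov["enrollment_date"]).dt.normalize()
    tx_enroll = tx["participant_id"].map(enroll)
    keep = (ts >= tx_enroll - pd.Timedelta(days=BASELINE_DAYS)) & (ts < tx_enroll)
    tx, ts = tx.loc[keep], ts.loc[keep]
    pid = tx["participant_id"]
    minutes = ts.dt.hour * 60 + ts.dt.minute

    out = pd.DataFrame(index=cov.index)

    w = tx["color"].map(COLOR_WEIGHTS)  # NaN for unlabeled
    out["healthy_purchasing_score"] = 100.0 * w.groupby(pid).mean()

    is_food = tx["item_class"] == "food"
    out["food_items"] = is_food.groupby(pid).sum()
    out["beverage_items"] = (tx["item_class"] == "beverage").groupby(pid).sum()
    for c in ("food_items", "beverage_items"):
        out[c] = out[c].fillna(0).astype(int)
    out["total_items"] = out["food_items"] + out["beverage_items"]

    for name, (lo, hi) in (("breakfast_time_median", BREAKFAST_WINDOW),
                           ("lunch_time_median", LUNCH_WINDOW)):
        sel = is_food & (minutes >= lo) & (minutes <= hi)
        firsts = minutes[sel].groupby([pid[sel], ts[sel].dt.date]).min()
        out[name] = firsts.groupby(level=0).median()

    for col, (out_name, kind) in SURVEY_BINARIES.items():
        vals = survey_idx[col].astype(str).str.strip() \
            .str.replace("–", "-").str.replace("—", "-")
        mapping = _SKIP_MAP if kind == "skip" else _HOME_MAP
        bad = ~vals.isin(mapping)
        if bad.any():
            raise ValueError("unrecognized survey category: "
                             f"'{vals[bad].iloc[0]}' in column '{col}'")
        out[out_name] = vals.map(mapping).reindex(out.index)

    cols = ["healthy_purchasing_score", "total_items", "food_items",
            "beverage_items", "breakfast_time_median", "lunch_time_median"] \
        + [name for name, _ in SURVEY_BINARIES.values()]
    return out[cols].reset_index()
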