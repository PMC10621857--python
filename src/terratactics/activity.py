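"""Minute-point activity coding and activity-budget summaries.

Focal activity (rest / feed / travel, with an implicit 'other' remainder)
is coded per minute of observation.  Because successive minutes are highly
dependent, modeling uses a 30-min greedy thinning per observation day —
roughly twice the mean activity-bout length, so thinned points come from
different bouts.  Budgets are tabulated over four territory sections by UD
kernel value (core < 25, post-core 25–50, pre-periphery 50–75,
periphery > 75).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ACTIVITIES = ["rest", "feed", "travel"]

SECTIONS = [("core", 0, 25), ("post_core", 25, 50),
            ("pre_periphery", 50, 75), ("periphery", 75, 100)]


def seasonal_terms(times) -> pd.DataFrame:
    """Sine/cosine of the day-of-year angle (period 365.25 d)."""
    doy = pd.to_datetime(times).dt.dayofyear
    ang = 2 * np.pi * doy / 365.25
    return pd.DataFrame({"day_sin": np.sin(ang), "day_cos": np.cos(ang)})


def thin(minutes: pd.DataFrame, spacing: int = 30) -> pd.DataFrame:
    """Greedy per-day thinning: keep the day's first point, then the next
    point at least ``spacing`` minutes later, and so on."""
    if len(minutes) == 0:
        return minutes.copy()
    t = pd.to_datetime(minutes["time"])
    keep = np.zeros(len(minutes), dtype=bool)
    for _, idx in t.groupby(t.dt.date).groups.items():
        sub = t.loc[idx].sort_values()
        last = None
        for lab, ti in sub.items():
            if last is None or (ti - last) >= pd.Timedelta(minutes=spacing):
                keep[minutes.index.get_loc(lab)] = True
                last = ti
    return minutes[keep]


def budgets(minutes: pd.DataFrame) -> pd.DataFrame:
    """Percent of observation time per activity within each territory section.

    Needs ``kernel`` and the 0/1 activity flags; percentages within a
    section are over that section's minutes (an 'other' remainder keeps the
    three activities from summing to 100).  Empty sections get NaN.
    """
    rows = []
    kv = minutes["kernel"].to_numpy(float)
    for name, lo, hi in SECTIONS:
        m = (kv >= lo) & (kv < hi) if name != "periphery" else kv >= lo
        sub = minutes[m]
        row = {"section": name, "n_minutes": len(sub)}
        for act in ACTIVITIES:
            row[act] = 100.0 * sub[act].mean() if len(sub) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("section")


def bout_lengths(minutes: pd.DataFrame) -> pd.DataFrame:
    """Mean length (min) of maximal same-activity runs, per activity x group.

    Operates on the un-thinned minute stream; runs are broken at follow
    boundaries and at gaps longer than one minute.
    """
    df = minutes.copy()
    df["_act"] = "other"
    for act in ACTIVITIES:
        df.loc[df[act].astype(bool), "_act"] = act
    records = []
    keys = ["group", "follow_id"] if "follow_id" in df.columns else ["group"]
    for key, sub in df.groupby(keys, sort=False):
        sub = sub.sort_values("time")
        t = pd.to_datetime(sub["time"]).to_numpy()
        acts = sub["_act"].to_numpy()
        gap = np.ones(len(sub), dtype=bool)
        if len(sub) > 1:
            dt = np.diff(t).astype("timedelta64[s]").astype(float)
            gap[1:] = dt > 90.0
        new_run = gap | np.r_[True, acts[1:] != acts[:-1]]
        run_id = np.cumsum(new_run)
        g = key[0] if isinstance(key, tuple) else key
        for (rid, act), cnt in pd.Series(1, index=[run_id, acts]).groupby(level=[0, 1]).count().items():
            records.append({"group": g, "activity": act, "length": int(cnt)})
    runs = pd.DataFrame(records)
    runs = runs[runs["activity"].isin(ACTIVITIES)]
    return runs.groupby(["group", "activity"])["length"].mean().unstack()


ACTIVITY_CONTROLS = ["sex_female", "sex_oestrus", "group_code", "day_sin",
                     "day_cos", "party_size", "food_avail", "n_oestrus"]


def build_activity_dataset(minutes: pd.DataFrame) -> pd.DataFrame:
    """Modeling table for the three activity models (thinned minutes).

    Response columns are the 0/1 activity flags; test predictors are
    ``kernel`` and ``elev`` (their interaction is formed at fit time);
    controls are sex class, group, seasonality, party size, food
    availability and oestrus-female count; random keys ``date_group`` and
    ``focal_id``.  Rows with missing covariates are dropped.
    """
    need = ["time", "group", "focal_id", "sex_class", "kernel", "elev",
            "party_size", "food_avail", "n_oestrus"] + ACTIVITIES
    missing = [c for c in need if c not in minutes.columns]
    if missing:
        raise KeyError(f"activity table missing columns: {missing}")
    df = minutes.copy().reset_index(drop=True)
    season = seasonal_terms(df["time"])
    df["day_sin"] = season["day_sin"].to_numpy()
    df["day_cos"] = season["day_cos"].to_numpy()
    df["sex_female"] = (df["sex_class"] == "female").astype(int)
    df["sex_oestrus"] = (df["sex_class"] == "oestrus_female").astype(int)
    df["group_code"] = pd.Categorical(df["group"]).codes
    df["date_group"] = (pd.to_datetime(df["time"]).dt.date.astype(str)
                        + ":" + df["group"].astype(str))
    num = ["kernel", "elev", "party_size", "food_avail", "n_oestrus"]
    df = df.dropna(subset=num)
    cols = (ACTIVITIES + ["kernel", "elev"] + ACTIVITY_CONTROLS
            + ["date_group", "focal_id", "time"])
    return df[cols].reset_index(drop=True)
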