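"""Behavioral event extraction from annotated tracklogs.

The analysis units are *visits* to peripheral hills or low rest locations
(travel within 50 m of the site at matching elevation), *stop events*
(a pause of at least 5 min during a visit), movement *direction* before
arrival (toward border vs. toward center, from the change in UD kernel
value over a 30-min lookback), *departures* (definitive travel beyond
50 m), and post-departure *advance/retreat* relative to the closest rival
party's position fixed at departure time (endpoint distance change over a
30-min horizon with a 50 m dead-band).

All rule thresholds are keyword arguments with field-realistic defaults;
exclusions (ambiguous direction, undetermined advance, missing rival data)
are counted, never silently dropped.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .territory import TerritoryModel, kernel_value

logger = logging.getLogger(__name__)

MIN = pd.Timedelta(minutes=1)


def _t(s):
    return pd.to_datetime(s)


# ---------------------------------------------------------------------------
# stops


def detect_stop(visit_fixes: pd.DataFrame, min_dur: int = 5,
                move_thresh: float = 25.0) -> tuple:
    """(stopped, stop_minutes) for the fixes of one visit.

    A stop is a window of consecutive fixes spanning >= ``min_dur`` minutes
    in which every fix stays within ``move_thresh`` of the window's first
    fix.  ``stop_minutes`` is the span of the longest such window (minutes
    covered at the 1 fix/min cadence, i.e. fix count).
    """
    if len(visit_fixes) == 0:
        raise ValueError("visit has no fixes")
    x = visit_fixes["x"].to_numpy(float)
    y = visit_fixes["y"].to_numpy(float)
    n = len(x)
    best = 0
    for i in range(n):
        d = np.hypot(x[i:] - x[i], y[i:] - y[i])
        out = np.flatnonzero(d > move_thresh)
        j = out[0] if len(out) else n - i  # window length from i
        if j > best:
            best = int(j)
    stopped = best >= min_dur
    return bool(stopped), int(best if stopped else 0)


# ---------------------------------------------------------------------------
# visits


def detect_visits(track: pd.DataFrame, sites: pd.DataFrame,
                  radius: float = 50.0, elev_tol: float = 13.0,
                  merge_gap: int = 5, min_dur: int = 5,
                  move_thresh: float = 25.0) -> pd.DataFrame:
    """Extract maximal visit intervals of one follow track to a site table.

    ``track`` must carry ``time, x, y, smoothed_elev`` (plus ``group`` /
    ``follow_id`` if present, copied through).  ``sites`` needs
    ``loc_id, loc_type, x, y, elev``.  A fix belongs to a site when it is
    within ``radius`` of the site and its smoothed elevation is within
    ``elev_tol`` of the site elevation; overlapping sites resolve to the
    nearest.  Consecutive visits to one site separated by < ``merge_gap``
    minutes merge.  Each visit row carries the stop classification.
    """
    cols = ["visit_id", "loc_id", "loc_type", "group", "follow_id",
            "t_arrive", "t_depart", "stopped", "stop_minutes",
            "site_x", "site_y", "site_elev"]
    if len(track) == 0 or len(sites) == 0:
        return pd.DataFrame(columns=cols)
    tx = track["x"].to_numpy(float)
    ty = track["y"].to_numpy(float)
    te = track["smoothed_elev"].to_numpy(float)
    tt = _t(track["time"]).to_numpy()
    sx = sites["x"].to_numpy(float)
    sy = sites["y"].to_numpy(float)
    se = sites["elev"].to_numpy(float)

    # per-fix site assignment (nearest admissible site, -1 if none)
    d2 = (tx[:, None] - sx[None, :]) ** 2 + (ty[:, None] - sy[None, :]) ** 2
    ok = (d2 <= radius ** 2) & (np.abs(te[:, None] - se[None, :]) <= elev_tol)
    d2m = np.where(ok, d2, np.inf)
    assign = np.where(ok.any(axis=1), np.argmin(d2m, axis=1), -1)

    # maximal runs per site, merging short same-site gaps
    segments = []  # (site_idx, i_start, i_end inclusive)
    i = 0
    n = len(assign)
    while i < n:
        if assign[i] < 0:
            i += 1
            continue
        s = assign[i]
        j = i
        while j + 1 < n and assign[j + 1] == s:
            j += 1
        segments.append([s, i, j])
        i = j + 1
    merged = []
    for seg in segments:
        if merged and merged[-1][0] == seg[0]:
            gap = (tt[seg[1]] - tt[merged[-1][2]]) / np.timedelta64(60, "s")
            if gap < merge_gap:
                merged[-1][2] = seg[2]
                continue
        merged.append(seg)

    rows = []
    for vid, (s, i0, i1) in enumerate(merged):
        sub = track.iloc[i0:i1 + 1]
        stopped, mins = detect_stop(sub, min_dur=min_dur, move_thresh=move_thresh)
        rows.append({
            "visit_id": vid,
            "loc_id": sites["loc_id"].iloc[s],
            "loc_type": sites["loc_type"].iloc[s],
            "group": track["group"].iloc[i0] if "group" in track else None,
            "follow_id": track["follow_id"].iloc[i0] if "follow_id" in track else None,
            "t_arrive": pd.Timestamp(tt[i0]),
            "t_depart": pd.Timestamp(tt[i1]) + MIN,
            "stopped": stopped,
            "stop_minutes": mins,
            "site_x": float(sx[s]),
            "site_y": float(sy[s]),
            "site_elev": float(se[s]),
        })
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# direction


def classify_direction(track: pd.DataFrame, t_arrive,
                       territory: TerritoryModel, lookback: int = 30,
                       deadband: float | None = None,
                       metric: str = "center") -> str:
    """Direction of travel before arrival on the center–border axis.

    Compares the start and end of the ``lookback``-minute window before
    arrival under one of two metrics:

    * ``metric='center'`` (default) — change in radial distance to the
      territory center; beyond ``deadband`` meters (default 100) outward is
      'toward_border', inward 'toward_center'.  Robust on kernel surfaces
      where heavily used sites form local density bumps.
    * ``metric='kernel'`` — change in UD kernel value; beyond ``deadband``
      kernel units (default 5) toward larger values is 'toward_border'.

    Anything inside the dead-band is 'ambiguous' (excluded from the stop
    model), as is an insufficient lookback track.
    """
    t_arrive = pd.Timestamp(t_arrive)
    tt = _t(track["time"])
    win = track[(tt >= t_arrive - pd.Timedelta(minutes=lookback)) & (tt <= t_arrive)]
    if len(win) < 2:
        warnings.warn("insufficient lookback track; direction ambiguous")
        return "ambiguous"
    x0, y0 = float(win["x"].iloc[0]), float(win["y"].iloc[0])
    x1, y1 = float(win["x"].iloc[-1]), float(win["y"].iloc[-1])
    if metric == "kernel":
        if deadband is None:
            deadband = 5
        delta = (kernel_value(territory.ud, x1, y1)
                 - kernel_value(territory.ud, x0, y0))
    elif metric == "center":
        if deadband is None:
            deadband = 100.0
        cx, cy = territory.center_xy
        delta = np.hypot(x1 - cx, y1 - cy) - np.hypot(x0 - cx, y0 - cy)
    else:
        raise ValueError("metric must be 'center' or 'kernel'")
    if delta > deadband:
        return "toward_border"
    if delta < -deadband:
        return "toward_center"
    return "ambiguous"


def hills_before_after(visits: pd.DataFrame) -> pd.DataFrame:
    """Count same-day hill visits before/after each visit of one (group, day).

    Only ``loc_type == 'hill'`` visits count; low-location rows still get
    counts of *hill* visits around them.  Input order is irrelevant — rows
    are ranked by arrival time.
    """
    out = visits.sort_values("t_arrive").reset_index(drop=True).copy()
    is_hill = (out["loc_type"] == "hill").to_numpy()
    csum = np.cumsum(is_hill)
    total = int(is_hill.sum())
    out["n_hills_before"] = csum - is_hill.astype(int)
    out["n_hills_after"] = total - csum
    return out


# ---------------------------------------------------------------------------
# rivals


def rival_party_size(rival_obs: pd.DataFrame, t, window: int = 30):
    """Aggregated adult count over rival parties seen in the last ``window`` min.

    For each distinct party observed in (t − window, t], its most recent
    adult party size contributes; sizes sum across spatially distinct
    parties.  Returns NaN when nothing was observed in the window.
    """
    t = pd.Timestamp(t)
    tt = _t(rival_obs["time"])
    win = rival_obs[(tt > t - pd.Timedelta(minutes=window)) & (tt <= t)]
    if len(win) == 0:
        return float("nan")
    if "party" in win.columns:
        last = win.sort_values("time").groupby("party").tail(1)
    else:
        last = win.sort_values("time").tail(1)
    return float(last["adult_party_size"].sum())


def _minute_positions(track: pd.DataFrame) -> pd.DataFrame:
    df = track.copy()
    df["minute"] = _t(df["time"]).dt.floor("min")
    return df.groupby("minute")[["x", "y"]].mean()


def intercommunity_distance(own_track: pd.DataFrame, rival_tracks,
                            t_from, t_to, mode: str = "mean_over_use"):
    """Distance to the closest rival party over a use interval.

    Per shared minute in [t_from, t_to], the distance to the closest of the
    rival parties; ``mode='mean_over_use'`` averages over the interval,
    ``mode='at_departure'`` takes the last shared minute at or before
    ``t_to``.  Returns NaN when no rival track overlaps in time.
    """
    if isinstance(rival_tracks, pd.DataFrame):
        if "party" in rival_tracks.columns:
            rival_tracks = [g for _, g in rival_tracks.groupby("party")]
        else:
            rival_tracks = [rival_tracks]
    t_from, t_to = pd.Timestamp(t_from), pd.Timestamp(t_to)
    own = _minute_positions(own_track)
    own = own[(own.index >= t_from.floor("min")) & (own.index <= t_to.floor("min"))]
    if len(own) == 0:
        return float("nan")
    per_minute = pd.Series(np.inf, index=own.index)
    for rt in rival_tracks:
        riv = _minute_positions(rt)
        common = own.index.intersection(riv.index)
        if len(common) == 0:
            continue
        d = np.hypot(own.loc[common, "x"].to_numpy() - riv.loc[common, "x"].to_numpy(),
                     own.loc[common, "y"].to_numpy() - riv.loc[common, "y"].to_numpy())
        per_minute.loc[common] = np.minimum(per_minute.loc[common].to_numpy(), d)
    per_minute = per_minute[np.isfinite(per_minute)]
    if len(per_minute) == 0:
        return float("nan")
    if mode == "mean_over_use":
        return float(per_minute.mean())
    if mode == "at_departure":
        return float(per_minute.iloc[-1])
    raise ValueError("mode must be 'mean_over_use' or 'at_departure'")


# ---------------------------------------------------------------------------
# departure and advance/retreat


def detect_departure(track: pd.DataFrame, location_xy, t_after,
                     leave_dist: float = 50.0, reentry_window: int = 5):
    """First definitive exit beyond ``leave_dist`` of the site after ``t_after``.

    An exit is definitive when the party does not re-enter the radius within
    ``reentry_window`` minutes.  Returns the exit fix time, or None if the
    track ends inside the radius.
    """
    t_after = pd.Timestamp(t_after)
    tt = _t(track["time"])
    sub = track[tt >= t_after]
    if len(sub) == 0:
        return None
    st = _t(sub["time"]).to_numpy()
    d = np.hypot(sub["x"].to_numpy(float) - location_xy[0],
                 sub["y"].to_numpy(float) - location_xy[1])
    outside = d > leave_dist
    for i in np.flatnonzero(outside):
        ahead = (st > st[i]) & (st <= st[i] + np.timedelta64(reentry_window, "m"))
        if not (~outside & ahead).any():
            return pd.Timestamp(st[i])
    return None


def classify_advance(track: pd.DataFrame, t_depart, rival_xy_at_depart,
                     horizon: int = 30, deadband: float = 50.0,
                     min_track: int = 5, statistic: str = "endpoint") -> str:
    """'advance' / 'retreat' / 'undetermined' from post-departure travel.

    d0 = distance to the rival's departure-time position at ``t_depart``;
    d1 = the same distance at ``t_depart + horizon`` (or track end).
    Advance when d0 − d1 > deadband, retreat when d1 − d0 > deadband, else
    undetermined.  ``statistic='min'`` replaces d1 with the minimum distance
    inside the horizon.  Less than ``min_track`` minutes of post-departure
    track, or a missing rival position, gives 'undetermined'.
    """
    if rival_xy_at_depart is None or not np.all(np.isfinite(rival_xy_at_depart)):
        return "undetermined"
    t_depart = pd.Timestamp(t_depart)
    tt = _t(track["time"])
    post = track[(tt >= t_depart) & (tt <= t_depart + pd.Timedelta(minutes=horizon))]
    if len(post) == 0:
        return "undetermined"
    span = (_t(post["time"]).iloc[-1] - t_depart) / MIN
    if span < min_track:
        return "undetermined"
    d = np.hypot(post["x"].to_numpy(float) - rival_xy_at_depart[0],
                 post["y"].to_numpy(float) - rival_xy_at_depart[1])
    d0 = d[0]
    d1 = d.min() if statistic == "min" else d[-1]
    if d0 - d1 > deadband:
        return "advance"
    if d1 - d0 > deadband:
        return "retreat"
    return "undetermined"


# ---------------------------------------------------------------------------
# model tables


STOP_PREDICTORS = ["direction_border", "n_hills_before", "n_hills_after",
                   "adult_party_size", "intercomm_dist"]
STOP_CONTROLS = ["rel_center_dist", "kernel", "elev", "time_of_day",
                 "sex_male", "group_code"]
RANDOM_KEYS = ["loc_key", "date_group", "focal_id"]


def build_stop_dataset(visits: pd.DataFrame) -> pd.DataFrame:
    """Modeling table for the likelihood-to-stop analysis (one row per
    unambiguous hill visit).

    Expects visit rows annotated with ``stopped, direction,
    n_hills_before, n_hills_after, adult_party_size, intercomm_dist,
    rel_center_dist, kernel, elev, time_of_day, sex, group, loc_id, date,
    focal_id``.  Ambiguous-direction visits and rows with missing
    covariates are excluded (counts logged).
    """
    required = ["stopped", "direction", "n_hills_before", "n_hills_after",
                "adult_party_size", "intercomm_dist", "rel_center_dist",
                "kernel", "elev", "time_of_day", "sex", "group", "loc_id",
                "date", "focal_id"]
    out_cols = (["stopped"] + STOP_PREDICTORS + STOP_CONTROLS
                + ["rel_center_dist_sq"] + RANDOM_KEYS)
    if len(visits) == 0:
        return pd.DataFrame(columns=out_cols)
    missing = [c for c in required if c not in visits.columns]
    if missing:
        raise KeyError(f"stop dataset input missing columns: {missing}")
    df = visits.copy()
    n0 = len(df)
    df = df[df["direction"].isin(["toward_border", "toward_center"])]
    n_ambig = n0 - len(df)
    df = df.assign(
        stopped=df["stopped"].astype(int),
        direction_border=(df["direction"] == "toward_border").astype(int),
        sex_male=(df["sex"] == "male").astype(int),
        group_code=pd.Categorical(df["group"]).codes,
        rel_center_dist_sq=df["rel_center_dist"].astype(float) ** 2,
        loc_key=df["loc_id"].astype(str),
        date_group=df["date"].astype(str) + ":" + df["group"].astype(str),
    )
    num = ["n_hills_before", "n_hills_after", "adult_party_size",
           "intercomm_dist", "rel_center_dist", "kernel", "elev", "time_of_day"]
    n1 = len(df)
    df = df.dropna(subset=num)
    if n_ambig or n1 - len(df):
        logger.info("stop dataset: %d ambiguous-direction, %d incomplete rows dropped",
                    n_ambig, n1 - len(df))
    return df[out_cols].reset_index(drop=True)


ADVANCE_PREDICTORS = ["direction_border", "n_hills_before", "n_hills_after",
                      "elev", "imbalance", "ln_dist"]


def build_advance_dataset(stops: pd.DataFrame) -> pd.DataFrame:
    """Modeling table for the advance-toward-rivals analysis (one row per
    determined stop event at a hill or low location).

    Expects stop rows annotated with ``advance`` ('advance'/'retreat'/
    'undetermined'), ``intercomm_dist_depart``, ``imbalance`` and the same
    covariates as the stop table.  ``ln_dist`` is the natural log of the
    departure-time intercommunity distance, taken before any z-transform.
    """
    out_cols = ["advance"] + ADVANCE_PREDICTORS
    out_cols += [c for c in STOP_CONTROLS if c not in out_cols]
    out_cols += ["rel_center_dist_sq"] + RANDOM_KEYS + ["loc_type", "t_out"]
    if len(stops) == 0:
        return pd.DataFrame(columns=out_cols)
    df = stops.copy()
    n0 = len(df)
    df = df[df["advance"].isin(["advance", "retreat"])]
    n_und = n0 - len(df)
    df = df[df["direction"].isin(["toward_border", "toward_center"])]
    df = df[np.isfinite(df["intercomm_dist_depart"].astype(float))
            & (df["intercomm_dist_depart"].astype(float) > 0)
            & np.isfinite(df["imbalance"].astype(float))]
    if n_und or n0 - n_und - len(df):
        logger.info("advance dataset: %d undetermined, %d incomplete rows dropped",
                    n_und, n0 - n_und - len(df))
    if len(df) == 0:
        return pd.DataFrame(columns=out_cols)
    df = df.assign(
        advance=(df["advance"] == "advance").astype(int),
        direction_border=(df["direction"] == "toward_border").astype(int),
        ln_dist=np.log(df["intercomm_dist_depart"].astype(float)),
        sex_male=(df["sex"] == "male").astype(int),
        group_code=pd.Categorical(df["group"]).codes,
        rel_center_dist_sq=df["rel_center_dist"].astype(float) ** 2,
        loc_key=df["loc_type"].astype(str) + ":" + df["loc_id"].astype(str),
        date_group=df["date"].astype(str) + ":" + df["group"].astype(str),
    )
    return df[out_cols].reset_index(drop=True)
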