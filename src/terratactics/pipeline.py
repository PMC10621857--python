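"""End-to-end orchestration: tracklogs -> landscape -> territory -> events
-> modeling tables -> fitted models.

Three analyses mirror the three questions the pipeline answers:

* ``run_stop_analysis`` — does travel direction (and hill-use context)
  drive the likelihood of stopping on a peripheral hill?
* ``run_activity_analysis`` — do elevation and territory location jointly
  modulate resting / feeding / traveling?
* ``run_advance_analysis`` — after a peripheral stop, do elevation,
  imbalance of power and (log) intercommunity distance drive advances
  toward rivals?  Includes the likelihood-maximized temporal
  autocorrelation term.

Every exclusion along the way (ambiguous direction, undetermined advance,
missing rival data) is counted in the returned objects, and dataset sizes
reconcile: visits >= stops >= advance rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import activity as activity_mod
from . import autocorr, events, glmm, landscape, territory

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    bin_size: float = 10.0
    hill_elev_threshold: float | None = 230.0   # None -> use elev_percentile_q
    elev_percentile_q: float = 99.0
    link_dist: float = 50.0
    low_max_elev: float = 180.0
    use_radius: float = 50.0
    elev_tol: float = 13.0
    stop_min_dur: int = 5
    move_thresh: float = 25.0
    lookback: int = 30
    direction_metric: str = "center"
    direction_deadband: float | None = None   # metric-specific default
    advance_horizon: int = 30
    advance_deadband: float = 50.0
    rival_window: int = 30
    ud_bandwidth: float = 149.0
    ud_cell: float = 25.0
    thin_spacing: int = 30
    alpha: float = 0.05
    seed: int = 0


@dataclass
class LandscapeBundle:
    grid: landscape.ElevationGrid
    territories: dict          # group -> TerritoryModel
    band: territory.OverlapBand
    hills: landscape.HillSet
    west_group: str
    east_group: str
    hill_threshold: float


def extract_landscape(fixes: pd.DataFrame,
                      config: RunConfig | None = None) -> LandscapeBundle:
    """Grid, per-group territory UDs, overlap band and band-masked hills."""
    config = config or RunConfig()
    landscape.validate_fixes(fixes)
    grid = landscape.build_grid(fixes, bin_size=config.bin_size)
    groups = list(pd.unique(fixes["group"]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    mean_x = fixes.groupby("group")["x"].mean()
    west, east = mean_x.idxmin(), mean_x.idxmax()
    terrs = {g: territory.fit_territory(fixes[fixes["group"] == g],
                                        h=config.ud_bandwidth,
                                        cell=config.ud_cell)
             for g in groups}
    band = territory.overlap_band(fixes[fixes["group"] == west],
                                  fixes[fixes["group"] == east])
    thr = (config.hill_elev_threshold
           if config.hill_elev_threshold is not None
           else landscape.elevation_percentile(grid, config.elev_percentile_q))
    mask = band.contains(grid.cells["x_center"].to_numpy(),
                         grid.cells["y_center"].to_numpy()) \
        if not band.empty else np.zeros(len(grid.cells), bool)
    hills = landscape.detect_hills(grid, elev_threshold=thr,
                                   link_dist=config.link_dist, mask=mask)
    return LandscapeBundle(grid=grid, territories=terrs, band=band,
                           hills=hills, west_group=west, east_group=east,
                           hill_threshold=float(thr))


def find_rest_stops(track: pd.DataFrame, band: territory.OverlapBand,
                    min_dur: int = 5, move_thresh: float = 25.0) -> pd.DataFrame:
    """Stationary >= min_dur segments inside the overlap band (one follow).

    Greedy left-to-right scan: a segment starts at the first fix from which
    at least ``min_dur`` consecutive fixes stay within ``move_thresh``.
    Returns segment centroids and times.
    """
    x = track["x"].to_numpy(float)
    y = track["y"].to_numpy(float)
    rows = []
    i, n = 0, len(track)
    while i < n:
        d = np.hypot(x[i:] - x[i], y[i:] - y[i])
        out = np.flatnonzero(d > move_thresh)
        j = (out[0] if len(out) else n - i)
        if j >= min_dur:
            cx, cy = float(x[i:i + j].mean()), float(y[i:i + j].mean())
            if band.contains(cx, cy):
                rows.append({"x": cx, "y": cy,
                             "t_start": track["time"].iloc[i],
                             "t_end": track["time"].iloc[i + j - 1],
                             "minutes": int(j)})
            i += j
        else:
            i += 1
    return pd.DataFrame(rows, columns=["x", "y", "t_start", "t_end", "minutes"])


@dataclass
class EventBundle:
    visits: pd.DataFrame           # all annotated visits (hills + low sites)
    stop_table: pd.DataFrame       # modeling table, stop model
    advance_table: pd.DataFrame    # modeling table, advance model
    low_locations: landscape.LowLocationSet
    exclusions: dict = field(default_factory=dict)


def _merge_party(visits: pd.DataFrame, party_obs: pd.DataFrame,
                 minutes: pd.DataFrame) -> pd.DataFrame:
    """Attach own adult party size / focal / sex at the arrival minute."""
    out = visits.copy()
    p = party_obs.copy()
    p["minute"] = pd.to_datetime(p["time"]).dt.floor("min")
    p = p.sort_values("time").groupby(["group", "minute"]).tail(1)
    p = p.set_index(["group", "minute"])
    m = minutes.copy()
    m["minute"] = pd.to_datetime(m["time"]).dt.floor("min")
    m = m.sort_values("time").groupby(["group", "minute"]).tail(1)
    m = m.set_index(["group", "minute"])
    key = pd.MultiIndex.from_arrays(
        [out["group"], pd.to_datetime(out["t_arrive"]).dt.floor("min")])
    out["adult_party_size"] = p["adult_party_size"].reindex(key).to_numpy()
    out["focal_id"] = m["focal_id"].reindex(key).to_numpy()
    sex = m["sex_class"].reindex(key).to_numpy()
    out["sex"] = np.where(pd.Series(sex).isin(["male"]), "male", "female")
    return out


def extract_events(fixes: pd.DataFrame, party_obs: pd.DataFrame,
                   minutes: pd.DataFrame, land: LandscapeBundle,
                   config: RunConfig | None = None) -> EventBundle:
    """Hill/low-site visits with all model covariates, plus both tables."""
    config = config or RunConfig()
    grid, band = land.grid, land.band
    groups = list(land.territories)
    excl = {"ambiguous_direction": 0, "undetermined_advance": 0,
            "missing_rival": 0}

    ann = landscape.annotate_elevation(fixes, grid, on_missing="nearest")
    hill_sites = land.hills.summits()
    hill_sites["loc_id"] = hill_sites.pop("hill_id")
    hill_sites["loc_type"] = "hill"

    # low rest locations from stationary band segments at low smoothed elev
    rest_rows = []
    for _, tr in ann.groupby("follow_id", sort=False):
        rs = find_rest_stops(tr, band, config.stop_min_dur,
                             config.move_thresh)
        if len(rs):
            rest_rows.append(rs)
    rest_stops = pd.concat(rest_rows, ignore_index=True) if rest_rows \
        else pd.DataFrame(columns=["x", "y"])
    low_set = landscape.detect_low_locations(
        rest_stops, grid, max_elev=config.low_max_elev,
        merge_dist=config.link_dist)
    low_sites = low_set.to_frame()
    if len(low_sites):
        low_sites["loc_id"] = low_sites.pop("loc_id")
        low_sites["loc_type"] = "low"
    sites = pd.concat([
        hill_sites[["loc_id", "loc_type", "x", "y", "elev"]],
        low_sites[["loc_id", "loc_type", "x", "y", "elev"]]
        if len(low_sites) else pd.DataFrame(
            columns=["loc_id", "loc_type", "x", "y", "elev"]),
    ], ignore_index=True)

    group_fixes = {g: ann[ann["group"] == g] for g in groups}
    all_visits = []
    for (g, fid), tr in ann.groupby(["group", "follow_id"], sort=False):
        v = events.detect_visits(tr, sites, radius=config.use_radius,
                                 elev_tol=config.elev_tol,
                                 min_dur=config.stop_min_dur,
                                 move_thresh=config.move_thresh)
        if len(v) == 0:
            continue
        terr = land.territories[g]
        rival_g = [x for x in groups if x != g][0]
        rival_track = group_fixes[rival_g]
        rival_party = party_obs[party_obs["group"] == rival_g]
        dirs, icd_mean, icd_dep, adv, imb, tdep = [], [], [], [], [], []
        for _, row in v.iterrows():
            dirs.append(events.classify_direction(
                tr, row["t_arrive"], terr, lookback=config.lookback,
                deadband=config.direction_deadband,
                metric=config.direction_metric))
            icd_mean.append(events.intercommunity_distance(
                tr, rival_track, row["t_arrive"], row["t_depart"],
                mode="mean_over_use"))
            t_out = events.detect_departure(
                tr, (row["site_x"], row["site_y"]), row["t_depart"] -
                pd.Timedelta(minutes=1), leave_dist=config.use_radius)
            tdep.append(t_out)
            if row["stopped"] and t_out is not None:
                d_dep = events.intercommunity_distance(
                    tr, rival_track, row["t_arrive"], t_out,
                    mode="at_departure")
                icd_dep.append(d_dep)
                rp = events.rival_party_size(rival_party, t_out,
                                             window=config.rival_window)
                imb.append(rp)
                rxy = _position_at(rival_track, t_out)
                adv.append(events.classify_advance(
                    tr, t_out, rxy, horizon=config.advance_horizon,
                    deadband=config.advance_deadband))
            else:
                icd_dep.append(np.nan)
                imb.append(np.nan)
                adv.append("undetermined")
        v["direction"] = dirs
        v["intercomm_dist"] = icd_mean
        v["intercomm_dist_depart"] = icd_dep
        v["t_out"] = tdep
        v["rival_adults"] = imb
        v["advance"] = adv
        all_visits.append(v)

    if not all_visits:
        empty = pd.DataFrame()
        return EventBundle(empty, events.build_stop_dataset(empty),
                           events.build_advance_dataset(empty), low_set, excl)
    visits = pd.concat(all_visits, ignore_index=True)
    visits["date"] = pd.to_datetime(visits["t_arrive"]).dt.date
    parts = [events.hills_before_after(sub)
             for _, sub in visits.groupby(["group", "date"], sort=False)]
    visits = pd.concat(parts, ignore_index=True)
    visits = _merge_party(visits, party_obs, minutes)
    visits["imbalance"] = (visits["adult_party_size"].astype(float)
                           - visits["rival_adults"].astype(float))
    visits["time_of_day"] = (pd.to_datetime(visits["t_arrive"]).dt.hour
                             + pd.to_datetime(visits["t_arrive"]).dt.minute / 60)
    kv, rcd, elev_sm = [], [], []
    for _, row in visits.iterrows():
        terr = land.territories[row["group"]]
        kv.append(territory.kernel_value(terr.ud, row["site_x"], row["site_y"]))
        yr = pd.Timestamp(row["t_arrive"]).year
        if yr not in terr.yearly_size:
            yr = next(iter(terr.yearly_size))
        rcd.append(float(territory.relative_center_distance(
            row["site_x"], row["site_y"], terr, year=yr)))
    visits["kernel"] = kv
    visits["rel_center_dist"] = rcd
    visits["elev"] = visits["site_elev"]

    excl["ambiguous_direction"] = int((visits["direction"] == "ambiguous").sum())
    stops = visits[visits["stopped"].astype(bool)]
    excl["undetermined_advance"] = int((stops["advance"] == "undetermined").sum())
    excl["missing_rival"] = int(stops["rival_adults"].isna().sum())

    stop_table = events.build_stop_dataset(
        visits[visits["loc_type"] == "hill"])
    advance_table = events.build_advance_dataset(stops)
    return EventBundle(visits=visits, stop_table=stop_table,
                       advance_table=advance_table, low_locations=low_set,
                       exclusions=excl)


def _position_at(track: pd.DataFrame, t):
    tt = pd.to_datetime(track["time"])
    sel = track[tt.dt.floor("min") == pd.Timestamp(t).floor("min")]
    if len(sel) == 0:
        return None
    return (float(sel["x"].iloc[0]), float(sel["y"].iloc[0]))


# ---------------------------------------------------------------------------
# model specifications


def stop_model_spec() -> glmm.ModelSpec:
    test = [("direction_border",), ("n_hills_before",), ("n_hills_after",),
            ("adult_party_size",), ("intercomm_dist",),
            ("adult_party_size", "intercomm_dist")]
    controls = [("rel_center_dist",), ("rel_center_dist", "rel_center_dist"),
                ("kernel",), ("elev",), ("time_of_day",), ("sex_male",),
                ("group_code",)]
    return glmm.ModelSpec(
        response="stopped", terms=tuple(test + controls),
        controls=tuple(controls),
        random=("loc_key", "date_group", "focal_id"),
        z_cols=("n_hills_before", "n_hills_after", "adult_party_size",
                "intercomm_dist", "rel_center_dist", "kernel", "elev",
                "time_of_day"),
    )


def advance_model_spec() -> glmm.ModelSpec:
    test = [("direction_border",), ("n_hills_before",), ("n_hills_after",),
            ("elev",), ("imbalance",), ("ln_dist",),
            ("elev", "imbalance"), ("elev", "ln_dist"),
            ("imbalance", "ln_dist"), ("elev", "imbalance", "ln_dist")]
    controls = [("rel_center_dist",), ("rel_center_dist", "rel_center_dist"),
                ("kernel",), ("time_of_day",), ("sex_male",), ("group_code",)]
    return glmm.ModelSpec(
        response="advance", terms=tuple(test + controls),
        controls=tuple(controls),
        random=("loc_key", "date_group", "focal_id"),
        z_cols=("n_hills_before", "n_hills_after", "elev", "imbalance",
                "ln_dist", "rel_center_dist", "kernel", "time_of_day"),
    )


def activity_model_spec(response: str) -> glmm.ModelSpec:
    test = [("kernel",), ("elev",), ("kernel", "elev")]
    controls = [("sex_female",), ("sex_oestrus",), ("group_code",),
                ("day_sin",), ("day_cos",), ("party_size",), ("food_avail",),
                ("n_oestrus",)]
    return glmm.ModelSpec(
        response=response, terms=tuple(test + controls),
        controls=tuple(controls), random=("date_group", "focal_id"),
        z_cols=("kernel", "elev", "party_size", "food_avail", "n_oestrus"),
    )


@dataclass
class AnalysisBundle:
    full: glmm.ModelResult
    null: glmm.ModelResult
    full_null: glmm.LRTResult
    drop1: pd.DataFrame
    reduced_spec: glmm.ModelSpec
    reduced: glmm.ModelResult
    table: pd.DataFrame
    extras: dict = field(default_factory=dict)


def _run_model(spec: glmm.ModelSpec, table: pd.DataFrame,
               alpha: float = 0.05) -> AnalysisBundle:
    full = glmm.fit(spec, table)
    null = glmm.fit(glmm.null_spec(spec), table)
    fn = glmm.lrt(full, null)
    d1 = glmm.drop1(spec, table, fitted=full)
    red_spec, red = glmm.reduce(spec, table, alpha=alpha)
    return AnalysisBundle(full=full, null=null, full_null=fn, drop1=d1,
                          reduced_spec=red_spec, reduced=red, table=table)


def run_stop_analysis(stop_table: pd.DataFrame,
                      config: RunConfig | None = None) -> AnalysisBundle:
    """Likelihood-to-stop model (full / null / reduced + LRTs)."""
    if "stopped" not in stop_table.columns:
        raise KeyError("stop table lacks the response column 'stopped'")
    config = config or RunConfig()
    return _run_model(stop_model_spec(), stop_table, alpha=config.alpha)


def run_advance_analysis(advance_table: pd.DataFrame,
                         config: RunConfig | None = None,
                         fit_ac: bool = True) -> AnalysisBundle:
    """Advance-toward-rivals model with the temporal autocorrelation term."""
    for c in ("advance", "imbalance", "ln_dist"):
        if c not in advance_table.columns:
            raise KeyError(f"advance table lacks required column {c!r}")
    config = config or RunConfig()
    spec = advance_model_spec()
    out = _run_model(spec, advance_table, alpha=config.alpha)
    if fit_ac and len(advance_table) > 20:
        times = (pd.to_datetime(advance_table["date_group"].str.split(":").str[0])
                 .astype("int64") / 6e10)
        # absolute minutes of departure within the study
        if "t_out" in advance_table.columns:
            times = pd.to_datetime(advance_table["t_out"]).astype("int64") / 6e10
        grp = advance_table["group_code"]
        sf = autocorr.fit_sigma(out.reduced_spec, advance_table,
                                times.to_numpy(float), grp.to_numpy(),
                                base=out.reduced)
        out.extras["ac_sigma"] = sf.sigma
        out.extras["ac_fit"] = sf.result
        out.extras["ac_profile"] = sf.profile
    return out


def annotate_minutes(minutes: pd.DataFrame, fixes: pd.DataFrame,
                     land: LandscapeBundle) -> pd.DataFrame:
    """Attach location, smoothed elevation and kernel value to minute points.

    Minute rows join their group's fix at the same minute; elevation comes
    from the reconstructed grid, the kernel value from the group's own UD.
    """
    fx = fixes.copy()
    fx["minute"] = pd.to_datetime(fx["time"]).dt.floor("min")
    fx = fx.sort_values("time").groupby(["group", "minute"]).tail(1)
    fx = fx.set_index(["group", "minute"])
    out = minutes.copy()
    key = pd.MultiIndex.from_arrays(
        [out["group"], pd.to_datetime(out["time"]).dt.floor("min")])
    out["x"] = fx["x"].reindex(key).to_numpy()
    out["y"] = fx["y"].reindex(key).to_numpy()
    out = out.dropna(subset=["x", "y"]).reset_index(drop=True)
    out["elev"] = np.atleast_1d(land.grid.lookup(
        out["x"].to_numpy(float), out["y"].to_numpy(float),
        on_missing="nearest"))
    kv = np.empty(len(out), dtype=int)
    for g, terr in land.territories.items():
        m = (out["group"] == g).to_numpy()
        if m.any():
            kv[m] = np.atleast_1d(territory.kernel_value(
                terr.ud, out.loc[m, "x"].to_numpy(float),
                out.loc[m, "y"].to_numpy(float)))
    out["kernel"] = kv
    return out


def run_activity_analysis(minutes: pd.DataFrame,
                          config: RunConfig | None = None) -> dict:
    """Three activity models on the thinned minute table, plus budgets."""
    config = config or RunConfig()
    thinned = activity_mod.thin(minutes, spacing=config.thin_spacing)
    table = activity_mod.build_activity_dataset(thinned)
    out = {"budgets": activity_mod.budgets(minutes),
           "bouts": activity_mod.bout_lengths(minutes),
           "n_thinned": len(table)}
    for act in activity_mod.ACTIVITIES:
        out[act] = _run_model(activity_model_spec(act), table,
                              alpha=config.alpha)
    return out


# ---------------------------------------------------------------------------
# truth evaluation (synthetic runs)


def evaluate_against_truth(ev: EventBundle, truth_visits: pd.DataFrame,
                           truth_advances: pd.DataFrame,
                           true_hills: pd.DataFrame,
                           match_dist: float = 75.0) -> dict:
    """Agreement between generator truth labels and extracted events.

    A truth visit matches an extracted visit of the same group/day whose
    site lies within ``match_dist`` of the true site and whose interval
    contains the truth arrival.  Reports visit recall, stop-label
    agreement, direction agreement (both determined) and advance-label
    agreement.
    """
    vis = ev.visits
    out = {"n_truth_visits": len(truth_visits)}
    hills_xy = true_hills.set_index("hill_idx")[["x", "y"]]
    matched, stop_ok, dir_tot, dir_ok = 0, 0, 0, 0
    adv_key = {}
    for _, tv in truth_visits.iterrows():
        if tv["site_type"] != "hill":
            continue
        hx, hy = hills_xy.loc[tv["site_idx"]]
        t_arr = pd.Timestamp(tv["t_arrive"])
        cand = vis[(vis["group"] == tv["group"]) & (vis["loc_type"] == "hill")]
        cand = cand[np.hypot(cand["site_x"] - hx, cand["site_y"] - hy)
                    <= match_dist]
        cand = cand[(pd.to_datetime(cand["t_arrive"]) <= t_arr + pd.Timedelta(minutes=3))
                    & (pd.to_datetime(cand["t_depart"]) >= t_arr)]
        if len(cand) == 0:
            continue
        row = cand.iloc[0]
        matched += 1
        if bool(row["stopped"]) == bool(tv["stopped"]):
            stop_ok += 1
        if row["direction"] != "ambiguous" and tv["direction"] != "ambiguous":
            dir_tot += 1
            if row["direction"] == tv["direction"]:
                dir_ok += 1
        adv_key.setdefault((tv["group"], tv["site_idx"]), []).append(row)
    n_truth_hill = int((truth_visits["site_type"] == "hill").sum())
    out["visit_recall"] = matched / n_truth_hill if n_truth_hill else float("nan")
    out["stop_agreement"] = stop_ok / matched if matched else float("nan")
    out["direction_agreement"] = dir_ok / dir_tot if dir_tot else float("nan")

    adv_tot, adv_ok = 0, 0
    for _, ta in truth_advances.iterrows():
        if ta["site_type"] != "hill":
            continue
        cand = adv_key.get((ta["group"], ta["site_idx"]), [])
        t_dep = pd.Timestamp(ta["t_depart"])
        cand = [r for r in cand if pd.notna(r["t_out"])
                and abs(pd.Timestamp(r["t_out"]) - t_dep)
                <= pd.Timedelta(minutes=5)]
        if not cand or cand[0]["advance"] == "undetermined":
            continue
        row = cand[0]
        adv_tot += 1
        if (row["advance"] == "advance") == bool(ta["advance"]):
            adv_ok += 1
    out["advance_agreement"] = adv_ok / adv_tot if adv_tot else float("nan")
    out["n_advance_compared"] = adv_tot
    return out
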