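"""Synthetic two-group ranging data with known generating parameters.

The generator realizes the statistical structure the analysis assumes — it
is not a model of chimpanzee cognition.  Two groups hold neighboring
territories separated by a West–East overlap band studded with inselbergs
(Gaussian bumps on a low-relief ~190 m plain, summits up to ~287 m).  Days
are either ranging days (drifting near the territory center with an
activity-bout process) or patrol days: a waypoint route out through the
band visiting hills, an optional rest at a low-lying site, and a return
leg.  On arrival at each hill the party stops with probability
``logistic(b0 + b_dir * toward_border + b_after * n_hills_after + hill
intercept)``; on departure from a stop it advances toward (vs. retreats
from) the rival group's current position with probability
``logistic(g0 + g_imb * imbalance' + g_de * ln(distance)' * elevation' +
g_dir * toward_border)`` (primed quantities on fixed nominal scales, see
docs).  Both groups move in one joint minute loop, so rival positions and
party sizes at each departure are exact and the emitted truth tables are
consistent with the tracklogs by construction.

All randomness flows from ``numpy.random.default_rng([seed, day])``
substreams: a fixed seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

START_DATE = pd.Timestamp("2014-01-06")
DAY_START_HOUR = 7


@dataclass
class SimConfig:
    seed: int = 0
    # arena and landscape (meters)
    arena_x: float = 8000.0
    arena_y: float = 9000.0
    band_x: tuple = (3000.0, 5000.0)       # ~2,000 m West-East overlap band
    base_elev: float = 190.0
    ripple_amp: float = 8.0
    n_hills_band: int = 12
    n_hills_out: int = 6
    summit_range: tuple = (242.0, 287.0)
    hill_sd: float = 45.0                  # Gaussian bump scale
    min_hill_sep: float = 320.0
    n_low_sites: int = 8
    low_site_depth: float = 25.0           # depression depth below base
    low_site_sd: float = 160.0
    # sampling
    days: int = 60
    day_spacing: int = 5                   # calendar days between follow days
    minutes_per_day: int = 600             # 10 h at 1 fix/min
    gps_noise: float = 5.0
    elev_noise: float = 3.0
    speed: float = 45.0                    # travel speed m/min
    # social structure
    adults_mean: float = 8.0
    switch_rate: float = 1 / 45.0          # party birth-death events per min
    # activity bout means (min): (east-like group 0? see groups below)
    rest_bout: tuple = (11.6, 15.07)
    feed_bout: tuple = (16.46, 17.66)
    travel_bout: tuple = (5.61, 7.15)
    # behavior rates
    roam_waypoints: int = 6
    patrol_p: float = 0.6
    hills_per_patrol: float = 2.5          # Poisson mean beyond the first
    low_rest_p: float = 0.7
    return_hill_p: float = 0.35
    # generating coefficients
    stop_intercept: float = -0.9
    beta_dir: float = 1.6
    beta_after: float = -0.4
    adv_intercept: float = -0.35
    beta_imb: float = 0.5
    beta_dist_elev: float = 0.4
    beta_dir_adv: float = 0.75
    sigma_hill: float = 0.5
    # nominal scales for the advance logit (fixed, not data-derived)
    imb_scale: float = 3.0
    ln_dist_center: float = 7.3            # ln(1500 m)
    ln_dist_scale: float = 0.8
    elev_center: float = 195.0
    elev_scale: float = 35.0

    groups: tuple = ("west", "east")


@dataclass
class Landscape:
    config: SimConfig
    hills: pd.DataFrame        # hill_idx, x, y, amp, summit_elev, in_band
    low_sites: pd.DataFrame    # site_idx, x, y

    def elev(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        c = self.config
        z = (c.base_elev
             + 0.5 * c.ripple_amp * np.sin(2 * np.pi * x / 1700.0)
             + 0.5 * c.ripple_amp * np.cos(2 * np.pi * y / 2300.0))
        for _, h in self.hills.iterrows():
            d2 = (x - h["x"]) ** 2 + (y - h["y"]) ** 2
            z = z + h["amp"] * np.exp(-d2 / (2 * c.hill_sd ** 2))
        for _, s in self.low_sites.iterrows():
            d2 = (x - s["x"]) ** 2 + (y - s["y"]) ** 2
            z = z - c.low_site_depth * np.exp(-d2 / (2 * c.low_site_sd ** 2))
        return z if np.ndim(x) else float(z)


def _scatter_points(rng, n, x_range, y_range, min_sep, existing=None,
                    max_tries=4000):
    pts = [] if existing is None else [tuple(p) for p in existing]
    out = []
    tries = 0
    while len(out) < n and tries < max_tries:
        tries += 1
        p = (rng.uniform(*x_range), rng.uniform(*y_range))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep ** 2
               for q in pts):
            pts.append(p)
            out.append(p)
    if len(out) < n:
        raise RuntimeError("could not place points with the requested separation")
    return out


def gen_landscape(config: SimConfig) -> Landscape:
    """Analytic elevation field plus the true hill and low-site lists."""
    rng = np.random.default_rng([config.seed, 999])
    c = config
    band_pts = _scatter_points(
        rng, c.n_hills_band,
        (c.band_x[0] + 150, c.band_x[1] - 150), (1200, c.arena_y - 1200),
        c.min_hill_sep)
    out_pts = []
    if c.n_hills_out:
        west = _scatter_points(rng, c.n_hills_out // 2, (600, c.band_x[0] - 600),
                               (1200, c.arena_y - 1200), c.min_hill_sep, band_pts)
        east = _scatter_points(rng, c.n_hills_out - c.n_hills_out // 2,
                               (c.band_x[1] + 600, c.arena_x - 600),
                               (1200, c.arena_y - 1200), c.min_hill_sep,
                               band_pts + west)
        out_pts = west + east
    rows = []
    for i, (x, y) in enumerate(band_pts + out_pts):
        summit = rng.uniform(*c.summit_range)
        rows.append({"hill_idx": i, "x": x, "y": y,
                     "amp": summit - c.base_elev, "in_band": i < len(band_pts)})
    hills = pd.DataFrame(rows, columns=["hill_idx", "x", "y", "amp",
                                        "in_band"])
    low_pts = _scatter_points(
        rng, c.n_low_sites, (c.band_x[0] + 120, c.band_x[1] - 120),
        (1200, c.arena_y - 1200), 450.0, band_pts)
    low_sites = pd.DataFrame(
        [{"site_idx": i, "x": x, "y": y} for i, (x, y) in enumerate(low_pts)],
        columns=["site_idx", "x", "y"])
    land = Landscape(config=config, hills=hills, low_sites=low_sites)
    hills["summit_elev"] = land.elev(hills["x"].to_numpy(),
                                     hills["y"].to_numpy())
    return land


# ---------------------------------------------------------------------------
# movement


class _GroupState:
    """Per-group minute state machine: EN_ROUTE -> (DWELL) -> MANEUVER."""

    def __init__(self, name, center, pos, plan, adults, rng, cfg, land,
                 toward_positive_x):
        self.name = name
        self.center = np.asarray(center, float)
        self.pos = np.asarray(pos, float)
        self.plan = plan                       # list of waypoint dicts
        self.wp = 0
        self.mode = "route"
        self.dwell_left = 0
        self.man_left = 0
        self.man_target = None
        self.man_sign = 1.0
        self.adults = adults
        self.rng = rng
        self.cfg = cfg
        self.land = land
        self.toward_positive_x = toward_positive_x
        self.activity = "travel"
        self.bout_left = 0
        self.pending_departure = None          # waypoint dict of current dwell
        self.history = []                      # true positions, one per minute
        self.truth_visits = []
        self.truth_advances = []

    def realized_direction(self, lookback: int = 30,
                           deadband: float = 100.0) -> str:
        """Direction label from the actual motion over the last lookback min
        (change in true radial distance to the own territory center)."""
        if not self.history:
            return "ambiguous"
        p0 = (self.history[-lookback] if len(self.history) >= lookback
              else self.history[0])
        d = (np.hypot(*(self.pos - self.center))
             - np.hypot(*(np.asarray(p0) - self.center)))
        if d > deadband:
            return "toward_border"
        if d < -deadband:
            return "toward_center"
        return "ambiguous"

    def current_waypoint(self):
        return self.plan[self.wp] if self.wp < len(self.plan) else None


def _draw_bout(rng, mean):
    return max(1, round(rng.exponential(mean)))


def _plan_patrol(rng, cfg, land, center, group_i):
    """Waypoint plan: outbound hills (by increasing border proximity),
    optional low rest, optional return hill, then home."""
    hills = land.hills[land.hills["in_band"]]
    k = min(len(hills), 1 + rng.poisson(cfg.hills_per_patrol))
    chosen = hills.sample(n=k, random_state=int(rng.integers(2 ** 31)))
    # keep hills separated in x so the kernel-based direction rule is crisp
    asc = group_i == 0  # west group goes east (x increasing)
    chosen = chosen.sort_values("x", ascending=asc)
    picked = []
    for _, h in chosen.iterrows():
        if all(abs(h["x"] - p["x"]) >= 220 for p in picked):
            picked.append(h)
    plan = [{"kind": "hill", "x": h["x"], "y": h["y"],
             "site_idx": int(h["hill_idx"]), "direction": "toward_border",
             "elev": float(h["summit_elev"])} for h in picked]
    if rng.random() < cfg.low_rest_p and len(land.low_sites):
        s = land.low_sites.sample(n=1, random_state=int(rng.integers(2 ** 31))).iloc[0]
        plan.append({"kind": "low", "x": s["x"], "y": s["y"],
                     "site_idx": int(s["site_idx"]), "direction": "toward_border",
                     "elev": float(land.elev(s["x"], s["y"]))})
    if rng.random() < cfg.return_hill_p and len(picked):
        h = picked[int(rng.integers(len(picked)))]
        plan.append({"kind": "hill", "x": h["x"], "y": h["y"],
                     "site_idx": int(h["hill_idx"]), "direction": "toward_center",
                     "elev": float(h["summit_elev"])})
    plan.append({"kind": "home", "x": center[0] + rng.normal(0, 250),
                 "y": center[1] + rng.normal(0, 250)})
    # hill order counts for the before/after covariates
    n_hills = sum(1 for p in plan if p["kind"] == "hill")
    j = 0
    for p in plan:
        if p["kind"] == "hill":
            p["n_before"], p["n_after"] = j, n_hills - j - 1
            j += 1
        elif p["kind"] == "low":
            p["n_before"], p["n_after"] = j, n_hills - j
    return plan


def _plan_ranging(rng, center, n_waypoints=6):
    plan = []
    for _ in range(n_waypoints):
        plan.append({"kind": "roam", "x": center[0] + rng.normal(0, 600),
                     "y": center[1] + rng.normal(0, 600)})
    return plan


_DIR_TERM = {"toward_border": 1.0, "toward_center": 0.0, "ambiguous": 0.5}


def _stop_probability(cfg, direction, n_after, hill_re):
    eta = (cfg.stop_intercept + cfg.beta_dir * _DIR_TERM[direction]
           + cfg.beta_after * n_after + hill_re)
    return 1.0 / (1.0 + np.exp(-eta))


def _advance_probability(cfg, direction, imbalance, dist, elev):
    z_imb = imbalance / cfg.imb_scale
    z_d = (np.log(max(dist, 1.0)) - cfg.ln_dist_center) / cfg.ln_dist_scale
    z_e = (elev - cfg.elev_center) / cfg.elev_scale
    eta = (cfg.adv_intercept + cfg.beta_imb * z_imb
           + cfg.beta_dist_elev * z_d * z_e
           + cfg.beta_dir_adv * _DIR_TERM[direction])
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class SimBundle:
    config: SimConfig
    landscape: Landscape
    fixes: pd.DataFrame
    party_obs: pd.DataFrame
    minutes: pd.DataFrame       # activity minute-points with covariates
    truth_visits: pd.DataFrame
    truth_advances: pd.DataFrame
    hill_effects: pd.DataFrame


def gen_tracklogs(config: SimConfig,
                  landscape: Landscape | None = None) -> SimBundle:
    """Simulate both groups minute-by-minute for the configured study days."""
    cfg = config
    land = landscape if landscape is not None else gen_landscape(cfg)
    master = np.random.default_rng([cfg.seed, 0])
    hill_re = master.normal(0.0, cfg.sigma_hill, size=len(land.hills))
    centers = {0: np.array([1500.0, cfg.arena_y / 2]),
               1: np.array([cfg.arena_x - 1500.0, cfg.arena_y / 2])}
    focals = {g: [f"{cfg.groups[g]}_m{i}" for i in range(3)]
              + [f"{cfg.groups[g]}_f{i}" for i in range(3)] for g in (0, 1)}

    fix_rows, party_rows, minute_rows = [], [], []
    truth_visits, truth_advances = [], []
    for day in range(cfg.days):
        rng = np.random.default_rng([cfg.seed, 1, day])
        date = START_DATE + pd.Timedelta(days=day * cfg.day_spacing)
        t0 = date + pd.Timedelta(hours=DAY_START_HOUR)
        food = 1.0 + 0.5 * np.sin(2 * np.pi * date.dayofyear / 365.25) \
            + rng.normal(0, 0.05)
        states = {}
        for g in (0, 1):
            patrol = rng.random() < cfg.patrol_p
            plan = (_plan_patrol(rng, cfg, land, centers[g], g) if patrol
                    else _plan_ranging(rng, centers[g], cfg.roam_waypoints))
            adults = int(np.clip(rng.poisson(cfg.adults_mean), 2, 20))
            pos = centers[g] + rng.normal(0, 250, 2)
            states[g] = _GroupState(cfg.groups[g], centers[g], pos, plan,
                                    adults, rng, cfg, land, g == 0)
            st = states[g]
            st.focal = focals[g][int(rng.integers(len(focals[g])))]
            st.sex_class = ("male" if st.focal.split("_")[1][0] == "m"
                            else ("oestrus_female" if rng.random() < 0.15
                                  else "female"))
            st.n_oestrus = int(rng.poisson(0.4))
            st.party = st.adults + int(rng.poisson(2))
            st.visit_seq = 0

        for minute in range(cfg.minutes_per_day):
            t = t0 + pd.Timedelta(minutes=minute)
            for g in (0, 1):
                st = states[g]
                rival = states[1 - g]
                # party-size birth-death drift
                if rng.random() < cfg.switch_rate:
                    st.adults = int(np.clip(st.adults + rng.choice([-1, 1]),
                                            2, 20))
                    st.party = max(st.adults, st.party + rng.choice([-1, 1]))
                _step_group(st, rival, t, minute, rng, truth_visits,
                            truth_advances, hill_re, day, date)
                st.history.append(st.pos.copy())
                # record fix + minute point
                gx = st.pos[0] + rng.normal(0, cfg.gps_noise)
                gy = st.pos[1] + rng.normal(0, cfg.gps_noise)
                ge = land.elev(st.pos[0], st.pos[1]) + rng.normal(0, cfg.elev_noise)
                follow = f"{cfg.groups[g]}_{date.date()}"
                fix_rows.append((t, gx, gy, ge, cfg.groups[g], follow))
                party_rows.append((t, cfg.groups[g], gx, gy, st.adults,
                                   st.party, st.n_oestrus))
                minute_rows.append((t, cfg.groups[g], follow, st.focal,
                                    st.sex_class,
                                    int(st.activity == "rest"),
                                    int(st.activity == "feed"),
                                    int(st.activity == "travel"),
                                    st.party, st.n_oestrus, food))

    fixes = pd.DataFrame(fix_rows, columns=["time", "x", "y", "elev",
                                            "group", "follow_id"])
    party_obs = pd.DataFrame(party_rows, columns=[
        "time", "group", "x", "y", "adult_party_size", "party_size",
        "n_oestrus"])
    minutes = pd.DataFrame(minute_rows, columns=[
        "time", "group", "follow_id", "focal_id", "sex_class", "rest",
        "feed", "travel", "party_size", "n_oestrus", "food_avail"])
    tv = pd.DataFrame(truth_visits)
    ta = pd.DataFrame(truth_advances)
    he = pd.DataFrame({"hill_idx": np.arange(len(hill_re)), "re": hill_re})
    return SimBundle(config=cfg, landscape=land, fixes=fixes,
                     party_obs=party_obs, minutes=minutes, truth_visits=tv,
                     truth_advances=ta, hill_effects=he)


def _step_group(st: _GroupState, rival: _GroupState, t, minute, rng,
                truth_visits, truth_advances, hill_re, day, date):
    cfg = st.cfg
    if st.mode == "dwell":
        st.dwell_left -= 1
        st.activity = "rest"
        wp0 = st.pending_departure
        if wp0 is not None:                       # bounded jitter around the site
            st.pos = np.array([wp0["x"], wp0["y"]]) + rng.normal(0, 2.0, 2)
        else:
            st.pos = st.pos + rng.normal(0, 2.0, 2)
        if st.dwell_left <= 0:
            wp = st.pending_departure
            st.pending_departure = None
            if wp is not None and wp["kind"] in ("hill", "low"):
                d0 = float(np.hypot(*(st.pos - rival.pos)))
                imb = st.adults - rival.adults
                dir_real = wp.get("dir_real", wp["direction"])
                p_adv = _advance_probability(cfg, dir_real, imb, d0,
                                             wp["elev"])
                advance = bool(rng.random() < p_adv)
                truth_advances.append({
                    "date": date.date(), "group": st.name,
                    "site_type": wp["kind"], "site_idx": wp["site_idx"],
                    "t_depart": t, "advance": int(advance),
                    "imbalance": imb, "dist_depart": d0,
                    "elev": wp["elev"],
                    "direction": dir_real, "p_advance": p_adv,
                })
                st.mode = "maneuver"
                st.man_left = 31
                st.man_target = rival.pos.copy()
                st.man_sign = 1.0 if advance else -1.0
                st.activity = "travel"
                return
            st.mode = "route"
        return
    if st.mode == "maneuver":
        st.man_left -= 1
        st.activity = "travel"
        v = st.man_target - st.pos
        d = np.hypot(*v)
        if d > 1.0:
            u = v / d
            step = min(cfg.speed, d - 60.0) if st.man_sign > 0 else cfg.speed
            step = max(step, 0.0)
            st.pos = st.pos + st.man_sign * step * u + rng.normal(0, 3.0, 2)
        if st.man_left <= 0:
            st.mode = "route"
        return
    # route mode
    wp = st.current_waypoint()
    if wp is None:
        # day plan done: drift near center with the activity-bout process
        if st.bout_left <= 0:
            means = {"rest": cfg.rest_bout[0 if st.toward_positive_x else 1],
                     "feed": cfg.feed_bout[0 if st.toward_positive_x else 1],
                     "travel": cfg.travel_bout[0 if st.toward_positive_x else 1]}
            # no self-transitions, so observed runs equal generated bouts
            acts, probs = ["rest", "feed", "travel"], np.array([0.35, 0.4, 0.25])
            if st.activity in acts:
                keep = [a != st.activity for a in acts]
                acts = [a for a, k in zip(acts, keep) if k]
                probs = probs[keep] / probs[keep].sum()
            st.activity = rng.choice(acts, p=probs)
            st.bout_left = _draw_bout(rng, means[st.activity])
        st.bout_left -= 1
        if st.activity == "travel":
            v = st.center - st.pos + rng.normal(0, 400, 2)
            d = np.hypot(*v)
            st.pos = st.pos + (cfg.speed * 0.7) * v / max(d, 1.0)
        else:
            st.pos = st.pos + rng.normal(0, 2.0, 2)
        return
    v = np.array([wp["x"], wp["y"]]) - st.pos
    d = float(np.hypot(*v))
    st.activity = "travel"
    if d <= cfg.speed:
        st.pos = np.array([wp["x"], wp["y"]]) + rng.normal(0, 2.0, 2)
        st.wp += 1
        if wp["kind"] == "hill":
            dir_real = st.realized_direction()
            wp["dir_real"] = dir_real
            p_stop = _stop_probability(cfg, dir_real, wp["n_after"],
                                       hill_re[wp["site_idx"]])
            stopped = bool(rng.random() < p_stop)
            dwell = 5 + int(rng.exponential(12.0)) if stopped else 0
            truth_visits.append({
                "date": date.date(), "group": st.name, "site_type": "hill",
                "site_idx": wp["site_idx"], "t_arrive": t,
                "stopped": int(stopped), "dwell": dwell,
                "direction": dir_real, "direction_planned": wp["direction"],
                "n_before": wp["n_before"],
                "n_after": wp["n_after"], "p_stop": p_stop,
                "elev": wp["elev"], "adults": st.adults,
            })
            if stopped:
                st.mode = "dwell"
                st.dwell_left = dwell
                st.pending_departure = wp
                st.activity = "rest"
        elif wp["kind"] == "low":
            dir_real = st.realized_direction()
            wp["dir_real"] = dir_real
            dwell = 8 + int(rng.exponential(14.0))
            truth_visits.append({
                "date": date.date(), "group": st.name, "site_type": "low",
                "site_idx": wp["site_idx"], "t_arrive": t, "stopped": 1,
                "dwell": dwell, "direction": dir_real,
                "direction_planned": wp["direction"],
                "n_before": wp["n_before"], "n_after": wp["n_after"],
                "p_stop": 1.0, "elev": wp["elev"], "adults": st.adults,
            })
            st.mode = "dwell"
            st.dwell_left = dwell
            st.pending_departure = wp
            st.activity = "rest"
    else:
        st.pos = st.pos + cfg.speed * v / d + rng.normal(0, 3.0, 2)


def gen_fixture_suite(config: SimConfig, out_dir, force: bool = False) -> dict:
    """Write the CSV bundle (tracklogs, party observations, minute points,
    truth tables, generating values) a pipeline run can ingest."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    bundle = gen_tracklogs(config)
    paths = {}
    for name, df in [("fixes", bundle.fixes), ("party_obs", bundle.party_obs),
                     ("minutes", bundle.minutes),
                     ("truth_visits", bundle.truth_visits),
                     ("truth_advances", bundle.truth_advances),
                     ("true_hills", bundle.landscape.hills),
                     ("low_sites", bundle.landscape.low_sites)]:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    (out / "generating_values.json").write_text(
        json.dumps(asdict(config), indent=2, default=str))
    (out / "README.txt").write_text(
        "Synthetic two-group ranging bundle. generating_values.json holds\n"
        "the full generator configuration, truth_*.csv the event labels the\n"
        "pipeline should recover.\n")
    paths["config"] = str(out / "generating_values.json")
    return paths
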