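"""Event extraction rules: visits, stops, direction, departure, advance."""

import numpy as np
import pandas as pd
import pytest

from terratactics import events as E
from terratactics import territory as T
from conftest import make_fixes


def brute_force_stop(x, y, min_dur, move_thresh):
    """All-windows oracle for the stop rule."""
    n = len(x)
    best = 0
    for i in range(n):
        for j in range(i, n):
            win = slice(i, j + 1)
            if np.hypot(x[win] - x[i], y[win] - y[i]).max() <= move_thresh:
                best = max(best, j - i + 1)
            else:
                break
    return (best >= min_dur), (best if best >= min_dur else 0)


class TestDetectStop:
    def test_stationary_visit(self):
        f = make_fixes(np.zeros(10), np.zeros(10), np.full(10, 200.0))
        assert E.detect_stop(f) == (True, 10)

    def test_steady_traverse(self):
        f = make_fixes(np.arange(5) * 60.0, np.zeros(5), np.full(5, 200.0))
        assert E.detect_stop(f) == (False, 0)

    def test_random_walks_match_allwindows_oracle(self, rng):
        for _ in range(120):
            n = int(rng.integers(2, 25))
            x = np.cumsum(rng.normal(0, 12, n))
            y = np.cumsum(rng.normal(0, 12, n))
            f = make_fixes(x, y, np.full(n, 200.0))
            assert E.detect_stop(f) == brute_force_stop(x, y, 5, 25.0)


@pytest.fixture(scope="module")
def toy_sites():
    return pd.DataFrame({
        "loc_id": [0], "loc_type": ["hill"],
        "x": [0.0], "y": [0.0], "elev": [240.0],
    })


class TestDetectVisits:
    def _track(self, xs, ys, elevs):
        f = make_fixes(xs, ys, elevs)
        f["smoothed_elev"] = f["elev"]
        return f

    def test_short_pass_is_unstopped_visit(self, toy_sites):
        tr = self._track([-200, 30, 30, 30, 200],
                         [0, 0, 10, 20, 0],
                         [200, 238, 239, 238, 200])
        v = E.detect_visits(tr, toy_sites)
        assert len(v) == 1
        assert not v["stopped"].iloc[0]

    def test_dwell_is_stopped_visit(self, toy_sites):
        xs = [-200] + [35] * 8 + [200]
        tr = self._track(xs, np.zeros(10), [200] + [239] * 8 + [200])
        v = E.detect_visits(tr, toy_sites)
        assert len(v) == 1
        assert bool(v["stopped"].iloc[0])
        assert v["stop_minutes"].iloc[0] == 8

    def test_elevation_gate_blocks_cliff_base(self, toy_sites):
        tr = self._track([-200, 30, 30, 200], np.zeros(4),
                         [200, 200, 200, 200])   # 40 m below the summit
        assert len(E.detect_visits(tr, toy_sites)) == 0

    def test_short_gap_merges_same_site(self, toy_sites):
        xs = [30, 30, 120, 30, 30]   # off-site for 1 min mid-visit
        tr = self._track(xs, np.zeros(5), [239, 239, 200, 239, 239])
        v = E.detect_visits(tr, toy_sites)
        assert len(v) == 1


@pytest.fixture(scope="module")
def terr():
    r = np.random.default_rng(2)
    xy = r.normal(0, 400, (4000, 2))
    return T.fit_territory(
        make_fixes(xy[:, 0], xy[:, 1], np.full(4000, 200.0)))


class TestDirection:

    def _track_line(self, x0, x1, n=31):
        xs = np.linspace(x0, x1, n)
        return make_fixes(xs, np.zeros(n), np.full(n, 200.0))

    def test_outward_is_toward_border(self, terr):
        cx, cy = terr.center_xy
        tr = self._track_line(cx, cx + 1200)
        t_arr = tr["time"].iloc[-1]
        assert E.classify_direction(tr, t_arr, terr) == "toward_border"
        assert E.classify_direction(tr, t_arr, terr,
                                    metric="kernel") == "toward_border"

    def test_inward_is_toward_center(self, terr):
        cx, cy = terr.center_xy
        tr = make_fixes(np.linspace(cx + 1200, cx, 31), np.zeros(31),
                        np.full(31, 200.0))
        t_arr = tr["time"].iloc[-1]
        assert E.classify_direction(tr, t_arr, terr) == "toward_center"
        assert E.classify_direction(tr, t_arr, terr,
                                    metric="kernel") == "toward_center"

    def test_deadband_gives_ambiguous(self, terr):
        cx, cy = terr.center_xy
        tr = self._track_line(cx + 500, cx + 540)   # 40 m < 100 m dead-band
        assert E.classify_direction(tr, tr["time"].iloc[-1], terr) == "ambiguous"

    def test_insufficient_lookback_warns_ambiguous(self, terr):
        tr = self._track_line(0, 100, n=31)
        with pytest.warns(UserWarning):
            out = E.classify_direction(tr, tr["time"].iloc[0]
                                       - pd.Timedelta(minutes=60), terr)
        assert out == "ambiguous"


class TestHillsBeforeAfter:
    def _visits(self, kinds):
        n = len(kinds)
        return pd.DataFrame({
            "t_arrive": pd.date_range("2014-01-06 08:00", periods=n, freq="h"),
            "loc_type": kinds,
        })

    def test_single_visit(self):
        out = E.hills_before_after(self._visits(["hill"]))
        assert (out["n_hills_before"].iloc[0], out["n_hills_after"].iloc[0]) == (0, 0)

    def test_four_visits_counts(self):
        out = E.hills_before_after(self._visits(["hill"] * 4))
        assert out["n_hills_before"].tolist() == [0, 1, 2, 3]
        assert out["n_hills_after"].tolist() == [3, 2, 1, 0]

    def test_low_rows_count_surrounding_hills_only(self):
        out = E.hills_before_after(self._visits(["hill", "low", "hill"]))
        low = out[out["loc_type"] == "low"].iloc[0]
        assert (low["n_hills_before"], low["n_hills_after"]) == (1, 1)

    def test_order_invariance(self, rng):
        v = self._visits(["hill"] * 6)
        shuffled = v.sample(frac=1, random_state=3)
        a = E.hills_before_after(v)
        b = E.hills_before_after(shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestRivalPartySize:
    def _obs(self, times, sizes, parties=None):
        df = pd.DataFrame({"time": pd.to_datetime(times),
                           "adult_party_size": sizes})
        if parties is not None:
            df["party"] = parties
        return df

    def test_single_party(self):
        obs = self._obs(["2014-01-06 08:00"], [5])
        assert E.rival_party_size(obs, "2014-01-06 08:10") == 5

    def test_two_parties_aggregate(self):
        obs = self._obs(["2014-01-06 08:00", "2014-01-06 08:05"], [3, 4],
                        parties=["a", "b"])
        assert E.rival_party_size(obs, "2014-01-06 08:10") == 7

    def test_no_observation_in_window_missing(self):
        obs = self._obs(["2014-01-06 07:00"], [5])
        assert np.isnan(E.rival_party_size(obs, "2014-01-06 08:10"))


class TestIntercommunityDistance:
    def test_colocated_and_closest_party_rule(self):
        own = make_fixes([0, 0, 0], [0, 0, 0], [200] * 3)
        near = make_fixes([300, 300, 300], [0, 0, 0], [200] * 3)
        far = make_fixes([700, 700, 700], [0, 0, 0], [200] * 3)
        near["party"], far["party"] = "a", "b"
        rivals = pd.concat([near, far])
        d = E.intercommunity_distance(own, rivals, own["time"].iloc[0],
                                      own["time"].iloc[-1])
        assert d == pytest.approx(300.0)
        assert E.intercommunity_distance(own, own.assign(party="x"),
                                         own["time"].iloc[0],
                                         own["time"].iloc[-1]) == 0.0

    def test_mean_over_use(self):
        own = make_fixes([0, 0, 0], [0, 0, 0], [200] * 3)
        riv = make_fixes([100, 200, 300], [0, 0, 0], [200] * 3)
        t0, t1 = own["time"].iloc[0], own["time"].iloc[-1]
        assert E.intercommunity_distance(own, riv, t0, t1) == 200.0
        assert E.intercommunity_distance(own, riv, t0, t1,
                                         mode="at_departure") == 300.0

    def test_symmetry_between_groups(self, rng):
        a = make_fixes(rng.normal(0, 50, 10), rng.normal(0, 50, 10), [200] * 10)
        b = make_fixes(rng.normal(500, 50, 10), rng.normal(0, 50, 10), [200] * 10)
        t0, t1 = a["time"].iloc[0], a["time"].iloc[-1]
        assert E.intercommunity_distance(a, b, t0, t1) == pytest.approx(
            E.intercommunity_distance(b, a, t0, t1))

    def test_no_temporal_overlap_missing(self):
        own = make_fixes([0, 0], [0, 0], [200] * 2)
        riv = make_fixes([0, 0], [0, 0], [200] * 2, start="2014-02-01 07:00")
        assert np.isnan(E.intercommunity_distance(
            own, riv, own["time"].iloc[0], own["time"].iloc[-1]))


class TestDeparture:
    def test_straight_exit(self):
        xs = [0, 0, 20, 60, 120]
        tr = make_fixes(xs, np.zeros(5), [200] * 5)
        t = E.detect_departure(tr, (0.0, 0.0), tr["time"].iloc[0])
        assert t == tr["time"].iloc[3]

    def test_bounce_back_defers_departure(self):
        xs = [0, 60, 0, 0, 0, 0, 0, 80, 120, 150]
        tr = make_fixes(xs, np.zeros(10), [200] * 10)
        t = E.detect_departure(tr, (0.0, 0.0), tr["time"].iloc[0])
        assert t == tr["time"].iloc[7]

    def test_never_leaves_missing(self):
        tr = make_fixes(np.zeros(6), np.zeros(6), [200] * 6)
        assert E.detect_departure(tr, (0.0, 0.0), tr["time"].iloc[0]) is None


class TestAdvance:
    def _post_track(self, d_series):
        xs = np.asarray(d_series, float)
        return make_fixes(xs, np.zeros(len(xs)), [200] * len(xs))

    def test_advance_retreat_deadband(self):
        rival = (0.0, 0.0)
        adv = self._post_track(np.linspace(1000, 400, 31))
        ret = self._post_track(np.linspace(1000, 1300, 31))
        amb = self._post_track(np.linspace(1000, 980, 31))
        for tr, want in [(adv, "advance"), (ret, "retreat"),
                         (amb, "undetermined")]:
            assert E.classify_advance(tr, tr["time"].iloc[0], rival) == want

    def test_short_track_or_missing_rival_undetermined(self):
        tr = self._post_track([1000, 900, 800])
        assert E.classify_advance(tr, tr["time"].iloc[0], (0, 0)) == "undetermined"
        tr2 = self._post_track(np.linspace(1000, 400, 31))
        assert E.classify_advance(tr2, tr2["time"].iloc[0], None) == "undetermined"

    def test_antisymmetric_under_reflection(self, rng):
        """Reflecting the post-departure path about the departure point swaps
        advance and retreat (whenever the call is determined)."""
        rival = (0.0, 0.0)
        for _ in range(100):
            n = 31
            steps = rng.normal(0, 40, n - 1)
            xs = 1500 + np.r_[0, np.cumsum(steps)]
            tr = self._post_track(xs)
            refl = self._post_track(2 * xs[0] - xs)
            a = E.classify_advance(tr, tr["time"].iloc[0], rival)
            b = E.classify_advance(refl, refl["time"].iloc[0], rival)
            swap = {"advance": "retreat", "retreat": "advance",
                    "undetermined": "undetermined"}
            assert b == swap[a]


class TestDatasets:
    def _visits(self, n=8):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "stopped": rng.integers(0, 2, n).astype(bool),
            "direction": ["toward_border", "toward_center"] * (n // 2),
            "n_hills_before": rng.integers(0, 3, n),
            "n_hills_after": rng.integers(0, 3, n),
            "adult_party_size": rng.integers(2, 9, n),
            "intercomm_dist": rng.uniform(300, 3000, n),
            "intercomm_dist_depart": rng.uniform(300, 3000, n),
            "imbalance": rng.integers(-4, 5, n),
            "advance": ["advance", "retreat"] * (n // 2),
            "rel_center_dist": rng.uniform(0.2, 1.5, n),
            "kernel": rng.integers(50, 99, n),
            "elev": rng.uniform(180, 260, n),
            "time_of_day": rng.uniform(7, 17, n),
            "sex": ["male", "female"] * (n // 2),
            "group": ["west"] * (n // 2) + ["east"] * (n // 2),
            "loc_id": rng.integers(0, 4, n),
            "loc_type": ["hill"] * n,
            "date": ["2014-01-06"] * n,
            "focal_id": ["f1", "f2"] * (n // 2),
            "t_out": pd.date_range("2014-01-06 10:00", periods=n, freq="h"),
        })

    def test_stop_dataset_drops_ambiguous(self):
        v = self._visits()
        v.loc[0, "direction"] = "ambiguous"
        out = E.build_stop_dataset(v)
        assert len(out) == len(v) - 1
        assert set(out["direction_border"]) <= {0, 1}

    def test_empty_inputs_give_headers_only(self):
        empty = E.build_stop_dataset(pd.DataFrame())
        assert len(empty) == 0 and "stopped" in empty.columns
        empty2 = E.build_advance_dataset(pd.DataFrame())
        assert len(empty2) == 0 and "advance" in empty2.columns

    def test_advance_dataset_ln_before_z(self):
        v = self._visits()
        out = E.build_advance_dataset(v)
        assert np.allclose(out["ln_dist"],
                           np.log(v["intercomm_dist_depart"]))
        assert len(out) == len(v)

    def test_advance_subset_chain(self):
        """Advance rows are a subset of stops which are a subset of visits."""
        v = self._visits()
        v.loc[2, "advance"] = "undetermined"
        out = E.build_advance_dataset(v)
        assert len(out) == len(v) - 1
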