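"""Boundary responses, offset scoring, mediation, and event-wise ISFC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from narranet.neural import RoiTimeSeries
from narranet.timecourse import (boundary_timecourses, event_isfc,
                                 isfc_centrality_analysis, mediation_analysis,
                                 offset_response)


def _ts(values, shift=0, **kw):
    return RoiTimeSeries(participant="p0", values=np.asarray(values, float),
                         tr_s=1.0, shift=shift, **kw)


def _three_event_table():
    # middle event [20, 30) is the only interior one
    return pd.DataFrame({
        "movie": ["m"] * 3, "event": [0, 1, 2],
        "onset_s": [5.0, 20.0, 30.0], "offset_s": [20.0, 30.0, 45.0]})


class TestBoundaryTimecourses:
    def test_constant_series_gives_zero_curves_and_zero_t(self):
        events = pd.DataFrame({
            "movie": ["m"] * 4, "event": range(4),
            "onset_s": [5.0, 20.0, 35.0, 50.0],
            "offset_s": [20.0, 35.0, 50.0, 65.0]})
        labels = pd.DataFrame({"movie": "m", "event": range(4),
                               "condition": ["low", "high", "low", "high"]})
        series = {p: _ts(np.full(90, 3.3)) for p in ("p0", "p1", "p2")}
        btc = boundary_timecourses(series, events, labels, align="offset")
        assert np.allclose(btc.mean("high"), 0.0)
        assert np.allclose(btc.mean("low"), 0.0)
        assert np.allclose(btc.t[np.isfinite(btc.t)], 0.0)

    def test_hand_series_window_subtraction(self):
        vals = np.arange(60, dtype=float)
        series = {"p0": _ts(vals), "p1": _ts(vals)}
        events = _three_event_table()
        labels = pd.DataFrame({"movie": "m", "event": [0, 1, 2],
                               "condition": ["low", "high", "low"]})
        # only event 1 (offset TR 30) is interior and labeled high -> the
        # low curve has no interior event, so restrict to the high curve
        btc = boundary_timecourses(series, events, labels, align="offset")
        baseline = (vals[28] + vals[29]) / 2
        expect = vals[30 - 2:30 + 16] - baseline
        assert np.allclose(btc.curves["high"][0], expect)

    def test_baseline_window_is_exactly_zero(self, rng):
        T = 200
        events = pd.DataFrame({
            "movie": ["m"] * 5, "event": range(5),
            "onset_s": [10.0, 40.0, 70.0, 100.0, 130.0],
            "offset_s": [40.0, 70.0, 100.0, 130.0, 160.0]})
        labels = pd.DataFrame({"movie": "m", "event": range(5),
                               "condition": ["low", "high", "low", "high", "low"]})
        series = {p: _ts(rng.standard_normal(T)) for p in ("p0", "p1")}
        btc = boundary_timecourses(series, events, labels, align="offset")
        for cond in ("high", "low"):
            base = btc.curves[cond][:, :2]  # offsets -2, -1
            assert np.allclose(base.mean(axis=1), 0.0, atol=1e-12)

    def test_planted_boxcar_for_high_events_recovered(self, rng):
        T = 400
        onsets = np.arange(10, 370, 45, dtype=float)
        events = pd.DataFrame({
            "movie": "m", "event": range(len(onsets)),
            "onset_s": onsets, "offset_s": onsets + 30.0})
        conds = ["high" if i % 2 else "low" for i in range(len(onsets))]
        labels = pd.DataFrame({"movie": "m", "event": range(len(onsets)),
                               "condition": conds})
        amp = 2.0
        series = {}
        for p in ("p0", "p1", "p2", "p3"):
            v = 0.1 * rng.standard_normal(T)
            for i, on in enumerate(onsets):
                if conds[i] == "high" and 0 < i < len(onsets) - 1:
                    off = int(on) + 30
                    v[off + 5: off + 12] += amp
                # first/last excluded anyway
            series[p] = _ts(v)
        btc = boundary_timecourses(series, events, labels, align="offset")
        window = (btc.offsets >= 6) & (btc.offsets <= 10)
        diff = btc.mean("high") - btc.mean("low")
        assert np.all(diff[window] > amp * 0.8)
        assert np.all(btc.q[window] < 0.05)

    def test_window_crossing_run_boundary_excluded(self):
        events = _three_event_table()
        labels = pd.DataFrame({"movie": "m", "event": [0, 1, 2],
                               "condition": ["low", "high", "low"]})
        # run ends at TR 40: event-1 offset window (-2..15 around TR 30) overruns
        series = {"p0": _ts(np.ones(40)), "p1": _ts(np.ones(40))}
        with pytest.warns(UserWarning, match="crosses"):
            btc = boundary_timecourses(series, events, labels, align="offset")
        assert np.isnan(btc.curves["high"]).all()


class TestOffsetResponse:
    def test_boxcar_amplitude_recovered(self):
        vals = np.zeros(60)
        off = 20
        vals[off + 10: off + 14] = 2.0
        events = pd.DataFrame({"movie": ["m"], "event": [0],
                               "onset_s": [5.0], "offset_s": [float(off)]})
        resp = offset_response(_ts(vals), events)
        assert resp[("m", 0)] == pytest.approx(2.0)

    def test_constant_series_gives_zero(self):
        events = pd.DataFrame({"movie": ["m"], "event": [0],
                               "onset_s": [5.0], "offset_s": [20.0]})
        resp = offset_response(_ts(np.full(60, 7.0)), events)
        assert resp[("m", 0)] == pytest.approx(0.0)

    def test_index_arithmetic_oracle(self, rng):
        vals = rng.standard_normal(80)
        off = 31
        events = pd.DataFrame({"movie": ["m"], "event": [0],
                               "onset_s": [10.0], "offset_s": [float(off)]})
        resp = offset_response(_ts(vals), events)
        expect = vals[off + 10: off + 14].mean() - vals[off - 2: off].mean()
        assert resp[("m", 0)] == pytest.approx(expect, abs=1e-12)

    def test_shift_applies_to_the_boundary(self, rng):
        vals = rng.standard_normal(80)
        events = pd.DataFrame({"movie": ["m"], "event": [0],
                               "onset_s": [10.0], "offset_s": [30.0]})
        resp = offset_response(_ts(vals, shift=3), events)
        b = 33
        expect = vals[b + 10: b + 14].mean() - vals[b - 2: b].mean()
        assert resp[("m", 0)] == pytest.approx(expect, abs=1e-12)

    def test_out_of_run_window_gives_missing(self):
        events = pd.DataFrame({"movie": ["m"], "event": [0],
                               "onset_s": [5.0], "offset_s": [20.0]})
        with pytest.warns(UserWarning, match="outside run"):
            resp = offset_response(_ts(np.ones(25)), events)
        assert np.isnan(resp[("m", 0)])


class TestMediation:
    def test_linear_vanishing_noise_acme_equals_a_times_b(self, rng):
        # with an exactly deterministic mediator the outcome model is
        # collinear, so take the vanishing-noise limit
        n_p, n_e = 10, 20
        part = np.repeat([f"p{i}" for i in range(n_p)], n_e)
        x = rng.standard_normal(n_p * n_e)
        a, b, direct = 0.3, 0.5, 0.2
        mediator = a * x + 1e-6 * rng.standard_normal(x.size)
        outcome = direct * x + b * mediator
        data = pd.DataFrame({"participant": part, "centrality": x,
                             "mediator": mediator, "outcome": outcome})
        res = mediation_analysis(data, n_sims=200, seed=0,
                                 outcome_family="linear")
        assert res.acme == pytest.approx(a * b, abs=2e-3)
        assert res.direct_effect == pytest.approx(direct, abs=1e-4)
        assert res.total_effect == pytest.approx(a * b + direct, abs=1e-4)

    def test_positive_path_detected_logistic(self, rng):
        n_p, n_e = 40, 60
        part = np.repeat([f"p{i}" for i in range(n_p)], n_e)
        x = rng.standard_normal(n_p * n_e)
        mediator = 0.6 * x + 0.3 * rng.standard_normal(x.size)
        eta = 0.2 + 0.2 * x + 0.8 * mediator
        outcome = (rng.random(x.size) < 1 / (1 + np.exp(-eta))).astype(int)
        data = pd.DataFrame({"participant": part, "centrality": x,
                             "mediator": mediator, "outcome": outcome})
        res = mediation_analysis(data, n_sims=300, seed=1)
        assert res.acme > 0
        assert res.acme_ci[0] > 0
        assert res.p_value < 0.05
        assert res.scale == "probability"

    def test_incomplete_cases_rejected(self):
        data = pd.DataFrame({"participant": ["a", "a", "b", "b"],
                             "centrality": [1.0, -1.0, 0.5, -0.5],
                             "mediator": [0.1, np.nan, 0.2, 0.0],
                             "outcome": [1, 0, 1, 0]})
        with pytest.raises(ValueError, match="complete"):
            mediation_analysis(data)


class TestEventIsfc:
    @staticmethod
    def _events(n_trs=20):
        return pd.DataFrame({"movie": ["m"], "event": [0],
                             "onset_s": [0.0], "offset_s": [float(n_trs)]})

    def test_identical_sinusoid_gives_one(self):
        t = np.arange(20, dtype=float)
        sig = np.sin(t)
        ts_a = {f"p{i}": _ts(sig) for i in range(3)}
        ts_b = {f"p{i}": _ts(sig) for i in range(3)}
        out = event_isfc(ts_a, ts_b, self._events(), min_duration_s=10)
        assert out["isfc"].iloc[0] == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        n, T = 3, 15
        A = rng.standard_normal((n, T))
        B = rng.standard_normal((n, T))
        ts_a = {f"p{i}": _ts(A[i]) for i in range(n)}
        ts_b = {f"p{i}": _ts(B[i]) for i in range(n)}
        out = event_isfc(ts_a, ts_b, self._events(T), min_duration_s=10)
        d1 = np.mean([np.corrcoef(A[s], np.delete(B, s, 0).mean(0))[0, 1]
                      for s in range(n)])
        d2 = np.mean([np.corrcoef(B[s], np.delete(A, s, 0).mean(0))[0, 1]
                      for s in range(n)])
        assert out["isfc"].iloc[0] == pytest.approx((d1 + d2) / 2, abs=1e-12)

    def test_independent_noise_gives_near_zero_mean(self, rng):
        n, T, n_events, dur = 4, 2000, 100, 20
        A = rng.standard_normal((n, T))
        B = rng.standard_normal((n, T))
        ts_a = {f"p{i}": _ts(A[i]) for i in range(n)}
        ts_b = {f"p{i}": _ts(B[i]) for i in range(n)}
        onsets = np.arange(n_events) * dur
        events = pd.DataFrame({"movie": "m", "event": range(n_events),
                               "onset_s": onsets.astype(float),
                               "offset_s": (onsets + dur).astype(float)})
        out = event_isfc(ts_a, ts_b, events, min_duration_s=15.0)
        assert len(out) == n_events
        assert abs(out["isfc"].mean()) < 0.05

    def test_symmetric_in_regions(self, rng):
        n, T = 4, 18
        A = rng.standard_normal((n, T))
        B = rng.standard_normal((n, T))
        ts_a = {f"p{i}": _ts(A[i]) for i in range(n)}
        ts_b = {f"p{i}": _ts(B[i]) for i in range(n)}
        o1 = event_isfc(ts_a, ts_b, self._events(T), min_duration_s=10)
        o2 = event_isfc(ts_b, ts_a, self._events(T), min_duration_s=10)
        assert o1["isfc"].iloc[0] == pytest.approx(o2["isfc"].iloc[0], abs=1e-12)

    def test_duration_filter_and_error(self, rng):
        ts_a = {f"p{i}": _ts(rng.standard_normal(30)) for i in range(3)}
        ts_b = {f"p{i}": _ts(rng.standard_normal(30)) for i in range(3)}
        events = pd.DataFrame({"movie": ["m", "m"], "event": [0, 1],
                               "onset_s": [0.0, 20.0], "offset_s": [20.0, 28.0]})
        out = event_isfc(ts_a, ts_b, events, min_duration_s=15.0)
        assert list(out["event"]) == [0]
        with pytest.raises(ValueError, match="22.5"):
            event_isfc(ts_a, ts_b, events.iloc[1:], min_duration_s=22.5)


class TestIsfcCentrality:
    @staticmethod
    def _cent(z):
        return pd.DataFrame({"movie": "m", "event": range(len(z)),
                             "z_centrality": z})

    def test_perfect_coupling_vs_noise(self, rng):
        z = rng.standard_normal(26)
        isfc1 = pd.DataFrame({"movie": "m", "event": range(26), "isfc": z})
        isfc2 = pd.DataFrame({"movie": "m", "event": range(26),
                              "isfc": rng.standard_normal(26)})
        res = isfc_centrality_analysis(isfc1, isfc2, self._cent(z))
        assert res["r_pair1"] == pytest.approx(1.0)
        assert res["difference_ci"][0] > 0

    def test_threshold_sweep_interface(self, rng):
        n, T = 4, 40
        A = rng.standard_normal((n, T))
        B = rng.standard_normal((n, T))
        ts_a = {f"p{i}": _ts(A[i]) for i in range(n)}
        ts_b = {f"p{i}": _ts(B[i]) for i in range(n)}
        events = pd.DataFrame({"movie": "m", "event": [0, 1],
                               "onset_s": [0.0, 22.0], "offset_s": [20.0, 38.0]})
        rs = {thr: len(event_isfc(ts_a, ts_b, events, min_duration_s=thr))
              for thr in (10.0, 17.0)}
        assert rs[10.0] == 2 and rs[17.0] == 1

    def test_mismatched_event_sets_rejected(self, rng):
        isfc1 = pd.DataFrame({"movie": "m", "event": [0, 1, 2, 3],
                              "isfc": rng.standard_normal(4)})
        isfc2 = isfc1.copy()
        isfc2["event"] = [0, 1, 2, 4]
        with pytest.raises(ValueError, match="same events"):
            isfc_centrality_analysis(isfc1, isfc2,
                                     self._cent(rng.standard_normal(5)))
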