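"""Event-pattern extraction, pISC, randomization inference, and RSA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from narranet.embedding import SimilarityMatrix
from narranet.neural import (EventPatternSet, RoiTimeSeries,
                             cross_event_similarity, event_activation_regression,
                             event_pisc, extract_event_patterns,
                             highlow_pisc_test, pisc_randomization_map,
                             rsa_test)


def _patterns(data, phase="movie"):
    data = np.asarray(data, dtype=float)
    n, e, _ = data.shape
    events = pd.DataFrame({"movie": ["m"] * e, "event": range(e)})
    return EventPatternSet(data=data, participants=[f"p{i}" for i in range(n)],
                           events=events, phase=phase)


def _pisc_bruteforce(data):
    """Triple-loop oracle straight from the definition."""
    n, e, f = data.shape
    out = np.full((n, e), np.nan)
    for s in range(n):
        for ev in range(e):
            if np.isnan(data[s, ev]).any():
                continue
            cs = []
            for t in range(n):
                if t == s or np.isnan(data[t, ev]).any():
                    continue
                cs.append(np.corrcoef(data[s, ev], data[t, ev])[0, 1])
            if cs:
                out[s, ev] = np.mean(cs)
    return out


class TestExtractEventPatterns:
    @staticmethod
    def _series(values, **kw):
        return RoiTimeSeries(participant="p0", values=np.asarray(values, float),
                             tr_s=1.0, shift=0, **kw)

    def test_constant_series_gives_constant_patterns(self):
        ts = {"p0": self._series(np.full((30, 3), 4.2))}
        ev = pd.DataFrame({"movie": ["m", "m"], "event": [0, 1],
                           "onset_s": [2.0, 10.0], "offset_s": [6.0, 14.0]})
        pats = extract_event_patterns(ts, ev, exclude_first_event=False)
        assert np.allclose(pats.data, 4.2)

    def test_event_window_mean_arithmetic(self):
        vals = np.zeros(20)
        vals[4:8] = [1, 2, 3, 4]
        ts = {"p0": self._series(vals[:, None])}
        ev = pd.DataFrame({"movie": ["m"], "event": [0],
                           "onset_s": [4.0], "offset_s": [8.0]})
        pats = extract_event_patterns(ts, ev, exclude_first_event=False)
        assert pats.data[0, 0, 0] == pytest.approx(2.5)

    def test_hemodynamic_shift_moves_the_window(self):
        vals = np.zeros(20)
        vals[7:11] = 1.0  # shifted window of event [4, 8) at shift 3
        ts = {"p0": RoiTimeSeries("p0", vals[:, None], tr_s=1.0, shift=3)}
        ev = pd.DataFrame({"movie": ["m"], "event": [0],
                           "onset_s": [4.0], "offset_s": [8.0]})
        pats = extract_event_patterns(ts, ev, exclude_first_event=False)
        assert pats.data[0, 0, 0] == pytest.approx(1.0)

    def test_matches_naive_slicing_oracle(self, rng):
        T, F = 60, 4
        ts = {p: self._series(rng.standard_normal((T, F))) for p in ("p0", "p1")}
        bounds = np.sort(rng.choice(np.arange(1, T - 1), size=6, replace=False))
        rows = []
        for e in range(3):
            rows.append({"movie": "m", "event": e,
                         "onset_s": float(bounds[2 * e]),
                         "offset_s": float(bounds[2 * e + 1])})
        ev = pd.DataFrame(rows)
        pats = extract_event_patterns(ts, ev, exclude_first_event=False)
        for pi, p in enumerate(sorted(ts)):
            for e in range(3):
                lo, hi = int(bounds[2 * e]), int(bounds[2 * e + 1])
                expect = ts[p].values[lo:hi].mean(axis=0)
                assert np.allclose(pats.data[pi, e], expect)

    def test_first_event_excluded_in_movie_phase(self):
        ts = {"p0": self._series(np.ones((30, 2)))}
        ev = pd.DataFrame({"movie": ["m", "m"], "event": [0, 1],
                           "onset_s": [0.0, 10.0], "offset_s": [5.0, 15.0]})
        pats = extract_event_patterns(ts, ev, phase="movie")
        assert np.isnan(pats.data[0, 0]).all()
        assert not np.isnan(pats.data[0, 1]).any()

    def test_recall_phase_missing_iff_not_recalled(self):
        ts = {"p0": self._series(np.ones((30, 2)))}
        ev = pd.DataFrame({"movie": ["m", "m"], "event": [0, 1],
                           "onset_s": [0.0, 10.0], "offset_s": [5.0, 15.0]})
        pats = extract_event_patterns(ts, ev, phase="recall",
                                      recalled={"p0": {("m", 1)}})
        assert np.isnan(pats.data[0, 0]).all()
        assert not np.isnan(pats.data[0, 1]).any()

    def test_shift_past_run_end_rejected(self):
        ts = {"p0": RoiTimeSeries("p0", np.ones((10, 2)), tr_s=1.0, shift=3)}
        ev = pd.DataFrame({"movie": ["m"], "event": [0],
                           "onset_s": [5.0], "offset_s": [9.0]})
        with pytest.raises(ValueError, match="run"):
            extract_event_patterns(ts, ev, exclude_first_event=False)


class TestEventPisc:
    def test_identical_patterns_give_one(self, rng):
        base = rng.standard_normal((1, 3, 5))
        data = np.repeat(base, 4, axis=0)
        out = event_pisc(_patterns(data))
        assert np.allclose(out["pisc"], 1.0)
        assert (out["n_partners"] == 3).all()

    def test_matches_triple_loop_oracle(self, rng):
        data = rng.standard_normal((3, 4, 6))
        out = event_pisc(_patterns(data))
        oracle = _pisc_bruteforce(data)
        for _, row in out.iterrows():
            s = int(row["participant"][1:])
            assert row["pisc"] == pytest.approx(oracle[s, row["event"]], abs=1e-12)

    def test_min_participants_threshold_drops_events(self, rng):
        data = rng.standard_normal((6, 2, 5))
        data[2:, 0] = np.nan  # event 0 present for only 2 participants
        out = event_pisc(_patterns(data, phase="recall"), min_participants=5)
        assert set(out["event"]) == {1}
        out_all = event_pisc(_patterns(data, phase="recall"), min_participants=2)
        assert set(out_all["event"]) == {0, 1}

    def test_pearson_invariance_to_shift_and_scale(self, rng):
        data = rng.standard_normal((4, 3, 8))
        out1 = event_pisc(_patterns(data))
        data2 = data.copy()
        data2[1] = 3.5 * data2[1] + 2.0  # one participant rescaled/shifted
        out2 = event_pisc(_patterns(data2))
        assert np.allclose(out1["pisc"], out2["pisc"], atol=1e-12)

    def test_single_feature_rejected(self, rng):
        with pytest.raises(ValueError, match="2 features"):
            event_pisc(_patterns(rng.standard_normal((3, 2, 1))))

    def test_constant_pattern_skipped_with_warning(self, rng):
        data = rng.standard_normal((3, 2, 5))
        data[0, 0] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            out = event_pisc(_patterns(data))
        ev0 = out[out["event"] == 0]
        assert set(ev0["participant"]) == {"p1", "p2"}


class TestPiscRandomization:
    def test_strong_signal_hits_p_floor(self, rng):
        template = rng.standard_normal((1, 6, 10))
        data = np.repeat(template, 5, axis=0) + 0.05 * rng.standard_normal((5, 6, 10))
        obs, res = pisc_randomization_map(_patterns(data), n_perm=200, seed=0)
        assert obs > 0.9
        assert res.p_value == pytest.approx(1 / 201)

    def test_sampled_p_matches_exhaustive_enumeration(self, rng):
        data = rng.standard_normal((3, 4, 5))
        pats = _patterns(data)
        U = data - data.mean(axis=2, keepdims=True)
        U /= np.linalg.norm(U, axis=2, keepdims=True)

        def stat(perm):
            vals = []
            for s in range(3):
                per_event = []
                for e in range(4):
                    cs = [U[s, e] @ U[t, perm[e]] for t in range(3) if t != s]
                    per_event.append(np.mean(cs))
                vals.append(np.mean(per_event))
            return np.mean(vals)

        observed = stat(list(range(4)))
        exhaustive = [stat(list(p)) for p in itertools.permutations(range(4))]
        p_exh = np.mean([v >= observed for v in exhaustive])
        obs, res = pisc_randomization_map(pats, n_perm=500, seed=3)
        assert obs == pytest.approx(observed, abs=1e-10)
        # sampled add-one p within sampling error of the exhaustive proportion
        se = np.sqrt(p_exh * (1 - p_exh) / 500)
        assert abs(res.p_value - p_exh) < 4 * se + 2 / 501

    def test_within_movie_scope_requires_multi_event_movies(self, rng):
        data = rng.standard_normal((3, 3, 4))
        events = pd.DataFrame({"movie": ["a", "a", "b"], "event": [0, 1, 0]})
        pats = EventPatternSet(data=data, participants=["p0", "p1", "p2"],
                               events=events, phase="movie")
        with pytest.raises(ValueError, match="<2 events"):
            pisc_randomization_map(pats, n_perm=10, shuffle_scope="within-movie")


class TestHighLowPiscTest:
    def test_hand_built_two_movie_difference(self):
        pisc = pd.DataFrame({
            "participant": ["p0"] * 4 + ["p1"] * 4,
            "movie": ["a", "a", "b", "b"] * 2,
            "event": [0, 1, 0, 1] * 2,
            "pisc": [0.4, 0.1, 0.6, 0.2, 0.3, 0.0, 0.5, 0.3],
            "n_partners": 1,
        })
        labels = pd.DataFrame({"movie": ["a", "a", "b", "b"],
                               "event": [0, 1, 0, 1],
                               "condition": ["high", "low", "high", "low"]})
        res = highlow_pisc_test(pisc, labels, n_perm=50, seed=0)
        # p0: high (0.4+0.6)/2=0.5, low 0.15; p1: high 0.4, low 0.15
        expect = np.mean([0.5 - 0.15, 0.4 - 0.15])
        assert res["difference"] == pytest.approx(expect, abs=1e-12)

    def test_movie_without_both_conditions_excluded(self):
        pisc = pd.DataFrame({
            "participant": ["p0"] * 4, "movie": ["a", "a", "b", "b"],
            "event": [0, 1, 0, 1], "pisc": [0.1, 0.2, 0.3, 0.4], "n_partners": 1})
        labels = pd.DataFrame({"movie": ["a", "a", "b", "b"],
                               "event": [0, 1, 0, 1],
                               "condition": ["high", "low", "high", "high"]})
        with pytest.warns(UserWarning, match="lacks"):
            res = highlow_piscs = highlow_pisc_test(pisc, labels, n_perm=20, seed=0)
        assert res["difference"] == pytest.approx(0.1 - 0.2)


class TestCrossEventSimilarity:
    def test_shared_orthonormal_patterns_give_identity(self):
        eye = np.eye(4)
        # 4 events, patterns = orthonormal rows, identical across participants
        data = np.stack([eye, eye, eye])  # (3, 4, 4)
        # center-corrected correlation of orthonormal one-hot rows is not 1;
        # use high-dim nearly-orthogonal patterns instead
        rng = np.random.default_rng(0)
        base = rng.standard_normal((4, 200))
        data = np.stack([base] * 3)
        mats = cross_event_similarity(_patterns(data))
        m = mats[("p0", "m")]
        assert np.allclose(np.diag(m), 1.0)
        assert np.max(np.abs(m - np.diag(np.diag(m)))) < 1.0
        off = m[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.3

    def test_symmetry_exact_after_symmetrization(self, rng):
        data = rng.standard_normal((3, 5, 6))
        mats = cross_event_similarity(_patterns(data))
        for m in mats.values():
            assert np.max(np.abs(m - m.T)) == 0.0

    def test_matches_quadruple_loop_oracle(self, rng):
        data = rng.standard_normal((3, 4, 6))
        mats = cross_event_similarity(_patterns(data))
        n, e, _ = data.shape
        for s in range(n):
            expect = np.zeros((e, e))
            for t in range(n):
                if t == s:
                    continue
                M = np.zeros((e, e))
                for a in range(e):
                    for b in range(e):
                        M[a, b] = np.corrcoef(data[s, a], data[t, b])[0, 1]
                expect += (M + M.T) / 2
            expect /= n - 1
            assert np.allclose(mats[(f"p{s}", "m")], expect, atol=1e-12)

    def test_movie_with_two_events_rejected(self, rng):
        data = rng.standard_normal((3, 2, 5))
        with pytest.raises(ValueError, match="fewer than 3"):
            cross_event_similarity(_patterns(data))


class TestRsaTest:
    def test_neural_equal_to_reference_gives_r_one(self, rng):
        ref = rng.standard_normal((5, 5))
        ref = (ref + ref.T) / 2
        np.fill_diagonal(ref, 1.0)
        ref = np.clip(ref, -1, 1)
        neural = {("p0", "m"): ref.copy(), ("p1", "m"): ref.copy()}
        reference = {"m": SimilarityMatrix("m", ref)}
        r, res = rsa_test(neural, reference, n_perm=100, seed=0)
        assert r == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_matches_flatten_and_correlate_oracle(self, rng):
        nm = rng.standard_normal((4, 4))
        nm = (nm + nm.T) / 2
        ref = rng.standard_normal((4, 4))
        ref = (ref + ref.T) / 2
        np.fill_diagonal(ref, 1.0)
        ref = np.clip(ref, -1, 1)
        r, _ = rsa_test({("p0", "m"): nm}, {"m": SimilarityMatrix("m", ref)},
                        n_perm=20, seed=0)
        il = np.tril_indices(4, k=-1)
        expect = np.corrcoef(nm[il], ref[il])[0, 1]
        assert r == pytest.approx(expect, abs=1e-12)

    def test_missing_cells_dropped_pairwise(self, rng):
        nm = rng.standard_normal((4, 4))
        nm = (nm + nm.T) / 2
        nm[3, 0] = nm[0, 3] = np.nan
        ref = rng.standard_normal((4, 4))
        ref = np.clip((ref + ref.T) / 2, -1, 1)
        np.fill_diagonal(ref, 1.0)
        r, _ = rsa_test({("p0", "m"): nm}, {"m": SimilarityMatrix("m", ref)},
                        n_perm=20, seed=0)
        assert np.isfinite(r)


class TestEventActivationRegression:
    @staticmethod
    def _cent(movies, z):
        rows = []
        for m in movies:
            for e, zv in enumerate(z[m]):
                rows.append({"movie": m, "event": e, "z_centrality": zv})
        return pd.DataFrame(rows)

    def test_noiseless_linear_recovers_slope(self):
        movies = ["a", "b"]
        z = {"a": [1.0, 0.0, -1.0], "b": [0.5, -0.5, 0.0]}
        offsets = {"a": 10.0, "b": -5.0}
        rows = []
        for p in ("p0", "p1"):
            for m in movies:
                for e, zv in enumerate(z[m]):
                    rows.append({"participant": p, "movie": m, "event": e,
                                 "activation": 2.0 * zv + offsets[m]})
        res = event_activation_regression(pd.DataFrame(rows), self._cent(movies, z))
        assert all(b == pytest.approx(2.0, abs=1e-10) for b in res["betas"].values())

    def test_matches_two_stage_least_squares_oracle(self, rng):
        movies = ["a", "b"]
        z = {m: list(rng.standard_normal(3)) for m in movies}
        rows = []
        for m in movies:
            for e, zv in enumerate(z[m]):
                rows.append({"participant": "p0", "movie": m, "event": e,
                             "activation": float(rng.standard_normal())})
        df = pd.DataFrame(rows)
        # need a second participant for the group t-test
        df2 = df.copy()
        df2["participant"] = "p1"
        df2["activation"] = rng.standard_normal(len(df2))
        res = event_activation_regression(pd.concat([df, df2]), self._cent(movies, z))
        # oracle for p0: demean within movie, then OLS slope
        y = df["activation"] - df.groupby("movie")["activation"].transform("mean")
        x = np.concatenate([z["a"], z["b"]])
        slope = np.sum((x - x.mean()) * y) / np.sum((x - x.mean()) ** 2)
        assert res["betas"]["p0"] == pytest.approx(slope, abs=1e-10)

    def test_single_movie_rejected(self, rng):
        df = pd.DataFrame({"participant": "p0", "movie": "a", "event": range(4),
                           "activation": rng.standard_normal(4)})
        with pytest.raises(ValueError, match="movie"):
            event_activation_regression(df, self._cent(["a"], {"a": [1., 0., -1., 2.]}))
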