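"""Boundary-locked BOLD time courses, mediation, and event-wise ISFC.

Hippocampal encoding signals are probed by extracting baseline-corrected
BOLD time courses around event onsets/offsets, scoring each event's
post-offset response, testing whether that response mediates the effect
of centrality on recall, and measuring event-wise intersubject functional
connectivity (ISFC) between a hippocampal and a cortical region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_stats import bh_fdr, compare_dependent_correlations, fit_mixed_model
from .neural import RoiTimeSeries, _event_trs

__all__ = [
    "BoundaryTimecourse",
    "MediationResult",
    "boundary_timecourses",
    "offset_response",
    "mediation_analysis",
    "event_isfc",
    "isfc_centrality_analysis",
]

BOUNDARY_WINDOW = (-2, 15)  # TR offsets relative to the boundary, inclusive
BASELINE_TRS = 2            # TRs immediately preceding the boundary
OFFSET_RESPONSE_WINDOW = (10, 13)  # TRs after the event offset, inclusive
DEFAULT_MIN_EVENT_DURATION_S = 22.5


@dataclass
class BoundaryTimecourse:
    """Participant-mean boundary-locked responses per condition.

    ``curves[cond]`` is a participants x time-offsets matrix; time offsets
    run over ``offsets`` (default -2..15 TRs). Each event's time course
    was baseline-corrected by the mean of the two pre-boundary TRs, so the
    baseline window averages 0 per event by construction.
    """

    offsets: np.ndarray
    curves: dict[str, np.ndarray]
    align: str  # onset | offset
    t: np.ndarray | None = None
    p: np.ndarray | None = None
    q: np.ndarray | None = None

    def mean(self, cond: str) -> np.ndarray:
        return np.nanmean(self.curves[cond], axis=0)


@dataclass
class MediationResult:
    """Average causal mediation effect (ACME) and companions."""

    acme: float
    acme_ci: tuple[float, float]
    direct_effect: float
    total_effect: float
    n_sims: int
    p_value: float
    scale: str  # 'probability' for a logistic outcome, 'response' for linear

    def __post_init__(self):
        lo, hi = self.acme_ci
        if not (lo <= self.acme <= hi):
            raise ValueError("ACME must lie inside its CI")


def _boundary_tr(time_s: float, tr_s: float, shift: int) -> int:
    """BOLD TR index of a boundary: first TR starting at/after the boundary,
    plus the hemodynamic shift."""
    return int(np.ceil(time_s / tr_s - 1e-9)) + shift


def boundary_timecourses(
    series: dict[str, RoiTimeSeries],
    events: pd.DataFrame,
    labels: pd.DataFrame,
    align: str = "offset",
    window: tuple[int, int] = BOUNDARY_WINDOW,
    fdr_q: float = 0.05,
) -> BoundaryTimecourse:
    """Baseline-corrected BOLD around event boundaries, high vs low.

    Per event (first and last events of each movie excluded), the region-
    mean signal at TR offsets ``window[0]..window[1]`` around the aligned
    boundary is extracted and corrected by subtracting the mean of the two
    immediately preceding TRs. Curves are averaged events -> movies ->
    participants within each condition; each time point gets a two-tailed
    paired t-test (high vs low) with BH-FDR across time points. Events
    whose window crosses a run boundary are excluded with a warning.
    """
    if align not in ("onset", "offset"):
        raise ValueError(f"align must be 'onset' or 'offset', got '{align}'")
    offs = np.arange(window[0], window[1] + 1)
    lab = labels.set_index(["movie", "event"])["condition"]
    ev = events.sort_values(["movie", "event"])
    interior = []
    for movie, sub in ev.groupby("movie", sort=False):
        emin, emax = sub["event"].min(), sub["event"].max()
        for _, row in sub.iterrows():
            if emin < row["event"] < emax:
                interior.append(row)
    participants = sorted(series)
    curves = {c: np.full((len(participants), len(offs)), np.nan)
              for c in ("high", "low")}
    for pi, p in enumerate(participants):
        ts = series[p]
        vals = ts.values
        if vals.ndim != 1:
            raise ValueError("boundary time courses need a 1-D region-mean series")
        per_movie: dict[str, dict[str, list[np.ndarray]]] = {}
        for row in interior:
            cond = lab.get((row["movie"], row["event"]))
            if cond not in ("high", "low"):
                continue
            t0 = row["onset_s"] if align == "onset" else row["offset_s"]
            b = _boundary_tr(t0, ts.tr_s, ts.shift)
            idx = b + offs
            try:
                run = ts.run_of(b)
            except ValueError:
                warnings.warn(f"event ({row['movie']},{row['event']}): boundary outside "
                              "runs; excluded")
                continue
            if idx[0] < run[0] or idx[-1] >= run[1]:
                warnings.warn(f"event ({row['movie']},{row['event']}): window crosses "
                              "run boundary; excluded")
                continue
            baseline = vals[b - BASELINE_TRS:b].mean()
            curve = vals[idx] - baseline
            per_movie.setdefault(row["movie"], {}).setdefault(cond, []).append(curve)
        for cond in ("high", "low"):
            movie_means = [np.mean(d[cond], axis=0)
                           for d in per_movie.values() if cond in d]
            if movie_means:
                curves[cond][pi] = np.mean(movie_means, axis=0)
    t_vals = np.full(len(offs), np.nan)
    p_vals = np.full(len(offs), np.nan)
    hi, lo = curves["high"], curves["low"]
    ok = ~np.isnan(hi).any(axis=1) & ~np.isnan(lo).any(axis=1)
    if ok.sum() >= 2:
        for k in range(len(offs)):
            d = hi[ok, k] - lo[ok, k]
            if np.std(d, ddof=1) == 0:
                t_vals[k], p_vals[k] = 0.0, 1.0
            else:
                t_vals[k], p_vals[k] = stats.ttest_rel(hi[ok, k], lo[ok, k])
    finite = np.isfinite(p_vals)
    q_vals = np.full(len(offs), np.nan)
    if finite.any():
        _, q_vals[finite] = bh_fdr(p_vals[finite], q=fdr_q)
    return BoundaryTimecourse(offsets=offs, curves=curves, align=align,
                              t=t_vals, p=p_vals, q=q_vals)


def offset_response(ts: RoiTimeSeries, events: pd.DataFrame) -> pd.Series:
    """Post-offset hippocampal response per event for one participant.

    Mean signal at 10-13 TRs after the event offset minus the mean of the
    two TRs immediately preceding the offset. Windows falling outside the
    run yield NaN with a warning.
    """
    vals = ts.values
    if vals.ndim != 1:
        raise ValueError("offset responses need a 1-D region-mean series")
    out = {}
    for _, row in events.iterrows():
        b = _boundary_tr(row["offset_s"], ts.tr_s, ts.shift)
        lo, hi = b + OFFSET_RESPONSE_WINDOW[0], b + OFFSET_RESPONSE_WINDOW[1]
        try:
            run = ts.run_of(b)
        except ValueError:
            run = None
        if run is None or b - BASELINE_TRS < run[0] or hi >= run[1]:
            warnings.warn(f"event ({row['movie']},{row['event']}): offset window "
                          "outside run; response missing")
            out[(row["movie"], int(row["event"]))] = np.nan
            continue
        baseline = vals[b - BASELINE_TRS:b].mean()
        out[(row["movie"], int(row["event"]))] = float(vals[lo:hi + 1].mean() - baseline)
    s = pd.Series(out, name="offset_response")
    s.index.names = ["movie", "event"]
    return s


def mediation_analysis(
    data: pd.DataFrame,
    n_sims: int = 1000,
    seed: int | None = None,
    outcome_family: str = "logistic",
    treat: float = 1.0,
    control: float = 0.0,
) -> MediationResult:
    """Does the hippocampal offset response mediate centrality -> recall?

    ``data`` needs columns participant, centrality, mediator, outcome
    (complete cases only). Three mixed models with participant random
    intercepts are fitted: outcome ~ centrality (total effect, logistic or
    linear per ``outcome_family``); mediator ~ centrality (linear); and
    outcome ~ centrality + mediator (direct effect). The average causal
    mediation effect (ACME) is computed by quasi-Bayesian Monte Carlo:
    coefficient vectors are drawn from the asymptotic normal of each
    model's estimates, expected potential outcomes are formed per
    observation (conditional on the estimated participant intercepts) for
    centrality at ``treat`` vs ``control``, and the simulated indirect
    effects are averaged. The CI is the percentile 95% interval over
    simulations. For a logistic outcome the ACME is on the outcome-
    probability scale.
    """
    for c in ("participant", "centrality", "mediator", "outcome"):
        if c not in data.columns:
            raise ValueError(f"data missing column '{c}'")
    if data[["centrality", "mediator", "outcome"]].isna().any().any():
        raise ValueError("mediation requires complete cases")
    fam = outcome_family
    if fam not in ("logistic", "linear"):
        raise ValueError("outcome_family must be 'logistic' or 'linear'")
    rng = np.random.default_rng(seed)
    groups = {"participant": data["participant"]}

    total_fit = fit_mixed_model(data["outcome"], data[["centrality"]], groups,
                                family=fam)
    med_fit = fit_mixed_model(data["mediator"], data[["centrality"]], groups,
                              family="linear")
    out_fit = fit_mixed_model(data["outcome"], data[["centrality", "mediator"]],
                              groups, family=fam)
    for name, fit in (("total", total_fit), ("mediator", med_fit),
                      ("outcome", out_fit)):
        if not fit.converged:
            raise RuntimeError(f"mediation sub-model '{name}' did not converge: "
                               f"{fit.message}")

    def draws(fit, n):
        mean = np.array([fit.coefficients[k] for k in fit.fit.names])
        cov = fit.fit.vcov_beta
        if cov is None or not np.isfinite(cov).all():
            return np.tile(mean, (n, 1))
        # guard: symmetric PSD projection for near-singular (e.g. noiseless) fits
        cov = 0.5 * (cov + cov.T)
        w, V = np.linalg.eigh(cov)
        cov = (V * np.clip(w, 0.0, None)) @ V.T
        return rng.multivariate_normal(mean, cov, size=n, method="svd")

    a_draw = draws(med_fit, n_sims)    # [a0, a1]
    y_draw = draws(out_fit, n_sims)    # [c0, c_cent, c_med]
    # participant intercepts (estimated, conditional)
    part_codes = pd.Categorical(data["participant"])
    u_m = med_fit.fit.u["participant"][part_codes.codes]
    u_y = out_fit.fit.u["participant"][part_codes.codes]

    def link(x):
        if fam == "logistic":
            from scipy.special import expit
            return expit(x)
        return x

    acme_sims = np.empty(n_sims)
    for j in range(n_sims):
        a0, a1 = a_draw[j]
        c0, c_cent, c_med = y_draw[j]
        m_t = a0 + a1 * treat + u_m
        m_c = a0 + a1 * control + u_m
        vals = []
        for tval in (treat, control):
            eta_t = c0 + c_cent * tval + c_med * m_t + u_y
            eta_c = c0 + c_cent * tval + c_med * m_c + u_y
            vals.append(np.mean(link(eta_t) - link(eta_c)))
        acme_sims[j] = 0.5 * (vals[0] + vals[1])
    acme = float(np.mean(acme_sims))
    lo, hi = np.percentile(acme_sims, [2.5, 97.5])
    lo, hi = min(lo, acme), max(hi, acme)
    share_pos = np.mean(acme_sims > 0)
    share_neg = np.mean(acme_sims < 0)
    p = float(min(1.0, 2.0 * min(share_pos, share_neg) + (share_pos + share_neg == 0)))

    # direct & total effects on the same scale, at the point estimates
    c0, c_cent, c_med = [out_fit.coefficients[k] for k in out_fit.fit.names]
    a0, a1 = [med_fit.coefficients[k] for k in med_fit.fit.names]
    m_t, m_c = a0 + a1 * treat + u_m, a0 + a1 * control + u_m
    direct = float(np.mean(0.5 * (
        (link(c0 + c_cent * treat + c_med * m_t + u_y)
         - link(c0 + c_cent * control + c_med * m_t + u_y))
        + (link(c0 + c_cent * treat + c_med * m_c + u_y)
           - link(c0 + c_cent * control + c_med * m_c + u_y)))))
    t0, t1 = [total_fit.coefficients[k] for k in total_fit.fit.names]
    u_t = total_fit.fit.u["participant"][part_codes.codes]
    total = float(np.mean(link(t0 + t1 * treat + u_t) - link(t0 + t1 * control + u_t)))
    scale = "probability" if fam == "logistic" else "response"
    return MediationResult(acme=acme, acme_ci=(float(lo), float(hi)),
                           direct_effect=direct, total_effect=total,
                           n_sims=n_sims, p_value=p, scale=scale)


def event_isfc(
    ts_a: dict[str, RoiTimeSeries],
    ts_b: dict[str, RoiTimeSeries],
    events: pd.DataFrame,
    min_duration_s: float = DEFAULT_MIN_EVENT_DURATION_S,
) -> pd.DataFrame:
    """Event-wise intersubject functional connectivity between two regions.

    For each event at least ``min_duration_s`` long: each participant's
    region-A event time series is correlated with the mean of the other
    participants' region-B series (and vice versa); the two direction-
    averages are averaged into one ISFC value per event. Symmetric in the
    two regions.
    """
    participants = sorted(ts_a)
    if sorted(ts_b) != participants:
        raise ValueError("region A and B must cover the same participants")
    if len(participants) < 3:
        raise ValueError("ISFC needs at least 3 participants")
    rows = []
    for _, row in events.sort_values(["movie", "event"]).iterrows():
        ts0 = ts_a[participants[0]]
        trs = _event_trs(row["onset_s"], row["offset_s"], ts0.tr_s, ts0.shift)
        min_trs = int(np.ceil(min_duration_s / ts0.tr_s))
        if trs.size < min_trs:
            continue
        A = np.stack([ts_a[p].values[trs] for p in participants])  # (N, L)
        B = np.stack([ts_b[p].values[trs] for p in participants])
        n = len(participants)
        dirs = []
        for X, Y in ((A, B), (B, A)):
            cs = []
            sum_y = Y.sum(axis=0)
            for s in range(n):
                others = (sum_y - Y[s]) / (n - 1)
                cs.append(stats.pearsonr(X[s], others).statistic)
            dirs.append(np.mean(cs))
        rows.append({"movie": row["movie"], "event": int(row["event"]),
                     "isfc": float(np.mean(dirs)), "n_trs": int(trs.size)})
    if not rows:
        raise ValueError(f"no events of duration >= {min_duration_s} s")
    return pd.DataFrame(rows)


def isfc_centrality_analysis(isfc_pair1: pd.DataFrame, isfc_pair2: pd.DataFrame,
                             cent: pd.DataFrame) -> dict:
    """Correlate event-wise ISFC with centrality for two region pairs.

    Returns the two Pearson correlations (with two-tailed p-values) and
    the Zou CI for their difference, using the correlation between the two
    ISFC series as the overlap term. Both pairs must cover the same event
    set.
    """
    k1 = isfc_pair1[["movie", "event"]].apply(tuple, axis=1)
    k2 = isfc_pair2[["movie", "event"]].apply(tuple, axis=1)
    if set(k1) != set(k2):
        raise ValueError("the two region pairs must cover the same events")
    m1 = isfc_pair1.merge(cent[["movie", "event", "z_centrality"]],
                          on=["movie", "event"]).sort_values(["movie", "event"])
    m2 = isfc_pair2.merge(cent[["movie", "event", "z_centrality"]],
                          on=["movie", "event"]).sort_values(["movie", "event"])
    n = len(m1)
    if n < 4:
        raise ValueError("need at least 4 events")
    x = m1["z_centrality"].to_numpy()
    y1 = m1["isfc"].to_numpy()
    y2 = m2["isfc"].to_numpy()
    r1, p1 = stats.pearsonr(x, y1)
    r2, p2 = stats.pearsonr(x, y2)
    r_bc = float(stats.pearsonr(y1, y2).statistic)
    # perfect sample correlations (noiseless toys) would put Fisher z at
    # infinity; nudge inside the open interval for the CI
    eps = 1e-12
    clip = lambda r: float(np.clip(r, -1 + eps, 1 - eps))
    ci = compare_dependent_correlations(clip(r1), clip(r2), clip(r_bc), n)
    return {"r_pair1": float(r1), "p_pair1": float(p1),
            "r_pair2": float(r2), "p_pair2": float(p2),
            "r_between_pairs": r_bc, "n_events": n,
            "difference_ci": ci}
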