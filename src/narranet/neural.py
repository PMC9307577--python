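"""Event-pattern extraction and intersubject pattern statistics.

Per-event multivoxel patterns are extracted from ROI/parcel time series by
averaging BOLD samples across the TRs of each event (after a fixed
hemodynamic shift). Intersubject pattern correlation (pISC) correlates one
participant's event pattern with every other participant's pattern of the
same event; randomization tests shuffle event labels to build the null.
Cross-event pattern similarity matrices feed representational similarity
analysis (RSA) against text-embedding similarity, and event-level mean
activations feed a centrality regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_stats import PermutationResult, bh_fdr, permutation_pvalue
from .embedding import SimilarityMatrix

__all__ = [
    "RoiTimeSeries",
    "EventPatternSet",
    "extract_event_patterns",
    "event_pisc",
    "pisc_randomization_map",
    "pisc_map_parcels",
    "highlow_pisc_test",
    "cross_event_similarity",
    "rsa_test",
    "event_activation_regression",
]

DEFAULT_TR_S = 1.5
DEFAULT_HEMODYNAMIC_SHIFT = 3  # TRs (~4.5 s at TR = 1.5 s)


@dataclass
class RoiTimeSeries:
    """TR-indexed ROI signal for one participant.

    ``values`` is (T,) for a region-mean signal or (T, F) for a multi-
    feature (voxel/vertex) pattern, assumed z-scored per feature upstream.
    ``runs`` are half-open (start, stop) TR index ranges; events must not
    straddle runs. ``shift`` is the hemodynamic delay in TRs applied when
    mapping stimulus time to BOLD time.
    """

    participant: str
    values: np.ndarray
    roi: str = ""
    tr_s: float = DEFAULT_TR_S
    shift: int = DEFAULT_HEMODYNAMIC_SHIFT
    runs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")
        if self.shift < 0:
            raise ValueError("hemodynamic shift must be >= 0")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not self.runs:
            self.runs = [(0, self.values.shape[0])]
        prev_stop = -1
        for start, stop in self.runs:
            if start < prev_stop:
                raise ValueError("runs must be non-overlapping and ordered")
            prev_stop = stop

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]

    def run_of(self, tr: int) -> tuple[int, int]:
        for start, stop in self.runs:
            if start <= tr < stop:
                return start, stop
        raise ValueError(f"TR {tr} falls outside every run")


@dataclass
class EventPatternSet:
    """Participants x events x features tensor of event patterns.

    Missing entries (events not recalled, excluded first events) are NaN.
    """

    data: np.ndarray  # (N, E, F)
    participants: list[str]
    events: pd.DataFrame  # columns movie, event
    phase: str  # movie | recall

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("pattern tensor must be (participants, events, features)")
        if self.data.shape[0] != len(self.participants):
            raise ValueError("participant axis mismatch")
        if self.data.shape[1] != len(self.events):
            raise ValueError("event axis mismatch")

    @property
    def n_features(self) -> int:
        return self.data.shape[2]

    def valid_mask(self) -> np.ndarray:
        """(N, E) flag: pattern present (no NaN feature)."""
        return ~np.isnan(self.data).any(axis=2)


def _event_trs(onset_s, offset_s, tr_s, shift):
    """Shifted BOLD TR indices of an event: base TRs are those whose start
    time lies in [onset, offset), then the hemodynamic shift is added."""
    first = int(np.ceil(onset_s / tr_s - 1e-9))
    last = int(np.ceil(offset_s / tr_s - 1e-9))  # exclusive
    base = np.arange(first, last)
    return base + shift


def extract_event_patterns(
    series: dict[str, RoiTimeSeries],
    events: pd.DataFrame,
    phase: str = "movie",
    recalled: dict[str, set] | None = None,
    exclude_first_event: bool = True,
) -> EventPatternSet:
    """Average each participant's time series over the TRs of each event.

    ``events`` needs columns movie, event, onset_s, offset_s (stimulus
    time, seconds, within the series timeline). For the movie phase the
    first event of each movie is marked missing by default (movie-onset
    transient). For the recall phase, ``recalled`` maps each participant
    to their set of recalled (movie, event) pairs; everything else is
    missing.
    """
    if phase not in ("movie", "recall"):
        raise ValueError(f"unknown phase '{phase}'")
    if phase == "recall" and recalled is None:
        raise ValueError("recall phase requires the recalled-event sets")
    participants = sorted(series)
    ev = events.sort_values(["movie", "event"]).reset_index(drop=True)
    first_events = set()
    for movie, sub in ev.groupby("movie", sort=False):
        first_events.add((movie, int(sub["event"].min())))
    n_feat = None
    for p in participants:
        v = series[p].values
        f = 1 if v.ndim == 1 else v.shape[1]
        if n_feat is None:
            n_feat = f
        elif f != n_feat:
            raise ValueError("feature count differs across participants")
    data = np.full((len(participants), len(ev), n_feat), np.nan)
    for pi, p in enumerate(participants):
        ts = series[p]
        vals = ts.values if ts.values.ndim == 2 else ts.values[:, None]
        for ei, row in ev.iterrows():
            key = (row["movie"], int(row["event"]))
            if phase == "movie" and exclude_first_event and key in first_events:
                continue
            if phase == "recall" and key not in recalled.get(p, set()):
                continue
            trs = _event_trs(row["onset_s"], row["offset_s"], ts.tr_s, ts.shift)
            if trs.size == 0:
                raise ValueError(f"event {key} covers zero TRs")
            run = ts.run_of(int(trs[0]))
            if trs[-1] >= run[1]:
                raise ValueError(f"event {key}: hemodynamic shift pushes TRs past "
                                 f"the run end for participant {p}")
            data[pi, ei] = vals[trs].mean(axis=0)
    return EventPatternSet(data=data, participants=participants,
                           events=ev[["movie", "event"]].copy(), phase=phase)


def _unit_center_rows(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center each (participant, event) pattern and scale to unit norm.

    Returns (U, valid) where invalid rows (missing or constant patterns)
    are zeroed and flagged False.
    """
    n, e, f = data.shape
    valid = ~np.isnan(data).any(axis=2)
    centered = data - np.nanmean(data, axis=2, keepdims=True)
    norms = np.sqrt(np.nansum(centered ** 2, axis=2))
    constant = valid & (norms == 0)
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant pattern(s) skipped "
                      "(correlation undefined)")
        valid = valid & ~constant
    U = np.where(valid[:, :, None], centered, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        U = np.where(valid[:, :, None], U / np.where(norms == 0, 1.0, norms)[:, :, None], 0.0)
    return U, valid


def event_pisc(patterns: EventPatternSet,
               min_participants: int = 2) -> pd.DataFrame:
    """Intersubject pattern correlation per (participant, event).

    For participant s and event e: the mean Pearson correlation between
    s's pattern and each other participant's pattern of the same event.
    Events present for fewer than ``min_participants`` participants are
    dropped (the recall analyses use a threshold of 5 recallers; pass
    ``min_participants=2`` for the all-events variant).
    """
    if patterns.n_features < 2:
        raise ValueError("pISC needs at least 2 features")
    if min_participants < 2:
        raise ValueError("min_participants must be >= 2")
    U, valid = _unit_center_rows(patterns.data)
    n, e, _ = U.shape
    rows = []
    for ei in range(e):
        v = valid[:, ei]
        if v.sum() < min_participants:
            continue
        Ue = U[v, ei]  # (n_valid, F)
        C = Ue @ Ue.T
        np.fill_diagonal(C, 0.0)
        partners = v.sum() - 1
        means = C.sum(axis=1) / partners
        for k, pi in enumerate(np.flatnonzero(v)):
            rows.append((patterns.participants[pi],
                         patterns.events.iloc[ei]["movie"],
                         int(patterns.events.iloc[ei]["event"]),
                         float(means[k]), int(partners)))
    return pd.DataFrame(rows, columns=["participant", "movie", "event",
                                       "pisc", "n_partners"])


def _movie_blocks(events: pd.DataFrame) -> list[np.ndarray]:
    return [np.flatnonzero((events["movie"] == m).to_numpy())
            for m in dict.fromkeys(events["movie"])]


def _permute_events(rng, n_events, blocks, scope):
    if scope == "across-movies":
        return rng.permutation(n_events)
    perm = np.arange(n_events)
    for idx in blocks:
        perm[idx] = rng.permutation(idx)
    return perm


def pisc_randomization_map(
    patterns: EventPatternSet,
    n_perm: int = 1000,
    shuffle_scope: str = "across-movies",
    seed: int | None = None,
    min_participants: int = 2,
) -> tuple[float, PermutationResult]:
    """Mean pISC with an event-label randomization test (one parcel).

    The observed statistic is the event-level pISC averaged over events
    within participant, then over participants. Each permutation draws one
    event-relabeling (global, or within movie for
    ``shuffle_scope='within-movie'``) and correlates each participant's
    pattern of event e with the other participants' patterns of the
    permuted event, reproducing the matching-vs-non-matching null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if shuffle_scope not in ("across-movies", "within-movie"):
        raise ValueError(f"unknown shuffle scope '{shuffle_scope}'")
    if patterns.n_features < 2:
        raise ValueError("pISC needs at least 2 features")
    blocks = _movie_blocks(patterns.events)
    if shuffle_scope == "within-movie" and any(len(b) < 2 for b in blocks):
        raise ValueError("within-movie shuffling impossible: a movie has <2 events")
    rng = np.random.default_rng(seed)
    U, valid = _unit_center_rows(patterns.data)
    n, e, f = U.shape
    # all cross-participant, cross-event pattern correlations
    V = U.reshape(n * e, f)
    G = (V @ V.T).reshape(n, e, n, e)
    m = valid.astype(float)
    # T1[s, e, f] = sum_t valid(t,f) * corr(P_se, P_tf)
    T1 = np.einsum("setf,tf->sef", G, m, optimize=True)
    Dg = np.einsum("sesf->sef", G)  # s's own cross-event correlations
    col_counts = m.sum(axis=0)  # valid participants per event

    def stat(perm):
        pe = perm  # event -> partner event
        num = T1[:, np.arange(e), pe] - m[:, pe] * Dg[:, np.arange(e), pe]
        den = col_counts[pe][None, :] - m[:, pe]
        ok = valid & (den >= max(1, min_participants - 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            pisc = np.where(ok, num / np.where(den == 0, 1.0, den), np.nan)
        per_participant = np.nanmean(np.where(ok, pisc, np.nan), axis=1)
        return float(np.nanmean(per_participant))

    observed = stat(np.arange(e))
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = stat(_permute_events(rng, e, blocks, shuffle_scope))
    res = permutation_pvalue(observed, null, tail="one-tailed-greater", seed=seed)
    return observed, res


def pisc_map_parcels(
    patterns_by_parcel: dict[str, EventPatternSet],
    n_perm: int = 1000,
    shuffle_scope: str = "across-movies",
    seed: int | None = None,
    q: float = 0.05,
    min_participants: int = 2,
) -> pd.DataFrame:
    """pISC randomization test per parcel, BH-FDR corrected across parcels."""
    rows = []
    for i, (parcel, pats) in enumerate(sorted(patterns_by_parcel.items())):
        sub_seed = None if seed is None else seed + i
        obs, res = pisc_randomization_map(pats, n_perm=n_perm,
                                          shuffle_scope=shuffle_scope,
                                          seed=sub_seed,
                                          min_participants=min_participants)
        rows.append({"parcel": parcel, "mean_pisc": obs, "p": res.p_value})
    out = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(out["p"].to_numpy(), q=q)
    out["q_value"] = p_adj
    out["significant"] = reject
    return out


def _condition_diff(pisc_wide: np.ndarray, valid: np.ndarray,
                    labels: np.ndarray, movie_ids: np.ndarray) -> float:
    """Mean over participants of (high - low), each condition averaged over
    events within movie then across movies."""
    n = pisc_wide.shape[0]
    movies = np.unique(movie_ids)
    per_part = np.full((n, 2), np.nan)  # high, low
    for ci, cond in enumerate(("high", "low")):
        mask_c = labels == cond
        per_movie = np.full((n, len(movies)), np.nan)
        for mi, mv in enumerate(movies):
            cols = mask_c & (movie_ids == mv)
            if not cols.any():
                continue
            block = np.where(valid[:, cols], pisc_wide[:, cols], np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                per_movie[:, mi] = np.nanmean(block, axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_part[:, ci] = np.nanmean(per_movie, axis=1)
    diffs = per_part[:, 0] - per_part[:, 1]
    return float(np.nanmean(diffs))


def highlow_pisc_test(
    pisc: pd.DataFrame,
    labels: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict:
    """High vs low centrality difference in event-level pISC.

    Event-level pISC values (from :func:`event_pisc`) are averaged within
    condition per movie, then across movies, per participant; the test
    statistic is the participant-mean difference. The null shuffles the
    high/low event labels within each movie (one shuffle applied to all
    participants per iteration); the p-value is two-tailed.
    """
    lab = labels.copy()
    lab = lab[lab["condition"].isin(["high", "low"])]
    merged_events = pisc[["movie", "event"]].drop_duplicates()
    lab = lab.merge(merged_events, on=["movie", "event"])
    # movies must have both conditions among events with pISC
    keep_movies = []
    for movie, sub in lab.groupby("movie", sort=True):
        conds = set(sub["condition"])
        if conds >= {"high", "low"}:
            keep_movies.append(movie)
        else:
            warnings.warn(f"movie {movie} lacks a condition after pISC filtering; excluded")
    lab = lab[lab["movie"].isin(keep_movies)]
    if lab.empty:
        raise ValueError("no movies with both conditions")
    key = list(map(tuple, lab[["movie", "event"]].itertuples(index=False)))
    pivot = pisc.pivot_table(index="participant", columns=["movie", "event"],
                             values="pisc")
    participants = list(pivot.index)
    wide = pivot.reindex(columns=pd.MultiIndex.from_tuples(key)).to_numpy()
    valid = ~np.isnan(wide)
    labels_arr = lab["condition"].to_numpy()
    movie_arr = lab["movie"].to_numpy()
    observed = _condition_diff(wide, valid, labels_arr, movie_arr)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm_labels = labels_arr.copy()
        for mv in np.unique(movie_arr):
            idx = np.flatnonzero(movie_arr == mv)
            perm_labels[idx] = perm_labels[rng.permutation(idx)]
        null[b] = _condition_diff(wide, valid, perm_labels, movie_arr)
    res = permutation_pvalue(observed, null, tail="two-tailed", seed=seed)
    # per-condition participant means for reporting
    return {"difference": observed, "p": res.p_value, "permutation": res}


def cross_event_similarity(patterns: EventPatternSet) -> dict[tuple[str, str], np.ndarray]:
    """Cross-event intersubject similarity matrix per (participant, movie).

    For participant s and movie m, each partner t yields the events x
    events matrix corr(P_s,a, P_t,b); each matrix is symmetrized by
    averaging with its transpose, then matrices are averaged over
    partners (cell-wise, ignoring missing). Movies with fewer than 3
    events raise (no usable lower triangle).
    """
    if len(patterns.participants) < 2:
        raise ValueError("need at least 2 participants")
    U, valid = _unit_center_rows(patterns.data)
    out = {}
    for movie in dict.fromkeys(patterns.events["movie"]):
        idx = np.flatnonzero((patterns.events["movie"] == movie).to_numpy())
        if idx.size < 3:
            raise ValueError(f"movie {movie} has fewer than 3 events")
        Um = U[:, idx]        # (N, Em, F)
        vm = valid[:, idx]    # (N, Em)
        n, em, _ = Um.shape
        for si in range(n):
            total = np.zeros((em, em))
            cnt = np.zeros((em, em))
            for ti in range(n):
                if ti == si:
                    continue
                M = Um[si] @ Um[ti].T  # corr(s_a, t_b)
                ok = np.outer(vm[si], vm[ti])
                M_sym = 0.5 * (np.where(ok, M, 0.0) + np.where(ok, M, 0.0).T)
                ok_sym = ok & ok.T
                total += np.where(ok_sym, M_sym, 0.0)
                cnt += ok_sym
            with np.errstate(invalid="ignore"):
                avg = np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)
            out[(patterns.participants[si], movie)] = avg
    return out


def rsa_test(
    neural: dict[tuple[str, str], np.ndarray],
    reference: dict[str, SimilarityMatrix],
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, PermutationResult]:
    """Representational similarity between neural and text similarity matrices.

    For each participant and movie, the Pearson correlation between the
    lower triangles (diagonal excluded) of the neural cross-event matrix
    and the reference (embedding-derived) matrix, over cells present in
    both. Correlations are averaged across movies then participants. The
    null shuffles the reference event labels within each movie; the
    p-value is one-tailed (greater).
    """
    rng = np.random.default_rng(seed)
    participants = sorted({p for (p, _) in neural})
    movies = sorted({m for (_, m) in neural})
    for m in movies:
        if m not in reference:
            raise ValueError(f"no reference similarity matrix for movie {m}")

    # pre-extract lower-triangle vectors: per movie, a participants x cells
    # array of neural values (NaN where missing or participant absent)
    tri = {}
    for m in movies:
        il = np.tril_indices(reference[m].n_events, k=-1)
        X = np.full((len(participants), il[0].size), np.nan)
        for pi, p in enumerate(participants):
            if (p, m) in neural:
                nm = neural[(p, m)]
                if nm.shape[0] != reference[m].n_events:
                    raise ValueError(f"movie {m}: neural/reference event mismatch")
                X[pi] = nm[il]
        tri[m] = (il, X)

    def mean_r(ref_perms: dict[str, np.ndarray], warn: bool = False) -> float:
        per_part = np.zeros(len(participants))
        counts = np.zeros(len(participants))
        for m in movies:
            il, X = tri[m]
            rm = reference[m].matrix[np.ix_(ref_perms[m], ref_perms[m])]
            y = rm[il]
            mask = np.isfinite(X) & np.isfinite(y)[None, :]
            n_ok = mask.sum(axis=1)
            usable = n_ok >= 3
            if warn and np.any(~usable & np.isfinite(X).any(axis=1)):
                warnings.warn(f"movie {m}: participant(s) with <3 usable cells; excluded")
            Xz = np.where(mask, X, 0.0)
            Yz = np.where(mask, y[None, :], 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                n_ok_f = np.where(n_ok > 0, n_ok, 1).astype(float)
                mx = Xz.sum(1) / n_ok_f
                my = Yz.sum(1) / n_ok_f
                sxy = (Xz * Yz).sum(1) / n_ok_f - mx * my
                sxx = (Xz ** 2).sum(1) / n_ok_f - mx ** 2
                syy = (Yz ** 2).sum(1) / n_ok_f - my ** 2
                r = sxy / np.sqrt(sxx * syy)
            good = usable & np.isfinite(r)
            per_part[good] += r[good]
            counts[good] += 1
        if not np.any(counts > 0):
            raise ValueError("no usable participant/movie combinations")
        return float(np.mean(per_part[counts > 0] / counts[counts > 0]))

    ident = {m: np.arange(reference[m].n_events) for m in movies}
    observed = mean_r(ident, warn=True)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perms = {m: rng.permutation(reference[m].n_events) for m in movies}
        null[b] = mean_r(perms)
    res = permutation_pvalue(observed, null, tail="one-tailed-greater", seed=seed)
    return observed, res


def event_activation_regression(activations: pd.DataFrame,
                                cent: pd.DataFrame) -> dict:
    """Event-level activation regressed on centrality, per participant.

    ``activations`` needs columns participant, movie, event, activation.
    Per participant, event activations are residualized on movie
    indicator regressors (removing the movie-level mean signal), and the
    residuals are regressed on z-centrality; the per-participant slopes
    are tested against zero with a two-tailed one-sample t-test.
    """
    merged = activations.merge(cent[["movie", "event", "z_centrality"]],
                               on=["movie", "event"])
    if merged["movie"].nunique() < 2:
        raise ValueError("need at least 2 movies (movie regressor saturates otherwise)")
    betas = {}
    for p, sub in merged.groupby("participant", sort=True):
        sub = sub.dropna(subset=["activation"])
        if sub["movie"].nunique() < 2:
            raise ValueError(f"participant {p}: fewer than 2 movies with data")
        # residualize activation on movie indicators == demean within movie
        resid = sub["activation"] - sub.groupby("movie")["activation"].transform("mean")
        x = sub["z_centrality"].to_numpy(dtype=float)
        y = resid.to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        betas[p] = float(coef[1])
    if len(betas) < 2:
        raise ValueError("need at least 2 participants")
    b = np.array(list(betas.values()))
    t, p = stats.ttest_1samp(b, 0.0)
    return {"betas": betas, "t": float(t), "df": len(b) - 1, "p": float(p),
            "mean_beta": float(b.mean())}
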