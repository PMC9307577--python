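"""Recall-behavior analytics.

Recall probabilities, recall-order statistics, serial-position tests, and
centrality-recall relationships (correlation, paired high/low tests, and
the mixed-effects logistic model with crossed participant and movie
random intercepts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_stats import MixedModelResult, fit_mixed_model

__all__ = [
    "RecallMatrix",
    "recall_matrix_from_utterances",
    "recall_probability",
    "recall_order_spearman",
    "serial_position_anova",
    "highlow_recall_ttest",
    "correlate_centrality_recall",
    "recall_glmm",
]


@dataclass
class RecallMatrix:
    """Participant x event binary recall plus per-participant recall order.

    ``recalled`` is a 0/1 DataFrame indexed by participant with a
    (movie, event) column MultiIndex; ``order`` lists each participant's
    recalled (movie, event) pairs in recall order (first mention only).
    """

    recalled: pd.DataFrame
    order: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    validate: bool = True

    def __post_init__(self):
        vals = self.recalled.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("recall indicators must be 0/1")
        if not self.validate:
            return
        cols = list(self.recalled.columns)
        for participant, seq in self.order.items():
            if len(set(seq)) != len(seq):
                raise ValueError(f"participant {participant}: duplicate events in order")
            row = self.recalled.loc[participant].to_numpy()
            marked = {cols[i] for i in np.flatnonzero(row == 1)}
            if set(seq) != marked:
                raise ValueError(f"participant {participant}: order list does not match "
                                 "recall indicators")

    @property
    def participants(self) -> list:
        return list(self.recalled.index)

    @property
    def movies(self) -> list:
        return list(dict.fromkeys(m for m, _ in self.recalled.columns))

    def movie_recalled(self) -> pd.DataFrame:
        """Participant x movie flag: movie counts as recalled if any of its
        events was recalled."""
        return self.recalled.T.groupby(level="movie", sort=False).max().T


def recall_matrix_from_utterances(utterances: pd.DataFrame,
                                  event_index: pd.DataFrame) -> RecallMatrix:
    """Build a RecallMatrix from an utterance-level attribution table.

    ``utterances`` needs columns participant, utterance, movie, event;
    repeated mentions of an event count once, order uses the first
    mention. ``event_index`` (columns movie, event) fixes the full event
    grid, so unrecalled events appear as explicit zeros.
    """
    for c in ("participant", "utterance", "movie", "event"):
        if c not in utterances.columns:
            raise ValueError(f"utterances missing column '{c}'")
    cols = pd.MultiIndex.from_frame(event_index[["movie", "event"]])
    participants = sorted(utterances["participant"].unique())
    recalled = pd.DataFrame(0, index=participants, columns=cols)
    order: dict[str, list[tuple[str, int]]] = {p: [] for p in participants}
    valid = set(map(tuple, event_index[["movie", "event"]].itertuples(index=False)))
    for p, sub in utterances.sort_values("utterance").groupby("participant"):
        seen = set()
        for _, row in sub.iterrows():
            key = (row["movie"], int(row["event"]))
            if key not in valid:
                raise ValueError(f"participant {p}: attribution {key} outside event table")
            if key in seen:
                continue
            seen.add(key)
            order[p].append(key)
            recalled.loc[p, key] = 1
    return RecallMatrix(recalled=recalled, order=order)


def recall_probability(rm: RecallMatrix,
                       scope: str = "unconditional") -> pd.DataFrame:
    """Per-event proportion of participants who recalled the event.

    ``scope='unconditional'`` divides by all participants;
    ``'movie-conditional'`` divides by the participants who recalled the
    movie (NaN with a warning if nobody did).
    """
    if len(rm.participants) < 1:
        raise ValueError("need at least one participant")
    counts = rm.recalled.sum(axis=0)
    if scope == "unconditional":
        probs = counts / len(rm.participants)
    elif scope == "movie-conditional":
        mflags = rm.movie_recalled()
        denom = mflags.sum(axis=0)
        probs = pd.Series(index=counts.index, dtype=float)
        for (movie, event) in counts.index:
            d = denom[movie]
            if d == 0:
                warnings.warn(f"movie {movie} recalled by nobody; conditional "
                              "probability undefined")
                probs[(movie, event)] = np.nan
            else:
                probs[(movie, event)] = counts[(movie, event)] / d
    else:
        raise ValueError(f"unknown scope '{scope}'")
    out = probs.rename("probability").reset_index()
    out.columns = ["movie", "event", "probability"]
    return out


def recall_order_spearman(rm: RecallMatrix, level: str = "event") -> pd.Series:
    """Per-participant Spearman rho between presentation and recall order.

    ``level='movie'``: rank correlation over recalled movies (recall rank
    of a movie = first time any of its events is mentioned).
    ``level='event'``: within each movie, rho over the participant's
    recalled events, then averaged across that participant's movies.
    Participants (or movies) with <2 recalled units are excluded with a
    warning.
    """
    movie_order = {m: i for i, m in enumerate(rm.movies)}
    out = {}
    for p in rm.participants:
        seq = rm.order.get(p, [])
        if level == "movie":
            seen: list[str] = []
            for movie, _ in seq:
                if movie not in seen:
                    seen.append(movie)
            if len(seen) < 2:
                warnings.warn(f"participant {p}: fewer than 2 recalled movies; excluded")
                continue
            pres = [movie_order[m] for m in seen]
            rho = stats.spearmanr(pres, np.arange(len(seen))).statistic
            out[p] = float(rho)
        elif level == "event":
            rhos = []
            by_movie: dict[str, list[int]] = {}
            for movie, event in seq:
                by_movie.setdefault(movie, []).append(event)
            for movie, events in by_movie.items():
                if len(events) < 2:
                    continue
                rho = stats.spearmanr(events, np.arange(len(events))).statistic
                rhos.append(rho)
            if not rhos:
                warnings.warn(f"participant {p}: no movie with >=2 recalled events; excluded")
                continue
            out[p] = float(np.mean(rhos))
        else:
            raise ValueError(f"unknown level '{level}'")
    return pd.Series(out, name=f"spearman_{level}")


def serial_position_anova(rm: RecallMatrix) -> dict:
    """Primacy/recency check: first vs middle vs last three events per movie.

    Per movie (>=9 events; shorter movies excluded with a warning), the
    mean recall probability of the first three, middle three (centered on
    ceil(M/2), 1-based), and last three events. A one-way repeated-measures
    ANOVA treats movies as subjects and the three positions as the
    within-subject factor. Returns F, (df1, df2), p, partial eta squared,
    and the condition table.
    """
    probs = recall_probability(rm, scope="unconditional")
    rows = []
    for movie, sub in probs.groupby("movie", sort=False):
        sub = sub.sort_values("event")
        m = len(sub)
        if m < 9:
            warnings.warn(f"movie {movie} has {m} < 9 events; excluded")
            continue
        vals = sub["probability"].to_numpy()
        mid = int(np.ceil(m / 2))  # 1-based center
        first = vals[:3].mean()
        middle = vals[mid - 2: mid + 1].mean()
        last = vals[-3:].mean()
        rows.append({"movie": movie, "first": first, "middle": middle, "last": last})
    if len(rows) < 2:
        raise ValueError("need at least two movies with >=9 events")
    table = pd.DataFrame(rows).set_index("movie")
    data = table.to_numpy()  # movies x 3
    n, k = data.shape
    grand = data.mean()
    ss_total = float(((data - grand) ** 2).sum())
    ss_subj = float(k * ((data.mean(axis=1) - grand) ** 2).sum())
    ss_cond = float(n * ((data.mean(axis=0) - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_cond
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond, ms_err = ss_cond / df1, ss_err / df2
    f = ms_cond / ms_err if ms_err > 0 else 0.0
    p = float(stats.f.sf(f, df1, df2)) if ms_err > 0 else 1.0
    eta_p2 = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return {"F": float(f), "df": (df1, df2), "p": p, "eta_sq_partial": float(eta_p2),
            "table": table}


def _per_participant_condition_means(rm: RecallMatrix, labels: pd.DataFrame):
    """Per participant, recall proportion per condition per movie, then the
    mean across movies. Returns (high_means, low_means) arrays."""
    lab = labels.set_index(["movie", "event"])["condition"]
    highs, lows = [], []
    for p in rm.participants:
        row = rm.recalled.loc[p]
        h_by_movie, l_by_movie = [], []
        for movie in rm.movies:
            events = [e for (m, e) in rm.recalled.columns if m == movie]
            h = [row[(movie, e)] for e in events if lab.get((movie, e)) == "high"]
            l = [row[(movie, e)] for e in events if lab.get((movie, e)) == "low"]
            if not h or not l:
                raise ValueError(f"movie {movie} lacks a high or low condition")
            h_by_movie.append(np.mean(h))
            l_by_movie.append(np.mean(l))
        highs.append(np.mean(h_by_movie))
        lows.append(np.mean(l_by_movie))
    return np.asarray(highs), np.asarray(lows)


def highlow_recall_ttest(rm: RecallMatrix, labels: pd.DataFrame,
                         conf: float = 0.95) -> dict:
    """Paired t-test of recall for high vs low centrality events.

    Per participant, the recall proportion of high (low) centrality events
    is computed within each movie and averaged across movies; the paired
    two-tailed t-test compares conditions across participants
    (df = n_participants - 1). Returns t, df, p, Cohen's d_z, the CI of
    the mean difference, and the per-participant means.
    """
    high, low = _per_participant_condition_means(rm, labels)
    n = len(high)
    if n < 2:
        raise ValueError("need at least two participants")
    diff = high - low
    sd = diff.std(ddof=1)
    if sd == 0:
        t, p, dz = 0.0, 1.0, 0.0
    else:
        t, p = stats.ttest_rel(high, low)
        dz = diff.mean() / sd
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + conf / 2, df=n - 1)
    ci = (float(diff.mean() - tcrit * se), float(diff.mean() + tcrit * se))
    return {"t": float(t), "df": n - 1, "p": float(p), "cohens_dz": float(dz),
            "mean_difference": float(diff.mean()), "ci": ci,
            "high_means": high, "low_means": low}


def correlate_centrality_recall(cent: pd.DataFrame, probs: pd.DataFrame,
                                conf: float = 0.95) -> dict:
    """Pearson correlation between event centrality and recall probability.

    Events are pooled across movies; returns r, the event count N (the
    df convention used for reporting is the pooled event count), a
    Fisher-z CI, and the two-tailed p.
    """
    merged = cent.merge(probs, on=["movie", "event"])
    x = merged["z_centrality"].to_numpy(dtype=float)
    y = merged["probability"].to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 events")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in centrality or recall probability")
    r, p = stats.pearsonr(x, y)
    zcrit = stats.norm.ppf(0.5 + conf / 2)
    zr = np.arctanh(r)
    ci = (float(np.tanh(zr - zcrit / np.sqrt(n - 3))),
          float(np.tanh(zr + zcrit / np.sqrt(n - 3))))
    return {"r": float(r), "n": n, "p": float(p), "ci": ci}


def recall_glmm(rm: RecallMatrix, cent_semantic: pd.DataFrame,
                cent_causal: pd.DataFrame,
                lrt: bool = True) -> MixedModelResult:
    """Mixed-effects logistic regression of event recall on both centralities.

    Every (participant, event) is one observation; semantic and causal
    z-centralities are fixed effects, participant and movie are crossed
    random intercepts. Likelihood-ratio tests drop one predictor at a
    time, so each tests that predictor's unique contribution after
    controlling for the other.
    """
    cols = list(rm.recalled.columns)
    sem = cent_semantic.set_index(["movie", "event"])["z_centrality"].loc[cols].to_numpy()
    cau = cent_causal.set_index(["movie", "event"])["z_centrality"].loc[cols].to_numpy()
    n_p, n_e = rm.recalled.shape
    df = pd.DataFrame({
        "participant": np.repeat(rm.participants, n_e),
        "movie": np.tile([m for m, _ in cols], n_p),
        "recalled": rm.recalled.to_numpy().ravel(),
        "semantic": np.tile(sem, n_p),
        "causal": np.tile(cau, n_p),
    })
    return fit_mixed_model(
        outcome=df["recalled"],
        fixed=df[["semantic", "causal"]],
        random_intercepts={"participant": df["participant"], "movie": df["movie"]},
        family="logistic",
        lrt_predictors=("all" if lrt else None),
    )
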