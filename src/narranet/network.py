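"""Narrative networks and event centrality.

A narrative network represents one movie as a weighted undirected graph:
nodes are events, edge weights are either cosine similarities between
event text embeddings (semantic network) or the proportion of human
coders judging an event pair causally related (causal network). An
event's centrality is its weighted degree, normalized by the movie's
degree sum and z-scored within the movie; events in the top/bottom 40%
form the high/low centrality conditions used throughout the behavioral
and neural analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_stats import permutation_pvalue, PermutationResult
from .embedding import EmbeddingMatrix, SimilarityMatrix

__all__ = [
    "NarrativeNetwork",
    "CausalJudgmentSet",
    "build_semantic_network",
    "build_causal_network",
    "compute_centrality",
    "split_high_low",
    "partial_centrality",
    "coder_jaccard",
    "cross_movie_highlow_test",
]

DEFAULT_SPLIT_FRACTION = 0.4

CENTRALITY_COLUMNS = ["movie", "event", "raw_degree", "normalized_degree",
                      "z_centrality", "condition"]


@dataclass
class NarrativeNetwork:
    """Symmetric weighted adjacency over one movie's events, zero diagonal."""

    movie: str
    adjacency: np.ndarray
    kind: str  # semantic | causal
    n_raters: int | None = None

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.max(np.abs(a - a.T)) > 1e-12:
            raise ValueError("adjacency must be symmetric within 1e-12")
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 0.0)
        if self.kind == "causal":
            if np.any((a < 0) | (a > 1)):
                raise ValueError("causal weights must lie in [0, 1]")
        self.adjacency = a

    @property
    def n_events(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class CausalJudgmentSet:
    """Per-coder sets of unordered causally-related event pairs (one movie)."""

    movie: str
    n_events: int
    judgments: dict[str, set[frozenset]] = field(default_factory=dict)

    def __post_init__(self):
        for coder, pairs in self.judgments.items():
            norm = set()
            for pair in pairs:
                i, j = sorted(pair)
                if i == j:
                    raise ValueError(f"coder {coder}: self-pair ({i},{j})")
                if i < 0 or j >= self.n_events:
                    raise ValueError(f"coder {coder}: pair ({i},{j}) outside "
                                     f"[0, {self.n_events - 1}]")
                norm.add(frozenset((i, j)))
            self.judgments[coder] = norm

    @property
    def n_coders(self) -> int:
        return len(self.judgments)


def build_semantic_network(sim: SimilarityMatrix) -> NarrativeNetwork:
    """Semantic narrative network: the cosine matrix with a zeroed diagonal.

    Edges are unthresholded and undirected; negative cosines are kept
    (thresholding is a visualization device, not part of the analysis).
    """
    a = np.array(sim.matrix, dtype=float)
    if np.isnan(a).any():
        raise ValueError("semantic network requires a complete similarity matrix")
    np.fill_diagonal(a, 0.0)
    return NarrativeNetwork(movie=sim.movie, adjacency=a, kind="semantic")


def build_causal_network(judgments: CausalJudgmentSet) -> NarrativeNetwork:
    """Causal narrative network: edge weight = fraction of coders listing the pair.

    Undirected — a pair counts regardless of which event was the cause.
    Weights are rational with denominator ``n_coders``.
    """
    if judgments.n_coders < 1:
        raise ValueError("need at least one coder")
    n = judgments.n_events
    counts = np.zeros((n, n))
    for pairs in judgments.judgments.values():
        for pair in pairs:
            i, j = sorted(pair)
            counts[i, j] += 1.0
            counts[j, i] += 1.0
    adj = counts / judgments.n_coders
    return NarrativeNetwork(movie=judgments.movie, adjacency=adj, kind="causal",
                            n_raters=judgments.n_coders)


def compute_centrality(net: NarrativeNetwork) -> pd.DataFrame:
    """Weighted degree centrality, normalized and z-scored within the movie.

    raw_degree_i = sum_j w_ij; normalized = raw / sum(raw); z uses the
    sample standard deviation (ddof=1). Raises on networks with fewer than
    3 events or all-equal degrees (z undefined).
    """
    if net.n_events < 3:
        raise ValueError("centrality needs at least 3 events")
    raw = net.adjacency.sum(axis=1)
    total = raw.sum()
    if total == 0:
        raise ValueError("degenerate centrality: degree sum is 0")
    normalized = raw / total
    sd = normalized.std(ddof=1)
    if sd == 0 or np.isclose(sd, 0.0, atol=1e-15):
        raise ValueError("degenerate centrality: all degrees equal")
    z = (normalized - normalized.mean()) / sd
    return pd.DataFrame({
        "movie": net.movie,
        "event": np.arange(net.n_events),
        "raw_degree": raw,
        "normalized_degree": normalized,
        "z_centrality": z,
        "condition": "none",
    })


def split_high_low(cent: pd.DataFrame,
                   fraction: float = DEFAULT_SPLIT_FRACTION) -> pd.DataFrame:
    """Label the top/bottom ``fraction`` of events per movie as high/low.

    k = floor(fraction * M) events with the largest (smallest) z-centrality
    become 'high' ('low'); the rest are 'middle'. Ties at the boundary go
    to the earlier event index (stable, deterministic).
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    out = cent.copy()
    out["condition"] = "middle"
    for movie, sub in cent.groupby("movie", sort=False):
        m = len(sub)
        k = int(np.floor(fraction * m))
        if k == 0:
            raise ValueError(f"movie {movie}: floor({fraction} * {m}) = 0 events per condition")
        z = sub["z_centrality"].to_numpy()
        idx = sub.index.to_numpy()
        order_desc = np.argsort(-z, kind="stable")  # ties -> earlier index first
        order_asc = np.argsort(z, kind="stable")
        high = idx[order_desc[:k]]
        low = [i for i in idx[order_asc] if i not in set(high)][:k]
        out.loc[high, "condition"] = "high"
        out.loc[low, "condition"] = "low"
    return out


def partial_centrality(net: NarrativeNetwork, upto_event: int) -> pd.DataFrame:
    """Centrality from the network restricted to events 0..upto_event.

    Emulates the information available to a viewer mid-movie: edges to
    not-yet-presented events are excluded.
    """
    if upto_event < 2:
        raise ValueError("partial centrality needs upto_event >= 2 (>=3 events)")
    if upto_event >= net.n_events:
        raise ValueError(f"upto_event {upto_event} outside network of {net.n_events} events")
    sub = NarrativeNetwork(movie=net.movie,
                           adjacency=net.adjacency[:upto_event + 1, :upto_event + 1],
                           kind=net.kind, n_raters=net.n_raters)
    return compute_centrality(sub)


def coder_jaccard(judgments: CausalJudgmentSet | list[CausalJudgmentSet]) -> float:
    """Mean pairwise Jaccard similarity between coders' causal-pair sets.

    For one movie: |A∩B| / |A∪B| over all coder pairs, averaged. For a
    list of movies: the mean over movies of the per-movie means. Pairs of
    two empty sets are undefined and excluded with a warning.
    """
    if isinstance(judgments, CausalJudgmentSet):
        movies = [judgments]
    else:
        movies = list(judgments)
    movie_means = []
    for js in movies:
        coders = sorted(js.judgments)
        if len(coders) < 2:
            raise ValueError(f"movie {js.movie}: need at least two coders")
        vals = []
        for i in range(len(coders)):
            for j in range(i + 1, len(coders)):
                a, b = js.judgments[coders[i]], js.judgments[coders[j]]
                union = a | b
                if not union:
                    warnings.warn(f"movie {js.movie}: coders {coders[i]},{coders[j]} "
                                  "both empty; pair excluded")
                    continue
                vals.append(len(a & b) / len(union))
        if vals:
            movie_means.append(float(np.mean(vals)))
    if not movie_means:
        raise ValueError("no defined coder pairs")
    return float(np.mean(movie_means))


def _highlow_cross_movie_diff(matrices, highs, lows):
    """Mean corr(high_A, high_B) - mean corr(high_A, low_B) across movie pairs."""
    hh, hl = [], []
    n_movies = len(matrices)
    for a in range(n_movies):
        for b in range(n_movies):
            if a == b:
                continue
            ha = matrices[a][highs[a]]
            hb = matrices[b][highs[b]]
            lb = matrices[b][lows[b]]
            # Pearson correlation between embedding vectors of event pairs
            hh.append(_rowwise_corr_mean(ha, hb))
            hl.append(_rowwise_corr_mean(ha, lb))
    return float(np.mean(hh) - np.mean(hl))


def _rowwise_corr_mean(A, B):
    """Mean Pearson correlation over all row pairs of A (n x D) and B (m x D)."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    Ac /= np.linalg.norm(Ac, axis=1, keepdims=True)
    Bc /= np.linalg.norm(Bc, axis=1, keepdims=True)
    return float(np.mean(Ac @ Bc.T))


def cross_movie_highlow_test(
    embeddings: dict[str, EmbeddingMatrix],
    labels: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, PermutationResult]:
    """Do high-centrality events share semantics across movies?

    Computes the mean Pearson correlation between high-centrality event
    vectors of different movies minus the mean correlation between one
    movie's high- and another movie's low-centrality vectors. The null
    shuffles the high/low labels within each movie; the p-value is
    two-tailed. Movies lacking one of the conditions are excluded with a
    warning.
    """
    rng = np.random.default_rng(seed)
    matrices, highs, lows = [], [], []
    for movie, sub in labels.groupby("movie", sort=True):
        movie = str(movie)
        if movie not in embeddings:
            raise ValueError(f"no embeddings for movie {movie}")
        hi = sub.loc[sub["condition"] == "high", "event"].to_numpy(dtype=int)
        lo = sub.loc[sub["condition"] == "low", "event"].to_numpy(dtype=int)
        if hi.size == 0 or lo.size == 0:
            warnings.warn(f"movie {movie} lacks a high or low condition; excluded")
            continue
        matrices.append(np.asarray(embeddings[movie].matrix, dtype=float))
        highs.append(hi)
        lows.append(lo)
    if len(matrices) < 2:
        raise ValueError("need at least two movies with both conditions")
    observed = _highlow_cross_movie_diff(matrices, highs, lows)
    null = np.empty(n_perm)
    for b in range(n_perm):
        ph, pl = [], []
        for hi, lo in zip(highs, lows):
            pool = np.concatenate([hi, lo])
            perm = rng.permutation(pool)
            ph.append(perm[:hi.size])
            pl.append(perm[hi.size:])
        null[b] = _highlow_cross_movie_diff(matrices, ph, pl)
    # extremity relative to the null's own center: the shuffled statistic
    # is mean-zero by construction
    res = permutation_pvalue(observed, null, tail="two-tailed", seed=seed)
    return observed, res
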