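"""Event text embeddings and similarity matrices.

Per-annotator sub-event descriptions are concatenated into one text per
movie event, encoded into fixed-length vectors through a pluggable encoder
protocol, averaged across annotators, and turned into cosine similarity
matrices — the substrate of the semantic narrative network.

The bundled :class:`HashingStubEncoder` is a deterministic, download-free
sentence encoder stand-in: a hashed bag of tokens projected to ``dim``
dimensions by a seeded random matrix and unit-normalized. It preserves the
properties the pipeline relies on (fixed dimension, determinism, similar
texts -> similar vectors) without any pretrained weights. A real sentence
encoder (e.g. a 512-d universal sentence embedding model) can be plugged
in through the same ``encode`` interface.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EmbeddingMatrix",
    "SimilarityMatrix",
    "TextEncoder",
    "HashingStubEncoder",
    "build_event_texts",
    "encode_events",
    "average_embeddings",
    "cosine_similarity_matrix",
    "cross_annotator_consistency",
    "recall_similarity_matrix",
]

DEFAULT_EMBEDDING_DIM = 512

ANNOTATION_COLUMNS = ["movie", "event", "annotator", "subevent", "text"]


@dataclass
class EmbeddingMatrix:
    """Events x D embedding matrix for one movie.

    ``source`` is an annotator id, ``"averaged"``, or ``"recall"``.
    """

    movie: str
    matrix: np.ndarray
    source: str = "averaged"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("embedding matrix must be 2-D (events x D)")
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding matrix contains non-finite values")

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SimilarityMatrix:
    """Symmetric events x events similarity matrix (cosine, in [-1, 1])."""

    movie: str
    matrix: np.ndarray
    kind: str = "semantic"  # semantic | recall-derived

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("similarity matrix must be square")
        finite = np.isfinite(m)
        if np.nanmax(np.abs(np.where(finite, m - m.T, 0.0))) > 1e-12:
            raise ValueError("similarity matrix must be symmetric within 1e-12")

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]


class TextEncoder(Protocol):
    """Anything mapping a list of texts to a (len(texts), dim) float array."""

    def encode(self, texts: Sequence[str]) -> np.ndarray: ...


def _tokenize(text: str) -> list[str]:
    """Lowercase, split on non-alphanumerics, drop empties (pinned rules)."""
    out, cur = [], []
    for ch in text.lower():
        if ch.isalnum():
            cur.append(ch)
        elif cur:
            out.append("".join(cur))
            cur = []
    if cur:
        out.append("".join(cur))
    return out


class HashingStubEncoder:
    """Deterministic offline encoder: hashed bag-of-tokens projection.

    Every token gets a fixed pseudo-random Gaussian direction seeded from
    its MD5 hash (platform-independent) and the encoder seed; a text maps
    to the token-count-weighted sum of those directions, unit-normalized.
    Identical texts always map to identical unit vectors; texts with
    disjoint vocabulary are nearly orthogonal in expectation (inner
    products of independent random directions, sd ~ 1/sqrt(dim)).
    """

    def __init__(self, dim: int = DEFAULT_EMBEDDING_DIM, seed: int = 20220513):
        self.dim = int(dim)
        self.seed = int(seed)
        self._token_cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._token_cache.get(token)
        if vec is None:
            h = hashlib.md5(token.encode("utf-8")).digest()
            key = int.from_bytes(h[:8], "little")
            rng = np.random.default_rng((self.seed, key))
            vec = rng.standard_normal(self.dim) / np.sqrt(self.dim)
            self._token_cache[token] = vec
        return vec

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dim))
        for i, text in enumerate(texts):
            v = np.zeros(self.dim)
            tokens = _tokenize(text)
            for tok in tokens:
                v += self._token_vector(tok)
            if not tokens:
                # tokenless text: fixed fallback direction so no row is
                # all-zero (flagged by similarity checks downstream)
                v = self._token_vector("")
            out[i] = v / np.linalg.norm(v)
        return out


def build_event_texts(annotations: pd.DataFrame) -> pd.DataFrame:
    """Concatenate sub-event descriptions into one text per (event, annotator).

    ``annotations`` needs columns movie, event, annotator, subevent, text.
    Sub-event texts are joined in sub-event order with single spaces.
    Raises if any (movie, event) pair is missing for some annotator.
    """
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing_cols:
        raise ValueError(f"annotations missing columns: {missing_cols}")
    df = annotations.sort_values(["movie", "event", "annotator", "subevent"])
    texts = (df.groupby(["movie", "event", "annotator"], sort=True)["text"]
               .agg(" ".join).reset_index())
    # every annotator of a movie must cover every event of that movie
    gaps = []
    for movie, sub in texts.groupby("movie"):
        events = sorted(sub["event"].unique())
        annotators = sorted(sub["annotator"].unique())
        have = set(zip(sub["event"], sub["annotator"]))
        for e in events:
            for a in annotators:
                if (e, a) not in have:
                    gaps.append((movie, int(e), a))
    if gaps:
        raise ValueError(f"missing (movie, event, annotator) annotations: {gaps}")
    return texts


def encode_events(texts: pd.DataFrame, encoder: TextEncoder,
                  movie: str | None = None,
                  annotator: str | None = None) -> EmbeddingMatrix:
    """Encode one movie's per-event texts (one annotator) into a matrix.

    ``texts`` is the output of :func:`build_event_texts`, optionally
    pre-filtered; ``movie`` / ``annotator`` filter it here instead.
    Rows follow event order (event ids must be contiguous from 0).
    """
    df = texts
    if movie is not None:
        df = df[df["movie"] == movie]
    if annotator is not None:
        df = df[df["annotator"] == annotator]
    if df.empty:
        raise ValueError("no texts to encode after filtering")
    movies = df["movie"].unique()
    annotators = df["annotator"].unique()
    if len(movies) != 1 or len(annotators) != 1:
        raise ValueError("encode_events expects exactly one movie and one annotator; "
                         f"got movies={list(movies)} annotators={list(annotators)}")
    df = df.sort_values("event")
    events = df["event"].to_numpy()
    if not np.array_equal(events, np.arange(len(events))):
        raise ValueError(f"event ids must be contiguous from 0, got {events}")
    mat = np.asarray(encoder.encode(list(df["text"])), dtype=float)
    if mat.ndim != 2 or mat.shape[0] != len(events):
        raise ValueError("encoder returned a wrong-shaped matrix")
    return EmbeddingMatrix(movie=str(movies[0]), matrix=mat, source=str(annotators[0]))


def average_embeddings(per_annotator: Sequence[EmbeddingMatrix]) -> EmbeddingMatrix:
    """Element-wise mean of per-annotator embeddings (vector averaging)."""
    if not per_annotator:
        raise ValueError("need at least one embedding matrix")
    shapes = {m.matrix.shape for m in per_annotator}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch across annotators: {sorted(shapes)}")
    movies = {m.movie for m in per_annotator}
    if len(movies) != 1:
        raise ValueError(f"cannot average across movies: {sorted(movies)}")
    mean = np.mean([m.matrix for m in per_annotator], axis=0)
    return EmbeddingMatrix(movie=per_annotator[0].movie, matrix=mean, source="averaged")


def cosine_similarity_matrix(emb: EmbeddingMatrix,
                             kind: str = "semantic") -> SimilarityMatrix:
    """Pairwise cosine similarity between event embedding rows."""
    norms = np.linalg.norm(emb.matrix, axis=1)
    bad = np.flatnonzero(norms == 0.0)
    if bad.size:
        raise ValueError(f"zero-norm embedding rows for events {bad.tolist()} "
                         f"(movie {emb.movie})")
    unit = emb.matrix / norms[:, None]
    sim = unit @ unit.T
    sim = 0.5 * (sim + sim.T)  # kill asymmetry at floating-point level
    np.fill_diagonal(sim, 1.0)
    np.clip(sim, -1.0, 1.0, out=sim)
    return SimilarityMatrix(movie=emb.movie, matrix=sim, kind=kind)


def cross_annotator_consistency(per_annotator: Sequence[EmbeddingMatrix]) -> float:
    """Mean event-wise cosine similarity over all annotator pairs.

    For every pair of annotators, the cosine between their matching-event
    rows is averaged over events; the result is the mean over pairs.
    """
    if len(per_annotator) < 2:
        raise ValueError("need at least two annotators")
    shapes = {m.matrix.shape for m in per_annotator}
    if len(shapes) != 1:
        raise ValueError("shape mismatch across annotators")
    units = []
    for m in per_annotator:
        norms = np.linalg.norm(m.matrix, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm embedding row")
        units.append(m.matrix / norms[:, None])
    vals = []
    for i in range(len(units)):
        for j in range(i + 1, len(units)):
            vals.append(np.mean(np.sum(units[i] * units[j], axis=1)))
    return float(np.mean(vals))


def recall_similarity_matrix(
    recall_embeddings: dict[str, tuple[np.ndarray, np.ndarray]],
    n_events: int,
    movie: str = "",
) -> SimilarityMatrix:
    """Participant-averaged cosine similarity between recalled-event texts.

    Parameters
    ----------
    recall_embeddings : dict participant -> (event_ids, matrix)
        For each participant, the ids of the events they recalled (within
        one movie) and the corresponding embedding rows.
    n_events : int
        Number of events in the movie; cells never jointly recalled stay
        NaN and are dropped from downstream RSA.

    Each participant contributes a cosine matrix over their own recalled
    events; cells are averaged over contributing participants with a plain
    (unweighted) mean, so the per-cell participant count varies.
    """
    total = np.zeros((n_events, n_events))
    count = np.zeros((n_events, n_events))
    for participant, (event_ids, mat) in recall_embeddings.items():
        event_ids = np.asarray(event_ids, dtype=int)
        mat = np.asarray(mat, dtype=float)
        if event_ids.size == 0:
            continue
        if event_ids.min() < 0 or event_ids.max() >= n_events:
            raise ValueError(f"participant {participant}: event attribution outside "
                             f"[0, {n_events - 1}]")
        if mat.shape[0] != event_ids.size:
            raise ValueError(f"participant {participant}: embedding rows do not "
                             "match recalled events")
        norms = np.linalg.norm(mat, axis=1)
        if np.any(norms == 0):
            raise ValueError(f"participant {participant}: zero-norm recall embedding")
        unit = mat / norms[:, None]
        sim = unit @ unit.T
        ix = np.ix_(event_ids, event_ids)
        total[ix] += sim
        count[ix] += 1.0
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    mean = np.where(count > 0, mean, np.nan)
    return SimilarityMatrix(movie=movie, matrix=mean, kind="recall-derived")
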