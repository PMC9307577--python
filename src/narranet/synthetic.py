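"""Seeded synthetic-data generators with planted ground truth.

Every pipeline stage can be exercised without any download: the
generators emulate the structure of a movie-watching / free-recall study
— ~10 movies of ~20 events annotated by 3 annotators, causal judgments
from 13 coders, 15 participants whose binary event recall follows a
logistic model on semantic and causal centrality with participant and
movie random intercepts, and ROI "neural" data with event-specific
shared signal whose strength is modulated by centrality, hippocampus-like
post-offset boundary responses, and centrality-coupled intersubject
functional connectivity.

Event similarity structure is planted directly in embedding space (each
event vector mixes a movie-level topic direction with an event-specific
direction; "hub" events load more on the topic, giving them elevated
pairwise cosine and hence centrality). A text mode through the stub
encoder exists for I/O testing but the embedding-space path is primary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import RecallMatrix
from .embedding import EmbeddingMatrix
from .network import CausalJudgmentSet
from .neural import EventPatternSet, RoiTimeSeries

__all__ = [
    "GeneratorConfig",
    "NarrativeData",
    "NeuralData",
    "generate_narrative",
    "generate_events",
    "generate_recall",
    "generate_neural",
    "generate_media",
]


@dataclass
class GeneratorConfig:
    """Study-scale defaults for every generator.

    Counts mirror the emulated study design (10 movies x ~20 events, 3
    annotators, 13 causal coders, 15 analyzed participants, 512-d
    embeddings, TR = 1.5 s); recall coefficients default to the
    centrality effects the recall model is built around (semantic .17,
    causal .38 on the z-centrality scale).
    """

    n_movies: int = 10
    events_per_movie: int = 20
    n_annotators: int = 3
    n_coders: int = 13
    n_participants: int = 15
    embedding_dim: int = 512
    tr_s: float = 1.5
    hemodynamic_shift: int = 3
    seed: int = 0

    # semantic structure: event vector = s*topic + sqrt(1-s^2)*specific;
    # hub events draw s near s_hi, others near s_lo
    hub_fraction: float = 0.4
    topic_loading_low: float = 0.25
    topic_loading_high: float = 0.75
    annotator_noise: float = 0.53     # targets cross-annotator cosine ~ .78
    cross_movie_high_strength: float = 0.0  # shared direction added to hub events

    # causal judgments: mostly sparse and adjacent
    causal_adjacent_prob: float = 0.70
    causal_base_prob: float = 0.03
    causal_topic_gain: float = 0.06   # couples causal to semantic structure

    # recall model (logit scale)
    recall_intercept: float = 1.45    # overall recall ~ .78
    beta_semantic: float = 0.17
    beta_causal: float = 0.38
    sd_participant: float = 0.5
    sd_movie: float = 0.3
    event_swap_prob: float = 0.45     # adjacent transpositions; order rho ~ .97
    movie_order_noise: float = 3.5    # movie recall order jitter; rho ~ .5

    # neural patterns: participant pattern = sqrt(rho)*template + sqrt(1-rho)*noise;
    # rho = clip(base + slope * z_centrality)
    n_features: int = 100
    regions: dict = field(default_factory=lambda: {
        "pmc": {"movie": (0.12, 0.008), "recall": (0.06, 0.008)},
        "evc": {"movie": (0.30, -0.006), "recall": (0.01, -0.006)},
    })

    # event durations (TRs) and run padding for time-series phases
    event_duration_trs: tuple[int, int] = (6, 16)
    run_pad_start_trs: int = 6
    run_pad_end_trs: int = 22

    # hippocampus-like boundary responses: amplitude = alpha0 + alpha1 * z
    boundary_alpha0: float = 0.3
    boundary_alpha1: float = 0.15
    boundary_kernel_peak_trs: float = 11.5
    boundary_kernel_sd_trs: float = 1.5
    hippo_noise_sd: float = 1.0

    # ISFC coupling: region-B shared-signal fraction = clip(base + slope * z)
    isfc_shared_a: float = 0.5
    isfc_base: float = 0.3
    isfc_slope: float = 0.1
    isfc_noise_floor: float = 0.05

    def __post_init__(self):
        if not 0 < self.hub_fraction < 1:
            raise ValueError("hub fraction must lie in (0, 1)")
        for region, phases in self.regions.items():
            for phase, (base, slope) in phases.items():
                if not 0 <= base <= 1:
                    raise ValueError(f"{region}/{phase}: shared-signal fraction "
                                     "outside [0, 1]")
        if self.n_movies < 2 or self.events_per_movie < 5:
            raise ValueError("need >=2 movies and >=5 events per movie")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


@dataclass
class NarrativeData:
    """Planted narrative structure for one synthetic study."""

    config: GeneratorConfig
    embeddings: dict[str, dict[str, EmbeddingMatrix]]  # movie -> annotator -> matrix
    averaged: dict[str, EmbeddingMatrix]
    judgments: dict[str, CausalJudgmentSet]
    truth: pd.DataFrame  # movie, event, topic_loading, is_hub
    annotations: pd.DataFrame | None = None  # text mode only

    @property
    def movies(self) -> list[str]:
        return sorted(self.embeddings)


@dataclass
class NeuralData:
    """Synthetic ROI data: event patterns plus boundary/ISFC time series."""

    events: pd.DataFrame  # movie, event, onset_s, offset_s
    patterns: dict[tuple[str, str], EventPatternSet]  # (region, phase) -> set
    hippocampus: dict[str, RoiTimeSeries]
    region_a: dict[str, RoiTimeSeries]
    region_b: dict[str, RoiTimeSeries]


def _movie_ids(cfg: GeneratorConfig) -> list[str]:
    return [f"m{i:02d}" for i in range(cfg.n_movies)]


def _participant_ids(cfg: GeneratorConfig) -> list[str]:
    return [f"p{i:02d}" for i in range(cfg.n_participants)]


def generate_narrative(cfg: GeneratorConfig, with_text: bool = False) -> NarrativeData:
    """Plant semantic and causal structure for every movie.

    Event embeddings mix a movie topic direction with event-specific
    directions; a hub subset gets elevated topic loading, hence elevated
    pairwise cosine and centrality. Per-annotator matrices are noisy
    copies of the latent event vectors. Causal judgments are sampled per
    coder with inclusion probability elevated for adjacent events and
    mildly coupled to the semantic structure.
    """
    rng = cfg.rng(1)
    D = cfg.embedding_dim
    cross_dir = _unit(rng.standard_normal(D))
    embeddings: dict[str, dict[str, EmbeddingMatrix]] = {}
    averaged: dict[str, EmbeddingMatrix] = {}
    judgments: dict[str, CausalJudgmentSet] = {}
    truth_rows = []
    ann_rows = []
    n_hub = max(1, int(round(cfg.hub_fraction * cfg.events_per_movie)))
    for movie in _movie_ids(cfg):
        E = cfg.events_per_movie
        topic = _unit(rng.standard_normal(D))
        hubs = rng.choice(E, size=n_hub, replace=False)
        is_hub = np.zeros(E, dtype=bool)
        is_hub[hubs] = True
        loading = np.where(
            is_hub,
            cfg.topic_loading_high + 0.05 * rng.standard_normal(E),
            cfg.topic_loading_low + 0.05 * rng.standard_normal(E),
        )
        loading = np.clip(loading, 0.05, 0.95)
        latent = np.empty((E, D))
        for e in range(E):
            specific = _unit(rng.standard_normal(D))
            v = loading[e] * topic + np.sqrt(1 - loading[e] ** 2) * specific
            if cfg.cross_movie_high_strength > 0 and is_hub[e]:
                v = v + cfg.cross_movie_high_strength * cross_dir
            latent[e] = _unit(v)
        per_ann = {}
        for a in range(cfg.n_annotators):
            noisy = latent + cfg.annotator_noise * rng.standard_normal((E, D)) / np.sqrt(D)
            noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
            per_ann[f"a{a}"] = EmbeddingMatrix(movie=movie, matrix=noisy, source=f"a{a}")
        embeddings[movie] = per_ann
        averaged[movie] = EmbeddingMatrix(
            movie=movie,
            matrix=np.mean([m.matrix for m in per_ann.values()], axis=0),
            source="averaged")
        # causal judgments
        pair_prob = {}
        for i in range(E):
            for j in range(i + 1, E):
                p = cfg.causal_base_prob + cfg.causal_topic_gain * loading[i] * loading[j]
                if j == i + 1:
                    p += cfg.causal_adjacent_prob
                pair_prob[(i, j)] = min(1.0, p)
        coder_sets = {}
        for c in range(cfg.n_coders):
            chosen = {frozenset(pair) for pair, p in pair_prob.items()
                      if rng.random() < p}
            coder_sets[f"c{c:02d}"] = chosen
        judgments[movie] = CausalJudgmentSet(movie=movie, n_events=E,
                                             judgments=coder_sets)
        for e in range(E):
            truth_rows.append({"movie": movie, "event": e,
                               "topic_loading": loading[e], "is_hub": bool(is_hub[e])})
        if with_text:
            for a in range(cfg.n_annotators):
                for e in range(E):
                    n_sub = int(rng.integers(1, 4))
                    for s in range(n_sub):
                        words = [f"w{int(w)}" for w in
                                 rng.integers(0, 500, size=int(rng.integers(4, 10)))]
                        ann_rows.append({"movie": movie, "event": e,
                                         "annotator": f"a{a}", "subevent": s,
                                         "text": " ".join(words)})
    return NarrativeData(config=cfg, embeddings=embeddings, averaged=averaged,
                         judgments=judgments, truth=pd.DataFrame(truth_rows),
                         annotations=pd.DataFrame(ann_rows) if with_text else None)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_events(cfg: GeneratorConfig) -> pd.DataFrame:
    """Event table with onsets/offsets (seconds) and one run per movie.

    Within each movie's run, events are contiguous; the run starts
    ``run_pad_start_trs`` TRs before the first event and extends
    ``run_pad_end_trs`` TRs beyond the last offset (room for the
    hemodynamic shift and post-offset windows). Returns columns movie,
    event, onset_s, offset_s, run_start_tr, run_stop_tr.
    """
    rng = cfg.rng(2)
    rows = []
    tr_cursor = 0
    lo, hi = cfg.event_duration_trs
    for movie in _movie_ids(cfg):
        run_start = tr_cursor
        t = run_start + cfg.run_pad_start_trs
        for e in range(cfg.events_per_movie):
            dur = int(rng.integers(lo, hi + 1))
            rows.append({"movie": movie, "event": e,
                         "onset_s": t * cfg.tr_s,
                         "offset_s": (t + dur) * cfg.tr_s})
            t += dur
        run_stop = t + cfg.run_pad_end_trs
        for r in rows:
            if r["movie"] == movie:
                r["run_start_tr"] = run_start
                r["run_stop_tr"] = run_stop
        tr_cursor = run_stop
    return pd.DataFrame(rows)


def generate_recall(cfg: GeneratorConfig, cent_semantic: pd.DataFrame,
                    cent_causal: pd.DataFrame,
                    with_order: bool = True) -> RecallMatrix:
    """Binary event recall from the planted logistic model, plus order.

    P(recall) = logistic(b0 + b_sem*z_sem + b_cau*z_cau + u_participant +
    u_movie), u ~ Normal with the configured SDs. Recall order follows
    presentation order with occasional adjacent transpositions within
    movies and jittered movie order (skipped with ``with_order=False``
    for analyses that only need the binary matrix).
    """
    rng = cfg.rng(3)
    sem = cent_semantic.set_index(["movie", "event"])["z_centrality"].sort_index()
    cau = cent_causal.set_index(["movie", "event"])["z_centrality"].sort_index()
    cols = pd.MultiIndex.from_tuples(sorted(sem.index), names=["movie", "event"])
    movies = sorted({m for m, _ in cols})
    participants = _participant_ids(cfg)
    u_p = rng.normal(0, cfg.sd_participant, size=len(participants))
    u_m_vals = rng.normal(0, cfg.sd_movie, size=len(movies))
    u_m = dict(zip(movies, u_m_vals))
    event_eta = (cfg.recall_intercept
                 + cfg.beta_semantic * sem.loc[cols].to_numpy()
                 + cfg.beta_causal * cau.loc[cols].to_numpy()
                 + np.array([u_m[m] for m, _ in cols]))
    eta = u_p[:, None] + event_eta[None, :]
    prob = 1.0 / (1.0 + np.exp(-eta))
    rec = (rng.random(eta.shape) < prob).astype(int)
    recalled = pd.DataFrame(rec, index=participants, columns=cols)
    order: dict[str, list[tuple[str, int]]] = {}
    if with_order:
        events_by_movie = {m: [e for (mm, e) in cols if mm == m] for m in movies}
        for pi, p in enumerate(participants):
            keys = (np.arange(len(movies))
                    + cfg.movie_order_noise * rng.standard_normal(len(movies)))
            movie_order = [movies[i] for i in np.argsort(keys, kind="stable")]
            seq: list[tuple[str, int]] = []
            for m in movie_order:
                events = sorted(e for e in events_by_movie[m]
                                if rec[pi, cols.get_loc((m, e))] == 1)
                i = 0
                while i < len(events) - 1:  # adjacent transpositions
                    if rng.random() < cfg.event_swap_prob:
                        events[i], events[i + 1] = events[i + 1], events[i]
                        i += 2
                    else:
                        i += 1
                seq.extend((m, e) for e in events)
            order[p] = seq
    return RecallMatrix(recalled=recalled, order=order, validate=with_order)


def _boundary_kernel(cfg: GeneratorConfig) -> np.ndarray:
    """Smooth lag kernel peaking ~11.5 TRs (~17 s) after the boundary."""
    lags = np.arange(0, 16)
    k = np.exp(-0.5 * ((lags - cfg.boundary_kernel_peak_trs)
                       / cfg.boundary_kernel_sd_trs) ** 2)
    return k


def generate_neural(cfg: GeneratorConfig, cent: pd.DataFrame,
                    recall: RecallMatrix,
                    events: pd.DataFrame | None = None) -> NeuralData:
    """Synthetic ROI data with centrality-modulated shared signal.

    For each region and phase, every event has a shared template pattern;
    a participant's pattern is sqrt(rho)*template + sqrt(1-rho)*noise with
    rho = clip(base + slope*z_centrality). The hippocampus-like channel
    carries post-offset responses of amplitude alpha0 + alpha1*z convolved
    with a smooth lag kernel peaking ~10-13 TRs after each offset. Two
    extra 1-D channels plant ISFC coupling increasing with centrality.
    Recall-phase patterns exist only for recalled events.
    """
    rng = cfg.rng(4)
    if events is None:
        events = generate_events(cfg)
    z = cent.set_index(["movie", "event"])["z_centrality"]
    ev = events.sort_values(["movie", "event"]).reset_index(drop=True)
    participants = _participant_ids(cfg)
    E = len(ev)
    F = cfg.n_features
    recalled_sets = {
        p: {(m, e) for (m, e) in recall.recalled.columns
            if recall.recalled.loc[p, (m, e)] == 1}
        for p in participants}

    patterns: dict[tuple[str, str], EventPatternSet] = {}
    for region, phases in cfg.regions.items():
        for phase, (base, slope) in phases.items():
            data = np.full((len(participants), E, F), np.nan)
            templates = rng.standard_normal((E, F))
            for ei, row in ev.iterrows():
                rho = float(np.clip(base + slope * z[(row["movie"], int(row["event"]))],
                                    0.0, 1.0))
                for pi, p in enumerate(participants):
                    if phase == "recall" and (row["movie"], int(row["event"])) \
                            not in recalled_sets[p]:
                        continue
                    noise = rng.standard_normal(F)
                    data[pi, ei] = np.sqrt(rho) * templates[ei] + np.sqrt(1 - rho) * noise
            patterns[(region, phase)] = EventPatternSet(
                data=data, participants=participants,
                events=ev[["movie", "event"]].copy(), phase=phase)

    # time-series channels
    total_trs = int(ev["run_stop_tr"].max())
    runs = sorted({(int(r["run_start_tr"]), int(r["run_stop_tr"]))
                   for _, r in ev.iterrows()})
    kernel = _boundary_kernel(cfg)
    # shared per-event stimulus signal for ISFC
    shared = {}
    for _, row in ev.iterrows():
        on = int(round(row["onset_s"] / cfg.tr_s)) + cfg.hemodynamic_shift
        off = int(round(row["offset_s"] / cfg.tr_s)) + cfg.hemodynamic_shift
        shared[(row["movie"], int(row["event"]))] = (on, off, rng.standard_normal(off - on))

    hippocampus, region_a, region_b = {}, {}, {}
    for p in participants:
        hip = cfg.hippo_noise_sd * rng.standard_normal(total_trs)
        a_ts = np.zeros(total_trs)
        b_ts = np.zeros(total_trs)
        for _, row in ev.iterrows():
            key = (row["movie"], int(row["event"]))
            zval = float(z[key])
            off_tr = int(round(row["offset_s"] / cfg.tr_s)) + cfg.hemodynamic_shift
            amp = cfg.boundary_alpha0 + cfg.boundary_alpha1 * zval
            hi = min(total_trs, off_tr + kernel.size)
            hip[off_tr:hi] += amp * kernel[:hi - off_tr]
            on, off, sig = shared[key]
            ra = cfg.isfc_shared_a
            rb = float(np.clip(cfg.isfc_base + cfg.isfc_slope * zval,
                               cfg.isfc_noise_floor, 0.95))
            a_ts[on:off] += np.sqrt(ra) * sig
            b_ts[on:off] += np.sqrt(rb) * sig
        a_ts += np.sqrt(1 - cfg.isfc_shared_a) * rng.standard_normal(total_trs)
        b_ts += rng.standard_normal(total_trs) * np.sqrt(1 - cfg.isfc_base)
        hippocampus[p] = RoiTimeSeries(participant=p, values=hip, roi="hippocampus",
                                       tr_s=cfg.tr_s, shift=cfg.hemodynamic_shift,
                                       runs=runs)
        region_a[p] = RoiTimeSeries(participant=p, values=a_ts, roi="region_a",
                                    tr_s=cfg.tr_s, shift=cfg.hemodynamic_shift,
                                    runs=runs)
        region_b[p] = RoiTimeSeries(participant=p, values=b_ts, roi="region_b",
                                    tr_s=cfg.tr_s, shift=cfg.hemodynamic_shift,
                                    runs=runs)
    return NeuralData(events=ev, patterns=patterns, hippocampus=hippocampus,
                      region_a=region_a, region_b=region_b)


def generate_media(cfg: GeneratorConfig, cent: pd.DataFrame | None = None,
                   planted_dependence: float = 0.0,
                   n_frames: int = 3, frame_shape: tuple[int, int] = (16, 16),
                   audio_s: float = 1.0, sample_rate_hz: float = 8000.0
                   ) -> dict[str, "MediaArrays"]:
    """Decoded media arrays per movie, by default independent of centrality.

    With ``planted_dependence`` > 0, luminance gains a linear term in the
    event's z-centrality (per unit z, in pixel-intensity units) so the
    control test has a positive case. Returns a dict movie -> MediaArrays.
    """
    from .stimulus import MediaArrays

    rng = cfg.rng(5)
    E = cfg.events_per_movie
    out = {}
    for movie in _movie_ids(cfg):
        zvals = np.zeros(E)
        if cent is not None:
            sub = cent[cent["movie"] == movie].set_index("event")["z_centrality"]
            zvals = np.array([sub.get(e, 0.0) for e in range(E)])
        frames, audio = [], []
        for e in range(E):
            base_lum = 110 + 15 * rng.standard_normal() + planted_dependence * zvals[e]
            spread = 30 + 10 * rng.random()
            fl = []
            for _ in range(n_frames):
                img = base_lum + spread * (rng.random(frame_shape) - 0.5)
                fl.append(np.clip(img, 0, 255))
            frames.append(fl)
            n_samp = int(audio_s * sample_rate_hz)
            gain = 40 + 10 * rng.random()
            audio.append(gain * (rng.random(n_samp) - 0.5))
        out[movie] = MediaArrays(movie=movie, frames=frames, audio=audio,
                                 sample_rate_hz=sample_rate_hz)
    return out
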