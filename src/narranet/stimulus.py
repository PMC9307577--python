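"""Low-level audiovisual features of movie events and the control test.

A memorability effect of centrality could in principle be confounded by
low-level sensory properties of events. This module computes per-event
luminance, visual contrast, and auditory amplitude from decoded media
arrays (decoding itself is out of scope; the module consumes arrays) and
tests whether any feature is modulated by centrality with a linear mixed
model (movies as random intercepts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_stats import MixedModelResult, fit_mixed_model

__all__ = ["MediaArrays", "compute_sensory_features", "feature_modulation_test"]

AUDIO_SEGMENT_S = 0.1  # 100-ms amplitude segments


@dataclass
class MediaArrays:
    """Decoded media per event of one movie.

    ``frames[e]`` is a list of grayscale pixel matrices (0-255);
    ``audio[e]`` is a 1-D sample vector at ``sample_rate_hz``.
    """

    movie: str
    frames: list[list[np.ndarray]]
    audio: list[np.ndarray]
    sample_rate_hz: float

    def __post_init__(self):
        if self.sample_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.frames) != len(self.audio):
            raise ValueError("frames and audio must cover the same events")
        for e, fl in enumerate(self.frames):
            if not fl:
                raise ValueError(f"event {e}: empty frame list")
            for fr in fl:
                if np.min(fr) < 0 or np.max(fr) > 255:
                    raise ValueError(f"event {e}: pixel intensities outside 0-255")

    @property
    def n_events(self) -> int:
        return len(self.frames)


def compute_sensory_features(media: MediaArrays, zscore: bool = True,
                             exclude_first_event: bool = True) -> pd.DataFrame:
    """Per-event luminance, contrast, and auditory amplitude.

    Luminance: mean over frames of the per-frame pixel mean. Contrast:
    mean over frames of the per-frame (max - min). Amplitude: the audio
    is cut into 100-ms segments (trailing partial segment dropped) and
    the per-segment (max - min) is averaged. Features are z-scored across
    events (sample SD) unless ``zscore=False``; the first event of the
    movie is excluded by default (movie-onset transient), mirroring the
    neural analyses.
    """
    seg_len = int(round(media.sample_rate_hz * AUDIO_SEGMENT_S))
    rows = []
    for e in range(media.n_events):
        lum = float(np.mean([np.mean(fr) for fr in media.frames[e]]))
        con = float(np.mean([np.max(fr) - np.min(fr) for fr in media.frames[e]]))
        audio = np.asarray(media.audio[e], dtype=float)
        n_seg = audio.size // seg_len
        if n_seg < 1:
            raise ValueError(f"event {e}: audio shorter than one "
                             f"{AUDIO_SEGMENT_S * 1000:.0f}-ms segment")
        segs = audio[:n_seg * seg_len].reshape(n_seg, seg_len)
        amp = float(np.mean(segs.max(axis=1) - segs.min(axis=1)))
        rows.append({"movie": media.movie, "event": e, "luminance": lum,
                     "contrast": con, "amplitude": amp})
    df = pd.DataFrame(rows)
    if exclude_first_event:
        df = df.iloc[1:].reset_index(drop=True)
    if zscore:
        for col in ("luminance", "contrast", "amplitude"):
            v = df[col]
            sd = v.std(ddof=1)
            df[col] = (v - v.mean()) / sd if sd > 0 else 0.0
    return df


def feature_modulation_test(features: pd.DataFrame, cent: pd.DataFrame,
                            feature: str = "luminance") -> MixedModelResult:
    """Is a sensory feature modulated by centrality? (control analysis)

    Linear mixed model: feature ~ centrality with movies as random
    intercepts; the likelihood-ratio test compares against the movie-only
    null (chi2 with 1 df).
    """
    merged = features.merge(cent[["movie", "event", "z_centrality"]],
                            on=["movie", "event"])
    if merged.empty:
        raise ValueError("no overlapping events between features and centrality")
    return fit_mixed_model(
        outcome=merged[feature],
        fixed=merged[["z_centrality"]].rename(columns={"z_centrality": "centrality"}),
        random_intercepts={"movie": merged["movie"]},
        family="linear",
        lrt_predictors="centrality",
    )
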