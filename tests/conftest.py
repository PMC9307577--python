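"""Shared fixtures: a small synthetic study reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from narranet import network as nw
from narranet.embedding import cosine_similarity_matrix
from narranet.synthetic import (GeneratorConfig, generate_events,
                                generate_narrative, generate_neural,
                                generate_recall)


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=11, n_movies=4, events_per_movie=12,
                           n_participants=8, embedding_dim=64, n_features=30)


@pytest.fixture(scope="session")
def narrative(small_cfg):
    return generate_narrative(small_cfg)


@pytest.fixture(scope="session")
def centrality_tables(small_cfg, narrative):
    cent_sem = pd.concat(
        [nw.compute_centrality(nw.build_semantic_network(cosine_similarity_matrix(e)))
         for e in narrative.averaged.values()], ignore_index=True)
    cent_cau = pd.concat(
        [nw.compute_centrality(nw.build_causal_network(j))
         for j in narrative.judgments.values()], ignore_index=True)
    return nw.split_high_low(cent_sem), nw.split_high_low(cent_cau)


@pytest.fixture(scope="session")
def recall(small_cfg, centrality_tables):
    cent_sem, cent_cau = centrality_tables
    return generate_recall(small_cfg, cent_sem, cent_cau)


@pytest.fixture(scope="session")
def neural_data(small_cfg, centrality_tables, recall):
    cent_sem, _ = centrality_tables
    return generate_neural(small_cfg, cent_sem, recall)


@pytest.fixture(scope="session")
def events(small_cfg):
    return generate_events(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
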