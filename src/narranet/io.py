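"""Readers and writers for the pipeline's tabular and matrix formats.

Tables are TSV with a header (UTF-8); floats are written with 10
significant digits so reruns diff cleanly. Embeddings and pattern tensors
go into ``.npz`` containers with a TSV/JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding import EmbeddingMatrix
from .network import CausalJudgmentSet, NarrativeNetwork

__all__ = [
    "write_tsv", "read_tsv", "write_json", "sha256_file",
    "write_network_edges", "read_network_edges",
    "write_judgments", "read_judgments",
    "write_embeddings", "read_embeddings",
]

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def read_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
    return path


def sha256_file(path: Path | str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_network_edges(net: NarrativeNetwork, path: Path | str) -> Path:
    rows = []
    a = net.adjacency
    for i in range(net.n_events):
        for j in range(i + 1, net.n_events):
            rows.append({"movie": net.movie, "i": i, "j": j, "weight": a[i, j]})
    return write_tsv(pd.DataFrame(rows), path)


def read_network_edges(path: Path | str, kind: str,
                       n_raters: int | None = None) -> dict[str, NarrativeNetwork]:
    df = read_tsv(path)
    out = {}
    for movie, sub in df.groupby("movie"):
        n = int(max(sub["i"].max(), sub["j"].max())) + 1
        a = np.zeros((n, n))
        a[sub["i"], sub["j"]] = sub["weight"]
        a[sub["j"], sub["i"]] = sub["weight"]
        out[str(movie)] = NarrativeNetwork(movie=str(movie), adjacency=a, kind=kind,
                                           n_raters=n_raters)
    return out


def write_judgments(judgments: dict[str, CausalJudgmentSet], path: Path | str) -> Path:
    rows = []
    for movie in sorted(judgments):
        js = judgments[movie]
        for coder in sorted(js.judgments):
            for pair in sorted(js.judgments[coder], key=sorted):
                i, j = sorted(pair)
                rows.append({"movie": movie, "coder": coder, "event_i": i, "event_j": j,
                             "n_events": js.n_events})
    return write_tsv(pd.DataFrame(rows), path)


def read_judgments(path: Path | str) -> dict[str, CausalJudgmentSet]:
    df = read_tsv(path)
    out = {}
    for movie, sub in df.groupby("movie"):
        coders: dict[str, set] = {}
        for _, row in sub.iterrows():
            coders.setdefault(str(row["coder"]), set()).add(
                frozenset((int(row["event_i"]), int(row["event_j"]))))
        out[str(movie)] = CausalJudgmentSet(movie=str(movie),
                                            n_events=int(sub["n_events"].iloc[0]),
                                            judgments=coders)
    return out


def write_embeddings(embs: dict[str, EmbeddingMatrix], path: Path | str) -> Path:
    """One npz of matrices plus a TSV index (movie, source, n_events, dim)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {movie: e.matrix for movie, e in embs.items()}
    np.savez_compressed(path, **arrays)
    index = pd.DataFrame(
        [{"movie": m, "source": e.source, "n_events": e.n_events, "dim": e.dim}
         for m, e in sorted(embs.items())])
    write_tsv(index, path.with_suffix(".index.tsv"))
    return path


def read_embeddings(path: Path | str) -> dict[str, EmbeddingMatrix]:
    path = Path(path)
    index = read_tsv(path.with_suffix(".index.tsv")).set_index("movie")
    out = {}
    with np.load(path) as z:
        for movie in z.files:
            out[movie] = EmbeddingMatrix(movie=movie, matrix=z[movie],
                                         source=str(index.loc[movie, "source"]))
    return out
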