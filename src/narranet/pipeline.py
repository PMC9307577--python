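"""End-to-end orchestration with config, manifest, and provenance.

``run_pipeline`` executes the requested stages in dependency order on a
synthetic dataset (or a dataset directory written by the synth stage),
writing diffable TSV/JSON outputs and a run manifest that ties every
output to the config snapshot and seed. Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import behavior as bh
from . import network as nw
from . import neural as ne
from . import timecourse as tc
from . import stimulus as st
from .io import (sha256_file, write_embeddings, write_json, write_judgments,
                 write_network_edges, write_tsv)
from .synthetic import (GeneratorConfig, generate_events, generate_media,
                        generate_narrative, generate_neural, generate_recall)

__all__ = ["default_config", "validate_config", "run_pipeline"]

STAGES = ["synth", "network", "behavior", "neural", "timecourse", "features"]


def default_config() -> dict:
    return {
        "seed": 0,
        "n_permutations": 1000,
        "fdr_q": 0.05,
        "split_fraction": 0.4,
        "min_recallers": 5,
        "stages": list(STAGES),
        "generator": {},
    }


def validate_config(config: dict) -> dict:
    cfg = default_config()
    unknown = set(config) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(config)
    if not 0 < cfg["split_fraction"] <= 0.5:
        raise ValueError("config error at split_fraction: must lie in (0, 0.5]")
    if cfg["n_permutations"] < 1:
        raise ValueError("config error at n_permutations: must be >= 1")
    if not 0 < cfg["fdr_q"] < 1:
        raise ValueError("config error at fdr_q: must lie in (0, 1)")
    bad = set(cfg["stages"]) - set(STAGES)
    if bad:
        raise ValueError(f"config error at stages: unknown stages {sorted(bad)}")
    gen_fields = {f.name for f in dataclasses.fields(GeneratorConfig)}
    bad = set(cfg["generator"]) - gen_fields
    if bad:
        raise ValueError(f"config error at generator: unknown keys {sorted(bad)}")
    return cfg


def run_pipeline(config: dict, out_dir: Path | str) -> dict:
    """Run the requested stages; return (and write) the run manifest."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = GeneratorConfig(seed=cfg["seed"], **cfg["generator"])
    manifest = {"config": cfg, "version": __version__, "outputs": {}, "stages_run": []}

    def record(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path.relative_to(out)),
                                     "sha256": sha256_file(path)}

    stages = [s for s in STAGES if s in cfg["stages"]]

    # ---- synth: planted dataset every later stage consumes
    narrative = generate_narrative(gen, with_text=True)
    events = generate_events(gen)
    record("events", write_tsv(events, out / "events.tsv"))
    record("annotations", write_tsv(narrative.annotations, out / "annotations.tsv"))
    record("judgments", write_judgments(narrative.judgments, out / "causal_judgments.tsv"))
    record("embeddings", write_embeddings(narrative.averaged, out / "embeddings.npz"))
    record("truth", write_tsv(narrative.truth, out / "generator_truth.tsv"))
    manifest["stages_run"].append("synth")

    # ---- network: semantic + causal centrality, high/low split
    from .embedding import cosine_similarity_matrix

    semantic_nets = {m: nw.build_semantic_network(cosine_similarity_matrix(e))
                     for m, e in narrative.averaged.items()}
    causal_nets = {m: nw.build_causal_network(j)
                   for m, j in narrative.judgments.items()}
    cent_sem = pd.concat([nw.compute_centrality(n) for n in semantic_nets.values()],
                         ignore_index=True)
    cent_cau = pd.concat([nw.compute_centrality(n) for n in causal_nets.values()],
                         ignore_index=True)
    cent_sem = nw.split_high_low(cent_sem, fraction=cfg["split_fraction"])
    cent_cau = nw.split_high_low(cent_cau, fraction=cfg["split_fraction"])
    if "network" in stages:
        record("semantic_edges", write_tsv(
            pd.concat([_edges(n) for n in semantic_nets.values()], ignore_index=True),
            out / "semantic_network.tsv"))
        record("causal_edges", write_tsv(
            pd.concat([_edges(n) for n in causal_nets.values()], ignore_index=True),
            out / "causal_network.tsv"))
        record("centrality_semantic", write_tsv(cent_sem, out / "centrality_semantic.tsv"))
        record("centrality_causal", write_tsv(cent_cau, out / "centrality_causal.tsv"))
        jac = nw.coder_jaccard(list(narrative.judgments.values()))
        write_json({"coder_jaccard": jac}, out / "network_stats.json")
        record("network_stats", out / "network_stats.json")
        manifest["stages_run"].append("network")

    recall = generate_recall(gen, cent_sem, cent_cau)

    # ---- behavior
    if "behavior" in stages:
        probs = bh.recall_probability(recall, scope="unconditional")
        record("recall_probability", write_tsv(probs, out / "recall_probability.tsv"))
        stats = {
            "order_rho_movie": bh.recall_order_spearman(recall, level="movie").mean(),
            "order_rho_event": bh.recall_order_spearman(recall, level="event").mean(),
        }
        sp = bh.serial_position_anova(recall)
        stats["serial_position"] = {"F": sp["F"], "df": list(sp["df"]), "p": sp["p"]}
        tt = bh.highlow_recall_ttest(recall, cent_sem)
        stats["highlow_semantic"] = {k: tt[k] for k in
                                     ("t", "df", "p", "mean_difference", "ci")}
        corr = bh.correlate_centrality_recall(cent_sem, probs)
        stats["centrality_recall_r"] = corr
        glmm = bh.recall_glmm(recall, cent_sem, cent_cau)
        stats["glmm"] = {"coefficients": glmm.coefficients,
                         "std_errors": glmm.std_errors,
                         "lrt": {k: list(v) for k, v in glmm.lrt.items()},
                         "converged": glmm.converged}
        record("behavior_stats", write_json(stats, out / "behavior_stats.json"))
        manifest["stages_run"].append("behavior")

    # ---- neural / timecourse share the generated ROI data
    neural_data = None
    if "neural" in stages or "timecourse" in stages:
        neural_data = generate_neural(gen, cent_sem, recall, events=events)

    if "neural" in stages:
        nstats = {}
        for (region, phase), pats in neural_data.patterns.items():
            min_p = cfg["min_recallers"] if phase == "recall" else 2
            obs, res = ne.pisc_randomization_map(
                pats, n_perm=cfg["n_permutations"], shuffle_scope="across-movies",
                seed=cfg["seed"], min_participants=min_p)
            pisc = ne.event_pisc(pats, min_participants=min_p)
            hl = ne.highlow_pisc_test(pisc, cent_sem, n_perm=cfg["n_permutations"],
                                      seed=cfg["seed"])
            nstats[f"{region}_{phase}"] = {
                "mean_pisc": obs, "p": res.p_value,
                "highlow_difference": hl["difference"], "highlow_p": hl["p"],
            }
        # RSA in the region/phase with planted positive coupling
        pats = neural_data.patterns[("pmc", "recall")]
        neural_mats = ne.cross_event_similarity(pats)
        reference = {m: cosine_similarity_matrix(e)
                     for m, e in narrative.averaged.items()}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, res = ne.rsa_test(neural_mats, reference,
                                 n_perm=cfg["n_permutations"], seed=cfg["seed"])
        nstats["rsa_pmc_recall"] = {"mean_r": r, "p": res.p_value}
        record("neural_stats", write_json(nstats, out / "neural_stats.json"))
        manifest["stages_run"].append("neural")

    if "timecourse" in stages:
        tstats = {}
        btc = tc.boundary_timecourses(neural_data.hippocampus, events, cent_sem,
                                      align="offset", fdr_q=cfg["fdr_q"])
        curve_df = pd.DataFrame({
            "tr_offset": btc.offsets,
            "high_mean": btc.mean("high"), "low_mean": btc.mean("low"),
            "t": btc.t, "p": btc.p, "q": btc.q})
        record("boundary_offset", write_tsv(curve_df, out / "boundary_offset.tsv"))
        offsets = {p: tc.offset_response(ts, events)
                   for p, ts in neural_data.hippocampus.items()}
        # first/last events per movie excluded (between-movie transitions)
        interior = set()
        for movie, sub in events.groupby("movie"):
            emin, emax = sub["event"].min(), sub["event"].max()
            interior |= {(movie, e) for e in sub["event"] if emin < e < emax}
        med_rows = []
        zc = cent_sem.set_index(["movie", "event"])["z_centrality"]
        for p, resp in offsets.items():
            for (movie, event), val in resp.items():
                if np.isnan(val) or (movie, event) not in interior:
                    continue
                med_rows.append({"participant": p, "centrality": zc[(movie, event)],
                                 "mediator": val,
                                 "outcome": recall.recalled.loc[p, (movie, event)]})
        med_df = pd.DataFrame(med_rows)
        med = tc.mediation_analysis(med_df, n_sims=cfg["n_permutations"],
                                    seed=cfg["seed"])
        tstats["mediation"] = {"acme": med.acme, "ci": list(med.acme_ci),
                               "p": med.p_value, "direct": med.direct_effect,
                               "total": med.total_effect, "scale": med.scale}
        isfc = tc.event_isfc(neural_data.region_a, neural_data.region_b, events)
        record("isfc", write_tsv(isfc, out / "isfc.tsv"))
        merged = isfc.merge(cent_sem, on=["movie", "event"])
        from scipy import stats as sps
        r, pv = sps.pearsonr(merged["z_centrality"], merged["isfc"])
        tstats["isfc_centrality"] = {"r": float(r), "p": float(pv),
                                     "n_events": len(merged)}
        record("timecourse_stats", write_json(tstats, out / "timecourse_stats.json"))
        manifest["stages_run"].append("timecourse")

    if "features" in stages:
        media = generate_media(gen, cent_sem)
        feats = pd.concat([st.compute_sensory_features(m, zscore=False)
                           for m in media.values()], ignore_index=True)
        for col in ("luminance", "contrast", "amplitude"):  # z across all events
            feats[col] = (feats[col] - feats[col].mean()) / feats[col].std(ddof=1)
        record("sensory_features", write_tsv(feats, out / "sensory_features.tsv"))
        fstats = {}
        for feature in ("luminance", "contrast", "amplitude"):
            res = st.feature_modulation_test(feats, cent_sem, feature=feature)
            fstats[feature] = {"beta": res.coefficients.get("centrality"),
                               "lrt_chi2": res.lrt_chi2, "lrt_p": res.lrt_p,
                               "converged": res.converged}
        record("feature_stats", write_json(fstats, out / "feature_stats.json"))
        manifest["stages_run"].append("features")

    write_json(manifest, out / "manifest.json")
    return manifest


def _edges(net) -> pd.DataFrame:
    rows = []
    for i in range(net.n_events):
        for j in range(i + 1, net.n_events):
            rows.append({"movie": net.movie, "i": i, "j": j,
                         "weight": net.adjacency[i, j]})
    return pd.DataFrame(rows)
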