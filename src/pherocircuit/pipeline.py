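"""End-to-end study orchestration: simulate or ingest, cluster, test, summarize.

``run_pipeline`` reads a TOML config, generates (or loads) a population of
morphologies plus per-cell recordings, scores and Ward-clusters the
morphologies, runs the spiking response statistics, and writes the joint
morphology x physiology summary ordered by dendrogram leaf order, together
with the distance matrix, Newick dendrogram, full response table and a run log
listing every parameter.  Deterministic given config + seed.
"""

from __future__ import annotations

import os
import tomllib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import similarity
from .responses import build_response_table, lifetime_sparseness
from .simulate import EphysSimSpec, MorphoPopulationSpec, simulate_skeleton_population, simulate_trialset
from .skeletons import resample_skeleton, to_dotprops

__all__ = ["StudySummary", "run_pipeline", "DEFAULT_CONFIG"]

# every analysis constant has a named key defaulting to its standard value
DEFAULT_CONFIG = {
    "simulation": {
        "seed": 0,
        "n_per_group": 20,
        "group_labels": ["A", "B"],
        "dendrite_centroids": [[0.0, 40.0, 0.0], [0.0, 70.0, 0.0]],
        "axon_target": [150.0, -50.0, 30.0],
        "jitter_sd_um": 2.0,
        "odors": ["cva", "phenylacetic_acid"],
        "responsive_group": "A",
        "responsive_odors": ["cva"],
        "odor_rate_hz": 40.0,
        "control_rate_hz": 2.0,
        "epsp_amplitude_mv": 5.0,
        "noise_sd_mv": 0.5,
        "n_trials": 4,
        "control_label": "oil",
    },
    "morphology": {
        "sigma_um": 3.0,
        "symmetrize": "mean",
        "linkage": "ward",
        "k_clusters": 2,
        "resample_step_um": 1.0,
        "k_neighbors": 5,
    },
    "responses": {
        "smooth_cutoff_hz": 400.0,
        "response_start_s": 0.15,
        "response_window_s": 0.5,
        "alpha": 0.01,
        "fdr_scope": "cell",
    },
    "output": {"dir": "pherocircuit_out"},
}


@dataclass
class StudySummary:
    summary: pd.DataFrame  # one row per cell, dendrogram leaf order
    responses: pd.DataFrame
    distances: similarity.DistanceMatrix
    dendrogram: similarity.Dendrogram
    cluster_labels: dict


def _merged(user: dict) -> dict:
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in user.items():
        cfg.setdefault(section, {}).update(values)
    return cfg


def run_pipeline(config_path, out_dir=None) -> StudySummary:
    with open(config_path, "rb") as fh:
        cfg = _merged(tomllib.load(fh))
    sim, morpho, resp = cfg["simulation"], cfg["morphology"], cfg["responses"]
    out = out_dir or cfg["output"]["dir"]

    try:
        summary = _run(sim, morpho, resp)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    os.makedirs(out, exist_ok=True)
    pd.DataFrame(summary.distances.values,
                 index=summary.distances.labels,
                 columns=summary.distances.labels).to_csv(
        os.path.join(out, "matrix.csv"), float_format="%.10g")
    with open(os.path.join(out, "dendrogram.nwk"), "w") as fh:
        fh.write(similarity.to_newick(summary.dendrogram) + "\n")
    summary.responses.to_csv(os.path.join(out, "responses.csv"),
                             index=False, float_format="%.10g")
    summary.summary.to_csv(os.path.join(out, "summary.csv"),
                           index=False, float_format="%.10g")
    with open(os.path.join(out, "run.log"), "w") as fh:
        for section in sorted(cfg):
            for key in sorted(cfg[section]):
                fh.write(f"{section}.{key} = {cfg[section][key]!r}\n")
    return summary


def _run(sim: dict, morpho: dict, resp: dict) -> StudySummary:
    if sim["n_per_group"] < 1:
        raise ValueError("n_per_group must be >= 1 (empty cell list)")
    groups = tuple(
        (label, tuple(centroid), tuple(sim["axon_target"]))
        for label, centroid in zip(sim["group_labels"], sim["dendrite_centroids"])
    )
    mspec = MorphoPopulationSpec(
        n_per_group=int(sim["n_per_group"]), groups=groups,
        jitter_sd=float(sim["jitter_sd_um"]), seed=int(sim["seed"]))
    skels, true_groups = simulate_skeleton_population(mspec)

    dotprops = [
        to_dotprops(resample_skeleton(s, float(morpho["resample_step_um"])),
                    k_neighbors=int(morpho["k_neighbors"]))
        for s in skels
    ]
    params = similarity.SimilarityParams(sigma=float(morpho["sigma_um"]),
                                         symmetrize=str(morpho["symmetrize"]))
    dm = similarity.distance_matrix(dotprops, params,
                                    labels=[s.label for s in skels])
    dendro = similarity.cluster_neurons(dm, method=str(morpho["linkage"]))
    clusters = similarity.cut_clusters(dendro, int(morpho["k_clusters"]))
    cluster_of = dict(zip(dm.labels, (int(c) for c in clusters)))

    # one recording per cell: responsive-group cells respond to the designated odors
    odors = list(sim["odors"])
    cell_seeds = np.random.SeedSequence(int(sim["seed"])).generate_state(
        len(skels)) % (2**31)
    response_frames = []
    for skel, group, cell_seed in zip(skels, true_groups, cell_seeds):
        responsive = (list(sim["responsive_odors"])
                      if group == sim["responsive_group"] else [])
        espec = EphysSimSpec(
            odor_rate_hz=float(sim["odor_rate_hz"]),
            control_rate_hz=float(sim["control_rate_hz"]),
            epsp_amplitude=float(sim["epsp_amplitude_mv"]),
            noise_sd=float(sim["noise_sd_mv"]),
            n_trials=int(sim["n_trials"]),
            pre_s=1.0, post_s=0.5,
            seed=int(cell_seed))
        ts, _ = simulate_trialset(espec, odors, control_label=sim["control_label"],
                                  responsive=responsive, cell_id=skel.label)
        response_frames.append(build_response_table(
            ts, alpha=float(resp["alpha"]),
            start_offset=float(resp["response_start_s"]),
            window=float(resp["response_window_s"]),
            smooth_cutoff=float(resp["smooth_cutoff_hz"]),
            fdr_scope=str(resp["fdr_scope"])))
    responses = pd.concat(response_frames, ignore_index=True)

    rows = []
    group_of = dict(zip([s.label for s in skels], true_groups))
    for cell in dendro.leaf_order():
        sub = responses[responses["cell_id"] == cell]
        row = {"cell_id": cell, "true_group": group_of[cell],
               "morphology_cluster": cluster_of[cell],
               "sparseness": lifetime_sparseness(sub["rate_hz"].to_numpy())
               if len(sub) >= 2 else np.nan}
        for r in sub.itertuples():
            row[f"rate_hz_{r.stimulus_label}"] = r.rate_hz
            row[f"significant_{r.stimulus_label}"] = bool(r.significant)
        rows.append(row)
    summary = pd.DataFrame(rows)
    if summary.empty or responses.empty:
        raise ValueError("summary has no cells")
    return StudySummary(summary=summary, responses=responses, distances=dm,
                        dendrogram=dendro, cluster_labels=cluster_of)
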