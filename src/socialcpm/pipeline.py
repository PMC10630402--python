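"""End-to-end analysis pipeline.

Stage order mirrors the study design the package implements: behavioral
scoring feeds a first-stage whole-connectome CPM of task performance (with
head motion as a confound), whose permutation-tested robust positive
network becomes the feature mask of second-stage CPMs predicting each
latent trait score with the other two trait scores as covariates.  An
optional questionnaire stage runs bootstrap EGA and writes community
scores.

Every stage writes its outputs plus a JSON run record; a manifest links
every output file to the resolved config hash and seed, so a rerun with
identical inputs and seed reproduces identical hashes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .cpm import (
    CPMConfig,
    CPMResult,
    EdgeMask,
    lobewise_summary,
    permutation_test,
    robust_edges,
    run_cpm,
)
from .ega import BootEGA
from .synthio import (
    LatentSpec,
    PlantedSignalSpec,
    SubjectDataset,
    simulate_correlated_traits,
    simulate_cpm_dataset,
    simulate_questionnaire,
)

logger = logging.getLogger(__name__)


def _dataset_from_config(cfg: dict, seed: int) -> SubjectDataset:
    sim = cfg.get("simulate")
    if sim is not None:
        spec_kwargs = dict(sim.get("cpm", {}))
        n_signal = spec_kwargs.pop("n_signal_edges", None)
        spec = PlantedSignalSpec(seed=seed, **spec_kwargs)
        if n_signal:
            rng = np.random.default_rng(seed)
            n_edges = spec.n_nodes * (spec.n_nodes - 1) // 2
            signal = tuple(sorted(rng.choice(n_edges, size=n_signal, replace=False)))
            spec = PlantedSignalSpec(seed=seed, signal_edges=signal, **spec_kwargs)
        data = simulate_cpm_dataset(spec)
        traits_cfg = sim.get("traits")
        if traits_cfg is not None:
            simulate_correlated_traits(data, seed=seed + 7, **traits_cfg)
        return data
    inputs = cfg.get("inputs")
    if inputs is None:
        raise ValueError("config needs either a 'simulate' or an 'inputs' block")
    edges, subjects, index_map = io.read_edge_matrix(inputs["edges"])
    behavior_tbl = io.read_table(
        inputs["behavior"], {"subject": "str", inputs.get("behavior_column", "d_prime"): "float"}
    ).set_index("subject")
    behavior = behavior_tbl.loc[subjects, inputs.get("behavior_column", "d_prime")].to_numpy()
    confounds = behavior_tbl.drop(columns=[inputs.get("behavior_column", "d_prime")])
    atlas = io.read_atlas(inputs["atlas"]) if "atlas" in inputs else None
    return SubjectDataset(
        edges=edges, behavior=behavior, confounds=confounds,
        subjects=subjects, index_map=index_map, atlas=atlas,
    )


def _write_cpm_outputs(
    out: Path, name: str, data: SubjectDataset, result: CPMResult, files: list[Path]
) -> None:
    n_iter, n = result.predictions.shape
    pred = pd.DataFrame(
        {
            "subject": np.tile(data.subjects, n_iter),
            "iteration": np.repeat(np.arange(n_iter), n),
            "predicted": result.predictions.ravel(),
            "observed": result.observed_residuals.ravel(),
        }
    )
    files.append(io.write_table(pred, out / f"{name}_predictions.csv"))
    files.append(
        io.write_table(
            pd.DataFrame(
                {"iteration": np.arange(n_iter), "accuracy": result.accuracies}
            ),
            out / f"{name}_accuracies.csv",
        )
    )
    freq = pd.DataFrame(
        {
            "edge": data.index_map.edge_labels(),
            "pos_freq": result.pos_frequency,
            "neg_freq": result.neg_frequency,
        }
    )
    files.append(io.write_table(freq[(freq.pos_freq > 0) | (freq.neg_freq > 0)],
                                out / f"{name}_selection_frequency.csv"))


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns a summary dict.

    Config blocks: ``simulate`` (or ``inputs``), ``cpm`` (threshold,
    k_folds, n_iterations, n_permutations, robustness, confounds),
    ``masked`` (list of trait targets), ``ega`` (n_boot, questionnaire
    simulation parameters), plus top-level ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    files: list[Path] = []
    summary: dict = {"seed": seed}

    data = _dataset_from_config(config, seed)
    files.append(
        io.write_edge_matrix(data.edges, data.subjects, data.index_map, out / "edges.csv")
    )
    behavior_tbl = data.confounds.copy()
    behavior_tbl.insert(0, "behavior", data.behavior)
    if data.traits is not None:
        behavior_tbl = pd.concat([behavior_tbl, data.traits], axis=1)
    behavior_tbl.index.name = "subject"
    files.append(io.write_table(behavior_tbl.reset_index(), out / "behavior.csv"))
    if data.atlas is not None:
        files.append(io.write_atlas(data.atlas, out / "atlas.tsv"))

    cpm_cfg = dict(config.get("cpm", {}))
    confounds = cpm_cfg.pop("confounds", list(data.confounds.columns))
    cfg = CPMConfig(seed=seed, **cpm_cfg)
    files.append(io.write_run_record(out, "cpm", {**cpm_cfg, "confounds": confounds}, seed))

    result = run_cpm(data, cfg, confounds=confounds)
    _write_cpm_outputs(out, "cpm", data, result, files)
    perm = permutation_test(data, cfg, result, confounds=confounds)
    files.append(
        io.write_table(
            pd.DataFrame(
                {"replicate": np.arange(len(perm.null_accuracies)),
                 "accuracy": perm.null_accuracies}
            ),
            out / "cpm_permutation.csv",
        )
    )
    stats = {
        "median_accuracy": result.median_accuracy,
        "p_value": perm.p_value,
        "config": cpm_cfg,
        "seed": seed,
    }
    (out / "cpm_stats.json").write_text(json.dumps(stats, indent=2, default=str))
    files.append(out / "cpm_stats.json")
    summary["cpm"] = {"median_accuracy": result.median_accuracy, "p_value": perm.p_value}

    mask = robust_edges(result)
    files.append(io.write_table(mask.to_frame(data.index_map), out / "robust_mask.csv"))
    summary["robust_mask"] = {
        "n_positive": int(mask.positive.size),
        "n_negative": int(mask.negative.size),
    }
    if data.atlas is not None and mask.n_edges:
        lobe = lobewise_summary(mask, data.atlas, data.index_map)
        files.append(io.write_table(lobe.pair_counts, out / "lobewise_summary.csv"))
        files.append(io.write_table(lobe.key_nodes, out / "key_nodes.csv"))

    masked_cfg = config.get("masked")
    if masked_cfg and data.traits is not None and mask.positive.size:
        positive_mask = EdgeMask(mask.positive, np.empty(0, dtype=int))
        targets = masked_cfg.get("targets", list(data.traits.columns))
        summary["masked"] = {}
        for trait in targets:
            covs = [t for t in data.traits.columns if t != trait]
            tr_result = run_cpm(
                data, cfg, feature_mask=positive_mask, target=trait, confounds=covs
            )
            tr_perm = permutation_test(
                data, cfg, tr_result, feature_mask=positive_mask,
                target=trait, confounds=covs,
            )
            _write_cpm_outputs(out, f"masked_{trait}", data, tr_result, files)
            stats = {
                "target": trait,
                "covariates": covs,
                "median_accuracy": tr_result.median_accuracy,
                "p_value": tr_perm.p_value,
                "seed": seed,
            }
            path = out / f"masked_{trait}_stats.json"
            path.write_text(json.dumps(stats, indent=2))
            files.append(path)
            summary["masked"][trait] = {
                "median_accuracy": tr_result.median_accuracy,
                "p_value": tr_perm.p_value,
            }

    ega_cfg = config.get("ega")
    if ega_cfg:
        spec_kwargs = dict(ega_cfg.get("simulate", {}))
        spec = LatentSpec(seed=seed + 11, **spec_kwargs)
        items = simulate_questionnaire(spec)
        files.append(io.write_items(items.responses, out / "items.csv"))
        model = BootEGA(
            n_boot=int(ega_cfg.get("n_boot", 500)), seed=seed + 13
        ).fit(items)
        res = model.result_
        net = res.typical_network.stack()
        net = net[net != 0]
        files.append(
            io.write_table(
                net.rename_axis(["item_i", "item_j"]).rename("weight").reset_index(),
                out / "ega_network.csv",
            )
        )
        files.append(
            io.write_table(res.membership.rename_axis("item").reset_index(), out / "ega_membership.csv")
        )
        files.append(
            io.write_table(
                res.item_stability.rename_axis("item").reset_index(), out / "ega_stability.csv"
            )
        )
        files.append(io.write_table(model.transform(items).rename_axis("participant").reset_index(),
                                    out / "ega_scores.csv"))
        record = {
            "n_boot": int(ega_cfg.get("n_boot", 500)),
            "seed": seed + 13,
            "community_count": res.n_communities,
        }
        (out / "ega_run.json").write_text(json.dumps(record, indent=2))
        files.append(out / "ega_run.json")
        summary["ega"] = {"n_communities": res.n_communities}

    files.append(io.write_run_record(out, "pipeline", config, seed))
    io.write_manifest(out, files, config, seed)
    summary["manifest"] = str(out / "manifest.json")
    return summary
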