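"""End-to-end orchestration of the synthetic experiment.

Stages: stimulus synthesis -> regressor construction -> data generation
-> volume trimming + nuisance regression -> ISC mapping -> group ICA with
stability selection and back-reconstruction -> extrinsic/intrinsic
classification, FNC and stimulus regression -> (optional) voxelwise GLM.
Every stage draws its randomness from seeds derived from the single
config seed, so a rerun with the same config reproduces identical
manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify as classify_mod
from . import glm as glm_mod
from .config import PipelineConfig
from .gica import GroupICAModel, OrderEstimate, estimate_order, fit_group_ica
from .isc import ISCResult, run_isc
from .prep import GroupDataset, regress_out_nuisance, trim_volumes
from .stimreg import Regressor, envelope, to_regressor, write_regressors_tsv
from .synthdata import SyntheticDataset, generate_dataset, synthesize_audio_tracks

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: SyntheticDataset
    group: GroupDataset  # trimmed + nuisance-cleaned
    regressors: list[Regressor]  # trimmed to the retained volumes
    isc_result: ISCResult
    order_estimate: OrderEstimate | None
    model: GroupICAModel
    classification: classify_mod.ComponentClassification
    glm_results: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    cfg = config
    manifest: dict = {"seed": cfg.seed, "stages": {}}

    # --- stimulus + regressors -------------------------------------------
    duration = cfg.n_volumes_total * cfg.tr_seconds
    speech, nonspeech = synthesize_audio_tracks(
        duration, rate_hz=cfg.audio_rate_hz, seed=cfg.seed
    )
    regs_full, regs_trim = [], []
    for track in (speech, nonspeech):
        env = envelope(track, cfg.envelope_cutoff_hz, cfg.envelope_decim)
        full = to_regressor(env, cfg.tr_seconds, n_volumes=cfg.n_volumes_total)
        trimmed = to_regressor(
            env,
            cfg.tr_seconds,
            n_volumes=cfg.n_volumes_total,
            trim_start=cfg.trim_start,
            trim_end=cfg.trim_end,
        )
        regs_full.append(full)
        regs_trim.append(trimmed)
    manifest["stages"]["regressors"] = {
        "hash": _hash(np.column_stack([r.values for r in regs_trim])),
        "n_volumes": regs_trim[0].values.size,
    }

    # --- synthetic cohort -------------------------------------------------
    synth_cfg = cfg.synth
    synth_cfg.seed = cfg.seed
    dataset = generate_dataset(synth_cfg, regs_full)
    manifest["stages"]["synth"] = {
        "hash": _hash(dataset.subjects[0].bold),
        "n_subjects": len(dataset.subjects),
    }

    # --- prep: trim + nuisance regression ---------------------------------
    trimmed = [
        trim_volumes(s, cfg.trim_start, cfg.trim_end) for s in dataset.subjects
    ]
    cleaned = [regress_out_nuisance(s, include_global=True) for s in trimmed]
    group_raw = GroupDataset(trimmed, dataset.group.mask, cfg.tr_seconds)
    group = GroupDataset(cleaned, dataset.group.mask, cfg.tr_seconds)
    manifest["stages"]["prep"] = {
        "hash": _hash(group.subjects[0].bold),
        "n_time": group.n_time,
    }

    # --- ISC ---------------------------------------------------------------
    isc_result = run_isc(
        group,
        alpha=cfg.isc_alpha,
        fwe_method=cfg.isc_method,
        t_fixed=cfg.isc_t_fixed,
        extent=cfg.isc_extent,
        connectivity=cfg.isc_connectivity,
        n_perm=cfg.isc_n_perm,
        seed=cfg.seed + 1,
    )
    manifest["stages"]["isc"] = {
        "hash": _hash(isc_result.group_t),
        "n_pairs": isc_result.n_pairs,
        "df": isc_result.df,
        "n_sig_voxels": int(isc_result.mask_sig.sum()),
        "n_clusters": len(isc_result.clusters),
    }

    # --- group ICA ---------------------------------------------------------
    ica_group = group if cfg.ica_on_cleaned else group_raw
    order_est = None
    if cfg.ica_order is None:
        order_est = estimate_order(ica_group)
        k = max(2, order_est.k_mdl)
    else:
        k = cfg.ica_order
    model = fit_group_ica(
        ica_group,
        k=k,
        n_runs=cfg.ica_runs,
        seed=cfg.seed + 2,
        iq_threshold=cfg.iq_threshold,
    )
    manifest["stages"]["gica"] = {
        "hash": _hash(model.aggregate_maps),
        "k": k,
        "n_retained": int(model.retained.sum()),
    }

    # --- classification + FNC + stimulus regression ------------------------
    classification = classify_mod.sort_extrinsic(
        model,
        isc_result,
        r_min=cfg.extrinsic_r_min,
        overlap_min=cfg.extrinsic_overlap_min,
        alpha=cfg.ic_map_alpha,
        extent=cfg.ic_map_extent,
        connectivity=cfg.isc_connectivity,
    )
    n_ext = int(classification.is_extrinsic.sum())
    n_other = int((model.retained & ~classification.is_extrinsic).sum())
    if n_ext >= 2 and n_other >= 1 and model.n_subjects >= 3:
        classification.fnc_result = classify_mod.fnc(
            model, classification, alpha=cfg.fnc_alpha
        )
    classification.regression = classify_mod.regress_on_stimuli(
        model, regs_trim, alpha=cfg.stim_alpha
    )
    manifest["stages"]["classify"] = {
        "n_extrinsic": n_ext,
        "n_non_extrinsic": n_other,
        "fnc_tests": (
            classification.fnc_result.n_tests if classification.fnc_result else 0
        ),
    }

    # --- GLM ----------------------------------------------------------------
    glm_results: dict = {}
    if cfg.run_glm:
        firsts = [
            glm_mod.fit_first_level(s, regs_trim, include_global=True)
            for s in trimmed
        ]
        betas = np.stack([f.betas for f in firsts])
        n_col = betas.shape[2]
        for j, reg in enumerate(regs_trim):
            contrast = np.zeros(n_col)
            contrast[j] = 1.0
            glm_results[reg.label] = glm_mod.second_level(
                betas,
                contrast,
                group.mask,
                alpha=cfg.glm_alpha,
                extent=cfg.glm_extent,
                connectivity=cfg.isc_connectivity,
            )
        glm_results["first_level_rho"] = [f.rho_hat for f in firsts]
        glm_results["regressor_corr"] = firsts[0].regressor_corr
        manifest["stages"]["glm"] = {
            "rho_mean": float(np.mean(glm_results["first_level_rho"])),
            "regressor_corr": glm_results["regressor_corr"],
        }

    result = PipelineResult(
        config=cfg,
        dataset=dataset,
        group=group,
        regressors=regs_trim,
        isc_result=isc_result,
        order_estimate=order_est,
        model=model,
        classification=classification,
        glm_results=glm_results,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_regressors_tsv(result.regressors, out / "regressors.tsv")
    clusters = [
        {
            "label": c.label,
            "size": c.size,
            "peak_x": c.peak_coord[0],
            "peak_y": c.peak_coord[1],
            "peak_z": c.peak_coord[2],
            "peak_t": c.peak_stat,
        }
        for c in result.isc_result.clusters
    ]
    import pandas as pd

    pd.DataFrame(clusters).to_csv(out / "isc_clusters.tsv", sep="\t", index=False)
    classify_mod.classification_table(result.model, result.classification).to_csv(
        out / "classification.tsv", sep="\t", index=False
    )
    if result.classification.fnc_result is not None:
        classify_mod.write_fnc_tsv(
            result.classification.fnc_result, out / "fnc_matrix.tsv"
        )
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
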