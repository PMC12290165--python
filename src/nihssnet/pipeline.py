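"""End-to-end orchestration: filter -> descriptives -> GDM/GSM -> RSC ->
profiles, density maps and one-vs-rest voxel tests, with provenance."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._validate import ValidationError
from .cohort import (
    CohortMetadata,
    OrdinalScoreMatrix,
    cluster_profile_summary,
    cooccurrence_counts,
    filter_cohort,
    spearman_network,
)
from .gdm import gdm_distance, gsm_network
from .lesionmap import (
    LesionVolumeSet,
    density_map,
    lesion_volume_comparison,
    one_vs_rest_analysis,
    save_volume,
)
from .rsc import rsc_partition, select_k

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All paths and analysis parameters of the full workflow.

    ``k`` fixes the cluster count; ``k_range`` instead selects it by the
    eigengap criterion.  ``masks_manifest`` may be omitted to run the
    behavioral stages only.
    """

    scores_csv: str
    out_dir: str
    metadata_csv: str | None = None
    masks_manifest: str | None = None
    scores_config: str | None = None
    loc_item: str = "loc_vigilance"
    k: int | None = 5
    k_range: list[int] | None = None
    n_runs: int = 500
    n_score_permutations: int = 10_000
    fdr_alpha: float = 0.05
    n_voxel_permutations: int = 5000
    overall_alpha: float = 0.05
    min_fraction: float = 0.05
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)


def _seed_for(master_seed: int, stage: str) -> int:
    entropy = [int(master_seed)] + [ord(c) for c in stage]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage of the workflow and write all artifacts.

    Returns the artifact manifest (also written as ``manifest.json``),
    which records package version, parameters and all stage seeds so any
    artifact can be regenerated from the manifest alone.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "nihssnet_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "seeds": {},
        "artifacts": {},
        "stages": [],
    }

    def record(stage: str, name: str, path: Path) -> None:
        manifest["artifacts"][name] = str(path)
        if stage not in manifest["stages"]:
            manifest["stages"].append(stage)

    # --- load + filter -----------------------------------------------------
    raw = OrdinalScoreMatrix.from_csv(config.scores_csv, config=config.scores_config)
    volumes = None
    if config.masks_manifest is not None:
        volumes = LesionVolumeSet.from_manifest(config.masks_manifest)
    if config.metadata_csv is not None:
        meta = CohortMetadata.from_csv(config.metadata_csv, raw.subject_ids)
    elif volumes is not None:
        # mirror the "available brain scans" criterion: a subject without a
        # mask in the manifest is treated as lacking a scan
        have = set(volumes.subject_ids or [])
        meta = CohortMetadata(
            scan_available=np.array([s in have for s in raw.subject_ids])
        )
    else:
        meta = CohortMetadata(scan_available=np.ones(raw.n, dtype=bool))

    filtered, drop_log = filter_cohort(raw, meta, loc_item=config.loc_item)
    logger.info("filter: kept %d of %d subjects", filtered.n, raw.n)
    filtered.to_csv(out / "scores_filtered.csv")
    drop_log.to_csv(out / "drop_log.csv", index=False)
    record("filter", "scores_filtered", out / "scores_filtered.csv")
    record("filter", "drop_log", out / "drop_log.csv")

    if volumes is not None:
        keep = [volumes.subject_ids.index(s) for s in filtered.subject_ids]
        volumes = LesionVolumeSet(
            masks=volumes.masks[keep],
            affine=volumes.affine,
            subject_ids=list(filtered.subject_ids),
        )

    # --- descriptive statistics -------------------------------------------
    cooccurrence_counts(filtered).to_csv(out / "cooccurrence.csv")
    record("stats", "cooccurrence", out / "cooccurrence.csv")
    corr_seed = _seed_for(config.master_seed, "spearman")
    manifest["seeds"]["spearman"] = corr_seed
    network = spearman_network(
        filtered,
        n_perm=config.n_score_permutations,
        alpha=config.fdr_alpha,
        seed=corr_seed,
    )
    network.edges.to_csv(out / "correlation_network.csv", index=False)
    record("stats", "correlation_network", out / "correlation_network.csv")

    # --- similarity network ------------------------------------------------
    D = gdm_distance(filtered)
    W = gsm_network(D)
    D.to_csv(out / "gdm_distance.csv")
    W.to_csv(out / "gsm_similarity.csv")
    record("similarity", "gdm_distance", out / "gdm_distance.csv")
    record("similarity", "gsm_similarity", out / "gsm_similarity.csv")

    # --- clustering ----------------------------------------------------------
    rsc_seed = _seed_for(config.master_seed, "rsc")
    manifest["seeds"]["rsc"] = rsc_seed
    k = config.k
    if config.k_range:
        selection = select_k(W, config.k_range, N=config.n_runs, master_seed=rsc_seed)
        selection.table.to_csv(out / "gap_table.csv", index=False)
        record("cluster", "gap_table", out / "gap_table.csv")
        k = selection.k
        logger.info("select_k chose k=%d", k)
    if k is None:
        raise ValidationError("either k or k_range must be configured")
    manifest["selected_k"] = int(k)
    assignment, consensus = rsc_partition(
        W, k, N=config.n_runs, master_seed=rsc_seed
    )
    labels_df = pd.DataFrame(
        {"subject_id": filtered.subject_ids, "cluster": assignment.labels}
    )
    labels_df.to_csv(out / "cluster_labels.csv", index=False)
    record("cluster", "cluster_labels", out / "cluster_labels.csv")
    pd.DataFrame(
        consensus.C, index=filtered.subject_ids, columns=filtered.subject_ids
    ).to_csv(out / "consensus_matrix.csv")
    record("cluster", "consensus_matrix", out / "consensus_matrix.csv")

    cluster_profile_summary(filtered, assignment.labels).to_csv(
        out / "cluster_profiles.csv"
    )
    record("cluster", "cluster_profiles", out / "cluster_profiles.csv")

    # --- lesion mapping ------------------------------------------------------
    if volumes is not None:
        lesion_seed = _seed_for(config.master_seed, "lesions")
        manifest["seeds"]["lesions"] = lesion_seed
        for cl in np.unique(assignment.labels):
            dm = density_map(volumes, assignment.labels, int(cl))
            path = out / f"density_cluster{cl}.nii"
            save_volume(dm, volumes.affine, path)
            record("lesions", f"density_cluster{cl}", path)
        results = one_vs_rest_analysis(
            volumes,
            assignment.labels,
            overall_alpha=config.overall_alpha,
            B=config.n_voxel_permutations,
            seed=lesion_seed,
            min_fraction=config.min_fraction,
        )
        volume_tests = []
        for res in results:
            path = out / f"significant_cluster{res.cluster_id}.nii"
            save_volume(res.significance_mask(), volumes.affine, path)
            record("lesions", f"significant_cluster{res.cluster_id}", path)
            table = res.to_frame(affine=volumes.affine)
            tpath = out / f"voxel_stats_cluster{res.cluster_id}.csv"
            table.to_csv(tpath, index=False)
            record("lesions", f"voxel_stats_cluster{res.cluster_id}", tpath)
            H, p = lesion_volume_comparison(volumes, assignment.labels, res.cluster_id)
            volume_tests.append(
                {"cluster": int(res.cluster_id), "H": H, "p": p,
                 "n_significant_voxels": int(res.significant.sum())}
            )
        pd.DataFrame(volume_tests).to_csv(out / "lesion_volume_tests.csv", index=False)
        record("lesions", "lesion_volume_tests", out / "lesion_volume_tests.csv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
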