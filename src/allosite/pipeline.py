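"""End-to-end orchestration of the pocket-restriction analysis.

``run`` executes the full chain on a set of labelled condition trajectories:
concatenation, invariant-core superposition, binding-site definition from the
ligand-bound condition, shared-space site PCA, per-frame pocket volumes,
state classification, distance-volume correlation scan, per-condition and
state-conditioned protein structure networks with difference edges, and
matrix-PCA clustering of the condition networks.  Every stage writes its TSV
outputs under the run directory and the headline numbers are collected in a
machine-readable summary.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import ConvexHull

from . import coordinate_pca, geometry_states, pocket_volume, psn, synthetic_data
from .matrix_pca_cluster import matrix_pca, single_linkage
from .site_definition import define_binding_site
from .structure_io import (
    ResidueSelection,
    Trajectory,
    concatenate,
    read_trajectory,
    split_by_condition,
    write_labels,
    write_matrix,
)
from .superposition import find_invariant_core, superpose_trajectory

__all__ = ["RunConfig", "run", "load_config"]

logger = logging.getLogger("allosite")


@dataclass
class RunConfig:
    """All fixed constants of the analysis in one audited place."""

    # inputs: condition label -> multi-model PDB path (ignored when
    # trajectories are passed to run() directly)
    trajectories: dict[str, str] = field(default_factory=dict)
    ligand_resname: str = synthetic_data.LIGAND_RESNAME
    site_cutoff: float = 4.5  # A, ligand-to-residue heavy-atom cutoff
    psn_cutoff: float = 4.5  # A, side-chain contact cutoff
    contact_cutoff: float = 4.5  # A, consensus-contact cutoff
    min_separation: int = 3  # sequence-adjacency skip for the PSN
    roi_radius: float = 10.0  # A
    grid_spacing: float = 0.5  # A
    closed_perimeter: float = 16.0  # A
    closed_distance: float = 8.0  # A
    open_perimeter: float = 21.0  # A
    open_distance: float = 13.0  # A
    core_target_fraction: float = 0.5
    core_variance_threshold: float | None = 0.1  # A^2
    # classification markers: (residue_seq, atom_name) triples and a residue pair
    triangle: tuple = tuple(
        (seq, atom) for (_, seq), atom in synthetic_data.TRIANGLE
    )
    distance_pair: tuple = tuple(seq for _, seq in synthetic_data.DIST_PAIR)
    chain_id: str = "A"
    seed: int = 0
    output_dir: str = "allosite_run"

    def thresholds(self) -> geometry_states.StateThresholds:
        return geometry_states.StateThresholds(
            self.closed_perimeter, self.closed_distance,
            self.open_perimeter, self.open_distance,
        )

    def state_markers(self):
        triangle = tuple(((self.chain_id, seq), atom) for seq, atom in self.triangle)
        pair = tuple((self.chain_id, seq) for seq in self.distance_pair)
        return triangle, pair


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(**data)
    if cfg.site_cutoff <= 0 or cfg.psn_cutoff <= 0 or cfg.contact_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    return cfg


def _hull_area(scores: np.ndarray) -> float:
    if scores.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(scores[:, :2]).volume)  # 2-D "volume" is the area
    except Exception:
        return 0.0


def run(
    config: RunConfig,
    trajectories: dict[str, Trajectory] | None = None,
) -> dict:
    """Execute the full analysis; returns the summary dictionary.

    ``trajectories`` may be given in memory; otherwise the paths in
    ``config.trajectories`` are read.  Any stage failure aborts with the
    stage named in the raised error.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    timings: dict[str, float] = {}
    summary: dict = {"conditions": {}, "seed": config.seed}
    try:
        t0 = time.time()
        if trajectories is None:
            trajectories = {
                label: read_trajectory(path, condition_label=label)
                for label, path in config.trajectories.items()
            }
        if not trajectories:
            raise ValueError("no input trajectories")
        for label, traj in trajectories.items():
            traj.condition_label = label
        # The shared "super trajectory" holds the receptor only: conditions may
        # carry extra ligand atoms that would break the common topology.
        receptor = {
            label: traj.subset(np.flatnonzero(~traj.topology.hetero))
            for label, traj in trajectories.items()
        }
        timings[stage] = time.time() - t0

        stage = "superpose"
        t0 = time.time()
        concat = concatenate(list(receptor.values()))
        core = find_invariant_core(
            concat, backbone_only=True,
            target_fraction=config.core_target_fraction,
            variance_threshold=config.core_variance_threshold,
        )
        core.to_file(out / "invariant_core.txt")
        aligned, _ = superpose_trajectory(concat, selection=core, backbone_only=True)
        by_condition = split_by_condition(aligned)
        timings[stage] = time.time() - t0

        stage = "site"
        t0 = time.time()
        ligand_condition = next(
            (label for label, traj in trajectories.items()
             if (traj.topology.residue_names == config.ligand_resname).any()),
            None,
        )
        if ligand_condition is None:
            raise ValueError(f"no condition contains ligand {config.ligand_resname!r}")
        site = define_binding_site(
            trajectories[ligand_condition].frame_structure(0),
            config.ligand_resname, config.site_cutoff,
        )
        site.to_file(out / "binding_site.txt")
        timings[stage] = time.time() - t0

        stage = "pca"
        t0 = time.time()
        model = coordinate_pca.fit_pca(aligned, site, include_sidechains=True)
        scores = coordinate_pca.project(aligned, model, n_components=2)
        score_table = pd.DataFrame({
            "condition": [label for label, _ in aligned.provenance],
            "frame": [i for _, i in aligned.provenance],
            "PC1": scores[:, 0], "PC2": scores[:, 1],
        })
        write_labels(score_table, out / "site_pca_scores.tsv")
        hull_areas = {
            label: _hull_area(scores[score_table["condition"] == label])
            for label in trajectories
        }
        timings[stage] = time.time() - t0

        stage = "volume"
        t0 = time.time()
        # Volumes use the original full trajectories so ligand atoms occlude the
        # grid; the per-frame re-centred ROI makes them rigid-motion invariant.
        volumes: dict[str, pocket_volume.VolumeSeries] = {}
        for label, traj in trajectories.items():
            volumes[label] = pocket_volume.volume_series(
                traj, site, grid_spacing=config.grid_spacing,
                roi_radius=config.roi_radius,
            )
            write_labels(
                pd.DataFrame({"frame": np.arange(traj.n_frames),
                              "volume": volumes[label].values}),
                out / f"volume_{label}.tsv",
            )
        timings[stage] = time.time() - t0

        stage = "states"
        t0 = time.time()
        triangle, pair = config.state_markers()
        states: dict[str, geometry_states.StateSeries] = {}
        for label, traj in by_condition.items():
            states[label] = geometry_states.state_series(
                traj, triangle, pair, config.thresholds()
            )
            write_labels(states[label].to_dataframe(), out / f"states_{label}.tsv")
        timings[stage] = time.time() - t0

        stage = "correlate"
        t0 = time.time()
        all_volumes = pocket_volume.VolumeSeries(
            np.concatenate([volumes[label].values for label in by_condition]),
            "concatenated", config.grid_spacing,
        )
        corr = geometry_states.correlate_distance_volume(aligned, site, all_volumes)
        write_labels(corr, out / "distance_volume_correlations.tsv")
        timings[stage] = time.time() - t0

        stage = "psn"
        t0 = time.time()
        norms = psn.NormalizationTable.published()
        matrices = {
            label: psn.average_psn(traj, cutoff=config.psn_cutoff, norms=norms,
                                   min_separation=config.min_separation)
            for label, traj in by_condition.items()
        }
        for label, matrix in matrices.items():
            write_matrix(matrix.to_dataframe(), out / f"psn_{label}.tsv")
        timings[stage] = time.time() - t0

        stage = "diffpsn"
        t0 = time.time()
        labels = list(by_condition)
        diff_edges = None
        if len(labels) >= 2:
            # State-conditioned contrast between the first two conditions that
            # both retain closed-state frames; falls back to plain averages.
            a_label, b_label = labels[0], labels[1]
            mask_a = states[a_label].mask("closed")
            mask_b = states[b_label].mask("closed")
            mat_a = (psn.average_psn(by_condition[a_label], cutoff=config.psn_cutoff,
                                     norms=norms, min_separation=config.min_separation,
                                     frame_mask=mask_a, state_filter="closed")
                     if mask_a.any() else matrices[a_label])
            mat_b = (psn.average_psn(by_condition[b_label], cutoff=config.psn_cutoff,
                                     norms=norms, min_separation=config.min_separation,
                                     frame_mask=mask_b, state_filter="closed")
                     if mask_b.any() else matrices[b_label])
            diff, diff_edges = psn.psn_difference(mat_a, mat_b)
            write_matrix(diff.to_dataframe(), out / "psn_difference.tsv")
            write_labels(diff_edges, out / "psn_difference_edges.tsv")
        timings[stage] = time.time() - t0

        stage = "cluster"
        t0 = time.time()
        cluster_labels = None
        if len(labels) >= 2:
            embedding = matrix_pca(list(matrices.values()))
            write_matrix(embedding.to_dataframe(), out / "matrix_pca_scores.tsv")
            k = min(2, len(labels))
            assignment, tree = single_linkage(embedding, n_clusters=k)
            cluster_labels = {label: int(c) for label, c in zip(labels, assignment)}
            write_labels(
                pd.DataFrame({"condition": labels, "cluster": assignment}),
                out / "clusters.tsv",
            )
        timings[stage] = time.time() - t0

        stage = "summary"
        for label in labels:
            summary["conditions"][label] = {
                "n_frames": int(by_condition[label].n_frames),
                "state_fractions": {
                    s: states[label].fraction(s) for s in ("closed", "intermediate", "open")
                },
                "volume_mean": float(np.mean(volumes[label].values)),
                "volume_std": float(np.std(volumes[label].values)),
                "pc_hull_area": hull_areas[label],
            }
        summary["binding_site"] = [f"{c}:{s}" for c, s in site.members]
        summary["invariant_core_size"] = len(core)
        summary["top_correlated_pairs"] = corr.head(5).to_dict(orient="records")
        if diff_edges is not None:
            summary["top_difference_edges"] = diff_edges.head(10).to_dict(orient="records")
        if cluster_labels is not None:
            summary["clusters"] = cluster_labels
        # Timings go to the log, not the summary: the summary must be
        # byte-identical across runs with the same inputs and seed.
        (out / "run.log").write_text(
            "".join(f"{name}\t{seconds:.3f}s\n" for name, seconds in timings.items())
        )
        for name, seconds in timings.items():
            logger.info("stage %s finished in %.3f s", name, seconds)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
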