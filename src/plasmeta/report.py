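"""Pipeline driver and exploratory outputs (clustering, PCA).

Clustering and PCA both work on log(1 + normalized abundance): average-
linkage agglomerative clustering with Euclidean distance, and PCA with each
taxon centered and unit-scaled (zero-variance taxa are left unscaled). PCA
signs follow a fixed convention — each component is flipped so its largest-
magnitude loading is positive — making coordinates reproducible bit-for-bit
on identical input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.decomposition import PCA

from . import contamination, inference, pairs, profile, qc, simulate

logger = logging.getLogger("plasmeta")


def _log_normalized(matrix: profile.TaxonCountMatrix) -> pd.DataFrame:
    if not matrix.normalized:
        raise ValueError("clustering and PCA use normalized abundances")
    return np.log1p(matrix.data)


def cluster_heatmap(
    matrix: profile.TaxonCountMatrix,
    metadata: pd.DataFrame,
    out_path: str | Path | None = None,
) -> dict:
    """Hierarchically cluster samples and taxa; return the leaf orders."""
    data = _log_normalized(matrix)
    meta = profile.validate_metadata(metadata).set_index("sample_id")

    if data.shape[0] < 2 or data.shape[1] < 2:
        sample_order = list(data.index)
        taxon_order = list(data.columns)
    else:
        sample_link = linkage(data.to_numpy(), method="average", metric="euclidean")
        taxon_link = linkage(data.to_numpy().T, method="average", metric="euclidean")
        sample_order = [data.index[i] for i in leaves_list(sample_link)]
        taxon_order = [data.columns[i] for i in leaves_list(taxon_link)]

    if out_path is not None and data.shape[0] >= 2 and data.shape[1] >= 2:
        batches = sorted(meta["batch"].unique())
        groups = sorted(meta["group"].unique())
        batch_palette = dict(zip(batches, sns.color_palette("Set2", len(batches))))
        group_palette = dict(zip(groups, sns.color_palette("Set1", len(groups))))
        row_colors = pd.DataFrame(
            {
                "batch": meta.loc[data.index, "batch"].map(batch_palette),
                "group": meta.loc[data.index, "group"].map(group_palette),
            },
            index=data.index,
        )
        grid = sns.clustermap(
            data, method="average", metric="euclidean",
            row_colors=row_colors, cmap="viridis",
            xticklabels=False, yticklabels=False,
        )
        grid.savefig(out_path, dpi=120)
        plt.close(grid.fig)

    return {"sample_order": sample_order, "taxon_order": taxon_order}


def pca_coordinates(matrix: profile.TaxonCountMatrix, n_components: int = 2) -> pd.DataFrame:
    """First principal components of log1p normalized abundances."""
    data = _log_normalized(matrix)
    if data.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    values = data.to_numpy(dtype=float)
    values = values - values.mean(axis=0)
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0  # zero-variance taxa contribute nothing either way
    values = values / sd
    n_components = min(n_components, *values.shape)
    if not values.any():  # constant matrix: all samples at the origin
        frame = pd.DataFrame(
            0.0, index=data.index, columns=[f"PC{j + 1}" for j in range(n_components)]
        )
        frame.attrs["explained_variance_ratio"] = [0.0] * n_components
        return frame
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(values)
    # Deterministic sign: largest-|loading| entry of each component positive.
    for j in range(coords.shape[1]):
        load = model.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
    frame = pd.DataFrame(
        coords, index=data.index,
        columns=[f"PC{j + 1}" for j in range(coords.shape[1])],
    )
    frame.attrs["explained_variance_ratio"] = list(model.explained_variance_ratio_)
    return frame


def pca_plot(
    matrix: profile.TaxonCountMatrix,
    metadata: pd.DataFrame,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """PCA scatter colored by batch, shaped by group; replicate pairs joined."""
    coords = pca_coordinates(matrix)
    meta = profile.validate_metadata(metadata).set_index("sample_id")
    if out_path is not None:
        frame = coords.join(meta[["group", "batch"]])
        fig, ax = plt.subplots(figsize=(7, 6))
        sns.scatterplot(
            data=frame.reset_index(names="sample_id"),
            x="PC1", y="PC2", hue="batch", style="group",
            palette="Set2", s=60, ax=ax,
        )
        for child, parent in meta["replicate_of"].dropna().items():
            if child in coords.index and parent in coords.index:
                ax.plot(
                    coords.loc[[child, parent], "PC1"],
                    coords.loc[[child, parent], "PC2"],
                    "k--", linewidth=0.8,
                )
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        fig.tight_layout()
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return coords


@dataclass
class PipelineConfig:
    """End-to-end run configuration (synthetic inputs unless paths given)."""

    out_dir: Path
    seed: int = 0
    rank: str = "genus"
    sim: simulate.SimulationConfig | None = None
    filter_config: qc.FilterConfig = field(default_factory=qc.FilterConfig)
    glm_config: inference.GLMConfig = field(default_factory=inference.GLMConfig)
    fastq1: Path | None = None
    fastq2: Path | None = None
    assignments_path: Path | None = None
    metadata_path: Path | None = None
    qc_pairs_per_sample: int = 2000
    validate_taxon: str | None = None


def run_pipeline(config: PipelineConfig) -> dict:
    """qc -> profile -> screen -> inference -> validation -> figures.

    With no input paths, a synthetic study is generated: one sample's read
    pairs for the QC stage and a full cohort count matrix (routed through
    per-read assignments) for the downstream stages. The summary JSON is a
    pure function of the seed and inputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path in (config.fastq1, config.fastq2, config.assignments_path,
                 config.metadata_path):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"pipeline input does not exist: {path}")
    summary: dict = {"seed": config.seed, "rank": config.rank, "stages": {}}

    sim_config = config.sim or simulate.SimulationConfig(seed=config.seed)

    # --- QC stage ---
    if config.fastq1 is not None and config.fastq2 is not None:
        in1, in2 = Path(config.fastq1), Path(config.fastq2)
    else:
        qc_sim = simulate.SimulationConfig(
            seed=sim_config.seed,
            n_per_group={"Healthy": 1},
            library_size_mean=float(config.qc_pairs_per_sample),
            library_size_cv=0.0,
            defect_rates=sim_config.defect_rates,
            read_length=sim_config.read_length,
        )
        files, _ = simulate.simulate_reads(qc_sim, out / "reads")
        in1, in2 = next(iter(files.values()))
    report = qc.run_qc(
        in1, in2, out / "filtered_R1.fastq", out / "filtered_R2.fastq",
        config.filter_config,
    )
    report.to_json(out / "qc_report.json")
    summary["stages"]["qc"] = report.to_dict()
    logger.info("QC: %d/%d pairs kept", report.surviving_pairs, report.input_pairs)

    # --- Profile stage ---
    if config.assignments_path is not None and config.metadata_path is not None:
        assignments = profile.read_assignments(config.assignments_path)
        metadata = profile.read_metadata(config.metadata_path)
    else:
        matrix0, metadata, _ = simulate.simulate_counts(sim_config)
        assignments, _ = simulate.simulate_assignments(sim_config, matrix0, metadata)
        assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
        profile.write_metadata(metadata, out / "metadata.tsv")
    matrix = profile.build_count_matrix(assignments, metadata, config.rank)
    matrix.to_tsv(out / f"counts_{config.rank}.tsv")
    normalized = profile.normalize_counts(matrix)
    summary["stages"]["profile"] = {
        "samples": len(matrix.samples),
        "taxa": len(matrix.taxa),
        "total_assigned_reads": int(matrix.data.to_numpy().sum()),
    }

    # --- Contamination screen ---
    stats = contamination.negcontrol_overlap(matrix, metadata)
    flags = contamination.flag_contaminants(stats, known_list=set())
    stats.to_json(out / "overlap.json")
    contamination.write_flags_tsv(flags, out / "contaminant_flags.tsv")
    summary["stages"]["screen"] = stats.to_dict()

    # --- Inference ---
    deduped, meta_dd = profile.drop_duplicates(matrix, metadata, seed=config.seed)
    results = inference.fit_taxon_glm(deduped, meta_dd, config.glm_config)
    results = inference.classify_taxa(results, flags, config.glm_config)
    inference.write_results_tsv(results, out / "regression.tsv")
    summary["stages"]["inference"] = {
        "taxa_tested": len(results),
        "group_significant": sum(r.group_significant for r in results),
        "batch_significant": sum(r.batch_significant for r in results),
        "classifications": {
            str(k): int(v)
            for k, v in pd.Series([r.classification for r in results])
            .value_counts()
            .sort_index()
            .items()
        },
    }

    # --- Paired-read validation ---
    taxon = config.validate_taxon
    if taxon is None and len(matrix.taxa):
        totals = matrix.data.sum(axis=0)
        positive = totals[totals > 0]
        taxon = str((positive if len(positive) else totals).idxmin())
    if taxon is not None:
        stats_v = pairs.pair_concordance(assignments, taxon)
        verdict = pairs.concordance_report(stats_v, total_samples=len(matrix.samples))
        pairs.write_report(verdict, out / "validation.json")
        summary["stages"]["validation"] = verdict

    # --- Figures ---
    orders = cluster_heatmap(normalized, metadata, out / "heatmap.png")
    coords = pca_plot(normalized, metadata, out / "pca.png")
    coords.to_csv(out / "pca_coordinates.tsv", sep="\t", index_label="sample")
    summary["stages"]["figures"] = {
        "sample_order": orders["sample_order"],
        "pca_explained_variance": coords.attrs["explained_variance_ratio"],
    }

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not serializable: {type(obj)}")

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_default) + "\n"
    )
    return summary


__all__ = [
    "cluster_heatmap",
    "pca_coordinates",
    "pca_plot",
    "PipelineConfig",
    "run_pipeline",
]
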