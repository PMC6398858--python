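"""End-to-end orchestration: simulate -> preprocess -> cluster -> validate.

``run_pipeline`` executes the full analysis from a :class:`RunConfig` and
writes all quantitative outputs as CSV/JSON plus a manifest that makes the
run reproducible (seeds, configuration hash, package versions).  Plots are
optional artifacts; nothing downstream parses them.

The ground-truth file of a simulated cohort (truth.csv) is written next to
the other inputs but never read by any analysis stage — only the optional
evaluation report compares labels against it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cimlr import Hyperparams, embed_and_cluster, fit_cimlr, select_num_clusters
from .interaction import SCHEMES, run_all
from .kernels import DEFAULT_K_GRID, DEFAULT_SIGMA_GRID, build_kernel_bank
from .preprocess import (
    filter_missing,
    minmax_scale,
    normalize_volumes,
    read_markers,
    read_metadata,
    read_volumes,
)
from .profiling import anova_by_cluster, marker_importance
from .stability import bootstrap_stability
from .synthetic import CohortConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``simulate`` is set (a CohortConfig; input CSVs are generated into
    the output directory) or the three input paths must point at existing
    files with the documented schemas.
    """

    out_dir: str = "plasmaclust_run"
    markers_csv: str | None = None
    volumes_csv: str | None = None
    metadata_csv: str | None = None
    simulate: CohortConfig | None = None
    n_clusters: int | None = 4          # None -> select from data
    c_range: tuple[int, int] = (2, 6)
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    stability_methods: tuple[str, ...] = ("cimlr", "kmeans_euclidean", "random")
    n_boot: int = 100
    schemes: tuple[str, ...] = SCHEMES
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    top_markers: int = 10
    make_plots: bool = False
    evaluate_truth: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = CohortConfig(**raw["simulate"])
        if "hyperparams" in raw and raw["hyperparams"] is not None:
            raw["hyperparams"] = Hyperparams(**raw["hyperparams"])
        for key in ("c_range", "k_grid", "sigma_grid", "stability_methods", "schemes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o).__name__)

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the output directory.

    Stages: simulate (optional) -> preprocess -> kernel bank -> model
    selection (optional) -> similarity fit -> embedding/labels -> stability
    -> marker profiling -> interaction analysis -> manifest.  A stage
    failure raises :class:`PipelineError` naming the stage; outputs of the
    completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": [],
    }

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(name, str(exc)) from exc
            manifest["stages"].append(name)
            return result

        return deco

    @stage("simulate")
    def cohort_paths():
        if config.simulate is None:
            for name, p in (("markers", config.markers_csv),
                            ("volumes", config.volumes_csv),
                            ("metadata", config.metadata_csv)):
                if p is None:
                    raise ValueError(f"{name}_csv must be set when not simulating")
            return {"markers": Path(config.markers_csv),
                    "volumes": Path(config.volumes_csv),
                    "metadata": Path(config.metadata_csv)}
        cohort = generate_cohort(config.simulate)
        return write_cohort(cohort, out / "inputs")

    @stage("preprocess")
    def prepared():
        raw_markers = read_markers(cohort_paths["markers"])
        volumes, icv = read_volumes(cohort_paths["volumes"])
        metadata = read_metadata(cohort_paths["metadata"])
        matrix, flog = filter_missing(raw_markers, metadata)
        keep = matrix.subject_ids
        scaled = minmax_scale(matrix)
        phen = normalize_volumes(volumes.loc[keep], icv.loc[keep])
        meta = metadata.loc[keep]
        pd.DataFrame({
            "dropped_subjects": pd.Series(flog.dropped_subjects, dtype=str),
        }).to_csv(out / "dropped_subjects.csv", index=False)
        pd.DataFrame({
            "dropped_markers": pd.Series(flog.dropped_markers, dtype=str),
        }).to_csv(out / "dropped_markers.csv", index=False)
        return scaled, phen, meta

    X, phenotypes, metadata = prepared

    @stage("kernel_bank")
    def bank():
        return build_kernel_bank(X, config.k_grid, config.sigma_grid)

    @stage("model_selection")
    def n_clusters():
        if config.n_clusters is not None:
            return config.n_clusters
        lo, hi = config.c_range
        sel = select_num_clusters(bank, range(lo, hi + 1), seed=config.seed,
                                  hyperparams=config.hyperparams)
        pd.DataFrame({
            "C": sel["c_range"],
            "eigengap": sel["eigengap"],
            "wcss": sel["wcss"],
            "elbow_score": sel["elbow_score"],
        }).to_csv(out / "model_selection.csv", index=False)
        manifest["chosen_n_clusters"] = int(sel["chosen"])
        return int(sel["chosen"])

    @stage("fit")
    def model():
        hp = config.hyperparams
        if hp.n_clusters != n_clusters:
            hp = dataclasses.replace(hp, n_clusters=n_clusters)
        m = fit_cimlr(bank, hp)
        embed_and_cluster(m, seed=config.seed)
        np.save(out / "similarity.npy", m.S)
        pd.DataFrame({"subject_id": X.subject_ids, "cluster": m.labels}).to_csv(
            out / "labels.csv", index=False)
        pd.DataFrame(m.embedding, columns=["dim1", "dim2"]).assign(
            subject_id=X.subject_ids).to_csv(out / "embedding.csv", index=False)
        return m

    @stage("stability")
    def stability_table():
        rows = []
        for method in config.stability_methods:
            rep = bootstrap_stability(
                X, model.labels, method, n_boot=config.n_boot, seed=config.seed,
                n_clusters=n_clusters, k_grid=config.k_grid,
                sigma_grid=config.sigma_grid, hyperparams=config.hyperparams)
            for c, mj in enumerate(rep.per_cluster_mean_jaccard):
                rows.append({"method": method, "cluster": c, "mean_jaccard": mj,
                             "n_boot": config.n_boot, "seed": config.seed})
        table = pd.DataFrame(rows)
        table.to_csv(out / "stability.csv", index=False)
        return table

    @stage("profiling")
    def profiles():
        imp = marker_importance(model, bank)
        imp.to_csv(out / "importance.csv", index=False)
        top = imp["marker_id"].head(config.top_markers).tolist()
        prof = anova_by_cluster(X, model.labels, top)
        prof.to_csv(out / "profiles.csv", index=False)
        return imp, prof

    @stage("interactions")
    def interactions():
        table = run_all(phenotypes, model.labels,
                        metadata["diagnosis"].to_numpy(),
                        schemes=config.schemes, n_perm=config.n_perm,
                        seed=config.seed, alpha=config.alpha)
        table.to_csv(out / "interactions.csv", index=False)
        return table

    if config.evaluate_truth and config.simulate is not None:
        @stage("evaluation")
        def _evaluation():
            from sklearn.metrics import adjusted_rand_score

            truth = pd.read_csv(out / "inputs" / "truth.csv")["true_cluster"]
            ari = adjusted_rand_score(truth, model.labels)
            (out / "evaluation.json").write_text(
                json.dumps({"ari_vs_truth": float(ari)}, indent=2))

    if config.make_plots:
        @stage("plots")
        def _plots():
            _make_plots(out, model, profiles[0], X)

    manifest["n_clusters"] = int(n_clusters)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out


def _make_plots(out: Path, model, importance: pd.DataFrame, X) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(model.labels, kind="stable")
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(model.S[np.ix_(order, order)], cmap="viridis", interpolation="nearest")
    ax.set_title("Learned similarity (ordered by cluster)")
    fig.savefig(out / "similarity_heatmap.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 5))
    for c in np.unique(model.labels):
        pts = model.embedding[model.labels == c]
        ax.scatter(pts[:, 0], pts[:, 1], s=12, label=f"C{c + 1}")
    ax.legend()
    ax.set_title("2-D embedding")
    fig.savefig(out / "embedding.png", dpi=120)
    plt.close(fig)

    top = importance.head(10)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.barh(top["marker_id"][::-1], top["importance"][::-1])
    ax.set_xlabel("importance (sum of kernel weights)")
    fig.tight_layout()
    fig.savefig(out / "importance.png", dpi=120)
    plt.close(fig)
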