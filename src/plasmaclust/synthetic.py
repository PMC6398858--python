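"""Synthetic ADNI-like cohorts with planted cluster structure.

Generates a cohort of subjects carrying

* a blood-marker matrix in which a small informative subset of markers is
  shifted by a cluster-specific signed pattern (each cluster raises or lowers
  each informative marker), on otherwise arbitrary per-marker raw scales;
* regional brain volumes with a monotone CN -> MCI -> AD atrophy effect on a
  fixed half of the regions, amplified or damped cluster-specifically on the
  designated interaction regions;
* an estimated intracranial volume (lognormal) per subject;
* diagnosis labels (CN / MCI / AD) drawn independently of cluster membership,
  so the planted subtypes are not confounded with disease stage;
* demographic covariates (age, sex, education, APOE4, MMSE) with
  stage-dependent means emulating a typical memory-clinic cohort.

Everything is deterministic given the master seed: each ingredient draws from
its own child generator spawned from ``SeedSequence(seed)`` in a fixed,
documented order (signatures, clusters, markers, diagnosis, volumes, icv,
demographics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import MarkerMatrix

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "write_cohort", "read_cohort"]

DIAGNOSES = ("CN", "MCI", "AD")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the simulated cohort.

    Defaults emulate the target study population: 298 subjects, 172 plasma
    markers of which 10 carry cluster signal, four subtypes with the observed
    size proportions, diagnosis mix 52/161/85 (CN/MCI/AD), and 39 subcortical
    volumes of which 6 carry a cluster-by-diagnosis interaction.
    ``marker_shift`` is the per-informative-marker mean offset in units of
    the marker noise SD.
    """

    n_subjects: int = 298
    n_markers: int = 172
    n_informative: int = 10
    n_clusters: int = 4
    cluster_proportions: tuple[float, ...] = (82 / 298, 77 / 298, 61 / 298, 78 / 298)
    marker_shift: float = 3.0
    marker_noise_sd: float = 1.0
    diag_proportions: tuple[float, ...] = (52 / 298, 161 / 298, 85 / 298)
    n_regions: int = 39
    n_interaction_regions: int = 6
    volume_diag_effect: float = 1.0
    volume_interaction_effect: float = 1.0
    volume_noise_sd: float = 1.0
    icv_log_mean: float = np.log(1.5e6)
    icv_log_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_markers", "n_informative", "n_clusters",
                     "n_regions", "n_interaction_regions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_informative > self.n_markers:
            raise ValueError("n_informative must be <= n_markers")
        if self.n_interaction_regions > self.n_regions:
            raise ValueError("n_interaction_regions must be <= n_regions")
        for name, vec, expect in (
            ("cluster_proportions", self.cluster_proportions, self.n_clusters),
            ("diag_proportions", self.diag_proportions, len(DIAGNOSES)),
        ):
            if len(vec) != expect:
                raise ValueError(f"{name} must have length {expect}")
            if any(p < 0 for p in vec):
                raise ValueError(f"{name} entries must be nonnegative")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if self.marker_shift < 0 or self.marker_noise_sd <= 0 or self.volume_noise_sd <= 0:
            raise ValueError("effect sizes must be >= 0 and noise SDs > 0")
        # downstream two-sample tests need at least 2 expected per stratum
        for name, vec in (("cluster", self.cluster_proportions),
                          ("diagnosis", self.diag_proportions)):
            smallest = self.n_subjects * min(vec)
            if smallest < 2:
                raise ValueError(
                    f"expected size of smallest {name} stratum is {smallest:.2f} < 2"
                )


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    marker_matrix: MarkerMatrix
    volumes: pd.DataFrame          # subjects x regions, positive, mm^3-like
    icv: pd.Series                 # per-subject intracranial volume
    diagnosis: pd.Series           # CN / MCI / AD
    metadata: pd.DataFrame         # diagnosis, age, sex, education, apoe4, mmse
    true_cluster: pd.Series        # int in [0, C)
    informative_marker_ids: list[str] = field(default_factory=list)
    interaction_region_ids: list[str] = field(default_factory=list)
    config: CohortConfig | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.true_cluster)


def _signed_patterns(n_clusters: int, n_informative: int, rng: np.random.Generator) -> np.ndarray:
    """Cluster signatures: a +-1 pattern per cluster over the informative
    markers.

    Patterns are rows of a Hadamard-type sign code tiled to the number of
    informative markers, so every pair of clusters differs on roughly half of
    them.  This keeps the planted partition identifiable from single-marker
    similarities: arbitrary sign patterns can place two clusters at Hamming
    distance 1, in which case they differ on a single marker and no
    marker-wise method can tell them apart reliably.  The assignment of code
    columns to markers is shuffled with ``rng`` (Hamming distances are
    unaffected).
    """
    from scipy.linalg import hadamard

    order = 1
    while order < n_clusters:
        order *= 2
    H = hadamard(order).astype(float)
    # keep only the sign-balanced columns (the all-ones column would shift
    # every cluster identically, planting a marker with no contrast)
    cols = H[:n_clusters, 1:]
    reps = int(np.ceil(n_informative / cols.shape[1]))
    patterns = np.tile(cols, (1, reps))[:, :n_informative]
    patterns = patterns[:, rng.permutation(n_informative)]
    return patterns


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a cohort per the config; deterministic for a fixed seed."""
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(7)
    rng_sig, rng_clu, rng_mrk, rng_dia, rng_vol, rng_icv, rng_dem = (
        np.random.default_rng(s) for s in streams
    )
    n, m, c = cfg.n_subjects, cfg.n_markers, cfg.n_clusters

    subject_ids = [f"S{i:04d}" for i in range(n)]
    marker_ids = [f"marker_{j:03d}" for j in range(m)]
    region_ids = [f"region_{r:02d}" for r in range(cfg.n_regions)]

    patterns = _signed_patterns(c, cfg.n_informative, rng_sig)
    true_cluster = rng_clu.choice(c, size=n, p=np.asarray(cfg.cluster_proportions))
    diagnosis = rng_dia.choice(len(DIAGNOSES), size=n, p=np.asarray(cfg.diag_proportions))

    # markers: arbitrary per-marker raw location/scale so min-max scaling is
    # exercised nontrivially; informative subset gets the cluster offsets.
    loc = rng_mrk.uniform(-50.0, 50.0, size=m)
    scale = rng_mrk.uniform(0.5, 20.0, size=m)
    values = rng_mrk.normal(0.0, cfg.marker_noise_sd, size=(n, m))
    informative = np.arange(cfg.n_informative)
    values[:, informative] += (
        cfg.marker_shift * cfg.marker_noise_sd * patterns[true_cluster]
    )
    values = loc[None, :] + scale[None, :] * values

    # volumes: half of the regions atrophy with disease stage; the first
    # n_interaction_regions of those additionally scale the stage effect by a
    # cluster-specific factor (alternating amplification / damping).
    base = rng_vol.uniform(1000.0, 20000.0, size=cfg.n_regions)
    region_sd = cfg.volume_noise_sd * base / 10.0
    effect_regions = np.arange(cfg.n_regions // 2)
    interaction_regions = np.arange(cfg.n_interaction_regions)
    cluster_factor = np.array([1.0 + cfg.volume_interaction_effect * (1 if k % 2 == 0 else -1)
                               for k in range(c)])
    stage = diagnosis.astype(float)  # CN=0, MCI=1, AD=2
    vol = base[None, :] + rng_vol.normal(0.0, 1.0, size=(n, cfg.n_regions)) * region_sd[None, :]
    diag_effect = np.zeros((n, cfg.n_regions))
    diag_effect[:, effect_regions] = (
        -cfg.volume_diag_effect * region_sd[None, effect_regions] * stage[:, None]
    )
    diag_effect[:, interaction_regions] *= cluster_factor[true_cluster][:, None]
    vol = np.maximum(vol + diag_effect, 1.0)

    icv = np.exp(rng_icv.normal(cfg.icv_log_mean, cfg.icv_log_sd, size=n))

    # demographics with stage-dependent means (ApoE4 fraction and MMSE track
    # disease stage; age/education roughly flat)
    age = rng_dem.normal(74.4, 7.4, size=n).round(1)
    sex = np.where(rng_dem.random(n) < 0.393, "F", "M")
    education = np.clip(rng_dem.normal(15.7, 2.7, size=n).round(), 6, 20).astype(int)
    apoe4_p = np.array([0.09, 0.52, 0.67])[diagnosis]
    apoe4 = (rng_dem.random(n) < apoe4_p).astype(int)
    mmse_mean = np.array([29.0, 26.9, 23.4])[diagnosis]
    mmse_sd = np.array([1.2, 1.8, 1.9])[diagnosis]
    mmse = np.clip(rng_dem.normal(mmse_mean, mmse_sd).round(), 0, 30).astype(int)

    diag_labels = pd.Series([DIAGNOSES[d] for d in diagnosis], index=subject_ids,
                            name="diagnosis")
    metadata = pd.DataFrame(
        {
            "diagnosis": diag_labels,
            "age": age,
            "sex": sex,
            "education": education,
            "apoe4": apoe4,
            "mmse": mmse,
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )

    return SyntheticCohort(
        marker_matrix=MarkerMatrix(
            values=values, subject_ids=subject_ids, marker_ids=marker_ids
        ),
        volumes=pd.DataFrame(vol, index=pd.Index(subject_ids, name="subject_id"),
                             columns=region_ids),
        icv=pd.Series(icv, index=subject_ids, name="icv"),
        diagnosis=diag_labels,
        metadata=metadata,
        true_cluster=pd.Series(true_cluster, index=subject_ids, name="true_cluster"),
        informative_marker_ids=[marker_ids[j] for j in informative],
        interaction_region_ids=[region_ids[r] for r in interaction_regions],
        config=cfg,
    )


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write markers.csv, volumes.csv, metadata.csv and truth.csv.

    Schemas (RFC-4180 CSV, header row, UTF-8):

    * markers.csv — subject_id, one column per marker
    * volumes.csv — subject_id, icv, one column per region
    * metadata.csv — subject_id, diagnosis, age, sex, education, apoe4, mmse
    * truth.csv — subject_id, true_cluster (ground truth; analysis stages
      must not read it)
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {directory}: {exc}") from exc

    paths = {}
    mm = cohort.marker_matrix
    markers = pd.DataFrame(mm.values, index=pd.Index(mm.subject_ids, name="subject_id"),
                           columns=mm.marker_ids)
    volumes = cohort.volumes.copy()
    volumes.insert(0, "icv", cohort.icv)
    truth = cohort.true_cluster.to_frame().rename_axis("subject_id")
    for name, frame in (
        ("markers", markers),
        ("volumes", volumes),
        ("metadata", cohort.metadata),
        ("truth", truth),
    ):
        path = directory / f"{name}.csv"
        try:
            frame.to_csv(path)
        except OSError as exc:
            raise OSError(f"failed writing {path}: {exc}") from exc
        paths[name] = path
    return paths


def read_cohort(directory) -> SyntheticCohort:
    """Round-trip reader for :func:`write_cohort` output (testing aid)."""
    directory = Path(directory)
    markers = pd.read_csv(directory / "markers.csv", index_col="subject_id")
    volumes = pd.read_csv(directory / "volumes.csv", index_col="subject_id")
    metadata = pd.read_csv(directory / "metadata.csv", index_col="subject_id")
    truth = pd.read_csv(directory / "truth.csv", index_col="subject_id")["true_cluster"]
    icv = volumes.pop("icv")
    return SyntheticCohort(
        marker_matrix=MarkerMatrix(
            values=markers.to_numpy(float),
            subject_ids=list(markers.index),
            marker_ids=list(markers.columns),
        ),
        volumes=volumes,
        icv=icv,
        diagnosis=metadata["diagnosis"],
        metadata=metadata,
        true_cluster=truth,
    )
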