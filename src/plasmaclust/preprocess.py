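"""Data preparation: missing-value filtering, ICV normalisation, min-max scaling.

The preparation mirrors a single-cohort cross-sectional design: subjects with
missing required baseline fields are dropped first, then any marker column
still containing a missing value is removed entirely, so the analysis matrix
is complete without imputation.  Regional brain volumes are divided by each
subject's estimated intracranial volume (ICV) to remove head-size effects, and
markers are min-max scaled to [0, 1] column by column before kernel
construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMatrix",
    "PhenotypeMatrix",
    "FilterLog",
    "filter_missing",
    "normalize_volumes",
    "minmax_scale",
    "read_markers",
    "read_volumes",
    "read_metadata",
]


@dataclass
class MarkerMatrix:
    """Complete subjects x markers matrix (x_im)."""

    values: np.ndarray
    subject_ids: list[str]
    marker_ids: list[str]
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.marker_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.marker_ids)} markers"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=pd.Index(self.subject_ids, name="subject_id"),
                            columns=self.marker_ids)


@dataclass
class PhenotypeMatrix:
    """Subjects x regions phenotype matrix, optionally ICV-normalized."""

    values: np.ndarray
    subject_ids: list[str]
    region_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.region_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.region_ids)} regions"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=pd.Index(self.subject_ids, name="subject_id"),
                            columns=self.region_ids)


@dataclass
class FilterLog:
    """Provenance of the missing-value filtering."""

    dropped_subjects: list[str] = field(default_factory=list)
    dropped_markers: list[str] = field(default_factory=list)


def filter_missing(raw_markers: pd.DataFrame,
                   raw_subjects: pd.DataFrame | None = None,
                   required_fields: list[str] | None = None,
                   ) -> tuple[MarkerMatrix, FilterLog]:
    """Drop subjects with missing required fields, then incomplete markers.

    Parameters
    ----------
    raw_markers : DataFrame indexed by subject id, one column per marker.
    raw_subjects : optional metadata DataFrame indexed by subject id; subjects
        with a missing value in any of ``required_fields`` (all metadata
        columns when None) are removed before the marker filter, and the
        marker table is restricted to subjects present in the metadata.
    required_fields : metadata columns that must be present per subject.

    Returns
    -------
    (MarkerMatrix, FilterLog) — the complete intersection matrix and the ids
    of everything dropped.
    """
    markers = raw_markers.copy()
    log = FilterLog()

    if raw_subjects is not None:
        cols = required_fields if required_fields is not None else list(raw_subjects.columns)
        missing_cols = [c for c in cols if c not in raw_subjects.columns]
        if missing_cols:
            raise KeyError(f"required fields {missing_cols} absent from subject table")
        bad = raw_subjects.index[raw_subjects[cols].isna().any(axis=1)]
        keep = raw_subjects.index.difference(bad, sort=False)
        dropped = [str(s) for s in markers.index if s not in set(keep)]
        log.dropped_subjects.extend(dropped)
        markers = markers.loc[[s for s in markers.index if s in set(keep)]]
        if markers.empty:
            raise ValueError("no subjects left after the subject-completeness filter")

    incomplete = markers.columns[markers.isna().any(axis=0)]
    log.dropped_markers.extend(str(c) for c in incomplete)
    markers = markers.drop(columns=incomplete)
    if markers.shape[1] == 0:
        raise ValueError("no markers left after the marker-completeness filter")

    if log.dropped_subjects or log.dropped_markers:
        logger.info(
            "filter_missing dropped %d subjects %s and %d markers %s",
            len(log.dropped_subjects), log.dropped_subjects,
            len(log.dropped_markers), log.dropped_markers,
        )
    return (
        MarkerMatrix(
            values=markers.to_numpy(float),
            subject_ids=[str(s) for s in markers.index],
            marker_ids=[str(c) for c in markers.columns],
        ),
        log,
    )


def normalize_volumes(volumes: pd.DataFrame, icv: pd.Series) -> PhenotypeMatrix:
    """Divide each region volume by the subject's intracranial volume."""
    icv = icv.reindex(volumes.index)
    if icv.isna().any():
        missing = list(volumes.index[icv.isna()])
        raise ValueError(f"ICV missing for subjects {missing}")
    bad = icv[icv <= 0]
    if len(bad):
        raise ValueError(
            f"nonpositive ICV for subject(s) {list(bad.index)}: {list(bad.values)}"
        )
    ratios = volumes.div(icv, axis=0)
    return PhenotypeMatrix(
        values=ratios.to_numpy(float),
        subject_ids=[str(s) for s in volumes.index],
        region_ids=[str(c) for c in volumes.columns],
        normalized=True,
    )


def minmax_scale(matrix):
    """Column-wise (x - min) / (max - min) scaling to [0, 1].

    Accepts a MarkerMatrix, PhenotypeMatrix or plain 2-D array and returns
    the same type.  Constant columns become all zeros (the formula is a 0/0
    there) with a warning.
    """
    if isinstance(matrix, MarkerMatrix):
        scaled = _minmax(matrix.values, matrix.marker_ids)
        return replace(matrix, values=scaled, scaled=True)
    if isinstance(matrix, PhenotypeMatrix):
        scaled = _minmax(matrix.values, matrix.region_ids)
        return replace(matrix, values=scaled)
    arr = np.asarray(matrix, dtype=float)
    return _minmax(arr, [str(j) for j in range(arr.shape[1])])


def _minmax(values: np.ndarray, col_ids) -> np.ndarray:
    if values.shape[0] < 2:
        raise ValueError("min-max scaling needs at least 2 subjects")
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        names = [col_ids[j] for j in np.flatnonzero(constant)]
        warnings.warn(f"constant column(s) {names} mapped to all zeros", stacklevel=3)
        span = np.where(constant, 1.0, span)
    return (values - lo) / span


def read_markers(path) -> pd.DataFrame:
    """Read a markers.csv (subject_id + one column per marker)."""
    return _read_csv(path, "markers")


def read_volumes(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a volumes.csv; returns (region volumes, icv)."""
    frame = _read_csv(path, "volumes")
    if "icv" not in frame.columns:
        raise KeyError(f"{path}: expected an 'icv' column")
    icv = frame.pop("icv")
    return frame, icv


def read_metadata(path) -> pd.DataFrame:
    """Read a metadata.csv (diagnosis, age, sex, education, apoe4, mmse)."""
    return _read_csv(path, "metadata")


def _read_csv(path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    frame = pd.read_csv(path)
    if "subject_id" not in frame.columns:
        raise KeyError(f"{path}: expected a 'subject_id' column")
    return frame.set_index("subject_id")
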