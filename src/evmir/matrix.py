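"""In-memory containers: the intensity matrix and the cohort label table.

The intensity matrix is probes x samples (microarray export convention),
carries a boolean detection mask of the same shape, and a processing-state
flag that enforces the pipeline order
``raw -> background_subtracted -> normalized -> log2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ShapeError, StateError, VocabularyError

STATES = ("raw", "background_subtracted", "normalized", "log2")

LABELS = ("cancer", "noncancer")
STAGES = ("I", "II", "III", "IV", "NA")


@dataclass
class IntensityMatrix:
    """Fluorescence intensities with a detection mask and a state flag.

    Parameters
    ----------
    values
        probes x samples DataFrame. Fluorescence units up to the
        ``normalized`` state, log2 units afterwards.
    mask
        Boolean DataFrame, same index/columns; True where the probe was
        detected in that sample. The mask never changes across transforms.
    state
        One of ``raw``, ``background_subtracted``, ``normalized``, ``log2``.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise StateError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.values.shape != self.mask.shape:
            raise ShapeError(
                f"values {self.values.shape} and mask {self.mask.shape} differ in shape"
            )
        if not (self.values.index.equals(self.mask.index)
                and self.values.columns.equals(self.mask.columns)):
            raise ShapeError("values and mask must share index (probes) and columns (samples)")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ShapeError(f"duplicate probe id {dup!r}")
        if self.state != "log2" and bool((self.values.to_numpy() < 0).any()):
            raise ShapeError("negative intensities are not allowed before log2 transform")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, state: str) -> "IntensityMatrix":
        """Return a new matrix with the same mask and a new state."""
        return IntensityMatrix(values=values, mask=self.mask, state=state)

    def require_state(self, state: str) -> None:
        if self.state != state:
            raise StateError(f"operation requires state {state!r}, matrix is {self.state!r}")


@dataclass
class CohortLabels:
    """Per-sample class and stage annotation.

    ``table`` is indexed by sample id with columns ``label`` (cancer /
    noncancer) and ``stage`` (I-IV for cancer subjects, NA otherwise or when
    unknown).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = {"label", "stage"} - set(self.table.columns)
        if missing:
            raise VocabularyError(f"metadata missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise VocabularyError(f"duplicate sample id {dup!r}")
        bad_label = set(self.table["label"]) - set(LABELS)
        if bad_label:
            raise VocabularyError(f"unknown label token(s): {sorted(bad_label)}")
        bad_stage = set(self.table["stage"]) - set(STAGES)
        if bad_stage:
            raise VocabularyError(f"unknown stage token(s): {sorted(bad_stage)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def is_cancer(self) -> pd.Series:
        return self.table["label"] == "cancer"

    @property
    def stage(self) -> pd.Series:
        return self.table["stage"]

    @property
    def n_cancer(self) -> int:
        return int(self.is_cancer.sum())

    @property
    def n_noncancer(self) -> int:
        return int((~self.is_cancer).sum())

    def y(self, sample_ids=None) -> np.ndarray:
        """0/1 label vector (1 = cancer) aligned to ``sample_ids`` order."""
        idx = self.table.index if sample_ids is None else pd.Index(sample_ids)
        return self.table.loc[idx, "label"].eq("cancer").to_numpy(dtype=float)

    def subset(self, sample_ids) -> "CohortLabels":
        return CohortLabels(self.table.loc[pd.Index(sample_ids)].copy())


def align(m: IntensityMatrix, labels: CohortLabels) -> None:
    """Check that the metadata covers exactly the matrix samples.

    Raises
    ------
    JoinError
        Listing the offending sample ids.
    """
    from .errors import JoinError

    mat = set(m.sample_ids)
    meta = set(labels.sample_ids)
    if mat != meta:
        only_mat = sorted(mat - meta)[:5]
        only_meta = sorted(meta - mat)[:5]
        raise JoinError(
            f"sample id mismatch: in matrix only {only_mat}, in metadata only {only_meta}"
        )


def to_design(m: IntensityMatrix, labels: CohortLabels):
    """samples x features design matrix + 0/1 labels for model fitting.

    Returns ``(X, y, probe_ids, sample_ids)`` with rows in matrix column
    order. The matrix must be in log2 state (the scale the classifier uses).
    """
    align(m, labels)
    X = m.values.to_numpy(dtype=float).T.copy()
    y = labels.y(m.sample_ids)
    return X, y, list(m.probe_ids), list(m.sample_ids)
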