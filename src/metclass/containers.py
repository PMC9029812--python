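"""Core in-memory containers shared across the pipeline.

The central object is :class:`FeatureMatrix`, a subjects-by-features
abundance table with an explicit observation mask.  Missing entries are
stored as NaN in ``values`` and as ``False`` in ``mask``; the two are kept
consistent by construction.  Subject metadata travels separately as a
pandas DataFrame (see :mod:`metclass.synthetic_data`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PHENOTYPES = ("Control", "AD", "PD")


class ConfigError(ValueError):
    """Raised for invalid generator or pipeline configuration."""


class ContractError(RuntimeError):
    """Raised when an intentionally unsupported code path is invoked."""


@dataclass
class FeatureMatrix:
    """Subjects x features abundance matrix with an explicit missing mask.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, n_features)
        Abundances; entries where ``mask`` is False are NaN.
    mask : ndarray of bool, same shape
        True where the entry was observed.
    subject_ids, feature_ids : ordered identifier lists.
    """

    values: np.ndarray
    mask: np.ndarray
    subject_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes disagree")
        if self.values.shape != (len(self.subject_ids), len(self.feature_ids)):
            raise ValueError("identifier lists do not match matrix shape")
        # enforce the NaN <-> unobserved convention
        self.values = np.where(self.mask, self.values, np.nan)

    # -- basic geometry -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(), self.mask.copy(),
            list(self.subject_ids), list(self.feature_ids),
        )

    # -- subsetting ------------------------------------------------------
    def select_subjects(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.values[idx], self.mask[idx],
            [self.subject_ids[i] for i in np.atleast_1d(idx)],
            list(self.feature_ids),
        )

    def select_features(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.values[:, idx], self.mask[:, idx],
            list(self.subject_ids),
            [self.feature_ids[j] for j in np.atleast_1d(idx)],
        )

    def drop_features(self, feature_ids) -> "FeatureMatrix":
        drop = set(feature_ids)
        keep = [j for j, f in enumerate(self.feature_ids) if f not in drop]
        if not keep:
            raise ValueError("dropping the requested features leaves an empty matrix")
        return self.select_features(np.array(keep, dtype=int))

    # -- summaries -------------------------------------------------------
    def missing_fraction(self, axis: int = 0) -> np.ndarray:
        """Per-feature (axis=0) or per-subject (axis=1) missing fraction."""
        return 1.0 - self.mask.mean(axis=axis)

    def overall_missing_fraction(self) -> float:
        return float(1.0 - self.mask.mean())

    # -- IO (RFC-4180 CSV, blank cell = missing) -------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=self.feature_ids)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "subject_id"
        df.to_csv(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        values = df.to_numpy(dtype=float)
        return cls(values, ~np.isnan(values),
                   [str(s) for s in df.index], [str(c) for c in df.columns])

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls.from_frame(df)


def feature_matrix_from_complete(values, subject_ids=None, feature_ids=None) -> FeatureMatrix:
    """Wrap a complete (no-missing) array as a FeatureMatrix."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if subject_ids is None:
        subject_ids = [f"S{i+1:04d}" for i in range(n)]
    if feature_ids is None:
        feature_ids = [f"F{j+1:05d}" for j in range(p)]
    return FeatureMatrix(values, ~np.isnan(values), list(subject_ids), list(feature_ids))
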