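"""Applicability-domain assessment.

A prediction is trusted only for compounds inside the model's domain. Two
views are provided: standardized descriptor values S_ki = (X_ki − X̄_i)/σ_i,
where the mean and standard deviation come from the *training* compounds
only and a compound is flagged when any |S_ki| of a model descriptor reaches
the threshold (default 3); and Tanimoto fingerprint similarity of each query
compound to every training compound, reported as advisory (max, mean, min)
summaries without a hard cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix, FingerprintSet

DEFAULT_AD_THRESHOLD = 3.0


@dataclass
class StandardizationStats:
    """Per-descriptor training mean and sample standard deviation."""

    descriptor_names: list[str]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        k = len(self.descriptor_names)
        if self.means.shape != (k,) or self.sds.shape != (k,):
            raise ValueError("means/sds length must match descriptor_names")
        if np.any(self.sds <= 0):
            raise ValueError("every descriptor needs positive training variance")

    @classmethod
    def from_training(cls, matrix: DescriptorMatrix) -> "StandardizationStats":
        vals = matrix.values
        return cls(
            descriptor_names=list(matrix.descriptor_names),
            means=vals.mean(axis=0),
            sds=vals.std(axis=0, ddof=1),
        )


@dataclass
class AdReport:
    """Standardized values, per-compound outlier flags and violation details."""

    compound_ids: list[str]
    descriptor_names: list[str]
    s_values: np.ndarray
    outlier_flags: np.ndarray  # bool per compound
    outlier_details: list[tuple[str, str, float]]  # (compound, descriptor, S)
    threshold: float

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.outlier_flags))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.s_values, index=self.compound_ids,
                          columns=self.descriptor_names)
        df["AD_outlier"] = self.outlier_flags
        return df


@dataclass
class SimilarityReport:
    """Query × train Tanimoto table plus (max, mean, min) per query."""

    query_ids: list[str]
    train_ids: list[str]
    matrix: np.ndarray  # (n_query, n_train) in [0, 1]

    @property
    def max(self) -> np.ndarray:
        return self.matrix.max(axis=1)

    @property
    def mean(self) -> np.ndarray:
        return self.matrix.mean(axis=1)

    @property
    def min(self) -> np.ndarray:
        return self.matrix.min(axis=1)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Tanimoto_max": self.max, "Tanimoto_mean": self.mean,
             "Tanimoto_min": self.min},
            index=self.query_ids,
        )


def standardize(matrix, stats: StandardizationStats) -> np.ndarray:
    """S_ki = (X_ki − X̄_i) / σ_i with training-set statistics.

    Applies identically to training, test, or new-set compounds; the
    descriptor sets must match exactly (same names, same order).
    """
    if isinstance(matrix, DescriptorMatrix):
        if list(matrix.descriptor_names) != list(stats.descriptor_names):
            raise ValueError(
                "descriptor sets differ between matrix and training stats"
            )
        values = matrix.values
    else:
        values = np.atleast_2d(np.asarray(matrix, dtype=float))
        if values.shape[1] != len(stats.descriptor_names):
            raise ValueError("column count does not match training stats")
    return (values - stats.means) / stats.sds


def flag_ad_outliers(
    s_matrix: np.ndarray,
    threshold: float = DEFAULT_AD_THRESHOLD,
    compound_ids: Sequence[str] | None = None,
    descriptor_names: Sequence[str] | None = None,
) -> AdReport:
    """Flag a compound iff any of its |S_ki| is at or above ``threshold``."""
    s = np.atleast_2d(np.asarray(s_matrix, dtype=float))
    if not np.all(np.isfinite(s)):
        raise ValueError("standardized matrix contains non-finite values")
    n, k = s.shape
    ids = list(compound_ids) if compound_ids is not None else [
        f"compound{i + 1}" for i in range(n)]
    names = list(descriptor_names) if descriptor_names is not None else [
        f"descriptor{j + 1}" for j in range(k)]
    mask = np.abs(s) >= threshold
    flags = mask.any(axis=1)
    details = [(ids[i], names[j], float(s[i, j]))
               for i in range(n) for j in range(k) if mask[i, j]]
    return AdReport(compound_ids=ids, descriptor_names=names, s_values=s,
                    outlier_flags=flags, outlier_details=details,
                    threshold=threshold)


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto similarity N_ab / (N_a + N_b − N_ab) of two bit vectors.

    Two all-zero fingerprints are taken as identical (similarity 1), since
    no bit distinguishes them.
    """
    a = np.asarray(fp_a).astype(bool)
    b = np.asarray(fp_b).astype(bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("fingerprints must be 1-D and of equal length")
    n_ab = int(np.sum(a & b))
    n_a = int(np.sum(a))
    n_b = int(np.sum(b))
    denom = n_a + n_b - n_ab
    if denom == 0:
        return 1.0
    return n_ab / denom


def similarity_to_train(query_fps: FingerprintSet,
                        train_fps: FingerprintSet) -> SimilarityReport:
    """Full query × train Tanimoto table with per-query summaries."""
    if train_fps.bits.shape[0] == 0:
        raise ValueError("empty training fingerprint set")
    if query_fps.n_bits != train_fps.n_bits:
        raise ValueError("fingerprint lengths differ between query and train")
    q = query_fps.bits.astype(np.int64)
    t = train_fps.bits.astype(np.int64)
    n_ab = q @ t.T
    n_a = q.sum(axis=1)[:, None]
    n_b = t.sum(axis=1)[None, :]
    denom = n_a + n_b - n_ab
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom == 0, 1.0, n_ab / np.where(denom == 0, 1, denom))
    return SimilarityReport(query_ids=list(query_fps.compound_ids),
                            train_ids=list(train_fps.compound_ids),
                            matrix=sim.astype(float))
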