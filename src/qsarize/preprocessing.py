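"""Descriptor-table cleaning.

Two passes: drop columns that cannot enter a regression (missing values or
zero variance), then optionally thin out highly correlated descriptors.
The correlation filter runs before any train/test split, on the whole table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorMatrix


@dataclass
class PreprocessReport:
    """What was removed and why.

    ``dropped_correlated`` holds ``(kept_name, removed_name, r)`` triples
    with the signed Pearson correlation; every recorded ``|r|`` is at or
    above ``threshold``.
    """

    dropped_invalid: list[str] = field(default_factory=list)
    dropped_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    threshold: float = 1.0

    def to_dict(self) -> dict:
        return {
            "dropped_invalid": list(self.dropped_invalid),
            "dropped_correlated": [
                {"kept": k, "removed": r, "correlation": c}
                for k, r, c in self.dropped_correlated
            ],
            "threshold": self.threshold,
        }


def drop_invalid(matrix: DescriptorMatrix) -> tuple[DescriptorMatrix, PreprocessReport]:
    """Remove columns with any missing value or zero variance across compounds."""
    if not matrix.descriptor_names:
        raise ValueError("empty descriptor matrix")
    keep, dropped = [], []
    for j, name in enumerate(matrix.descriptor_names):
        col = matrix.values[:, j]
        if not np.all(np.isfinite(col)) or np.ptp(col) == 0.0:
            dropped.append(name)
        else:
            keep.append(name)
    if not keep:
        raise ValueError("no usable descriptors: every column is missing or constant")
    return matrix.restrict(keep), PreprocessReport(dropped_invalid=dropped)


def remove_correlated(
    matrix: DescriptorMatrix, threshold: float
) -> tuple[DescriptorMatrix, PreprocessReport]:
    """Iteratively remove one member of each descriptor pair with
    |Pearson r| ≥ threshold until no such pair remains.

    A threshold of exactly 1 means "do not remove correlated descriptors":
    the matrix is returned unchanged. From a correlated pair, the member
    with the larger mean absolute correlation to all other remaining columns
    is dropped (ties broken toward the later column), so the survivor is the
    less redundant of the two. Deterministic for a given column order.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"correlation threshold must be in (0, 1], got {threshold}")
    report = PreprocessReport(threshold=threshold)
    if threshold == 1.0 or len(matrix.descriptor_names) < 2:
        return matrix, report

    names = matrix.descriptor_names
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(matrix.values, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    abs_corr = np.abs(corr)
    np.fill_diagonal(abs_corr, 0.0)

    keep = list(range(len(names)))
    while len(keep) > 1:
        sub = abs_corr[np.ix_(keep, keep)]
        flat = int(np.argmax(sub))
        i, j = divmod(flat, len(keep))
        if sub[i, j] < threshold:
            break
        ci, cj = keep[i], keep[j]
        mean_i = sub[i].sum() / (len(keep) - 1)
        mean_j = sub[j].sum() / (len(keep) - 1)
        if mean_i > mean_j or (mean_i == mean_j and ci > cj):
            drop, kept = ci, cj
        else:
            drop, kept = cj, ci
        report.dropped_correlated.append((names[kept], names[drop],
                                          float(corr[kept, drop])))
        keep.remove(drop)

    return matrix.restrict([names[k] for k in keep]), report
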