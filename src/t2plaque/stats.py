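"""Per-class T2 summaries and inter-reader agreement statistics.

Agreement between two readers grading the same arteries on an ordered
categorical scale (here the CMR-modified AHA plaque types: Normal, III,
IV-V, VI, VII, VIII) is summarized by the cross-classification table,
the fraction of matching classifications, and Cohen's kappa, which
corrects the observed agreement for the agreement expected by chance
from the marginal rating frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import T2Map
from .segmentation import SegmentationResult, SEG_CALCIFICATION

AHA_CATEGORIES = ("Normal", "III", "IV-V", "VI", "VII", "VIII")


@dataclass
class AgreementTable:
    """Square cross-classification counts; rows = rater A, cols = rater B."""

    categories: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        k = len(self.categories)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match categories")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(int)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.categories),
                            columns=list(self.categories))


def tabulate_agreement(ratings_a, ratings_b, categories) -> AgreementTable:
    """Cross-tabulate two equal-length rating vectors, preserving order."""
    ratings_a, ratings_b = list(ratings_a), list(ratings_b)
    if len(ratings_a) != len(ratings_b):
        raise ValueError("rating vectors differ in length")
    if not ratings_a:
        raise ValueError("empty rating vectors")
    idx = {c: i for i, c in enumerate(categories)}
    unknown = (set(ratings_a) | set(ratings_b)) - set(categories)
    if unknown:
        raise ValueError(f"unknown rating labels: {sorted(unknown)}")
    k = len(categories)
    counts = np.zeros((k, k), dtype=int)
    for a, b in zip(ratings_a, ratings_b):
        counts[idx[a], idx[b]] += 1
    return AgreementTable(categories=tuple(categories), counts=counts)


def percent_agreement(table: AgreementTable) -> float:
    """Observed agreement, trace / N, in [0, 1]."""
    if table.n == 0:
        raise ValueError("empty agreement table")
    return float(np.trace(table.counts)) / table.n


def cohens_kappa(table: AgreementTable, weights: str | None = None) -> float:
    """Cohen's kappa, ``(p_o - p_e) / (1 - p_e)``.

    ``p_o`` is the observed agreement and ``p_e = sum_i row_i * col_i / N^2``
    the chance agreement from the margins.  ``weights`` may be None
    (unweighted, the default), "linear" or "quadratic" for ordinal scales.
    """
    n = table.n
    if n == 0:
        raise ValueError("empty agreement table")
    k = len(table.categories)
    counts = table.counts.astype(float)
    if weights is None:
        w = 1.0 - np.eye(k)
    else:
        i, j = np.indices((k, k))
        d = np.abs(i - j) / (k - 1) if k > 1 else np.zeros((k, k))
        w = d if weights == "linear" else d**2 if weights == "quadratic" else None
        if w is None:
            raise ValueError(f"unknown weights {weights!r}")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    expected = np.outer(row, col) / n
    po_dis = float((w * counts).sum()) / n
    pe_dis = float((w * expected).sum()) / n
    if pe_dis == 0:
        raise ValueError("chance disagreement is zero; kappa undefined")
    return 1.0 - po_dis / pe_dis


def class_summary(segmentation: SegmentationResult, t2map: T2Map) -> pd.DataFrame:
    """Per-class voxel count, mean and SD (n-1) of accepted T2 values.

    Calcification reports a count only (it has no valid T2).  Classes
    with a single voxel have undefined SD; empty classes have undefined
    mean — both are flagged in the ``flag`` column.
    """
    if segmentation.label_map.shape != t2map.t2_ms.shape:
        raise ValueError("segmentation and T2 map grids differ")
    rows = []
    for cls in segmentation.model.classes:
        m = segmentation.label_map == cls
        vals = t2map.t2_ms[m]
        vals = vals[np.isfinite(vals)]
        n = len(vals)
        rows.append(dict(
            class_label=cls, n=n,
            mean_ms=float(vals.mean()) if n else np.nan,
            sd_ms=float(vals.std(ddof=1)) if n > 1 else np.nan,
            flag="" if n > 1 else ("single_voxel" if n == 1 else "empty"),
        ))
    n_calc = int((segmentation.label_map == SEG_CALCIFICATION).sum())
    rows.append(dict(class_label=SEG_CALCIFICATION, n=n_calc,
                     mean_ms=np.nan, sd_ms=np.nan, flag="count_only"))
    return pd.DataFrame(rows)
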