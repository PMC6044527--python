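"""Segmentation evaluation: DSC, 95-percentile Hausdorff distance, PKVD."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_volumes import RegionMap

__all__ = ["EvaluationReport", "dsc", "mhd95", "pkvd", "evaluate_cohort"]


def _labels(m) -> np.ndarray:
    return (m.labels if isinstance(m, RegionMap) else np.asarray(m)).astype(bool)


def dsc(a, b) -> float:
    """Dice similarity coefficient 2|A.B| / (|A|+|B|); 1.0 when both empty."""
    a, b = _labels(a), _labels(b)
    if a.shape != b.shape:
        raise ValueError("masks must share dims")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.count_nonzero(a & b) / denom)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Object voxels with at least one 6-neighbor background voxel."""
    mask = mask.astype(bool)
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=1
    )
    return mask & ~eroded


def mhd95(a, b, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
          percentile: float = 95.0) -> float:
    """Percentile of the pooled symmetric surface-to-surface distances (mm).

    Every boundary voxel of A contributes its Euclidean distance to the
    nearest boundary voxel of B and vice versa; both directions are pooled
    before taking the percentile.
    """
    a, b = _labels(a), _labels(b)
    if a.shape != b.shape:
        raise ValueError("masks must share dims")
    if not a.any() or not b.any():
        raise ValueError("mhd95 requires both masks nonempty")
    ba, bb = boundary_voxels(a), boundary_voxels(b)
    # EDT of the complement of each surface gives distance-to-surface fields
    da = ndimage.distance_transform_edt(~ba, sampling=spacing)
    db = ndimage.distance_transform_edt(~bb, sampling=spacing)
    pooled = np.concatenate([db[ba], da[bb]])
    return float(np.percentile(pooled, percentile))


def pkvd(seg, gt, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
         ) -> float:
    """Percentage kidney volume difference, normalized by the ground truth."""
    seg, gt = _labels(seg), _labels(gt)
    v_gt = gt.sum()
    if v_gt == 0:
        raise ValueError("ground truth mask is empty")
    vox = float(np.prod(spacing))
    return float(100.0 * abs(seg.sum() * vox - v_gt * vox) / (v_gt * vox))


@dataclass
class EvaluationReport:
    """Per-subject metric table with cohort summary statistics."""

    table: pd.DataFrame
    summary: pd.DataFrame
    paired_t: dict | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _metric_rows(pairs, spacing) -> pd.DataFrame:
    rows = []
    for i, (seg, gt) in enumerate(pairs):
        sp = spacing or getattr(seg, "spacing", (1.0, 1.0, 1.0))
        rows.append(
            {
                "subject": i,
                "dsc": dsc(seg, gt),
                "mhd95_mm": mhd95(seg, gt, sp),
                "pkvd_percent": pkvd(seg, gt, sp),
            }
        )
    return pd.DataFrame(rows)


def evaluate_cohort(pairs, spacing: tuple[float, float, float] | None = None,
                    pairs_other=None) -> EvaluationReport:
    """Cohort evaluation: per-subject metrics plus min/max/mean+-SD.

    ``pairs`` is a sequence of ``(segmentation, ground_truth)`` masks.  When
    ``pairs_other`` provides a second method's masks for the same subjects,
    paired two-sided t-tests compare the two methods per metric; zero
    between-method variance is flagged rather than tested.
    """
    if len(pairs) < 2:
        raise ValueError("cohort evaluation needs at least 2 subjects")
    table = _metric_rows(pairs, spacing)
    cols = ["dsc", "mhd95_mm", "pkvd_percent"]
    summary = pd.DataFrame(
        {
            "min": table[cols].min(),
            "max": table[cols].max(),
            "mean": table[cols].mean(),
            "sd": table[cols].std(ddof=1),
        }
    )
    paired = None
    if pairs_other is not None:
        from scipy import stats

        other = _metric_rows(pairs_other, spacing)
        paired = {}
        for c in cols:
            diff = table[c].to_numpy() - other[c].to_numpy()
            if np.allclose(diff, 0.0):
                paired[c] = {"p_value": 1.0, "zero_variance": True}
            else:
                t = stats.ttest_rel(table[c], other[c])
                paired[c] = {
                    "p_value": float(t.pvalue),
                    "statistic": float(t.statistic),
                    "zero_variance": False,
                }
    return EvaluationReport(table=table, summary=summary, paired_t=paired)
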