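"""Objectwise 3D validation, shrinkage estimation and subject aggregation.

Objectwise validation compares a reference (manually segmented) and a
predicted label volume by centroid-in-profile matching: a reference object
counts as a true positive when its centroid voxel lies inside a predicted
cell profile in the centroid's section, as a false negative otherwise, and
false positives are predicted centroids that fall in no reference profile.
Objects flagged as edge objects (centroid in the first/last sections) are
excluded from the tally.

Tissue deformation is quantified by point-count area estimation
A = ΣP·(a/p) before and after processing, with areal shrinkage
(before − after)/before.

Cross-subject aggregation reports the mean, the population SD (divisor n —
the convention needed to reproduce the published summary rows from their
per-subject values) and the coefficient of variation CV = SD/mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LabelVolume
from .segmentation import ConfusionCounts

__all__ = [
    "ObjectMatchResult",
    "ShrinkageEstimate",
    "SubjectSummary",
    "match_objects_3d",
    "point_count_area",
    "areal_shrinkage",
    "aggregate_subject_stats",
]


@dataclass
class ObjectMatchResult:
    """Centroid-in-profile matching between reference and predicted objects."""

    tp: int
    fn: int
    fp: int
    matches: list  # (reference id, predicted id or None)

    @property
    def counts(self) -> ConfusionCounts:
        return ConfusionCounts(tp=self.tp, fp=self.fp, tn=0, fn=self.fn)


def _centroid_voxels(vol: LabelVolume) -> dict[int, tuple[int, int, int]]:
    n_lab = int(vol.data.max())
    if n_lab == 0:
        return {}
    zi, yi, xi = np.nonzero(vol.data)
    fg = vol.data[vol.data > 0]
    counts = np.bincount(fg, minlength=n_lab + 1)[1:]
    coms = [np.bincount(fg, weights=w, minlength=n_lab + 1)[1:]
            / np.maximum(counts, 1) for w in (zi, yi, xi)]
    out = {}
    shape = vol.data.shape
    for lab in (int(i) for i in vol.labels):
        if lab in vol.edge_labels:
            continue
        idx = tuple(int(min(max(round(c[lab - 1]), 0), s - 1))
                    for c, s in zip(coms, shape))
        out[lab] = idx
    return out


def match_objects_3d(reference: LabelVolume,
                     predicted: LabelVolume) -> ObjectMatchResult:
    """Match reference and predicted 3D objects by centroid containment.

    Both volumes should already be filtered (artifact and consecutive-
    section rules); labels recorded in ``edge_labels`` are ignored.  The
    sub-voxel centroid is rounded to the nearest voxel, and membership is
    tested against the other volume's profile in that voxel's section.
    """
    if reference.data.shape != predicted.data.shape:
        raise ValueError("reference and predicted volumes differ in shape")
    matches = []
    tp = fn = 0
    for ref_id, (z, y, x) in _centroid_voxels(reference).items():
        pred_lab = int(predicted.data[z, y, x])
        if pred_lab > 0:
            tp += 1
            matches.append((ref_id, pred_lab))
        else:
            fn += 1
            matches.append((ref_id, None))
    fp = 0
    for pred_id, (z, y, x) in _centroid_voxels(predicted).items():
        if reference.data[z, y, x] == 0:
            fp += 1
    return ObjectMatchResult(tp=tp, fn=fn, fp=fp, matches=matches)


def point_count_area(hit_points: int, area_per_point: float) -> float:
    """Point-count area estimate A = ΣP · (a/p) in mm²."""
    if hit_points < 0:
        raise ValueError("hit count must be non-negative")
    if area_per_point <= 0:
        raise ValueError("area per point must be positive")
    return hit_points * area_per_point


@dataclass(frozen=True)
class ShrinkageEstimate:
    """Areal shrinkage of processed tissue; negative values mean swelling."""

    area_before: float  # mm²
    area_after: float   # mm²

    @property
    def shrinkage(self) -> float:
        return (self.area_before - self.area_after) / self.area_before


def areal_shrinkage(before: float, after: float) -> float:
    """(area before − area after) / area before; may be negative."""
    if before <= 0:
        raise ValueError("area before must be positive")
    return ShrinkageEstimate(before, after).shrinkage


@dataclass
class SubjectSummary:
    """Cross-subject mean, population SD and CV per measurement column."""

    per_subject: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    cv: pd.Series

    def table(self) -> pd.DataFrame:
        """Per-subject rows with Mean / SD / CV summary rows appended."""
        out = self.per_subject.copy()
        out.loc["Mean"] = self.mean
        out.loc["SD"] = self.sd
        out.loc["CV"] = self.cv
        return out


def aggregate_subject_stats(per_subject: pd.DataFrame) -> SubjectSummary:
    """Aggregate per-subject mean measurements across subjects.

    ``per_subject`` has one row per subject and one column per measurement
    (e.g. volume, orientation, sphericity, Dia_L, Dia_All).  The summary
    uses the population SD (divisor n, not n−1): the published summary
    rows are only reproducible from their per-subject values under that
    convention.
    """
    df = pd.DataFrame(per_subject).astype(float)
    if len(df) < 2:
        raise ValueError("need at least 2 subjects")
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=0)
    cv = sd / mean
    return SubjectSummary(per_subject=df, mean=mean, sd=sd, cv=cv)
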