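"""Published reference values used to validate metrics and aggregation.

These constants are the printed validation tables of a three-subject
serial-section study of layer-III pyramidal cells in human prefrontal
cortex (BA46): pixelwise confusion counts of a segmentation model per
subject, objectwise 3D-validation counts before/after edge filtering, and
per-subject morphometric summaries.  They serve as fixed inputs for
checking :func:`~cortex3d.segmentation.classification_metrics` and
:func:`~cortex3d.validation.aggregate_subject_stats` against their
published outputs.
"""

from __future__ import annotations

import pandas as pd

from .segmentation import ConfusionCounts

__all__ = [
    "PIXELWISE_CONFUSION",
    "PIXELWISE_METRICS_PUBLISHED",
    "OBJECTWISE_COUNTS",
    "SUBJECT_MORPHOMETRY_MEANS",
    "PYRAMIDAL_DENSITY_MM3",
    "MEAN_VOLUME_UM3",
    "subject_morphometry_frame",
]

#: Pixelwise confusion counts per (model, subject) on a 2048×2048 test image.
PIXELWISE_CONFUSION: dict[tuple[str, str], ConfusionCounts] = {
    ("individual", "subject1"): ConfusionCounts(tp=128937, fp=11710,
                                                tn=4033734, fn=19923),
    ("individual", "subject2"): ConfusionCounts(tp=83370, fp=14400,
                                                tn=4078724, fn=17810),
    ("individual", "subject3"): ConfusionCounts(tp=91266, fp=10717,
                                                tn=4080809, fn=11512),
    ("combined", "subject1"): ConfusionCounts(tp=119351, fp=9506,
                                              tn=4035938, fn=29509),
    ("combined", "subject2"): ConfusionCounts(tp=77409, fp=12994,
                                              tn=4083184, fn=20717),
    ("combined", "subject3"): ConfusionCounts(tp=92189, fp=12337,
                                              tn=4080847, fn=8931),
}

#: Published 2-decimal metrics corresponding to PIXELWISE_CONFUSION.
PIXELWISE_METRICS_PUBLISHED: dict[tuple[str, str], dict[str, float]] = {
    ("individual", "subject1"): {"sensitivity": 0.87, "precision": 0.92,
                                 "f1": 0.89},
    ("individual", "subject2"): {"sensitivity": 0.82, "precision": 0.85,
                                 "f1": 0.84},
    ("individual", "subject3"): {"sensitivity": 0.89, "precision": 0.89,
                                 "f1": 0.89},
    ("combined", "subject1"): {"sensitivity": 0.80, "precision": 0.93,
                               "f1": 0.86},
    ("combined", "subject2"): {"sensitivity": 0.79, "precision": 0.86,
                               "f1": 0.82},
    ("combined", "subject3"): {"sensitivity": 0.91, "precision": 0.88,
                               "f1": 0.90},
}

#: Objectwise 3D-validation counts (centroid-in-profile matching) for a
#: 30-section stack, before ("original") and after ("filtered") excluding
#: centroids from the first/last three sections.
OBJECTWISE_COUNTS: dict[str, ConfusionCounts] = {
    "original": ConfusionCounts(tp=472, fn=19, fp=33, tn=0),
    "filtered": ConfusionCounts(tp=368, fn=6, fp=29, tn=0),
}

#: Published objectwise metrics at 2 decimals.
OBJECTWISE_METRICS_PUBLISHED: dict[str, dict[str, float]] = {
    "original": {"sensitivity": 0.96, "precision": 0.93, "f1": 0.95},
    "filtered": {"sensitivity": 0.98, "precision": 0.93, "f1": 0.95},
}

#: Per-subject mean morphometric values of classified pyramidal cells.
SUBJECT_MORPHOMETRY_MEANS: dict[str, dict[str, float]] = {
    "subject1": {"volume_um3": 867, "orientation_deg": 34,
                 "sphericity": 0.38, "dia_L_um": 11.13, "dia_all_um": 7.23},
    "subject2": {"volume_um3": 709, "orientation_deg": 28,
                 "sphericity": 0.33, "dia_L_um": 11.13, "dia_all_um": 6.49},
    "subject3": {"volume_um3": 808, "orientation_deg": 24,
                 "sphericity": 0.35, "dia_L_um": 11.27, "dia_all_um": 7.37},
}

#: Published cross-subject summary (mean / CV rows).
SUBJECT_SUMMARY_PUBLISHED: dict[str, dict[str, float]] = {
    "mean": {"volume_um3": 795, "orientation_deg": 29, "sphericity": 0.35,
             "dia_L_um": 11.17, "dia_all_um": 7.03},
    "cv": {"volume_um3": 0.08, "orientation_deg": 0.14, "sphericity": 0.06,
           "dia_L_um": 0.01, "dia_all_um": 0.06},
}

#: Mean pyramidal-cell number density in the layer-III window, mm⁻³.
PYRAMIDAL_DENSITY_MM3: float = 28155.0

#: Cross-subject mean pyramidal soma volume, μm³.
MEAN_VOLUME_UM3: float = 795.0


def subject_morphometry_frame() -> pd.DataFrame:
    """Per-subject mean morphometry as a DataFrame (rows = subjects)."""
    return pd.DataFrame(SUBJECT_MORPHOMETRY_MEANS).T
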