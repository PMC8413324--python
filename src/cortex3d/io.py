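"""Reading and writing of stacks, masks, cell tables and point patterns.

Stacks travel as multi-page TIFF (16-bit grayscale for intensities, 8-bit
for masks, 32-bit for label volumes), tabular data as CSV, and scene /
window parameters as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import Box3D, ImageStack, LabelVolume, MaskStack, PointPattern3D

__all__ = [
    "write_stack", "read_stack", "write_mask", "read_mask",
    "write_labels", "read_labels", "write_cells_csv",
    "write_pattern_csv", "read_pattern_csv", "write_params_yaml",
    "read_params_yaml", "write_scene",
]


def write_stack(path, stack: ImageStack) -> None:
    tifffile.imwrite(path, np.asarray(stack.data, dtype=np.uint16))


def read_stack(path, spacing) -> ImageStack:
    return ImageStack(tifffile.imread(path), spacing)


def write_mask(path, mask: MaskStack) -> None:
    tifffile.imwrite(path, (mask.data * 255).astype(np.uint8))


def read_mask(path, spacing) -> MaskStack:
    return MaskStack((tifffile.imread(path) > 0).astype(np.uint8), spacing)


def write_labels(path, labels: LabelVolume) -> None:
    tifffile.imwrite(path, labels.data.astype(np.int32))


def read_labels(path, spacing) -> LabelVolume:
    return LabelVolume(tifffile.imread(path).astype(np.int32), spacing)


def write_cells_csv(path, cells) -> None:
    """Ground-truth or measured cell table as CSV."""
    from .synthetic import GroundTruthCell

    rows = []
    for c in cells:
        if isinstance(c, GroundTruthCell):
            rows.append({
                "id": c.id, "x": c.centroid[0], "y": c.centroid[1],
                "z": c.centroid[2], "a": c.semi_axes[0],
                "b": c.semi_axes[1], "c": c.semi_axes[2],
                "ux": c.orientation[0], "uy": c.orientation[1],
                "uz": c.orientation[2], "class": c.class_label,
            })
        else:  # CellObject
            rows.append({
                "id": c.id, "cx": c.centroid[0], "cy": c.centroid[1],
                "cz": c.centroid[2], "volume_um3": c.volume,
                "surface_um2": c.surface_area, "sphericity": c.sphericity,
                "feret2d_max_um": c.max_feret_2d,
                "feret3d_um": c.max_feret_3d,
                "theta_deg": c.orientation_angle,
                "n_sections": c.n_sections, "edge_flag": c.edge,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_pattern_csv(path, pattern: PointPattern3D) -> None:
    df = pd.DataFrame(pattern.points, columns=["x", "y", "z"])
    if pattern.marks is not None:
        df["mark"] = pattern.marks
    df.to_csv(path, index=False)


def read_pattern_csv(path, window) -> PointPattern3D:
    if isinstance(window, (tuple, list)):
        window = Box3D.from_lengths(window)
    df = pd.read_csv(path)
    marks = df["mark"].to_numpy() if "mark" in df else None
    return PointPattern3D(df[["x", "y", "z"]].to_numpy(), window, marks)


def write_params_yaml(path, params) -> None:
    from dataclasses import asdict, is_dataclass

    data = asdict(params) if is_dataclass(params) else dict(params)
    clean = {}
    for k, v in data.items():
        if isinstance(v, tuple):
            v = list(v)
        clean[k] = v
    Path(path).write_text(yaml.safe_dump(clean, sort_keys=False))


def read_params_yaml(path, cls=None):
    data = yaml.safe_load(Path(path).read_text())
    for k, v in data.items():
        if isinstance(v, list):
            data[k] = tuple(v)
    return data if cls is None else cls(**data)


def write_scene(outdir, scene) -> None:
    """Export a synthetic scene: stack, truth labels, cells, pattern, params."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_stack(outdir / "stack.tif", scene.stack)
    write_labels(outdir / "truth_labels.tif", scene.truth_labels)
    write_cells_csv(outdir / "cells.csv", scene.cells)
    write_pattern_csv(outdir / "pattern.csv", scene.pattern)
    write_params_yaml(outdir / "params.yaml", scene.params)
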