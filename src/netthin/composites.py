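"""Network cortical composites: label volumes, vertex mapping, mean thickness.

The composite machinery turns a set of volumetric network node masks into a
per-vertex network labelling and averages cortical thickness over each
network's vertices at each visit:

1. a group modal-label atlas codes every voxel as the most frequent label
   across individual label volumes;
2. node masks are upsampled by cubic interpolation; resampled values above
   0.25 that fall inside the gray-matter cortical partition receive the
   node's label (overlaps resolved by highest interpolated value);
3. each surface vertex collects the voxels whose centers lie within a radius
   (default 2 mm) and takes their modal label;
4. a network's composite thickness at a visit is the unweighted mean over
   its labelled vertices.

Ties in any modal step break toward the smallest label id, with the
undefined label 0 never beating a defined label on a tied count.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "modal_label_atlas",
    "resample_node_masks",
    "map_labels_to_vertices",
    "composite_thickness",
    "cohort_composites",
]


def _modal_with_tie_rule(counts: np.ndarray) -> np.ndarray:
    """Row-wise argmax with label 0 demoted on exact ties.

    ``counts`` is (n, n_labels+1) with column j the count of label j.
    Smallest label id wins among tied defined labels (argmax returns the
    first maximum); label 0 only wins when its count strictly exceeds all
    defined counts.
    """
    adj = counts.astype(float)
    adj[:, 0] -= 0.5
    out = np.argmax(adj, axis=1)
    out[counts.sum(axis=1) == 0] = 0
    return out


def modal_label_atlas(label_volumes: list[np.ndarray]) -> np.ndarray:
    """Per-voxel mode of a stack of integer label volumes."""
    if not label_volumes:
        raise ValueError("need at least one label volume")
    shape = label_volumes[0].shape
    vols = []
    for v in label_volumes:
        v = np.asarray(v)
        if v.shape != shape:
            raise ValueError("label volumes must share a grid")
        if not np.issubdtype(v.dtype, np.integer):
            raise ValueError("label volumes must be integer-valued")
        if v.min() < 0:
            raise ValueError("labels must be non-negative")
        vols.append(v.reshape(-1))
    max_label = int(max(v.max() for v in vols))
    n = vols[0].size
    counts = np.zeros((n, max_label + 1), dtype=np.int64)
    idx = np.arange(n)
    for v in vols:
        counts[idx, v] += 1
    return _modal_with_tie_rule(counts).reshape(shape)


def resample_node_masks(
    node_masks: dict[int, np.ndarray],
    zoom: float | tuple[float, float, float],
    gray_partition: np.ndarray,
    inclusion_threshold: float = 0.25,
) -> np.ndarray:
    """Upsample node masks and label the gray-matter partition.

    Each mask (binary or probabilistic) is resampled by cubic interpolation
    with the given zoom factor; target voxels whose interpolated value
    exceeds ``inclusion_threshold`` and that lie inside ``gray_partition``
    receive the node's label.  Where nodes overlap, the highest interpolated
    value wins (ties to the smallest label).  An all-empty result triggers a
    warning, not an error.
    """
    if not 0.0 < inclusion_threshold < 1.0:
        raise ValueError("inclusion_threshold must lie in (0, 1)")
    if not node_masks:
        raise ValueError("need at least one node mask")
    gray = np.asarray(gray_partition, dtype=bool)
    out = np.zeros(gray.shape, dtype=np.int32)
    best = np.zeros(gray.shape, dtype=float)
    for label in sorted(node_masks):
        if label <= 0:
            raise ValueError("node labels must be positive integers")
        vals = ndimage.zoom(np.asarray(node_masks[label], dtype=float), zoom, order=3)
        if vals.shape != gray.shape:
            raise ValueError(
                f"zoomed mask shape {vals.shape} does not match gray partition {gray.shape}"
            )
        sel = (vals > inclusion_threshold) & gray & (vals > best)
        out[sel] = label
        best[sel] = vals[sel]
    if not out.any():
        warnings.warn("resampled node masks produced an empty labelling", stacklevel=2)
    return out


def map_labels_to_vertices(
    labels: np.ndarray,
    affine: np.ndarray,
    vertices: np.ndarray,
    radius: float = 2.0,
) -> np.ndarray:
    """Assign each vertex the modal label of voxels within ``radius`` mm.

    Voxel centers are mapped to world coordinates through the NIfTI-style
    ``affine`` (0-based indices).  A vertex with no in-radius voxel, or whose
    neighborhood carries only the undefined label, stays undefined (0).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    labels = np.asarray(labels)
    vertices = np.atleast_2d(np.asarray(vertices, dtype=float))
    if vertices.shape[1] != 3:
        raise ValueError("vertices must be (n, 3) mm coordinates")
    idx = np.indices(labels.shape).reshape(3, -1).T  # (V, 3) ijk
    centers = idx @ affine[:3, :3].T + affine[:3, 3]
    tree = cKDTree(centers)
    flat = labels.reshape(-1)
    max_label = int(flat.max()) if flat.size else 0
    out = np.zeros(vertices.shape[0], dtype=np.int32)
    neighborhoods = tree.query_ball_point(vertices, r=radius)
    for i, neigh in enumerate(neighborhoods):
        if not neigh:
            continue
        counts = np.bincount(flat[neigh], minlength=max_label + 1)
        out[i] = _modal_with_tie_rule(counts[None, :])[0]
    return out


def composite_thickness(
    vertex_labels: np.ndarray, thickness: np.ndarray, network: int
) -> tuple[float, int]:
    """Unweighted mean thickness over a network's vertices at one visit.

    ``thickness`` may contain NaN for vertices undefined at this visit.
    Returns (mean thickness mm, contributing vertex count); raises when no
    labelled vertex has a defined thickness.
    """
    vertex_labels = np.asarray(vertex_labels)
    thickness = np.asarray(thickness, dtype=float)
    sel = (vertex_labels == network) & np.isfinite(thickness)
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"no vertices with defined thickness carry label {network}")
    return float(thickness[sel].mean()), n


def cohort_composites(
    vertex_labels: np.ndarray,
    thickness_table: pd.DataFrame,
    networks: dict[int, str],
) -> pd.DataFrame:
    """Tidy per-subject, per-visit composite table.

    ``thickness_table`` is long with columns (subject, visit_time, vertex,
    thickness).  Returns columns (subject, visit_time, network, thickness,
    n_vertices).
    """
    rows = []
    for (subject, t), grp in thickness_table.groupby(["subject", "visit_time"], sort=True):
        th = np.full(len(vertex_labels), np.nan)
        th[grp["vertex"].to_numpy()] = grp["thickness"].to_numpy()
        for label, name in networks.items():
            mean, n = composite_thickness(vertex_labels, th, label)
            rows.append((subject, t, name, mean, n))
    return pd.DataFrame(
        rows, columns=["subject", "visit_time", "network", "thickness", "n_vertices"]
    )
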