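"""Quantitative and qualitative registration evaluation.

Metrics: target registration error (TRE) between corresponding landmark
sets (Euclidean distance in mm), tumor volume ratio (TVR, shared
implementation with the training-time volume penalty), Jacobian
positivity (fraction of non-folding voxels), cumulative TRE histograms,
and 3-D checkerboard fusions for visual assessment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .objectives import volume_penalty
from .transforms import jacobian_determinant
from .volumes_io import (DisplacementField, Image3D, LandmarkSet,
                         SegmentationMask)

__all__ = ["tre", "tvr", "jacobian_positivity", "cumulative_tre_histogram",
           "checkerboard", "evaluation_report"]


def tre(mapped: LandmarkSet, reference: LandmarkSet):
    """Per-landmark Euclidean distances (mm) and pooled summary statistics.

    Landmark correspondences are positional: the two sets must have equal
    counts and matching order.
    """
    if len(mapped) != len(reference):
        raise ValueError("landmark sets must have equal counts")
    d = np.linalg.norm(mapped.points - reference.points, axis=1)
    summary = {"mean": float(d.mean()), "median": float(np.median(d)),
               "max": float(d.max()), "n": int(len(d))}
    return d, summary


def tvr(mask: SegmentationMask, u: DisplacementField) -> float:
    """Tumor volume ratio after/before warping (1.0 for the identity field).

    Identical computation to the training volume penalty, evaluated
    without gradients.
    """
    return float(volume_penalty(mask, np.asarray(u.data, dtype=float)))


def jacobian_positivity(u: DisplacementField,
                        region: SegmentationMask | None = None) -> float:
    """Fraction of voxels (optionally within ``region``) with positive
    Jacobian determinant of the deformation."""
    det = jacobian_determinant(u).data
    if region is not None:
        sel = region.data > 0.5
        if not sel.any():
            raise ValueError("empty evaluation region")
        det = det[sel]
    return float((det > 0).mean())


def cumulative_tre_histogram(distances, bin_edges) -> pd.DataFrame:
    """Cumulative fraction of landmarks with TRE <= each bin edge.

    The final row always closes at fraction 1.0 (edges are extended with
    the maximum distance when they do not cover it).
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no distances given")
    edges = np.asarray(sorted(bin_edges), dtype=float)
    if edges.size == 0 or edges[-1] < d.max():
        edges = np.append(edges, d.max())
    frac = [(d <= e).mean() for e in edges]
    return pd.DataFrame({"tre_mm": edges, "cumulative_fraction": frac})


def checkerboard(a: Image3D, b: Image3D, tile_voxels: int) -> Image3D:
    """Alternate ``tile_voxels``-cubed tiles of two same-grid volumes."""
    if a.shape != b.shape:
        raise ValueError("checkerboard inputs must share a grid")
    if tile_voxels < 1:
        raise ValueError("tile size must be >= 1")
    idx = np.indices(a.shape) // tile_voxels
    parity = idx.sum(axis=0) % 2
    return a.copy_with(np.where(parity == 0, a.data, b.data))


def evaluation_report(u: DisplacementField,
                      moving_landmarks: LandmarkSet | None = None,
                      fixed_landmarks: LandmarkSet | None = None,
                      mask: SegmentationMask | None = None) -> dict:
    """JSON-serializable summary of all metrics available for a case.

    Fixed-space landmarks are mapped through ``u`` (backward convention)
    and compared against the moving-space landmarks.
    """
    from .transforms import transform_landmarks
    report = {"jacobian_positivity": jacobian_positivity(u)}
    if moving_landmarks is not None and fixed_landmarks is not None:
        mapped, keep = transform_landmarks(fixed_landmarks, u,
                                           return_mask=True)
        ref = LandmarkSet(moving_landmarks.points[keep])
        d, summary = tre(mapped, ref)
        report["tre_mm"] = summary
        report["tre_per_landmark_mm"] = [float(x) for x in d]
    if mask is not None:
        report["tvr"] = tvr(mask, u)
        report["jacobian_positivity_tumor"] = jacobian_positivity(u, mask)
    return report
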