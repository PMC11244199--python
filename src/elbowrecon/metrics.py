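"""Segmentation and reconstruction quality metrics.

* Volume/slice overlap: IoU (|A∩B| / |A∪B|) and Dice.
* Per-slice IoU curves for inspecting joint-region behavior.
* Mesh surface error: one-directional distance from each vertex of the
  predicted mesh to the nearest point on the reference surface (triangle
  soup or point cloud), reported as max / mean / quartiles in mm; a
  symmetric (max of both directions) variant is available behind a flag.
* Order-statistic summaries (median, p10/p90, quartiles, range) with
  linearly interpolated (type-7) quantiles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DataError
from .reconstruction import SurfaceMesh


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two equal-shape binary masks.

    1.0 when the masks coincide, 0.0 when disjoint; two empty masks are
    defined as IoU 1.0 with a warning.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise DataError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("IoU of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|); two empty masks -> 1.0."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise DataError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def per_slice_iou(pred_volume: np.ndarray, gt_volume: np.ndarray) -> dict[int, float]:
    """IoU per slice, for slices where either mask is nonempty."""
    pred = np.asarray(pred_volume, dtype=bool)
    gt = np.asarray(gt_volume, dtype=bool)
    if pred.shape != gt.shape:
        raise DataError("volumes must be aligned")
    out: dict[int, float] = {}
    for z in range(pred.shape[0]):
        if pred[z].any() or gt[z].any():
            out[z] = iou(pred[z], gt[z])
    return out


# ---------------------------------------------------------------------------
# Surface error
# ---------------------------------------------------------------------------


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distance from each point to its matching triangle.

    ``points`` is (N, 3); ``tri`` is (N, 3, 3).  Standard region-based
    closest-point-on-triangle computation, fully vectorized.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    def assign(cond, value):
        sel = cond & ~done
        closest[sel] = value[sel] if value.ndim == 2 else value
        done[sel] = True

    assign((d1 <= 0) & (d2 <= 0), a)  # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)  # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)  # vertex C

    vc = d1 * d4 - d3 * d2
    v_ab = np.divide(d1, d1 - d3, out=np.zeros_like(d1), where=(d1 - d3) != 0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge AB

    vb = d5 * d2 - d1 * d6
    w_ac = np.divide(d2, d2 - d6, out=np.zeros_like(d2), where=(d2 - d6) != 0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge AC

    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    w_bc = np.divide(d4 - d3, denom_bc, out=np.zeros_like(d4), where=denom_bc != 0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))

    denom = va + vb + vc
    v = np.divide(vb, denom, out=np.zeros_like(vb), where=denom != 0)
    w = np.divide(vc, denom, out=np.zeros_like(vc), where=denom != 0)
    assign(np.ones(len(points), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return np.linalg.norm(points - closest, axis=1)


def _distances_to_surface(points: np.ndarray, target: SurfaceMesh | np.ndarray, k: int = 8):
    """Distance from each point to a reference mesh (exact, via candidate
    triangles found by a centroid KD-tree) or to a reference point cloud."""
    points = np.asarray(points, dtype=float)
    if isinstance(target, np.ndarray) or (
        not isinstance(target, SurfaceMesh) and np.ndim(target) == 2
    ):
        cloud = np.asarray(target, dtype=float)
        d, _ = cKDTree(cloud).query(points, k=1)
        return np.asarray(d, dtype=float)
    tri = target.vertices[target.faces]  # (M, 3, 3)
    centroids = tri.mean(axis=1)
    k = min(k, len(centroids))
    _, cand = cKDTree(centroids).query(points, k=k)
    cand = np.atleast_2d(cand.T).T if k == 1 else cand
    best = np.full(len(points), np.inf)
    for col in range(k):
        d = _point_triangle_distance(points, tri[cand[:, col]])
        best = np.minimum(best, d)
    return best


@dataclass
class SurfaceErrorStats:
    """Distance statistics (mm) from predicted vertices to a reference surface."""

    max: float
    mean: float
    q1: float
    q3: float

    def as_dict(self) -> dict:
        return asdict(self)


def surface_error(
    mesh_pred: SurfaceMesh,
    mesh_gt: SurfaceMesh | np.ndarray,
    symmetric: bool = False,
) -> SurfaceErrorStats:
    """One-directional surface error: each predicted vertex to the reference.

    With ``symmetric=True``, the reference mesh's vertices are also measured
    against the predicted mesh and the per-statistic maxima reported.
    """
    if len(mesh_pred.vertices) == 0:
        raise DataError("predicted mesh is empty")
    d = _distances_to_surface(mesh_pred.vertices, mesh_gt)
    stats = SurfaceErrorStats(
        max=float(d.max()),
        mean=float(d.mean()),
        q1=float(np.percentile(d, 25)),
        q3=float(np.percentile(d, 75)),
    )
    if symmetric:
        if not isinstance(mesh_gt, SurfaceMesh):
            raise DataError("symmetric surface error needs a reference mesh, not points")
        back = _distances_to_surface(mesh_gt.vertices, mesh_pred)
        stats = SurfaceErrorStats(
            max=max(stats.max, float(back.max())),
            mean=max(stats.mean, float(back.mean())),
            q1=max(stats.q1, float(np.percentile(back, 25))),
            q3=max(stats.q3, float(np.percentile(back, 75))),
        )
    return stats


# ---------------------------------------------------------------------------
# Summaries and plots
# ---------------------------------------------------------------------------


def summarize(values) -> dict[str, float]:
    """Order statistics (type-7 linear-interpolation quantiles) of a sample."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise DataError("cannot summarize an empty sample")
    q = np.percentile(values, [10, 25, 50, 75, 90])
    return {
        "median": float(q[2]),
        "p10": float(q[0]),
        "p90": float(q[4]),
        "q1": float(q[1]),
        "q3": float(q[3]),
        "min": float(values.min()),
        "max": float(values.max()),
    }


def save_report(report: dict, path) -> None:
    from pathlib import Path

    Path(path).write_text(json.dumps(report, indent=2))


def plot_per_slice_iou(curves: dict[str, dict[int, float]], path) -> None:
    """PNG of per-slice IoU curves, one line per bone."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for bone, curve in curves.items():
        zs = sorted(curve)
        ax.plot(zs, [curve[z] for z in zs], label=bone)
    ax.set_xlabel("slice index")
    ax.set_ylabel("IoU")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_box(groups: dict[str, list[float]], path, ylabel: str = "value") -> None:
    """PNG box plot (whiskers at the 10th/90th percentiles)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot([groups[k] for k in groups], tick_labels=list(groups), whis=(10, 90))
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
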