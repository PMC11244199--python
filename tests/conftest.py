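import numpy as np
import pytest

from elbowrecon import phantom, pipeline
from elbowrecon.recognition import ConnectedComponent


@pytest.fixture(scope="session")
def default_phantom():
    """The canonical mid-range phantom used across modules."""
    return phantom.generate(phantom.PhantomSpec(flexion_angle=110.0, seed=42))


@pytest.fixture(scope="session")
def default_products(default_phantom):
    """Full pipeline output (reference backend) on the canonical phantom."""
    return pipeline.run_pipeline(default_phantom.volume, gt=default_phantom.labels)


def make_component(indices, spacing=(1.0, 1.0, 1.0), comp_id=0) -> ConnectedComponent:
    """Build a component from an iterable of (z, y, x) voxel indices."""
    idx = np.asarray(sorted(tuple(i) for i in indices), dtype=np.int64).reshape(-1, 3)
    ds, dh = float(spacing[0]), float(spacing[2])
    pts = np.column_stack([idx[:, 2] * ds, idx[:, 1] * ds, idx[:, 0] * dh]).astype(float)
    return ConnectedComponent(comp_id, idx, pts)


def component_from_points_mm(points, comp_id=0) -> ConnectedComponent:
    """Component with explicit mm coordinates (voxel indices unused)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    idx = np.zeros((len(pts), 3), dtype=np.int64)
    return ConnectedComponent(comp_id, idx, pts)


def brute_force_min_distance(points_a, points_b) -> float:
    """O(n^2) pairwise scan oracle for the minimum inter-cloud distance."""
    a = np.asarray(points_a, float)
    b = np.asarray(points_b, float)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def naive_flood_fill_labels(mask, connectivity=26):
    """Brute-force BFS labeling oracle (set-of-frozensets of components)."""
    mask = np.asarray(mask, bool)
    if connectivity == 26:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    else:
        offsets = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    nz, ny, nx = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = []
        while queue:
            z, y, x = queue.pop()
            comp.append((z, y, x))
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if 0 <= p[0] < nz and 0 <= p[1] < ny and 0 <= p[2] < nx:
                    if mask[p] and not seen[p]:
                        seen[p] = True
                        queue.append(p)
        comps.append(frozenset(comp))
    return set(comps)
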