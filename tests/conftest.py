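"""Shared fixtures: digitized analytic shapes and a reference phantom run."""

from __future__ import annotations

import numpy as np
import pytest

from lacumorph.geometry import rasterize_ellipsoid
from lacumorph.morphometry import measure_lacunae
from lacumorph.phantom import PhantomSpec, generate_phantom
from lacumorph.segmentation import compute_threshold, extract_voids, label_and_classify


def digitize_ellipsoid(semi_axes, voxel_size_um=1.2, rotation=None, pad_um=6.0):
    """Boolean grid of an axis-aligned (or rotated) ellipsoid, center rule."""
    semi = np.asarray(semi_axes, dtype=float)
    n = int(np.ceil(2 * (semi.max() + pad_um) / voxel_size_um))
    shape = (n, n, n)
    center = np.array([n / 2 * voxel_size_um] * 3)
    rot = np.eye(3) if rotation is None else rotation
    sl, inside = rasterize_ellipsoid(shape, center, semi, rot, voxel_size_um)
    grid = np.zeros(shape, dtype=bool)
    grid[sl] = inside
    return grid


@pytest.fixture(scope="session")
def reference_phantom():
    """Default-SNR cortical phantom with 100 lacunae of 100-600 um^3."""
    spec = PhantomSpec(
        compartment="cortical",
        grid_shape=(110, 100, 100),
        voxel_size_um=1.2,
        slab_thickness_um=110.0,
        lacuna_count=100,
        volume_clip_um3=(100.0, 600.0),
        seed=1,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def reference_segmentation(reference_phantom):
    """Otsu threshold + labeled voids + per-lacuna records of the fixture."""
    res = reference_phantom
    thr = compute_threshold(res.volume, res.envelope)
    voids = extract_voids(res.volume, res.envelope, thr)
    labeled = label_and_classify(voids, res.volume.voxel_size_um)
    records = measure_lacunae(labeled, "ref", "cortical")
    return dict(threshold=thr, voids=voids, labeled=labeled, records=records)


def match_ground_truth(res, labeled):
    """Map each ground-truth lacuna to the segmented component under its center.

    Returns a list of (ground-truth row, component label or 0).
    """
    vs = res.volume.voxel_size_um
    out = []
    for _, row in res.ground_truth.iterrows():
        idx = tuple(
            int(np.clip(row[f"center_{ax}_um"] / vs, 0, n - 1))
            for ax, n in zip("zyx", labeled.labels.shape)
        )
        out.append((row, int(labeled.labels[idx])))
    return out
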