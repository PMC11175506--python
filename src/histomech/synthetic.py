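"""Synthetic fixture generators with known ground truth.

Every generator is deterministic under its seed and returns (or writes) a
ground-truth sidecar so analyses can be validated end to end without any
external data.  Noise is additive Gaussian (camera-like); the downstream
quantifications are ratio- or position-based, so the noise model's fine
structure is immaterial.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon
from skimage.morphology import dilation, erosion, footprint_rectangle
from skimage.segmentation import find_boundaries

from .core import TissueMesh


def render_label_image(
    mesh: TissueMesh, pixel_size: float, shape: tuple | None = None
) -> np.ndarray:
    """Rasterize mesh faces into an integer label image (0 = outside).

    Pixel (r, c) covers the square [c, c+1) x [r, r+1) * pixel_size in
    mesh coordinates; faces are filled by polygon scan conversion.  Face
    ``i`` receives label ``i + 1``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if shape is None:
        hi = mesh.positions.max(axis=0)
        shape = (int(np.ceil(hi[1] / pixel_size)) + 1, int(np.ceil(hi[0] / pixel_size)) + 1)
    labels = np.zeros(shape, dtype=np.int32)
    for fi, face in enumerate(mesh.faces):
        # integer index = pixel center at (index + 0.5) * pixel_size
        pts = mesh.positions[face] / pixel_size - 0.5
        rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=shape)
        free = labels[rr, cc] == 0
        labels[rr[free], cc[free]] = fi + 1
    return labels


def make_membrane_zstack(
    thickness_field: np.ndarray,
    z_spacing: float = 1.0,
    peak_width: float = 1.0,
    snr: float = np.inf,
    seed: int = 0,
    n_z: int = 16,
) -> tuple[np.ndarray, dict]:
    """Two-peak axial membrane stack with a per-pixel ground-truth thickness.

    Each pixel's z profile is the sum of two unit Gaussians of width
    ``peak_width`` (in z-planes) centered symmetrically about mid-stack and
    separated by ``thickness_field / z_spacing`` planes, plus Gaussian noise
    of standard deviation ``1 / snr``.
    """
    field = np.asarray(thickness_field, dtype=float)
    if np.any(field / z_spacing >= n_z):
        raise ValueError("thickness exceeds the z extent of the stack")
    z = np.arange(n_z, dtype=float)[:, None, None]
    mid = (n_z - 1) / 2.0
    sep = field[None, :, :] / z_spacing
    c1 = mid - sep / 2.0
    c2 = mid + sep / 2.0
    stack = (
        np.exp(-0.5 * ((z - c1) / peak_width) ** 2)
        + np.exp(-0.5 * ((z - c2) / peak_width) ** 2)
    )
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, 1.0 / snr, size=stack.shape)
    truth = {
        "kind": "membrane_zstack",
        "z_spacing": z_spacing,
        "peak_width_planes": peak_width,
        "snr": None if not np.isfinite(snr) else float(snr),
        "seed": seed,
        "mean_thickness_um": float(field.mean()),
    }
    return stack, truth


def make_trajectories(
    n_vertices: int,
    T: int,
    jitter_sigma: float,
    drift_per_frame=(0.0, 0.0),
    seed: int = 0,
    box: float = 20.0,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Vertex tracks: common rigid drift plus iid Gaussian jitter.

    Returns a tidy table (vertex_id, t, x, y), the raw (n, T, 2) array, and
    the ground truth.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    rng = np.random.default_rng(seed)
    drift = np.asarray(drift_per_frame, dtype=float)
    base = rng.uniform(0.0, box, size=(n_vertices, 2))
    t = np.arange(T, dtype=float)
    traj = base[:, None, :] + t[None, :, None] * drift[None, None, :]
    traj = traj + rng.normal(0.0, jitter_sigma, size=traj.shape)
    records = pd.DataFrame(
        {
            "vertex_id": np.repeat(np.arange(n_vertices), T),
            "t": np.tile(np.arange(T), n_vertices),
            "x": traj[:, :, 0].ravel(),
            "y": traj[:, :, 1].ravel(),
        }
    )
    truth = {
        "kind": "trajectories",
        "jitter_sigma": jitter_sigma,
        "drift_per_frame": drift.tolist(),
        "seed": seed,
        "n_vertices": n_vertices,
        "T": T,
    }
    return records, traj, truth


def trajectories_from_table(df: pd.DataFrame) -> np.ndarray:
    """(n, T, 2) array from a tidy (vertex_id, t, x, y) table."""
    piv_x = df.pivot(index="vertex_id", columns="t", values="x")
    piv_y = df.pivot(index="vertex_id", columns="t", values="y")
    if piv_x.isna().any().any():
        raise ValueError("ragged trajectory table")
    return np.stack([piv_x.to_numpy(), piv_y.to_numpy()], axis=2)


def make_enrichment_image(
    mesh: TissueMesh,
    ratio: float,
    background: float = 10.0,
    cytosol_level: float = 100.0,
    snr: float = np.inf,
    seed: int = 0,
    pixel_size: float = 0.2,
    shape: tuple | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Junction/cytosol intensity image with a set enrichment ratio.

    The junction mask is the 1-pixel-dilated boundary band of the rendered
    label image; the cytosol mask is the eroded cell interior.  Junction
    pixels sit at ``background + ratio * cytosol_level``, cytosol pixels at
    ``background + cytosol_level``; Gaussian noise has standard deviation
    ``cytosol_level / snr``.  Returns (image, junction_mask, cytosol_mask,
    ground_truth).
    """
    labels = render_label_image(mesh, pixel_size, shape)
    # Pad so a genuine outside-background region exists even when the nest
    # fills the rendered frame (background estimation needs it).
    labels = np.pad(labels, 8)
    boundary = find_boundaries(labels, mode="thick")
    junction = dilation(boundary, footprint_rectangle((3, 3)))
    interior = labels > 0
    cytosol = erosion(interior, footprint_rectangle((3, 3))) & ~junction
    image = np.full(labels.shape, background, dtype=float)
    image[cytosol] = background + cytosol_level
    image[junction] = background + ratio * cytosol_level
    # Remaining interior pixels (between the masks) get cytosol level.
    rest = interior & ~junction & ~cytosol
    image[rest] = background + cytosol_level
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, cytosol_level / snr, size=image.shape)
    truth = {
        "kind": "enrichment_image",
        "ratio": ratio,
        "background": background,
        "cytosol_level": cytosol_level,
        "snr": None if not np.isfinite(snr) else float(snr),
        "seed": seed,
        "pixel_size": pixel_size,
    }
    return image, junction, cytosol, truth
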