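"""Independent brute-force oracles (pure triple loops, no vectorization).

These deliberately re-derive voxel counts, face counts and radial binning
from first principles so the production implementations are checked against
a second, independent route.
"""

from __future__ import annotations

import math

import numpy as np

_NEIGHBORS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


def brute_class_count(labels: np.ndarray, codes) -> int:
    codes = set(int(c) for c in np.atleast_1d(codes))
    n = 0
    nz, ny, nx = labels.shape
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                if int(labels[k, j, i]) in codes:
                    n += 1
    return n


def _in_class(labels, k, j, i, codes):
    nz, ny, nx = labels.shape
    if not (0 <= k < nz and 0 <= j < ny and 0 <= i < nx):
        return False
    return int(labels[k, j, i]) in codes


def brute_exposed_faces(labels: np.ndarray, codes) -> int:
    """Faces separating class voxels from anything else (outside grid counts)."""
    codes = set(int(c) for c in np.atleast_1d(codes))
    n = 0
    nz, ny, nx = labels.shape
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                if int(labels[k, j, i]) not in codes:
                    continue
                for dk, dj, di in _NEIGHBORS:
                    if not _in_class(labels, k + dk, j + dj, i + di, codes):
                        n += 1
    return n


def brute_contact_faces(labels: np.ndarray, codes_a, codes_b) -> int:
    """Faces where an ``a``-class voxel abuts a ``b``-class voxel."""
    codes_a = set(int(c) for c in np.atleast_1d(codes_a))
    codes_b = set(int(c) for c in np.atleast_1d(codes_b))
    n = 0
    nz, ny, nx = labels.shape
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                if int(labels[k, j, i]) not in codes_a:
                    continue
                for dk, dj, di in _NEIGHBORS:
                    if _in_class(labels, k + dk, j + dj, i + di, codes_b):
                        n += 1
    return n


def brute_bic(labels: np.ndarray) -> float:
    """Percent of implant faces (codes {2,3}) abutting bone (code 1);
    outside-grid faces count as background."""
    implant = (2, 3)
    exposed = brute_exposed_faces(labels, implant)
    contact = brute_contact_faces(labels, implant, (1,))
    return 100.0 * contact / exposed


def brute_bvtv(labels: np.ndarray, roi: np.ndarray) -> float:
    nb = nbg = 0
    nz, ny, nx = labels.shape
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                if not roi[k, j, i]:
                    continue
                code = int(labels[k, j, i])
                if code == 1:
                    nb += 1
                elif code == 0:
                    nbg += 1
    return 100.0 * nb / (nb + nbg)


def brute_azimuthal(counts, geometry, n_bins):
    """Per-pixel radial q-binning loop mirroring the production contract."""
    ny, nx = counts.shape
    qmax = 0.0
    qs = np.empty((ny, nx))
    for j in range(ny):
        for i in range(nx):
            r = math.hypot(j - geometry.center_y_px, i - geometry.center_x_px)
            two_theta = math.atan(r * geometry.pixel_mm / geometry.distance_mm)
            q = 4.0 * math.pi / geometry.wavelength_nm * math.sin(two_theta / 2.0)
            qs[j, i] = q
            qmax = max(qmax, q)
    edges = np.linspace(0.0, qmax * (1 + 1e-12), n_bins + 1)
    sums = np.zeros(n_bins)
    nums = np.zeros(n_bins, dtype=int)
    for j in range(ny):
        for i in range(nx):
            b = int(np.digitize(qs[j, i], edges)) - 1
            b = min(b, n_bins - 1)
            sums[b] += counts[j, i]
            nums[b] += 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = (nums > 0) & (centers > 0)
    return centers[keep], sums[keep] / nums[keep]


def random_labeled_grid(rng, max_side=20, p_implant=0.3):
    """Random small label grid guaranteed to contain implant voxels."""
    shape = tuple(int(rng.integers(3, max_side + 1)) for _ in range(3))
    labels = rng.choice(
        [0, 1, 2, 3], size=shape, p=[0.4, 0.3, p_implant / 2, p_implant / 2]
    ).astype(np.uint8)
    if not np.isin(labels, (2, 3)).any():
        labels[0, 0, 0] = 3
    return labels
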