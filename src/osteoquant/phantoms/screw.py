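"""Eroded-screw phantom: labeled volume + reference screw + analytic truth.

The screw is an axisymmetric cylinder with a sinusoidal radial thread
modulation (pitch 0.4 mm, an M2-like thread), so the continuous geometry
stays tractable: the signed distance to the screw surface is computed in
the (rho, z) half-plane against a densely sampled boundary polyline, and

* residual metal   = { signed distance <= -erosion_depth }
* degradation layer= { -erosion < sdf <= -erosion + layer_thickness }
* bone             = azimuthal sector phi < 2*pi*bone_fill_fraction of the
                     peri-implant shell outside the layer

Ground truth is evaluated on the continuous geometry: volumes by fine 2D
midpoint quadrature with the 2*pi*rho axisymmetric weight, the initial
surface area by Pappus' theorem on the boundary polyline, and BIC/BV-TV
exactly from the azimuthal-sector construction (both equal
100 * bone_fill_fraction). The voxel grid is an independent measurement
route over the same geometry.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ..morphometry import (
    BACKGROUND,
    BONE,
    DEGRADATION,
    METAL,
    LabeledVolume,
    ScrewReference,
)
from .truth import PhantomTruth

THREAD_PITCH_UM = 400.0  # M2-like pitch

_FINE_UM = 0.5  # quadrature / sdf grid step
_BOUNDARY_STEP_UM = 0.25


class _ScrewGeometry:
    """Continuous axisymmetric screw: signed distance + analytic measures."""

    def __init__(self, length_um, radius_um, thread_depth_um):
        if radius_um <= thread_depth_um:
            raise ValueError("thread depth must be smaller than the radius")
        self.length_um = float(length_um)
        self.radius_um = float(radius_um)
        self.thread_depth_um = float(thread_depth_um)
        self._boundary = self._sample_boundary()
        self._tree = cKDTree(self._boundary)

    def profile(self, z):
        """Outer radius r0(z) of the thread profile (valid for 0<=z<=L)."""
        half = self.thread_depth_um / 2.0
        return (
            self.radius_um
            - half
            + half * np.sin(2.0 * np.pi * np.asarray(z) / THREAD_PITCH_UM)
        )

    def _sample_boundary(self):
        L, step = self.length_um, _BOUNDARY_STEP_UM
        nz = max(int(np.ceil(L / step)), 2) + 1
        z = np.linspace(0.0, L, nz)
        r = self.profile(z)
        lateral = np.column_stack([z, r])
        r0, rL = float(r[0]), float(r[-1])
        cap0 = np.column_stack(
            [np.zeros(max(int(r0 / step), 2)), np.linspace(0.0, r0, max(int(r0 / step), 2))]
        )
        # capL runs rL -> 0 so the three pieces chain into one open path
        # (zero-length seams); Pappus then integrates each surface once
        capL = np.column_stack(
            [np.full(max(int(rL / step), 2), L), np.linspace(rL, 0.0, max(int(rL / step), 2))]
        )
        return np.vstack([cap0, lateral, capL])

    def signed_distance(self, z, rho):
        """Signed distance (um) to the screw surface; negative inside."""
        z = np.asarray(z, dtype=float)
        rho = np.asarray(rho, dtype=float)
        pts = np.column_stack([z.ravel(), rho.ravel()])
        dist, _ = self._tree.query(pts, workers=-1)
        inside = (
            (pts[:, 0] >= 0.0)
            & (pts[:, 0] <= self.length_um)
            & (pts[:, 1] <= self.profile(pts[:, 0]))
        )
        sdf = np.where(inside, -dist, dist)
        return sdf.reshape(z.shape)

    def initial_surface_area_um2(self):
        """Pappus: A = sum over boundary segments of 2*pi*rho_mid*ds."""
        b = self._boundary
        # segments within each boundary piece; the vstack seams contribute
        # zero-length or duplicated points only
        seg = np.diff(b, axis=0)
        ds = np.hypot(seg[:, 0], seg[:, 1])
        rho_mid = 0.5 * (b[:-1, 1] + b[1:, 1])
        return float(np.sum(2.0 * np.pi * rho_mid * ds))


def _fine_grid(geom, rho_max, z_lo, z_hi, step=_FINE_UM):
    rho = np.arange(step / 2.0, rho_max, step)
    z = np.arange(z_lo + step / 2.0, z_hi, step)
    return rho, z


def make_screw_phantom(
    length_mm: float = 0.8,
    radius_mm: float = 0.25,
    thread_depth_mm: float = 0.05,
    erosion_depth_um: float = 50.0,
    layer_thickness_um: float = 30.0,
    bone_fill_fraction: float = 0.5,
    voxel_um: float = 5.0,
    seed: int = 0,
    *,
    t_years: float = 1.0,
    bone_margin_um: float = 200.0,
):
    """Generate an eroded-screw labeled volume with analytic ground truth.

    Returns ``(LabeledVolume, ScrewReference, PhantomTruth)``. The truth DR
    is (Vi - Vr) / (Ai * t_years) on the continuous geometry; BIC and BV/TV
    truths are exactly ``100 * bone_fill_fraction`` by construction.
    """
    if not 0.0 <= bone_fill_fraction <= 1.0:
        raise ValueError("bone_fill_fraction must be in [0, 1]")
    if erosion_depth_um > 0 and voxel_um > erosion_depth_um / 2.0:
        raise ValueError("voxel_um must be <= erosion_depth_um / 2")
    if layer_thickness_um < 0 or erosion_depth_um < 0:
        raise ValueError("erosion and layer thickness must be >= 0")
    if t_years <= 0:
        raise ValueError("t_years must be > 0")

    L = length_mm * 1e3
    R = radius_mm * 1e3
    geom = _ScrewGeometry(L, R, thread_depth_mm * 1e3)

    e = float(erosion_depth_um)
    layer = float(layer_thickness_um)
    outgrow = max(0.0, layer - e)  # how far the layer reaches past the screw

    pad = outgrow + bone_margin_um + 4.0 * voxel_um
    rho_max = R + pad
    z_lo, z_hi = -pad, L + pad

    # ---- continuous truth by fine 2D quadrature -------------------------
    rho_f, z_f = _fine_grid(geom, rho_max, z_lo, z_hi)
    Zf, Rf = np.meshgrid(z_f, rho_f, indexing="ij")
    sdf_f = geom.signed_distance(Zf, Rf)
    w = 2.0 * np.pi * Rf * _FINE_UM * _FINE_UM  # um^3 per 2D cell
    vi_um3 = float(np.sum(w[sdf_f <= 0.0]))
    metal_f = sdf_f <= -e
    if not metal_f.any():
        raise ValueError("fully degraded phantom")
    vr_um3 = float(np.sum(w[metal_f]))
    ai_um2 = geom.initial_surface_area_um2()

    um3_to_mm3 = 1e-9
    um2_to_mm2 = 1e-6
    Vi = vi_um3 * um3_to_mm3
    Vr = vr_um3 * um3_to_mm3
    Ai = ai_um2 * um2_to_mm2
    dr_true = (Vi - Vr) / (Ai * t_years)

    truth = PhantomTruth(
        seed=seed,
        dr_true=dr_true,
        bic_true=100.0 * bone_fill_fraction,
        bvtv_true=100.0 * bone_fill_fraction,
        extras={
            "Vi_mm3": Vi,
            "Vr_mm3": Vr,
            "Ai_mm2": Ai,
            "t_years": t_years,
            "erosion_depth_um": e,
            "layer_thickness_um": layer,
        },
    )

    # ---- voxelization ---------------------------------------------------
    nxy = int(np.ceil(2.0 * rho_max / voxel_um))
    nz = int(np.ceil((z_hi - z_lo) / voxel_um))
    xy = (np.arange(nxy) - (nxy - 1) / 2.0) * voxel_um
    zc = z_lo + (np.arange(nz) + 0.5) * voxel_um
    X, Y = np.meshgrid(xy, xy, indexing="ij")
    rho_xy = np.hypot(X, Y)
    phi_xy = np.mod(np.arctan2(Y, X), 2.0 * np.pi)
    in_sector = phi_xy < 2.0 * np.pi * bone_fill_fraction

    # bilinear lookup of the fine sdf grid, slice by slice in z
    rho_idx = np.clip((rho_xy - rho_f[0]) / _FINE_UM, 0, len(rho_f) - 1.001)
    r0i = rho_idx.astype(np.intp)
    rw = (rho_idx - r0i).astype(np.float32)

    labels = np.empty((nz, nxy, nxy), dtype=np.uint8)
    ref_mask = np.empty((nz, nxy, nxy), dtype=bool)
    z_idx = np.clip((zc - z_f[0]) / _FINE_UM, 0, len(z_f) - 1.001)
    sdf_f32 = sdf_f.astype(np.float32)
    for k in range(nz):
        zi = int(z_idx[k])
        zw = np.float32(z_idx[k] - zi)
        row0 = sdf_f32[zi]
        row1 = sdf_f32[zi + 1]
        s0 = row0[r0i] * (1 - rw) + row0[r0i + 1] * rw
        s1 = row1[r0i] * (1 - rw) + row1[r0i + 1] * rw
        s = s0 * (1 - zw) + s1 * zw
        ref_mask[k] = s <= 0.0
        slab = np.full(s.shape, BACKGROUND, dtype=np.uint8)
        bone_here = in_sector & (s > -e + layer) & (s <= bone_margin_um)
        slab[bone_here] = BONE
        slab[(s > -e) & (s <= -e + layer)] = DEGRADATION
        slab[s <= -e] = METAL
        labels[k] = slab

    vol = LabeledVolume(labels, voxel_um)
    ref = ScrewReference(mask=ref_mask, voxel_um=voxel_um, Vi=Vi, Ai=Ai)
    return vol, ref, truth
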