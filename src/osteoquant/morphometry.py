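"""Voxel morphometry of labeled bone-implant volumes.

Operates on isotropic 3D label grids with four classes (background, bone,
degradation layer, residual metal) and a co-registered pre-implantation
reference screw mask. Quantities:

* degradation rate  DR = (Vi - Vr) / (Ai * t)        [mm/year]
* bone-implant contact  BIC = 100 * A / Ad           [%]
* bone volume fraction  BV/TV inside a peri-implant ROI  [%]

Surface areas use 6-connectivity exposed-face counting; the same convention
is used for the contact area and the total degraded-implant surface so their
ratio is unbiased to first order. Distances are in micrometres, volumes in
mm^3, areas in mm^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

BACKGROUND = 0
BONE = 1
DEGRADATION = 2
METAL = 3
VALID_CODES = (BACKGROUND, BONE, DEGRADATION, METAL)
#: classes forming the "degraded implant" for BIC (residual metal + layer)
IMPLANT_CODES = (DEGRADATION, METAL)

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class LabeledVolume:
    """Validated 3D label field with isotropic voxel size in micrometres."""

    labels: np.ndarray
    voxel_um: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3 or labels.size == 0:
            raise ValueError("labels must be a non-empty 3D grid")
        if not float(self.voxel_um) > 0:
            raise ValueError("voxel_um must be > 0")
        bad = np.setdiff1d(np.unique(labels), VALID_CODES)
        if bad.size:
            raise ValueError(f"unknown label codes present: {bad.tolist()}")
        object.__setattr__(self, "labels", labels.astype(np.uint8, copy=False))
        object.__setattr__(self, "voxel_um", float(self.voxel_um))

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_um * 1e-3) ** 3

    @property
    def voxel_face_mm2(self) -> float:
        return (self.voxel_um * 1e-3) ** 2


@dataclass(frozen=True)
class ScrewReference:
    """Registered pre-implantation screw: binary mask + continuous Vi / Ai."""

    mask: np.ndarray
    voxel_um: float
    Vi: float  # mm^3
    Ai: float  # mm^2

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError("reference mask must be 3D")
        if not (self.Vi > 0 and self.Ai > 0):
            raise ValueError("Vi and Ai must be positive")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "voxel_um", float(self.voxel_um))


@dataclass
class MorphometryResult:
    dr: float  # mm/year
    bic: float  # percent
    bvtv: float  # percent
    vr: float  # residual metal volume mm^3
    volume_loss: float  # mm^3
    t_years: float
    vi: float = field(default=float("nan"))

    def as_record(self) -> dict:
        return {
            "Vi_mm3": self.vi,
            "Vr_mm3": self.vr,
            "volume_loss_mm3": self.volume_loss,
            "DR_mm_per_year": self.dr,
            "BIC_pct": self.bic,
            "BVTV_pct": self.bvtv,
            "t_years": self.t_years,
        }


def label_volume(labels: np.ndarray, voxel_um: float) -> LabeledVolume:
    """Validate a raw label grid into a :class:`LabeledVolume`."""
    return LabeledVolume(np.asarray(labels), voxel_um)


def class_volume(vol: LabeledVolume, code: int | Iterable[int]) -> float:
    """Volume (mm^3) of one class or a union of classes."""
    codes = _as_codes(code)
    count = int(np.isin(vol.labels, codes).sum())
    return count * vol.voxel_volume_mm3


def _as_codes(code: int | Iterable[int]) -> list[int]:
    codes = [int(code)] if np.isscalar(code) else [int(c) for c in code]
    for c in codes:
        if c not in VALID_CODES:
            raise ValueError(f"invalid class code {c}")
    return codes


def _exposed_face_count(mask: np.ndarray) -> int:
    """Count voxel faces separating ``mask`` voxels from anything else.

    Grid-boundary faces count as exposed (the outside is never the class).
    """
    m = np.pad(mask, 1, constant_values=False)
    n = 0
    for ax in range(3):
        a = np.swapaxes(m, 0, ax)
        n += int(np.count_nonzero(a[1:] != a[:-1]))
    return n


def _contact_face_count(a_mask: np.ndarray, b_mask: np.ndarray) -> int:
    """Count faces where an ``a`` voxel abuts a ``b`` voxel (disjoint masks)."""
    a = np.pad(a_mask, 1, constant_values=False)
    b = np.pad(b_mask, 1, constant_values=False)
    n = 0
    for ax in range(3):
        aa = np.swapaxes(a, 0, ax)
        bb = np.swapaxes(b, 0, ax)
        n += int(np.count_nonzero(aa[1:] & bb[:-1]))
        n += int(np.count_nonzero(aa[:-1] & bb[1:]))
    return n


def class_surface_area(vol: LabeledVolume, code: int | Iterable[int]) -> float:
    """Exposed-face surface area (mm^2) of a class or class union.

    Face counting overestimates smooth surfaces (by up to ~pi/2 for a
    sphere); both Ad and the contact area A use the same convention.
    """
    codes = _as_codes(code)
    mask = np.isin(vol.labels, codes)
    return _exposed_face_count(mask) * vol.voxel_face_mm2


def degradation_rate(Vi: float, Vr: float, Ai: float, t_years: float) -> float:
    """DR = (Vi - Vr) / (Ai * t), in mm/year."""
    if t_years <= 0:
        raise ValueError("t_years must be > 0")
    if Ai <= 0:
        raise ValueError("Ai must be > 0")
    return (Vi - Vr) / (Ai * t_years)


def bone_implant_contact(
    vol: LabeledVolume, implant_codes: Sequence[int] = IMPLANT_CODES
) -> float:
    """Percent of the degraded-implant surface in contact with bone.

    Numerator: faces where an implant voxel abuts a bone voxel. Denominator:
    faces where an implant voxel abuts any non-implant voxel (grid-boundary
    faces count as abutting background).
    """
    codes = _as_codes(implant_codes)
    implant = np.isin(vol.labels, codes)
    if not implant.any():
        raise ValueError("no implant in volume")
    bone = vol.labels == BONE
    exposed = _exposed_face_count(implant)
    contact = _contact_face_count(implant, bone)
    if exposed == 0:  # pragma: no cover - implant fills the whole grid
        raise ValueError("implant has no exposed surface")
    return 100.0 * contact / exposed


def make_roi(ref: ScrewReference, margin_um: float = 200.0) -> np.ndarray:
    """Voxels within Euclidean distance ``margin_um`` of the reference screw,
    excluding the screw itself."""
    if margin_um < 0:
        raise ValueError("margin_um must be >= 0")
    if 0 < margin_um < ref.voxel_um:
        warnings.warn(
            "ROI margin smaller than one voxel; shell may be empty",
            stacklevel=2,
        )
    if margin_um == 0:
        return np.zeros_like(ref.mask, dtype=bool)
    dist = ndimage.distance_transform_edt(~ref.mask, sampling=ref.voxel_um)
    return (dist > 0) & (dist <= margin_um)


def bv_tv(vol: LabeledVolume, roi: np.ndarray) -> float:
    """100 * bone / (bone + background) inside ``roi``.

    Degradation-layer and metal voxels inside the ROI are excluded from both
    numerator and denominator.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != vol.labels.shape:
        raise ValueError("roi shape does not match volume")
    labels = vol.labels[roi]
    n_bone = int(np.count_nonzero(labels == BONE))
    n_bg = int(np.count_nonzero(labels == BACKGROUND))
    if n_bone + n_bg == 0:
        raise ValueError("ROI contains no bone/background")
    return 100.0 * n_bone / (n_bone + n_bg)


def resample_labels(vol: LabeledVolume, new_voxel_um: float) -> LabeledVolume:
    """Optional nearest-neighbour label resampler (not applied by default)."""
    if new_voxel_um <= 0:
        raise ValueError("new_voxel_um must be > 0")
    zoom = vol.voxel_um / new_voxel_um
    out = ndimage.zoom(vol.labels, zoom, order=0, mode="nearest")
    return LabeledVolume(out, new_voxel_um)


def morphometry_report(
    vol: LabeledVolume,
    ref: ScrewReference,
    days: float,
    margin_um: float = 200.0,
) -> MorphometryResult:
    """Assemble DR, BIC, BV/TV and volume loss for one sample.

    ``days`` is the per-sample implantation time; converted internally via
    t_years = days / 365.25.
    """
    if ref.mask.shape != vol.labels.shape or ref.voxel_um != vol.voxel_um:
        raise ValueError("reference screw is not co-registered with the volume")
    t_years = days / DAYS_PER_YEAR
    vr = class_volume(vol, METAL)
    dr = degradation_rate(ref.Vi, vr, ref.Ai, t_years)
    bic = bone_implant_contact(vol)
    roi = make_roi(ref, margin_um=margin_um)
    bvtv = bv_tv(vol, roi)
    return MorphometryResult(
        dr=dr,
        bic=bic,
        bvtv=bvtv,
        vr=vr,
        volume_loss=ref.Vi - vr,
        t_years=t_years,
        vi=ref.Vi,
    )
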