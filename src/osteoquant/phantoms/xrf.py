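"""XRF element-map phantoms: Ca/P gradient vs distance, Gd-bearing layer."""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import ndimage

from ..elemental_maps import CLASS_BONE, CLASS_DEGRADATION, CLASS_EMPTY, ElementMapSet
from .truth import PhantomTruth

_BASE_INTENSITY = 100.0


def make_xrf_phantom(
    size_px: tuple[int, int] = (256, 256),
    pixel_um: float = 0.5,
    ca_p_profile: Callable[[np.ndarray], np.ndarray] | float = 2.0,
    gd_layer_width_um: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    band_start_px: int | None = None,
) -> tuple[ElementMapSet, PhantomTruth]:
    """Ca, P, Gd maps with a vertical degradation band and an imposed
    Ca/P-vs-distance profile in the bone.

    Layout (columns, left to right): empty space, Gd-bearing degradation
    band of ``gd_layer_width_um``, bone. In bone, Ca/P at each pixel equals
    ``ca_p_profile(distance to the band in um)``; Gd is nonzero only inside
    the band. Gaussian noise of absolute standard deviation ``noise_sd``
    (maps are scaled to a base intensity of 100) is added and clipped at 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ny, nx = int(size_px[0]), int(size_px[1])
    width_px = int(round(gd_layer_width_um / pixel_um))
    if width_px >= nx:
        raise ValueError("degradation band wider than image")
    if width_px < 1:
        raise ValueError("degradation band narrower than one pixel")
    if band_start_px is None:
        band_start_px = max(nx // 8, 1)
    band_end = band_start_px + width_px
    if band_end >= nx:
        raise ValueError("degradation band does not fit in the image")

    profile = _as_profile(ca_p_profile)

    cols = np.arange(nx)
    mask_row = np.full(nx, CLASS_EMPTY, dtype=np.uint8)
    mask_row[band_start_px:band_end] = CLASS_DEGRADATION
    mask_row[band_end:] = CLASS_BONE
    mask = np.tile(mask_row, (ny, 1))

    # distance from each bone column to the nearest band pixel
    dist_row = np.zeros(nx)
    dist_row[band_end:] = (cols[band_end:] - (band_end - 1)) * pixel_um
    dist = np.tile(dist_row, (ny, 1))

    ca = np.zeros((ny, nx))
    p = np.zeros((ny, nx))
    gd = np.zeros((ny, nx))
    bone = mask == CLASS_BONE
    band = mask == CLASS_DEGRADATION
    p[bone] = _BASE_INTENSITY
    ca[bone] = _BASE_INTENSITY * profile(dist[bone])
    p[band] = _BASE_INTENSITY
    gd[band] = _BASE_INTENSITY

    rng = np.random.default_rng(seed)
    maps = {"Ca": ca, "P": p, "Gd": gd}
    if noise_sd > 0:
        for k in maps:
            maps[k] = np.clip(
                maps[k] + rng.normal(0.0, noise_sd, size=(ny, nx)), 0.0, None
            )

    ems = ElementMapSet(maps=maps, pixel_um=pixel_um, mask=mask)
    truth = PhantomTruth(
        seed=seed,
        capratio_profile_true=profile,
        extras={
            "gd_layer_width_um": gd_layer_width_um,
            "band_cols": (band_start_px, band_end),
            "noise_sd": noise_sd,
        },
    )
    return ems, truth


def make_vessel_phantom(
    size_px: tuple[int, int] = (128, 128),
    pixel_um: float = 0.5,
    ca_p_profile: Callable[[np.ndarray], np.ndarray] | float = 2.0,
    vessel_radius_um: float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ElementMapSet, np.ndarray, PhantomTruth]:
    """Bone field with a central circular vessel (empty space) and a Ca/P
    profile imposed as a function of distance to the vessel wall.

    Returns ``(ElementMapSet, vessel_mask, PhantomTruth)``.
    """
    ny, nx = int(size_px[0]), int(size_px[1])
    profile = _as_profile(ca_p_profile)
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_um = np.hypot(yy - cy, xx - cx) * pixel_um
    vessel = r_um <= vessel_radius_um
    if not vessel.any():
        raise ValueError("vessel radius smaller than one pixel")

    dist = ndimage.distance_transform_edt(~vessel, sampling=pixel_um)
    ca = _BASE_INTENSITY * profile(dist)
    p = np.full((ny, nx), _BASE_INTENSITY)
    ca[vessel] = 0.0
    p[vessel] = 0.0
    gd = np.zeros((ny, nx))

    rng = np.random.default_rng(seed)
    maps = {"Ca": ca, "P": p, "Gd": gd}
    if noise_sd > 0:
        for k in ("Ca", "P"):
            maps[k] = np.clip(
                maps[k] + rng.normal(0.0, noise_sd, size=(ny, nx)), 0.0, None
            )

    mask = np.where(vessel, CLASS_EMPTY, CLASS_BONE).astype(np.uint8)
    ems = ElementMapSet(maps=maps, pixel_um=pixel_um, mask=mask)
    truth = PhantomTruth(
        seed=seed,
        capratio_profile_true=profile,
        extras={"vessel_radius_um": vessel_radius_um, "noise_sd": noise_sd},
    )
    return ems, vessel, truth


def _as_profile(profile) -> Callable[[np.ndarray], np.ndarray]:
    if callable(profile):
        return profile
    value = float(profile)
    return lambda d: np.full_like(np.asarray(d, dtype=float), value)
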