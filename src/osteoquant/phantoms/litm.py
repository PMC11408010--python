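"""LA-ICP-MS phantom: piecewise-constant ppm regions, drift, standards."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ..la_icp_ms import CalibrationModel, LitmScan, StandardSet, channel_element
from .truth import PhantomTruth

DEFAULT_CHANNELS = ("26Mg", "44Ca", "31P", "47Ti", "56Fe", "155Gd")
#: channels with gelatin standards (Mg, Ca, Gd, Ti salts)
CALIBRATED_ELEMENTS = ("Mg", "Ca", "Gd", "Ti")

DEFAULT_SENSITIVITY = {  # CPS per ppm
    "26Mg": 120.0,
    "44Ca": 80.0,
    "31P": 60.0,
    "47Ti": 100.0,
    "56Fe": 90.0,
    "155Gd": 150.0,
}
DEFAULT_BASELINE_CPS = {ch: 200.0 for ch in DEFAULT_CHANNELS}

#: vertical-strip layout fractions (left to right)
_STRIPS = (("degradation", 0.25), ("interface", 0.25), ("bone", 0.25), ("control", 0.25))

DEFAULT_PPM_TRUE = {
    "degradation": {"26Mg": 5000.0, "44Ca": 1000.0, "31P": 500.0, "47Ti": 0.0,
                    "56Fe": 2.0, "155Gd": 4400.0},
    "interface": {"26Mg": 1200.0, "44Ca": 15000.0, "31P": 8000.0, "47Ti": 0.0,
                  "56Fe": 20.0, "155Gd": 300.0},
    "bone": {"26Mg": 800.0, "44Ca": 20000.0, "31P": 10000.0, "47Ti": 0.0,
             "56Fe": 30.0, "155Gd": 50.0},
    "control": {"26Mg": 800.0, "44Ca": 20000.0, "31P": 10000.0, "47Ti": 0.0,
                "56Fe": 30.0, "155Gd": 0.0},
}


def default_litm_layout(shape: tuple[int, int] = (64, 64)) -> dict[str, np.ndarray]:
    """Four disjoint vertical strips: degradation, interface, bone, control."""
    ny, nx = shape
    layout = {}
    col = 0
    for i, (name, frac) in enumerate(_STRIPS):
        width = nx - col if i == len(_STRIPS) - 1 else int(round(frac * nx))
        mask = np.zeros(shape, dtype=bool)
        mask[:, col : col + width] = True
        layout[name] = mask
        col += width
    return layout


def make_litm_phantom(
    region_layout: Optional[Mapping[str, np.ndarray]] = None,
    ppm_true: Optional[Mapping[str, Mapping[str, float]]] = None,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    drift_slope_per_hour: float = 0.0,
    noise_model: tuple | None = None,
    standards_ppm: Sequence[float] = (10.0, 30.0, 100.0, 300.0, 1000.0),
    seed: int = 0,
    *,
    shape: tuple[int, int] = (64, 64),
    pixel_um: float = 15.0,
    scan_hours: float = 2.0,
    sensitivity: Optional[Mapping[str, float]] = None,
    baseline_cps: Optional[Mapping[str, float]] = None,
) -> tuple[LitmScan, StandardSet, PhantomTruth]:
    """Raster-scanned CPS maps with piecewise-constant ppm regions.

    CPS = sensitivity * ppm * (1 + drift_slope_per_hour * t) + baseline,
    with optional Poisson (``("poisson",)``) or Gaussian (``("gaussian", sd)``)
    noise. Gelatin standards spanning ``standards_ppm`` (the ~10-1000 ppm
    range) are scanned at the start, middle and end of the timeline for the
    calibratable elements (Mg, Ca, Gd, Ti), together with a gelatin blank.
    """
    lo, hi = min(standards_ppm), max(standards_ppm)
    if len(standards_ppm) < 2 or not (lo <= 15.0 and hi >= 900.0):
        raise ValueError("standards_ppm must span approximately 10 to 1000 ppm")
    if region_layout is None:
        region_layout = default_litm_layout(shape)
    else:
        shapes = {np.asarray(m).shape for m in region_layout.values()}
        if len(shapes) != 1:
            raise ValueError("layout masks must share one shape")
        shape = next(iter(shapes))
    _check_layout(region_layout, shape)
    if ppm_true is None:
        ppm_true = DEFAULT_PPM_TRUE
    missing = set(region_layout) - set(ppm_true)
    if missing:
        raise ValueError(f"ppm_true missing regions: {sorted(missing)}")
    sens = dict(DEFAULT_SENSITIVITY if sensitivity is None else sensitivity)
    base = dict(DEFAULT_BASELINE_CPS if baseline_cps is None else baseline_cps)

    rng = np.random.default_rng(seed)
    ny, nx = shape
    n_px = ny * nx
    time_h = (np.arange(n_px) / max(n_px - 1, 1) * scan_hours).reshape(shape)

    ppm_fields = {ch: np.zeros(shape) for ch in channels}
    for region, mask in region_layout.items():
        for ch in channels:
            ppm_fields[ch][np.asarray(mask, dtype=bool)] = float(
                ppm_true[region].get(ch, 0.0)
            )

    drift = 1.0 + drift_slope_per_hour * time_h
    cps_maps = {}
    for ch in channels:
        cps = sens[ch] * ppm_fields[ch] * drift + base[ch]
        cps_maps[ch] = _apply_noise(cps, noise_model, rng)

    scan = LitmScan(channels=cps_maps, pixel_um=pixel_um, time_h=time_h)

    std_times = (0.0, scan_hours / 2.0, scan_hours)
    records, blanks = [], []
    cal_channels = [ch for ch in channels if channel_element(ch) in CALIBRATED_ELEMENTS]
    for t in std_times:
        factor = 1.0 + drift_slope_per_hour * t
        for ch in cal_channels:
            el = channel_element(ch)
            for ppm in standards_ppm:
                cps = sens[ch] * float(ppm) * factor + base[ch]
                records.append(
                    {
                        "element": el,
                        "ppm": float(ppm),
                        "cps": _mean_noisy(cps, noise_model, rng),
                        "time_h": t,
                    }
                )
            blanks.append(
                {"element": el, "cps": _mean_noisy(base[ch], noise_model, rng), "time_h": t}
            )
    std = StandardSet(records=pd.DataFrame(records), blank=pd.DataFrame(blanks))

    truth = PhantomTruth(
        seed=seed,
        ppm_true={r: dict(v) for r, v in ppm_true.items()},
        extras={
            "sensitivity": sens,
            "baseline_cps": base,
            "drift_slope_per_hour": drift_slope_per_hour,
            "scan_hours": scan_hours,
            "std_times_h": std_times,
        },
    )
    return scan, std, truth


def _apply_noise(cps, noise_model, rng):
    if noise_model is None:
        return cps
    kind = noise_model[0]
    if kind == "poisson":
        return rng.poisson(np.clip(cps, 0.0, None)).astype(float)
    if kind == "gaussian":
        return np.clip(cps + rng.normal(0.0, float(noise_model[1]), size=cps.shape), 0.0, None)
    raise ValueError(f"unknown noise model {kind!r}")


def _mean_noisy(cps, noise_model, rng, n_rep: int = 100):
    """Recorded standard CPS: mean over a small scanned patch."""
    if noise_model is None:
        return float(cps)
    patch = _apply_noise(np.full(n_rep, float(cps)), noise_model, rng)
    return float(patch.mean())


def _check_layout(layout, shape):
    total = np.zeros(shape, dtype=np.uint8)
    for name, mask in layout.items():
        m = np.asarray(mask, dtype=bool)
        if m.shape != shape:
            raise ValueError(f"region {name!r} mask has wrong shape")
        total += m.astype(np.uint8)
    if np.any(total > 1):
        raise ValueError("overlapping regions in layout")
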