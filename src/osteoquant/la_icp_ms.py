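"""Calibration and region analysis of laser-ablation ICP-MS element maps.

CPS channel maps are converted to concentrations (ppm = mg/kg) against
gelatin standards scanned at the start, middle and end of the acquisition;
the drift model interpolates per-element slope/intercept piecewise-linearly
between standard scan times and applies them per pixel by timestamp. The
per-channel limit of detection is LOD = mean + 3*SD over a user-chosen
control area. Degradation regions are classified by percentile rules on the
implant / Ca / P / Fe channels; interface bands are built from the
degradation mask by Euclidean distance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

#: channels quantifiable against the gelatin standards (Mg, Ca, Gd, Ti salts)
DEFAULT_PASSTHROUGH = ("31P", "56Fe")
#: interface-band edges (um from the degradation boundary)
DEFAULT_BAND_EDGES_UM = (0.0, 50.0, 150.0)


def channel_element(channel: str) -> str:
    """'26Mg' -> 'Mg' (strip the leading mass number)."""
    return re.sub(r"^\d+", "", channel)


@dataclass
class LitmScan:
    """Multi-channel CPS maps with per-pixel acquisition timestamps (hours)."""

    channels: dict[str, np.ndarray]
    pixel_um: float
    time_h: np.ndarray

    def __post_init__(self):
        if not self.channels:
            raise ValueError("at least one channel required")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        shapes = {m.shape for m in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        for name, m in self.channels.items():
            if np.any(m < 0):
                raise ValueError(f"channel {name!r} has negative CPS")
        self.time_h = np.asarray(self.time_h, dtype=float)
        if self.time_h.shape != next(iter(shapes)):
            raise ValueError("time grid shape must match channels")
        if np.any(np.diff(self.time_h.ravel()) < 0):
            raise ValueError("timestamps must be non-decreasing in scan order")
        if not self.pixel_um > 0:
            raise ValueError("pixel_um must be > 0")

    @property
    def shape(self):
        return self.time_h.shape


@dataclass
class StandardSet:
    """Gelatin-standard scans: (element, ppm, cps, time_h) records + blank."""

    records: pd.DataFrame  # columns: element, ppm, cps, time_h
    blank: Optional[pd.DataFrame] = None  # columns: element, cps, time_h

    def __post_init__(self):
        required = {"element", "ppm", "cps", "time_h"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"standard records need columns {sorted(required)}")
        if (self.records["ppm"] <= 0).any():
            raise ValueError("standard concentrations must be > 0")
        for el, grp in self.records.groupby("element"):
            if grp["ppm"].nunique() < 2:
                raise ValueError(
                    f"element {el!r} has fewer than 2 standard concentrations"
                )

    def elements(self) -> list[str]:
        return sorted(self.records["element"].unique())


@dataclass
class CalibrationModel:
    """Per-element slope/intercept, optionally piecewise-linear in time."""

    times_h: dict[str, np.ndarray]
    slopes: dict[str, np.ndarray]  # CPS per ppm
    intercepts: dict[str, np.ndarray]  # CPS
    r_squared: dict[str, float]
    blank_times_h: dict[str, np.ndarray] = field(default_factory=dict)
    blank_cps: dict[str, np.ndarray] = field(default_factory=dict)
    model: str = "static"

    def covers(self, element: str) -> bool:
        return element in self.slopes

    def slope_at(self, element: str, t):
        return np.interp(t, self.times_h[element], self.slopes[element])

    def intercept_at(self, element: str, t):
        return np.interp(t, self.times_h[element], self.intercepts[element])

    def blank_at(self, element: str, t):
        if element not in self.blank_cps:
            return np.zeros_like(np.asarray(t, dtype=float))
        return np.interp(t, self.blank_times_h[element], self.blank_cps[element])


@dataclass
class PpmMaps:
    """Quantified maps; uncalibrated channels pass through flagged 'cps'."""

    maps: dict[str, np.ndarray]
    units: dict[str, str]  # 'ppm' or 'cps'
    floored_pixels: dict[str, int]
    pixel_um: float


def _ols(ppm: np.ndarray, cps: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(ppm, cps, 1)
    return float(slope), float(intercept)


def build_calibration(
    std: StandardSet, model: str = "static", blank_subtract: bool = True
) -> CalibrationModel:
    """Fit CPS = slope * ppm + intercept per element.

    ``model='static'`` pools all standard scans into one OLS line;
    ``model='drift'`` fits one line per standard scan time and interpolates
    slope and intercept piecewise-linearly in between (>= 2 time points
    required). A negative fitted slope raises "inverted calibration".
    """
    if model not in ("static", "drift"):
        raise ValueError("model must be 'static' or 'drift'")
    times, slopes, intercepts, r2 = {}, {}, {}, {}
    blank_t, blank_c = {}, {}

    blank = std.blank
    for el, grp in std.records.groupby("element"):
        cps = grp["cps"].to_numpy(dtype=float)
        ppm = grp["ppm"].to_numpy(dtype=float)
        t = grp["time_h"].to_numpy(dtype=float)
        if blank_subtract and blank is not None:
            bl = blank[blank["element"] == el]
            if len(bl):
                bt = bl["time_h"].to_numpy(dtype=float)
                bc = bl["cps"].to_numpy(dtype=float)
                order = np.argsort(bt)
                blank_t[el], blank_c[el] = bt[order], bc[order]
                cps = cps - np.interp(t, bt[order], bc[order])
        if model == "static":
            s, b = _ols(ppm, cps)
            times[el] = np.array([0.0])
            slopes[el] = np.array([s])
            intercepts[el] = np.array([b])
        else:
            ut = np.unique(t)
            if len(ut) < 2:
                raise ValueError(
                    f"drift model needs >= 2 standard scan times for {el!r}"
                )
            ss, bs = [], []
            for tt in ut:
                sel = t == tt
                if np.unique(ppm[sel]).size < 2:
                    raise ValueError(
                        f"standard scan at t={tt} h underdetermined for {el!r}"
                    )
                s, b = _ols(ppm[sel], cps[sel])
                ss.append(s)
                bs.append(b)
            times[el] = ut
            slopes[el] = np.asarray(ss)
            intercepts[el] = np.asarray(bs)
        if np.any(slopes[el] <= 0):
            raise ValueError(f"inverted calibration for element {el!r}")
        pred = np.interp(t, times[el], slopes[el]) * ppm + np.interp(
            t, times[el], intercepts[el]
        )
        ss_res = float(np.sum((cps - pred) ** 2))
        ss_tot = float(np.sum((cps - cps.mean()) ** 2))
        r2[el] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    return CalibrationModel(
        times_h=times,
        slopes=slopes,
        intercepts=intercepts,
        r_squared=r2,
        blank_times_h=blank_t,
        blank_cps=blank_c,
        model=model,
    )


def cps_to_ppm(
    scan: LitmScan,
    cal: CalibrationModel,
    passthrough: Sequence[str] = DEFAULT_PASSTHROUGH,
) -> PpmMaps:
    """ppm = (CPS - blank(t) - intercept(t)) / slope(t) per pixel.

    Negative results are floored at 0 with the floored-pixel count
    reported; channels without calibration that are on the pass-through
    list are returned unchanged and flagged with unit 'cps'.
    """
    maps, units, floored = {}, {}, {}
    for name, cps in scan.channels.items():
        el = channel_element(name)
        if cal.covers(el):
            t = scan.time_h
            ppm = (cps - cal.blank_at(el, t) - cal.intercept_at(el, t)) / cal.slope_at(
                el, t
            )
            n_neg = int(np.count_nonzero(ppm < 0))
            maps[name] = np.clip(ppm, 0.0, None)
            units[name] = "ppm"
            floored[name] = n_neg
        elif name in passthrough:
            maps[name] = cps.copy()
            units[name] = "cps"
            floored[name] = 0
        else:
            raise ValueError(
                f"channel {name!r} neither calibrated nor on the pass-through list"
            )
    return PpmMaps(maps=maps, units=units, floored_pixels=floored, pixel_um=scan.pixel_um)


def compute_lod(
    maps: LitmScan | PpmMaps | Mapping[str, np.ndarray],
    control_mask: np.ndarray,
    channel: str,
    min_pixels: int = 30,
) -> float:
    """LOD = mean + 3 * sample SD of the channel over the control area."""
    if isinstance(maps, LitmScan):
        data = maps.channels[channel]
    elif isinstance(maps, PpmMaps):
        data = maps.maps[channel]
    else:
        data = np.asarray(maps[channel], dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    vals = data[control_mask]
    if vals.size < min_pixels:
        raise ValueError(
            f"control area has {vals.size} pixels; need >= {min_pixels}"
        )
    return float(vals.mean() + 3.0 * vals.std(ddof=1))


def lod_in_ppm(
    lod_cps: float, cal: CalibrationModel, element: str, t: float = 0.0
) -> float:
    """Convert a channel LOD (CPS, from :func:`compute_lod` on the raw scan)
    to concentration units via the calibration at time ``t``.

    Computing the LOD on the raw channel and converting avoids the censoring
    bias that zero-flooring introduces into ppm-map statistics near zero.
    """
    val = (lod_cps - float(cal.blank_at(element, t)) - float(cal.intercept_at(element, t))) / float(
        cal.slope_at(element, t)
    )
    return max(val, 0.0)


def classify_regions(
    scan: LitmScan,
    implant_channel: str = "155Gd",
    visibility_fraction: float = 0.10,
    ca_fraction: float = 0.5,
    p_fraction: float = 0.5,
    fe_fraction: float = 0.2,
    percentile: float = 99.9,
    exclude_mask: Optional[np.ndarray] = None,
    band_edges_um: Sequence[float] = DEFAULT_BAND_EDGES_UM,
    control_mask: Optional[np.ndarray] = None,
    ca_channel: str = "44Ca",
    p_channel: str = "31P",
    fe_channel: str = "56Fe",
) -> dict[str, np.ndarray]:
    """Degradation mask by percentile rules + interface bands by distance.

    A pixel is degradation when the implant channel (Gd or Ti) is at least
    ``visibility_fraction`` of its 99.9th-percentile cutoff, Ca and P are
    below half of theirs, and Fe is below 20 % of its cutoff. Tail-streak
    artefacts are handled via the manual ``exclude_mask``. Percentiles use
    linear interpolation between order statistics.
    """
    for ch in (implant_channel, ca_channel, p_channel, fe_channel):
        if ch not in scan.channels:
            raise ValueError(f"required channel {ch!r} missing from scan")

    cutoffs = {}
    for ch in (implant_channel, ca_channel, p_channel, fe_channel):
        vals = scan.channels[ch]
        if np.ptp(vals) == 0:
            raise ValueError(f"degenerate percentile: channel {ch!r} is constant")
        cutoffs[ch] = float(np.percentile(vals, percentile, method="linear"))

    deg = (
        (scan.channels[implant_channel] >= visibility_fraction * cutoffs[implant_channel])
        & (scan.channels[ca_channel] < ca_fraction * cutoffs[ca_channel])
        & (scan.channels[p_channel] < p_fraction * cutoffs[p_channel])
        & (scan.channels[fe_channel] < fe_fraction * cutoffs[fe_channel])
    )
    if exclude_mask is not None:
        deg &= ~np.asarray(exclude_mask, dtype=bool)

    regions: dict[str, np.ndarray] = {"degradation": deg}
    control = None
    if control_mask is not None:
        # the control area is reserved: it never joins an interface band
        control = np.asarray(control_mask, dtype=bool) & ~deg
    if deg.any():
        dist = ndimage.distance_transform_edt(~deg, sampling=scan.pixel_um)
        edges = list(band_edges_um)
        taken = deg.copy()
        if exclude_mask is not None:
            taken |= np.asarray(exclude_mask, dtype=bool)
        if control is not None:
            taken |= control
        for lo, hi in zip(edges[:-1], edges[1:]):
            band = (dist > lo) & (dist <= hi) & ~taken
            regions[f"interface_{int(lo)}_{int(hi)}"] = band
            taken |= band
        far = (dist > edges[-1]) & ~taken
        regions[f"interface_gt_{int(edges[-1])}"] = far
    if control is not None:
        regions["control"] = control
    return regions


def region_report(
    ppm_maps: PpmMaps | Mapping[str, np.ndarray],
    regions: Mapping[str, np.ndarray],
    lods: Mapping[str, float],
) -> pd.DataFrame:
    """Per region x channel: mean, SD, median, n and % pixels above LOD."""
    if isinstance(ppm_maps, PpmMaps):
        maps = ppm_maps.maps
        units = ppm_maps.units
    else:
        maps = {k: np.asarray(v, dtype=float) for k, v in ppm_maps.items()}
        units = {k: "ppm" for k in maps}
    _check_disjoint(regions)
    rows = []
    for region, mask in regions.items():
        mask = np.asarray(mask, dtype=bool)
        n = int(mask.sum())
        for ch, data in maps.items():
            vals = data[mask]
            row = {
                "region": region,
                "channel": ch,
                "unit": units.get(ch, "ppm"),
                "n": n,
                "mean": float(vals.mean()) if n else None,
                "sd": float(vals.std(ddof=1)) if n > 1 else None,
                "median": float(np.median(vals)) if n else None,
                "pct_above_lod": None,
            }
            if ch in lods and n:
                row["pct_above_lod"] = float(
                    100.0 * np.count_nonzero(vals > lods[ch]) / n
                )
            rows.append(row)
    return pd.DataFrame(rows)


def region_scatter(
    maps: Mapping[str, np.ndarray] | PpmMaps,
    regions: Mapping[str, np.ndarray],
    channel_a: str,
    channel_b: str,
) -> pd.DataFrame:
    """Per-pixel (channel_a, channel_b) pairs per region, for scatter plots."""
    data = maps.maps if isinstance(maps, PpmMaps) else maps
    frames = []
    for region, mask in regions.items():
        mask = np.asarray(mask, dtype=bool)
        frames.append(
            pd.DataFrame(
                {
                    "region": region,
                    channel_a: np.asarray(data[channel_a])[mask],
                    channel_b: np.asarray(data[channel_b])[mask],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _check_disjoint(regions: Mapping[str, np.ndarray]) -> None:
    total = None
    for mask in regions.values():
        m = np.asarray(mask, dtype=bool).astype(np.uint8)
        total = m if total is None else total + m
    if total is not None and np.any(total > 1):
        raise ValueError("region masks overlap")
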