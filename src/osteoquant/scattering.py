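"""Small/wide-angle scattering analysis for bone ultrastructure.

Pipeline: 2D area-detector frame -> azimuthal (radial-q) integration ->
1D pattern -> parameter extraction:

* mineral platelet thickness T from the stack-of-cards identity
  T = 4*Q / (pi*P) with the invariant Q = integral of I*q^2 dq (low-q
  polynomial closure, high-q analytic Porod tail) and the Porod constant
  P = high-q plateau of I*q^4,
* (002) lattice spacing from Bragg's law n*lambda = 2*d*sin(theta),
* crystallite size from the Scherrer equation tau = K*lambda/(beta*cos(theta))
  with beta the Gaussian FWHM of the peak in 2-theta radians.

Flat-detector small-angle mapping: q = (4*pi/lambda)*sin(atan(r*pixel/L)/2).
No polarization or solid-angle corrections are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

TWO_SQRT_2LN2 = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class Geometry:
    """Flat area-detector geometry."""

    wavelength_nm: float
    distance_mm: float
    pixel_mm: float
    center_x_px: float
    center_y_px: float

    def __post_init__(self):
        for name in ("wavelength_nm", "distance_mm", "pixel_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def q_of_radius_px(self, r_px):
        """q (nm^-1) at radial pixel distance r from the beam center."""
        two_theta = np.arctan(np.asarray(r_px) * self.pixel_mm / self.distance_mm)
        return (4.0 * np.pi / self.wavelength_nm) * np.sin(two_theta / 2.0)

    def radius_px_of_q(self, q):
        two_theta = 2.0 * np.arcsin(np.asarray(q) * self.wavelength_nm / (4.0 * np.pi))
        return np.tan(two_theta) * self.distance_mm / self.pixel_mm


@dataclass
class DetectorImage:
    counts: np.ndarray
    geometry: Geometry
    mask: Optional[np.ndarray] = None  # True = bad pixel
    monitor: float = 1.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2D")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape must match counts")


@dataclass
class Pattern1D:
    q: np.ndarray  # nm^-1, strictly increasing
    I: np.ndarray
    sigma: Optional[np.ndarray] = None
    normalization: float = 1.0

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.shape != self.I.shape or self.q.ndim != 1:
            raise ValueError("q and I must be 1D arrays of equal length")
        if not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(self.q > 0):
            raise ValueError("q must be positive")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)


@dataclass
class PeakFit:
    center_q: float
    fwhm_q: float
    amplitude: float
    baseline_slope: float
    baseline_intercept: float
    goodness: float  # rms residual
    below_resolution: bool = False


@dataclass
class UltrastructureResult:
    T_nm: float = float("nan")
    d002_nm: float = float("nan")
    tau002_nm: float = float("nan")
    Q_invariant: float = float("nan")
    P_porod: float = float("nan")


# --------------------------------------------------------------------------
# azimuthal integration
# --------------------------------------------------------------------------

def azimuthal_integrate(
    img: DetectorImage, n_bins: int = 500, mode: str = "mean"
) -> Pattern1D:
    """Radial q-binning around the beam center.

    ``mode='mean'`` gives the mean intensity per q bin (the usual 1D
    pattern); ``mode='sum'`` conserves total unmasked counts. Intensities
    are divided by the frame monitor value.
    """
    geom = img.geometry
    ny, nx = img.counts.shape
    if not (0 <= geom.center_x_px < nx and 0 <= geom.center_y_px < ny):
        raise ValueError("beam center outside image")
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    r = np.hypot(yy - geom.center_y_px, xx - geom.center_x_px)
    q = geom.q_of_radius_px(r)
    good = np.ones((ny, nx), dtype=bool) if img.mask is None else ~img.mask

    qg = q[good]
    cg = img.counts[good]
    edges = np.linspace(0.0, qg.max() * (1 + 1e-12), n_bins + 1)
    idx = np.digitize(qg, edges) - 1
    sums = np.bincount(idx, weights=cg, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nonempty = counts > 0
    if mode == "mean":
        intensity = sums[nonempty] / counts[nonempty]
    elif mode == "sum":
        intensity = sums[nonempty]
    else:
        raise ValueError("mode must be 'mean' or 'sum'")
    qc = centers[nonempty]
    keep = qc > 0
    return Pattern1D(
        q=qc[keep], I=intensity[keep] / img.monitor, normalization=img.monitor
    )


def calibrate_q_scale(measured_q, reference_q) -> float:
    """Single multiplicative q-scale factor from known calibrant rings
    (least squares through the origin)."""
    m = np.asarray(measured_q, dtype=float)
    ref = np.asarray(reference_q, dtype=float)
    if m.shape != ref.shape or m.size == 0:
        raise ValueError("measured and reference ring lists must match")
    return float(np.dot(m, ref) / np.dot(m, m))


# --------------------------------------------------------------------------
# SAXS: stack-of-cards T parameter
# --------------------------------------------------------------------------

def fit_kratky_T(
    p: Pattern1D,
    porod_qmin: float = 4.5,
    knee_window: tuple[float, float] | None = None,
    plateau_tol: float = 0.2,
    kratky_tail_frac: float = 0.15,
) -> tuple[float, float, float]:
    """Platelet thickness T = 4*Q/(pi*P) from a 1D SAXS pattern.

    P is the weighted mean of I*q^4 over q >= ``porod_qmin`` (a plateau
    check rejects patterns that never reach the Porod regime). Q is the
    trapezoidal integral of I*q^2 over the data, closed at low q by an
    even-polynomial fit (c0 + c2*q^2) of the Kratky integrand over
    ``knee_window`` and at high q by the analytic Porod tail P/qmax.

    Returns ``(T_nm, Q_invariant, P_porod)``.
    """
    q, intensity = p.q, p.I
    sel = q >= porod_qmin
    if sel.sum() < 4:
        raise ValueError("Porod regime not reached: too few points above porod_qmin")
    iq4 = intensity[sel] * q[sel] ** 4
    P = float(np.mean(iq4))
    slope = np.polyfit(q[sel], iq4, 1)[0]
    rel_slope = abs(slope) * (q[sel][-1] - q[sel][0]) / max(P, 1e-300)
    if rel_slope > plateau_tol:
        raise ValueError(
            f"Porod regime not reached: relative I*q^4 slope {rel_slope:.3f} "
            f"> tolerance {plateau_tol}"
        )

    kratky = intensity * q**2
    # a flat I*q^4 alone can hide a Guinier hump; additionally require the
    # Kratky integrand to have decayed at the high-q end of the pattern
    tail = float(np.mean(kratky[-max(3, len(q) // 50):]))
    if tail > kratky_tail_frac * float(np.max(kratky)):
        raise ValueError(
            "Porod regime not reached: Kratky integrand has not decayed at qmax "
            f"(tail fraction {tail / float(np.max(kratky)):.2f} > {kratky_tail_frac})"
        )
    Q_data = float(np.trapezoid(kratky, q))

    if knee_window is None:
        knee_window = (q[0], min(0.6, porod_qmin / 3.0))
    lo, hi = knee_window
    ksel = (q >= lo) & (q <= hi)
    if ksel.sum() < 3:
        raise ValueError("knee window contains fewer than 3 points")
    coef = np.polyfit(q[ksel] ** 2, kratky[ksel], 1)  # kratky = c2*q^2 + c0
    c2, c0 = float(coef[0]), float(coef[1])
    q0 = q[0]
    Q_low = max(c0 * q0 + c2 * q0**3 / 3.0, 0.0)
    Q_tail = P / q[-1]

    Q = Q_data + Q_low + Q_tail
    T = 4.0 * Q / (np.pi * P)
    return T, Q, P


# --------------------------------------------------------------------------
# WAXS: Gaussian peak fit, Bragg, Scherrer
# --------------------------------------------------------------------------

def _gauss_lin(q, amp, center, sigma, slope, intercept):
    return amp * np.exp(-0.5 * ((q - center) / sigma) ** 2) + slope * q + intercept


def fit_peak(p: Pattern1D, window_q: tuple[float, float]) -> PeakFit:
    """Least-squares Gaussian + linear-baseline fit inside ``window_q``."""
    lo, hi = window_q
    sel = (p.q >= lo) & (p.q <= hi)
    if sel.sum() < 6:
        raise ValueError("fit window contains fewer than 6 points")
    q, intensity = p.q[sel], p.I[sel]
    i_max = int(np.argmax(intensity))
    base0 = float(np.minimum(intensity[0], intensity[-1]))
    amp0 = float(intensity[i_max] - base0)
    if amp0 <= 0:
        raise ValueError("no local maximum in fit window")
    p0 = [amp0, float(q[i_max]), (hi - lo) / 10.0, 0.0, base0]
    try:
        popt, _ = optimize.curve_fit(
            _gauss_lin, q, intensity, p0=p0, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise ValueError(
            f"peak fit did not converge in window {window_q}: {exc}"
        ) from exc
    amp, center, sigma, slope, intercept = popt
    sigma = abs(float(sigma))
    center = float(center)
    if not lo <= center <= hi:
        raise ValueError("fitted peak center outside window")
    fwhm = TWO_SQRT_2LN2 * sigma
    resid = intensity - _gauss_lin(q, *popt)
    dq = float(np.median(np.diff(q)))
    return PeakFit(
        center_q=center,
        fwhm_q=fwhm,
        amplitude=float(amp),
        baseline_slope=float(slope),
        baseline_intercept=float(intercept),
        goodness=float(np.sqrt(np.mean(resid**2))),
        below_resolution=fwhm < dq,
    )


def bragg_d(
    center: float, wavelength_nm: float, n: int = 1, input_kind: str = "q"
) -> float:
    """Lattice spacing from Bragg's law.

    ``input_kind='q'``: d = 2*pi*n/q. ``input_kind='two_theta'`` (radians):
    d = n*lambda / (2*sin(theta)).
    """
    if input_kind == "q":
        if center <= 0:
            raise ValueError("q must be > 0")
        return 2.0 * np.pi * n / center
    if input_kind == "two_theta":
        if not 0.0 < center < np.pi:
            raise ValueError("2theta must be in (0, pi)")
        s = np.sin(center / 2.0)
        if s == 0:
            raise ValueError("sin(theta) = 0")
        return n * wavelength_nm / (2.0 * s)
    raise ValueError("input_kind must be 'q' or 'two_theta'")


def scherrer_size(
    beta_rad: float, theta_rad: float, wavelength_nm: float, K: float = 1.0
) -> float:
    """Crystallite size tau = K*lambda / (beta*cos(theta)), beta the peak
    FWHM in 2-theta radians."""
    if beta_rad <= 0:
        raise ValueError("beta must be > 0")
    if not 0.0 < theta_rad < np.pi / 2.0:
        raise ValueError("theta must be in (0, pi/2)")
    return K * wavelength_nm / (beta_rad * np.cos(theta_rad))


def fwhm_q_to_beta(fwhm_q: float, wavelength_nm: float, theta_rad: float) -> float:
    """Convert a peak FWHM in q to the 2-theta FWHM beta (radians) via
    dq/d(2theta) = (2*pi/lambda)*cos(theta)."""
    return fwhm_q * wavelength_nm / (2.0 * np.pi * np.cos(theta_rad))


def theta_of_q(q: float, wavelength_nm: float) -> float:
    """Glancing angle theta (radians) for scattering vector q."""
    return float(np.arcsin(q * wavelength_nm / (4.0 * np.pi)))


# --------------------------------------------------------------------------
# per-ROI reporting
# --------------------------------------------------------------------------

def ultrastructure_point(
    saxs: Pattern1D | None,
    waxs: Pattern1D | None,
    wavelength_nm: float,
    waxs_window_q: tuple[float, float] = (16.0, 21.0),
    K: float = 1.0,
    **kratky_kwargs,
) -> UltrastructureResult:
    """Extract (T, d002, tau002) for a single scan point."""
    res = UltrastructureResult()
    if saxs is not None:
        res.T_nm, res.Q_invariant, res.P_porod = fit_kratky_T(saxs, **kratky_kwargs)
    if waxs is not None:
        fit = fit_peak(waxs, waxs_window_q)
        res.d002_nm = bragg_d(fit.center_q, wavelength_nm, input_kind="q")
        theta = theta_of_q(fit.center_q, wavelength_nm)
        beta = fwhm_q_to_beta(fit.fwhm_q, wavelength_nm, theta)
        res.tau002_nm = scherrer_size(beta, theta, wavelength_nm, K=K)
    return res


def ultrastructure_report(
    saxs_patterns: Sequence[Pattern1D] | None,
    waxs_patterns: Sequence[Pattern1D] | None,
    wavelength_nm: float,
    **kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Per-point ultrastructure parameters plus ROI medians and quartiles.

    Returns a DataFrame (one row per scan point) and a summary dict with
    per-parameter median / q25 / q75, the boxplot-style ROI statistics.
    """
    n_s = len(saxs_patterns) if saxs_patterns else 0
    n_w = len(waxs_patterns) if waxs_patterns else 0
    n = max(n_s, n_w)
    if n == 0:
        raise ValueError("empty ROI: no scan points provided")
    if n_s and n_w and n_s != n_w:
        raise ValueError("SAXS and WAXS point lists differ in length")
    rows = []
    for i in range(n):
        res = ultrastructure_point(
            saxs_patterns[i] if n_s else None,
            waxs_patterns[i] if n_w else None,
            wavelength_nm,
            **kwargs,
        )
        rows.append(
            {
                "point": i,
                "T_nm": res.T_nm,
                "d002_nm": res.d002_nm,
                "tau002_nm": res.tau002_nm,
                "Q_invariant": res.Q_invariant,
                "P_porod": res.P_porod,
            }
        )
    df = pd.DataFrame(rows)
    summary = {}
    for col in ("T_nm", "d002_nm", "tau002_nm"):
        vals = df[col].dropna()
        if len(vals):
            summary[col] = {
                "median": float(vals.median()),
                "q25": float(vals.quantile(0.25)),
                "q75": float(vals.quantile(0.75)),
                "n": int(len(vals)),
            }
    return df, summary


def compare_ultrastructure(a, b) -> dict:
    """Two-sided two-sample t-test on per-point parameter values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 points per group")
    t, p = stats.ttest_ind(a, b)
    return {"t": float(t), "p": float(p), "n_a": len(a), "n_b": len(b)}
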