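"""Scattering phantoms: Debye-Scherrer WAXS frames and two-phase SAXS patterns."""

from __future__ import annotations

import numpy as np

from ..scattering import DetectorImage, Geometry, Pattern1D
from .truth import PhantomTruth

#: Default flat-detector geometry: 15 keV beam (0.082656 nm), quarter-ring
#: layout with the beam center at the detector corner.
DEFAULT_WAXS_GEOMETRY = Geometry(
    wavelength_nm=0.082656,
    distance_mm=200.0,
    pixel_mm=0.15,
    center_x_px=0.0,
    center_y_px=0.0,
)


def make_waxs_frame(
    d_true_nm: float,
    tau_true_nm: float,
    geometry: Geometry = DEFAULT_WAXS_GEOMETRY,
    intensity: float = 1000.0,
    noise_model: tuple | None = None,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (400, 400),
    background: float = 50.0,
) -> tuple[DetectorImage, PhantomTruth]:
    """2D frame with one powder ring at the (002)-like spacing ``d_true_nm``.

    The radial intensity is Gaussian in q, centred at q0 = 2*pi/d with FWHM
    set by the Scherrer inversion at zero instrumental broadening:
    beta = K*lambda/(tau*cos(theta)) in 2-theta, i.e. fwhm_q = 2*pi*K/tau.

    ``noise_model``: None, ``("gaussian", sd)`` or ``("poisson",)``.
    """
    if d_true_nm <= 0 or tau_true_nm <= 0:
        raise ValueError("d_true_nm and tau_true_nm must be > 0")
    q0 = 2.0 * np.pi / d_true_nm
    arg = q0 * geometry.wavelength_nm / (4.0 * np.pi)
    if arg >= 1.0:
        raise ValueError("ring outside detector: d below wavelength limit")
    r0 = float(geometry.radius_px_of_q(q0))

    ny, nx = shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    r = np.hypot(yy - geometry.center_y_px, xx - geometry.center_x_px)
    r_max = float(r.max())
    if not 0.0 < r0 < r_max:
        raise ValueError("ring outside detector")

    q = geometry.q_of_radius_px(r)
    fwhm_q = 2.0 * np.pi / tau_true_nm  # K = 1
    sigma_q = fwhm_q / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    counts = intensity * np.exp(-0.5 * ((q - q0) / sigma_q) ** 2) + background

    rng = np.random.default_rng(seed)
    if noise_model is not None:
        kind = noise_model[0]
        if kind == "gaussian":
            counts = counts + rng.normal(0.0, float(noise_model[1]), size=counts.shape)
        elif kind == "poisson":
            counts = rng.poisson(np.clip(counts, 0.0, None)).astype(float)
        else:
            raise ValueError(f"unknown noise model {kind!r}")
        counts = np.clip(counts, 0.0, None)

    img = DetectorImage(counts=counts, geometry=geometry)
    truth = PhantomTruth(
        seed=seed,
        d_true=d_true_nm,
        tau_true=tau_true_nm,
        extras={"q0_nm_inv": q0, "ring_radius_px": r0, "fwhm_q": fwhm_q},
    )
    return img, truth


def make_saxs_pattern(
    T_true_nm: float,
    porod_constant: float = 1.0,
    qmin: float = 0.05,
    qmax: float = 6.5,
    n_points: int = 500,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Pattern1D, PhantomTruth]:
    """Two-phase SAXS pattern whose stack-of-cards thickness is exact.

    Model: I(q) = A*exp(-q^2*Rg^2/3) + P/q^4 * (1 - exp(-q^2*Rg^2/3)).
    Its invariant has the closed form Q = A*sqrt(pi)/(4*a^1.5) + P*sqrt(pi*a)
    with a = Rg^2/3, so with Rg fixed at 0.6*T_true, A is solved exactly so
    that T_true = 4*Q/(pi*P). Noise is multiplicative Gaussian with relative
    standard deviation ``noise_sd``.
    """
    if not 0.5 <= T_true_nm <= 20.0:
        raise ValueError("T_true outside [0.5, 20] nm (outside model validity)")
    if porod_constant <= 0:
        raise ValueError("porod_constant must be > 0")
    if not 0 < qmin < qmax:
        raise ValueError("need 0 < qmin < qmax")

    P = float(porod_constant)
    Rg = 0.6 * T_true_nm
    a = Rg**2 / 3.0
    Q_target = np.pi * P * T_true_nm / 4.0
    guinier_Q = P * np.sqrt(np.pi * a)
    A = (Q_target - guinier_Q) * 4.0 * a**1.5 / np.sqrt(np.pi)
    if A <= 0:
        raise ValueError("model degenerate: Porod term alone exceeds target Q")

    # Porod-regime check at qmax: the Guinier term must be negligible there
    contamination = A * qmax**4 * np.exp(-a * qmax**2) / P
    if contamination > 0.01:
        raise ValueError(
            f"qmax={qmax} too small: I*q^4 has not plateaued "
            f"(Guinier contamination {contamination:.2%})"
        )

    q = np.linspace(qmin, qmax, int(n_points))
    decay = np.exp(-a * q**2)
    intensity = A * decay + P / q**4 * (1.0 - decay)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        intensity = intensity * (1.0 + rng.normal(0.0, noise_sd, size=q.shape))
        intensity = np.clip(intensity, 1e-12, None)

    pattern = Pattern1D(q=q, I=intensity)
    truth = PhantomTruth(
        seed=seed,
        T_true=T_true_nm,
        extras={"P": P, "A": A, "Rg": Rg, "Q": Q_target, "noise_sd": noise_sd},
    )
    return pattern, truth
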