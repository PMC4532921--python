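"""Receptive-field estimation, Gabor fitting and shape statistics.

A hidden unit's receptive field is estimated by reverse correlation over a
stimulus ensemble: the activation-probability-weighted sum of stimulus
patches, RF_j = sum_s p(h_j=1|v_s) v_s.  Fields are then fitted with a
2-D Gabor function

    G(x, y) = A cos(2*pi*f*x' + phi) * exp(-x'^2/(2 sx^2) - y'^2/(2 sy^2)),

where (x', y') are patch coordinates rotated by theta about the center
(x0, y0), via Nelder-Mead least squares from a data-driven initialization
(FFT peak for orientation/frequency, intensity moments for center and
envelope) with seeded multi-start.  Envelope widths in units of the carrier
wavelength, (nx, ny) = (sx*f, sy*f), summarize receptive-field shape for
comparison with cortical simple-cell data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .rbm import RBMParams, prob_h_given_v


@dataclass
class ReceptiveField:
    rf: np.ndarray  # (side, side)
    unit_index: int

    def __post_init__(self):
        self.rf = np.asarray(self.rf, dtype=float)
        if self.rf.ndim != 2 or self.rf.shape[0] != self.rf.shape[1]:
            raise ValueError("rf must be a square 2-D array")
        if not np.all(np.isfinite(self.rf)):
            raise ValueError("rf contains non-finite values")


@dataclass
class GaborFit:
    """Fitted Gabor parameters, canonicalized: A >= 0, theta in [0, pi),
    phi in [-pi, pi), sigma_x, sigma_y, f > 0.  r2 = 1 - SSR/SST; a failed
    fit carries r2 = -inf."""

    x0: float
    y0: float
    A: float
    sigma_x: float
    sigma_y: float
    theta: float
    f: float
    phi: float
    r2: float
    unit_index: int = -1


@dataclass
class ShapeProfile:
    nx: float
    ny: float
    aspect_ratio: float
    unit_index: int = -1


def gabor(shape, x0, y0, A, sigma_x, sigma_y, theta, f, phi) -> np.ndarray:
    """Evaluate the Gabor function on a pixel grid (x = column, y = row)."""
    h, w = shape
    y, x = np.mgrid[0:h, 0:w].astype(float)
    xr = (x - x0) * np.cos(theta) + (y - y0) * np.sin(theta)
    yr = -(x - x0) * np.sin(theta) + (y - y0) * np.cos(theta)
    env = np.exp(-(xr**2) / (2 * sigma_x**2) - (yr**2) / (2 * sigma_y**2))
    return A * np.cos(2 * np.pi * f * xr + phi) * env


def estimate_rf(
    params: RBMParams, stimuli, unit: int, center: bool = False
) -> ReceptiveField:
    """Reverse-correlation receptive field of one hidden unit.

    RF = sum_s p(h_j=1|v_s) v_s over the stimulus ensemble.  With
    ``center=True`` the ensemble pedestal (total activation mass times the
    mean stimulus) is subtracted, removing the DC offset that otherwise
    biases a Gabor fit; the raw sum is the default.
    """
    V = np.atleast_2d(np.asarray(getattr(stimuli, "patches", stimuli), dtype=float))
    if V.shape[0] == 0:
        raise ValueError("empty stimulus set")
    p = prob_h_given_v(params, V)[:, unit]
    rf = p @ V
    if center:
        rf = rf - p.sum() * V.mean(axis=0)
    side = int(round(np.sqrt(V.shape[1])))
    return ReceptiveField(rf.reshape(side, side), unit_index=unit)


def rf_basis_agreement(rf: ReceptiveField | np.ndarray, basis_column) -> float:
    """Correlation coefficient of the best linear fit RF ~ a*basis + b.

    For a least-squares linear fit this is simply the Pearson correlation
    between the flattened field and the basis image; returns 0 (with a
    warning) if either input has zero variance.
    """
    a = np.asarray(getattr(rf, "rf", rf), dtype=float).ravel()
    b = np.asarray(basis_column, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("size mismatch between rf and basis column")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero-variance input to rf_basis_agreement", stacklevel=2)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _canonicalize(p: np.ndarray) -> np.ndarray:
    x0, y0, A, sx, sy, theta, f, phi = p
    sx, sy, f = abs(sx), abs(sy), abs(f)
    if A < 0:
        A = -A
        phi += np.pi
    k = int(np.floor(theta / np.pi))
    theta -= k * np.pi
    if k % 2:  # rotating by pi flips x', so the phase negates
        phi = -phi
    phi = (phi + np.pi) % (2 * np.pi) - np.pi
    return np.array([x0, y0, A, sx, sy, theta, f, phi])


def _initial_guess(z: np.ndarray) -> np.ndarray:
    """Data-driven Gabor init: FFT peak -> (theta, f); moments of |z| ->
    center and envelope widths."""
    h, w = z.shape
    F = np.fft.fft2(z)
    fr = np.fft.fftfreq(h)[:, None]
    fc = np.fft.fftfreq(w)[None, :]
    mag = np.abs(F)
    mag[0, 0] = 0.0
    i, j = np.unravel_index(np.argmax(mag), mag.shape)
    fx, fy = fc[0, j], fr[i, 0]
    f0 = max(np.hypot(fx, fy), 1.0 / (4 * max(h, w)))
    theta0 = np.arctan2(fy, fx) % np.pi
    wgt = np.abs(z)
    tot = wgt.sum()
    y, x = np.mgrid[0:h, 0:w].astype(float)
    if tot > 0:
        x0 = float((wgt * x).sum() / tot)
        y0 = float((wgt * y).sum() / tot)
        sx = float(np.sqrt((wgt * (x - x0) ** 2).sum() / tot))
        sy = float(np.sqrt((wgt * (y - y0) ** 2).sum() / tot))
    else:
        x0, y0 = (w - 1) / 2, (h - 1) / 2
        sx = sy = w / 4
    sx = np.clip(sx, 0.5, w)
    sy = np.clip(sy, 0.5, h)
    A0 = float(np.max(np.abs(z)))
    return np.array([x0, y0, A0, sx, sy, theta0, f0, 0.0])


def fit_gabor(
    rf: ReceptiveField | np.ndarray,
    n_restarts: int = 10,
    seed: int = 0,
    good_enough_r2: float = 0.999,
) -> GaborFit:
    """Least-squares Gabor fit by Nelder-Mead with seeded multi-start.

    The model is G(x, y) + B: a constant offset B is fitted alongside the
    eight Gabor parameters and discarded as a nuisance — low-frequency
    Gabors carry substantial DC which would otherwise bias the frequency
    estimate.  Restart 0 starts from the data-driven initialization, tried
    at four carrier phases; the remaining restarts perturb it with seeded
    noise.  The search stops early once r2 exceeds ``good_enough_r2``.
    sigma is bounded to [0.3, 2*side] pixels and the center to the patch
    during optimization via a smooth penalty; the best fit is canonicalized
    before return.  A constant field is rejected.
    """
    unit = getattr(rf, "unit_index", -1)
    z = np.asarray(getattr(rf, "rf", rf), dtype=float)
    z = z - z.mean()
    sst = float((z**2).sum())
    if sst == 0:
        raise ValueError("cannot fit a constant receptive field")
    h, w = z.shape
    side = max(h, w)
    lo = np.array([-1.0, -1.0, 0.0, 0.3, 0.3, -np.inf, 1e-3, -np.inf])
    hi = np.array([w + 0.0, h + 0.0, np.inf, 2.0 * side, 2.0 * side, np.inf, 0.6, np.inf])

    def objective(p):
        q = p[:8].copy()
        q[2:5] = np.abs(q[2:5])
        q[6] = abs(q[6])
        pen = 0.0
        for v, a, b_ in zip(q, lo, hi):
            if np.isfinite(a) and v < a:
                pen += (a - v) ** 2
            if np.isfinite(b_) and v > b_:
                pen += (v - b_) ** 2
        g = gabor(z.shape, *q) + p[8]
        return float(((g - z) ** 2).sum()) + 10.0 * sst * pen

    base = np.append(_initial_guess(z), 0.0)
    starts = []
    for phi0 in (0.0, np.pi / 2, np.pi, -np.pi / 2):
        s = base.copy()
        s[7] = phi0
        starts.append(s)
    starts.sort(key=objective)
    rng = np.random.default_rng(seed)
    best_p, best_ssr = None, np.inf
    for r in range(max(n_restarts, 1)):
        if r == 0:
            p0 = starts[0]
        else:
            p0 = starts[0] + rng.normal(
                0, [1.0, 1.0, 0.3 * base[2] + 1e-6, 1.0, 1.0, 0.4, 0.03, 1.0, 0.1 * base[2] + 1e-6]
            )
        res = minimize(
            objective,
            p0,
            method="Nelder-Mead",
            options={"maxiter": 6000, "xatol": 1e-7, "fatol": 1e-13 * max(sst, 1.0)},
        )
        if res.fun < best_ssr:
            best_ssr = res.fun
            best_p = res.x
        if 1.0 - best_ssr / sst > good_enough_r2:
            break
    offset = best_p[8]
    p = _canonicalize(best_p[:8])
    g = gabor(z.shape, *p) + offset
    ssr = float(((g - z) ** 2).sum())
    r2 = 1.0 - ssr / sst
    if not np.isfinite(r2):
        r2 = -np.inf
    return GaborFit(*p, r2=r2, unit_index=unit)


def quality_filter(
    fits: list[GaborFit],
    r2_min: float = 0.5,
    patch_side: int = 14,
    sanity_bounds: bool = True,
) -> list[GaborFit]:
    """Keep fits with r2 >= r2_min whose parameters are sane: center inside
    the patch, envelope widths no larger than the patch diagonal."""
    if not 0 <= r2_min <= 1:
        raise ValueError("r2_min must be in [0, 1]")
    diag = patch_side * np.sqrt(2.0)
    kept = []
    for ft in fits:
        if not np.isfinite(ft.r2) or ft.r2 < r2_min:
            continue
        if sanity_bounds:
            if not (0 <= ft.x0 <= patch_side - 1 and 0 <= ft.y0 <= patch_side - 1):
                continue
            if ft.sigma_x > diag or ft.sigma_y > diag:
                continue
        kept.append(ft)
    return kept


def shape_profiles(fits: list[GaborFit], aspect: str = "ny/nx") -> list[ShapeProfile]:
    """Envelope widths in carrier wavelengths, (nx, ny) = (sigma_x*f,
    sigma_y*f), per fit.  ``aspect`` selects the ratio orientation
    ("ny/nx" default, or "nx/ny")."""
    if aspect not in ("ny/nx", "nx/ny"):
        raise ValueError("aspect must be 'ny/nx' or 'nx/ny'")
    out = []
    for ft in fits:
        nx = ft.sigma_x * ft.f
        ny = ft.sigma_y * ft.f
        ratio = ny / nx if aspect == "ny/nx" else nx / ny
        out.append(ShapeProfile(nx=nx, ny=ny, aspect_ratio=ratio, unit_index=ft.unit_index))
    return out


def aspect_histogram(
    profiles: list[ShapeProfile], bin_edges
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of aspect ratios with explicit bin edges; counts include
    out-of-range values in the edge bins so they sum to len(profiles)."""
    ratios = np.array([p.aspect_ratio for p in profiles], dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    clipped = np.clip(ratios, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return counts, edges


def fits_table(fits: list[GaborFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit": ft.unit_index,
                "x0": ft.x0,
                "y0": ft.y0,
                "A": ft.A,
                "sigma_x": ft.sigma_x,
                "sigma_y": ft.sigma_y,
                "theta": ft.theta,
                "f": ft.f,
                "phi": ft.phi,
                "r2": ft.r2,
            }
            for ft in fits
        ]
    )


def rf_montage(rfs: list[ReceptiveField], n_cols: int = 10, pad: int = 1) -> np.ndarray:
    """Tile receptive fields into one grayscale image (each field
    independently normalized to [0, 1]); for gallery PNGs."""
    if not rfs:
        raise ValueError("no receptive fields to tile")
    side = rfs[0].rf.shape[0]
    n = len(rfs)
    n_rows = int(np.ceil(n / n_cols))
    out = np.full(
        (n_rows * (side + pad) + pad, n_cols * (side + pad) + pad), 0.5
    )
    for i, rf in enumerate(rfs):
        z = rf.rf
        rng_ = z.max() - z.min()
        z = (z - z.min()) / rng_ if rng_ > 0 else np.full_like(z, 0.5)
        r, c = divmod(i, n_cols)
        top = pad + r * (side + pad)
        left = pad + c * (side + pad)
        out[top : top + side, left : left + side] = z
    return out
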