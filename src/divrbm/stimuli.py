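"""Visual stimulus preparation.

Natural (or synthetic) grayscale images are pseudo-whitened in the frequency
domain, small square patches are cut out at random positions, pixel
intensities are squashed into [0, 1] with a logistic function, and
low-variance (flat) patches are discarded.  The surviving patches are the
training stimuli for the RBM.

The pseudo-whitening filter R(f) = f * exp(-(f/f0)^4) approximately flattens
the ~1/f amplitude spectrum of natural scenes while rolling off the highest
frequencies, loosely emulating retinal preprocessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from PIL import Image
from scipy.special import expit

DEFAULT_PATCH_SIDE = 14
DEFAULT_VARIANCE_THRESHOLD = 0.1
#: default whitening cutoff, as a fraction of the Nyquist frequency (0.5 cyc/px)
DEFAULT_F0_FRACTION = 0.4
DEFAULT_WHITEN_EXPONENT = 4.0
#: logistic gain used by the prepare pipeline (see docs/methods.md): whitened
#: images are heavy-tailed, so a steep logistic is needed for structured
#: patches to clear the variance filter while flat patches map near 0.5.
DEFAULT_PIPELINE_GAIN = 4.0


@dataclass
class PatchSet:
    """A stack of flattened, preprocessed stimulus patches.

    Attributes
    ----------
    patches : (L, Nv) float array, values in [0, 1] after preprocessing.
    patch_side : side length of the square patches; Nv == patch_side**2.
    provenance : (L, 3) int array of (image index, row offset, col offset).
    """

    patches: np.ndarray
    patch_side: int = DEFAULT_PATCH_SIDE
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.patches = np.atleast_2d(np.asarray(self.patches, dtype=float))
        if self.patches.shape[1] != self.patch_side**2:
            raise ValueError(
                f"patch dimension {self.patches.shape[1]} != patch_side**2 "
                f"({self.patch_side**2})"
            )
        if self.provenance is None:
            self.provenance = np.full((len(self.patches), 3), -1, dtype=int)
        else:
            self.provenance = np.asarray(self.provenance, dtype=int)

    @property
    def n_patches(self) -> int:
        return self.patches.shape[0]

    @property
    def n_visible(self) -> int:
        return self.patches.shape[1]

    def variances(self) -> np.ndarray:
        """Per-patch pixel variance (population convention, 1/N)."""
        return self.patches.var(axis=1)

    def images(self) -> np.ndarray:
        """Patches reshaped to (L, side, side)."""
        s = self.patch_side
        return self.patches.reshape(-1, s, s)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("patches", data=self.patches)
            f.create_dataset("provenance", data=self.provenance)
            f.attrs["patch_side"] = self.patch_side

    @classmethod
    def load(cls, path) -> "PatchSet":
        with h5py.File(path, "r") as f:
            return cls(
                patches=f["patches"][...],
                patch_side=int(f.attrs["patch_side"]),
                provenance=f["provenance"][...],
            )


def load_image(path) -> np.ndarray:
    """Read a grayscale image (PNG/PGM/TIFF); 16-bit depth is honored."""
    img = Image.open(path)
    if img.mode not in ("L", "I", "I;16", "F"):
        img = img.convert("L")
    return np.asarray(img, dtype=float)


def _frequency_modulus(shape) -> np.ndarray:
    fr = np.fft.fftfreq(shape[0])[:, None]
    fc = np.fft.fftfreq(shape[1])[None, :]
    return np.hypot(fr, fc)


def whiten_image(
    image: np.ndarray,
    f0: float | None = None,
    exponent: float = DEFAULT_WHITEN_EXPONENT,
) -> np.ndarray:
    """Apply the pseudo-whitening filter R(f) = f * exp(-(f/f0)^exponent).

    The filter rescales the amplitude at every 2-D frequency with modulus f
    (cycles/pixel); phases are untouched, so the operation is linear and
    shift-equivariant.  R(0) = 0, i.e. the DC component is removed.

    Parameters
    ----------
    f0 : low-pass cutoff in cycles/pixel; defaults to 0.4 * Nyquist = 0.2.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if f0 is None:
        f0 = DEFAULT_F0_FRACTION * 0.5
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    f = _frequency_modulus(image.shape)
    filt = f * np.exp(-((f / f0) ** exponent))
    return np.fft.ifft2(np.fft.fft2(image) * filt).real


def sigmoid_rescale(
    image: np.ndarray,
    gain: float = 1.0,
    mean: float | None = None,
    std: float | None = None,
) -> np.ndarray:
    """Squash intensities into (0, 1) with a logistic of z-scored values.

    ``mean``/``std`` default to the statistics of ``image`` itself; the
    prepare pipeline passes whole-image statistics so that each patch keeps
    its contrast relative to the image it came from.  A zero-variance input
    maps to 0.5 everywhere.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if mean is None:
        mean = image.mean()
    if std is None:
        std = image.std()
    if std == 0:
        return np.full_like(image, 0.5)
    return expit(gain * (image - mean) / std)


def extract_patches(
    images: list[np.ndarray],
    n_patches: int,
    patch_side: int = DEFAULT_PATCH_SIDE,
    seed: int = 0,
) -> PatchSet:
    """Cut ``n_patches`` square patches at uniformly random offsets.

    Source image and top-left (row, col) offset are drawn uniformly;
    provenance records (image index, row, col) for every patch.  0-based,
    half-open windows.  Reproducible given ``seed``.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    images = [np.asarray(im, dtype=float) for im in images]
    for im in images:
        if min(im.shape) < patch_side:
            raise ValueError(
                f"patch side {patch_side} exceeds image of shape {im.shape}"
            )
    rng = np.random.default_rng(seed)
    out = np.empty((n_patches, patch_side**2))
    prov = np.empty((n_patches, 3), dtype=int)
    idx = rng.integers(0, len(images), size=n_patches)
    for i, k in enumerate(idx):
        im = images[k]
        r = rng.integers(0, im.shape[0] - patch_side + 1)
        c = rng.integers(0, im.shape[1] - patch_side + 1)
        out[i] = im[r : r + patch_side, c : c + patch_side].ravel()
        prov[i] = (k, r, c)
    return PatchSet(out, patch_side=patch_side, provenance=prov)


def filter_low_variance(
    patches: PatchSet, threshold: float = DEFAULT_VARIANCE_THRESHOLD
) -> PatchSet:
    """Drop patches whose pixel variance is strictly below ``threshold``.

    Variance uses the population (1/N) convention; a patch with variance
    exactly equal to the threshold is retained.  Order is preserved.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = patches.variances() >= threshold
    if not keep.any():
        warnings.warn("variance filter removed every patch", stacklevel=2)
    return PatchSet(
        patches.patches[keep],
        patch_side=patches.patch_side,
        provenance=patches.provenance[keep],
    )


def generate_synthetic_images(
    n_images: int = 10,
    side: int = 256,
    spectral_slope: float = 1.0,
    n_edges: int = 60,
    seed: int = 0,
    background_weight: float = 0.3,
    edge_amplitude: tuple[float, float] = (2.0, 5.0),
    edge_width: float = 0.8,
) -> list[np.ndarray]:
    """Synthesize natural-image-like fields: 1/f^slope noise plus oriented
    structure.

    Each image is a Gaussian random field with amplitude spectrum
    proportional to 1/f^slope (scaled to ``background_weight`` standard
    deviations), on top of which ``n_edges`` localized oriented elements are
    superimposed — half soft step edges of transition width ``edge_width``
    pixels, half gratings — with random orientation, position, envelope
    scale and frequency.  As in natural scenes, the oriented structure
    dominates and the noise floor is comparatively weak, so whitened
    patches carry contours rather than texture.  Images are standardized to
    zero mean, unit variance.  Bit-reproducible given seed.
    """
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:side, 0:side].astype(float)
    images = []
    for _ in range(n_images):
        white = rng.standard_normal((side, side))
        f = _frequency_modulus((side, side))
        amp = np.zeros_like(f)
        nz = f > 0
        amp[nz] = f[nz] ** (-spectral_slope)
        field_ = np.fft.ifft2(np.fft.fft2(white) * amp).real
        s = field_.std()
        if s > 0:
            field_ = background_weight * field_ / s
        for e in range(n_edges):
            theta = rng.uniform(0, np.pi)
            x0 = rng.uniform(0, side)
            y0 = rng.uniform(0, side)
            d = (x - x0) * np.cos(theta) + (y - y0) * np.sin(theta)
            r2 = (x - x0) ** 2 + (y - y0) ** 2
            env_sigma = rng.uniform(8.0, side / 4.0)
            env = np.exp(-r2 / (2 * env_sigma**2))
            a = rng.uniform(*edge_amplitude) * rng.choice([-1.0, 1.0])
            if e % 2 == 0:
                elem = np.tanh(d / edge_width)
            else:
                freq = rng.uniform(0.03, 0.25)
                phase = rng.uniform(0, 2 * np.pi)
                elem = np.cos(2 * np.pi * freq * d + phase)
            field_ = field_ + a * env * elem
        field_ = field_ - field_.mean()
        s = field_.std()
        if s > 0:
            field_ = field_ / s
        images.append(field_)
    return images


def prepare_patches(
    images: list[np.ndarray],
    n_patches: int = 10_000,
    patch_side: int = DEFAULT_PATCH_SIDE,
    gain: float = DEFAULT_PIPELINE_GAIN,
    f0: float | None = None,
    exponent: float = DEFAULT_WHITEN_EXPONENT,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    seed: int = 0,
    exact_count: bool = True,
    max_rounds: int = 50,
) -> PatchSet:
    """Full preprocessing pipeline: whiten -> extract -> sigmoid -> filter.

    Patches are z-scored against their source image's post-whitening
    statistics before the logistic, so flat patches land near 0.5 (and are
    filtered) while contrasty patches survive.  With ``exact_count`` the
    extraction is repeated with fresh (seed-derived) draws until
    ``n_patches`` patches pass the variance filter; otherwise a single round
    of ``n_patches`` raw extractions is filtered and returned as-is.
    """
    whitened = [whiten_image(im, f0=f0, exponent=exponent) for im in images]
    stats = [(im.mean(), im.std()) for im in whitened]

    def one_round(count: int, round_seed: int) -> PatchSet:
        raw = extract_patches(whitened, count, patch_side, seed=round_seed)
        out = np.empty_like(raw.patches)
        for i, (k, _, _) in enumerate(raw.provenance):
            m, s = stats[k]
            out[i] = sigmoid_rescale(raw.patches[i], gain=gain, mean=m, std=s)
        return filter_low_variance(
            PatchSet(out, patch_side, raw.provenance), variance_threshold
        )

    kept = one_round(n_patches, seed)
    if not exact_count:
        return kept
    rounds = 1
    while kept.n_patches < n_patches and rounds < max_rounds:
        extra = one_round(n_patches, seed + 100_003 * rounds)
        kept = PatchSet(
            np.vstack([kept.patches, extra.patches]),
            patch_side,
            np.vstack([kept.provenance, extra.provenance]),
        )
        rounds += 1
    if kept.n_patches < n_patches:
        warnings.warn(
            f"only {kept.n_patches}/{n_patches} patches passed the variance "
            "filter; consider lowering the threshold or raising the gain",
            stacklevel=2,
        )
    return PatchSet(
        kept.patches[:n_patches],
        patch_side,
        kept.provenance[:n_patches],
    )


def radial_amplitude_spectrum(
    image: np.ndarray, n_bins: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged FFT amplitude, for spectral diagnostics.

    Returns (bin center frequencies in cycles/pixel, mean amplitude per bin).
    """
    amp = np.abs(np.fft.fft2(np.asarray(image, dtype=float)))
    f = _frequency_modulus(image.shape)
    edges = np.linspace(0, 0.5, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.digitize(f.ravel(), edges) - 1
    means = np.full(n_bins, np.nan)
    a = amp.ravel()
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            means[b] = a[sel].mean()
    return centers, means
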