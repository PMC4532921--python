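"""Deterministic image reconstruction through a trained RBM.

A preprocessed image (whitened, logistic-mapped to [0, 1]) is tiled into
non-overlapping patches; each patch v is encoded as the activation
probabilities p(h|v) and decoded as p(v|h) using those probabilities
directly — no sampling anywhere, so the reconstruction is deterministic.
Margins left over when the image size is not a multiple of the patch side
are cropped before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rbm import RBMParams, prob_h_given_v, prob_v_given_h


@dataclass
class ReconstructionReport:
    original: np.ndarray  # cropped to the tiled area
    reconstructed: np.ndarray
    mse: float
    per_patch_mse: np.ndarray  # (rows/side, cols/side) grid
    psnr: float


def reconstruct_image(params: RBMParams, image: np.ndarray) -> ReconstructionReport:
    """Patch-wise deterministic reconstruction and its error report.

    The patch side is inferred from the model (side = sqrt(Nv)).  MSE is the
    mean squared pixel error over the covered (cropped) area, which equals
    the mean of the per-patch values; PSNR assumes unit signal range.
    """
    image = np.asarray(image, dtype=float)
    side = int(round(np.sqrt(params.n_visible)))
    if side * side != params.n_visible:
        raise ValueError("model visible layer is not a square patch")
    if image.ndim != 2 or image.shape[0] < side or image.shape[1] < side:
        raise ValueError(f"image smaller than one {side}x{side} patch")
    nr, nc = image.shape[0] // side, image.shape[1] // side
    cropped = image[: nr * side, : nc * side]
    # (nr*nc, side*side) blocks, row-major over the tile grid
    blocks = (
        cropped.reshape(nr, side, nc, side)
        .transpose(0, 2, 1, 3)
        .reshape(nr * nc, side * side)
    )
    recon_blocks = prob_v_given_h(params, prob_h_given_v(params, blocks))
    recon = (
        recon_blocks.reshape(nr, nc, side, side)
        .transpose(0, 2, 1, 3)
        .reshape(nr * side, nc * side)
    )
    per_patch = ((recon_blocks - blocks) ** 2).mean(axis=1).reshape(nr, nc)
    mse = float(per_patch.mean())
    psnr = float(10.0 * np.log10(1.0 / mse)) if mse > 0 else np.inf
    return ReconstructionReport(cropped, recon, mse, per_patch, psnr)


def holdout_split(
    images: list[np.ndarray], n_test: int, seed: int = 0
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Seeded disjoint train/test split of an image list (e.g. 8/2 out of
    a 10-image database)."""
    if not 0 <= n_test < len(images):
        raise ValueError("n_test must be in [0, n_images)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(images))
    test_idx = set(order[:n_test].tolist())
    train = [images[i] for i in range(len(images)) if i not in test_idx]
    test = [images[i] for i in sorted(test_idx)]
    return train, test
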