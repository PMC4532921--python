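"""Build a training patch set from synthetic natural-image-like stimuli.

Generates ten 1/f images with oriented structure, pseudo-whitens them,
extracts 14x14 patches, squashes intensities into [0, 1] with a logistic,
and drops low-variance (flat) patches.
"""

import numpy as np

from divrbm import generate_synthetic_images, prepare_patches

images = generate_synthetic_images(n_images=10, side=256, seed=0)
patches = prepare_patches(images, n_patches=10_000, patch_side=14, seed=0)

print(f"patches: {patches.n_patches} x {patches.n_visible} "
      f"({patches.patch_side}x{patches.patch_side} pixels)")
print(f"value range: [{patches.patches.min():.3f}, {patches.patches.max():.3f}]")
print(f"per-patch variance: median {np.median(patches.variances()):.3f}, "
      f"min {patches.variances().min():.3f} (threshold 0.1)")
# Every patch is in [0,1] and has pixel variance >= 0.1, i.e. it carries
# visible structure rather than flat texture.
patches.save("scratch_patches.h5")
print("saved to scratch_patches.h5")
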