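"""Estimate receptive fields by reverse correlation and fit Gabors.

Each hidden unit's receptive field is the activation-probability-weighted
sum of stimulus patches.  Fields are fitted with a 2-D Gabor (center,
amplitude, envelope widths, orientation, spatial frequency, phase); fits
passing quality control are summarized as shape profiles
(nx, ny) = (sigma_x * f, sigma_y * f), the envelope size in units of the
carrier wavelength, for comparison with cortical simple-cell data.
"""

import numpy as np

from divrbm import (
    TrainConfig,
    estimate_rf,
    fit_gabor,
    generate_synthetic_images,
    initialize,
    prepare_patches,
    quality_filter,
    rf_basis_agreement,
    shape_profiles,
    train,
)

images = generate_synthetic_images(n_images=4, side=128, seed=3)
patches = prepare_patches(images, n_patches=3_000, patch_side=14, seed=3)
config = TrainConfig(lambda_div=1e-3, learning_rate=0.5, epochs=15,
                     batch_size=100, seed=3, regularizer="diversity")
params, _ = train(initialize(196, 20, seed=3), patches, config)

fits, agreements = [], []
for unit in range(params.n_hidden):
    field = estimate_rf(params, patches, unit, center=True)
    agreements.append(rf_basis_agreement(field, params.W[:, unit]))
    fits.append(fit_gabor(field, n_restarts=5, seed=unit))

kept = quality_filter(fits, r2_min=0.5, patch_side=14)
profiles = shape_profiles(kept)
print(f"median |RF-basis correlation|: {np.median(np.abs(agreements)):.2f}")
print(f"{len(kept)}/{len(fits)} units pass Gabor quality control (r2 >= 0.5)")
if profiles:
    nx = [p.nx for p in profiles]
    ny = [p.ny for p in profiles]
    print(f"shape profiles: nx median {np.median(nx):.2f}, "
          f"ny median {np.median(ny):.2f}, "
          f"aspect (ny/nx) median {np.median([p.aspect_ratio for p in profiles]):.2f}")
# A high RF-basis correlation means the reverse-correlation field matches
# the unit's weight column; (nx, ny) well below 1 indicates receptive
# fields spanning only a fraction of a carrier wavelength, as for V1
# simple cells.
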