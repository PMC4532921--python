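"""Measure Treves-Rolls selectivity and sparsity of a trained model.

Selectivity (lifetime sparseness) is computed per neuron across stimuli;
sparsity (population sparseness) per stimulus across neurons.  Both are 0
for uniform responses and approach 1 for one-hot responses.  Units whose
activation never exceeds 0.1 are counted as dead.
"""

from divrbm import (
    TrainConfig,
    activation_matrix,
    count_dead_neurons,
    generate_synthetic_images,
    initialize,
    mean_selectivity,
    mean_sparsity,
    prepare_patches,
    train,
)

images = generate_synthetic_images(n_images=4, side=128, seed=2)
patches = prepare_patches(images, n_patches=2_000, patch_side=14, seed=2)

for lam in (0.0, 1e-3):
    config = TrainConfig(lambda_div=lam, learning_rate=0.5, epochs=10,
                         batch_size=100, seed=2, regularizer="diversity")
    params, _ = train(initialize(196, 30, seed=2), patches, config)
    R = activation_matrix(params, patches)
    print(f"lambda={lam:g}: mean selectivity {mean_selectivity(R):.3f}, "
          f"mean sparsity {mean_sparsity(R):.3f}, "
          f"dead neurons {count_dead_neurons(R)}/30")
# Higher numbers mean more stimulus-specific neurons (selectivity) and
# fewer co-active neurons per stimulus (sparsity).
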