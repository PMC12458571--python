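"""Train a small autoencoder, encode UDIPs, and interpret one dimension.

Runs the core loop on a phantom cohort: masked-MSE training, latent
extraction, then a PerDI perturbation t-map for the dimension most
correlated with planted factor 0, scored against the atlas by the K-S
enrichment statistic.  Takes a couple of minutes on one CPU.
"""

import numpy as np

from udrwm import (
    AEConfig,
    PerturbationConfig,
    PhantomSpec,
    build_model,
    encode,
    ks_enrichment,
    perdi_tmap,
    simulate_cohort,
    train,
)

spec = PhantomSpec(grid=(32, 40, 32), n_latents=4, seed=0)
cohort = simulate_cohort(spec, n=200)

cfg = AEConfig(input_shape=spec.grid, channels=(8, 16), latent_dim=8,
               learning_rate=2e-3, epochs=20, batch_size=2, seed=0)
model = build_model(cfg)
report = train(model, cohort, cohort.mask)
print(f"trained {model.n_parameters} parameters; "
      f"best val masked-MSE {min(report.val_loss):.5f} at epoch {report.best_epoch}")

codes = encode(model, cohort)
z_true = cohort.true_latents.to_numpy()
z_hat = codes.to_numpy()

recovered = 0
for k in range(4):
    corrs = [abs(np.corrcoef(z_true[:, k], z_hat[:, d])[0, 1]) for d in range(8)]
    d = int(np.argmax(corrs))
    sigma = 0.3 * z_hat[:, d].std(ddof=1)
    tmap = perdi_tmap(model, codes,
                      PerturbationConfig(dim=d, sigma=sigma, n_subjects=200, seed=0, smooth_sigma=1.0))
    ks = ks_enrichment(tmap.raw, cohort.atlas)
    top = ks.top_region()
    recovered += int(top == k + 1)
    print(f"factor {k}: best dim {d} (|r| = {corrs[d]:.2f}), "
          f"top K-S region {top}, planted region {k + 1}")
print(f"recovered {recovered}/4 planted factors")
# A high K-S value means the region's voxels concentrate at the top of the
# |t| ranking, i.e. the decoder steers that region with this latent dim.
# Recovery is typically partial (2-3 of 4): with equal-variance planted
# factors the latent basis is rotation-degenerate, so some dimensions mix
# factors -- see docs/methods.md.
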