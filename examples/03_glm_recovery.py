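"""Fit a Bernoulli GLM to spikes from a known neuron and recover its filters.

A ground-truth linear-nonlinear neuron driven by the bending moment M and
the contact angle theta spikes on 100,000 one-millisecond bins of colored-
noise predictors.  The GLM (raised-cosine basis, 31 coefficients) is fit by
penalized maximum likelihood; the reconstructed temporal filters should
match the generating ones almost perfectly at this data size.
"""

import numpy as np

import whiskerglm as wg

basis = wg.make_basis()
predictors = wg.gen_noise_predictors(100_000, seed=5)
neuron = wg.GroundTruthNeuron.from_basis(
    basis,
    {"M": [0.8, 0.5, 0.25, 0.1, 0.05], "theta": [-0.4, 0.3, 0.15, -0.05, 0.02]},
    bias=float(np.log(0.05 / 0.95)), seed=42)
spikes = wg.simulate_spikes(neuron, predictors)
print(f"simulated {int(spikes.sum())} spikes over {spikes.size} ms "
      f"(rate {spikes.mean():.3f}/bin)")

design = wg.build_design(predictors, basis, "full")
fit = wg.fit(design, spikes)
print(f"fit converged in {fit.n_iter} Newton steps, "
      f"{fit.coef.size} coefficients")

filters = fit.filters()
for name in ("M", "theta"):
    corr = np.corrcoef(filters[name], neuron.filters[name])[0, 1]
    print(f"  filter recovery corr({name}) = {corr:.4f}")
for name in ("Fx", "V"):
    print(f"  undriven filter peak |alpha_{name}| = {np.abs(filters[name]).max():.4f}")

print("\nDriven filters are recovered with correlation near 1; undriven filters")
print("stay near zero -- the model identifies which variables drive the cell.")
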