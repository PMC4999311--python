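"""The central experiment in miniature: does decoupled stimulation reveal
what a population of neurons encodes?

Eight mechanics-driven model neurons are simulated on the same rendered
manual-stimulation trial and analyzed with full / mechanical-only /
kinematic-only GLMs (ten-fold cross-validation, contact-masked accuracy).
Under the wide decoupled protocol the mechanical subset should track the
full model and beat the kinematic subset for nearly every neuron; under a
coupled protocol (single radial distance, small pushes) the two subsets are
nearly interchangeable.
"""

import numpy as np

import whiskerglm as wg
from whiskerglm.io import results_table

geometry = wg.WhiskerGeometry()

for label, kwargs in (
    ("decoupled", dict(radial_range=(0.4, 0.9))),
    ("coupled", dict(radial_range=(0.6, 0.6), amplitude_range_mm=(0.4, 0.6))),
):
    protocol = wg.gen_passive_protocol(geometry, n_deflections=30, seed=3, **kwargs)
    predictors = wg.predictors_from_trial(wg.render_trial(protocol, geometry))
    results = wg.simulate_population(predictors, n_neurons=8, seed=11, kind="mechanics")
    df = results_table(results)
    n_mech_pref = int((df.R_mech >= df.R_kin).sum())
    print(f"\n=== {label} protocol ===")
    print(df.round(3).to_string(index=False))
    print(f"mechanical subset preferred for {n_mech_pref}/8 neurons; "
          f"median R_full = {df.R_full.median():.3f}")

print("\nBelow-diagonal rows (R_mech > R_kin) mean the mechanical description")
print("predicts firing better -- expected for mechanics-driven ground truth,")
print("but only resolvable when the stimulation decouples the two codes.")
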