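"""Does the size axis matter for recognition?

Fits a frozen linear readout for (size-informed) object categories, then
removes the size axis's variance from the responses and re-evaluates the
unchanged readout.  The accuracy drop is compared against removing axes of
baseline object spaces built from untrained encoders.
"""

import numpy as np

from sizeaxis import (ablate_recognition, build_encoder, build_object_space,
                      fit_readout, generate_planted_activations,
                      generate_size_stimuli)
from sizeaxis.synthetic import PlantedGroundTruth

stim = generate_size_stimuli(seed=0, image_px=32)
truth = PlantedGroundTruth.default(64, 10, seed=1, beta=2.0)
resp = generate_planted_activations(stim, 64, truth, seed=2)

enc = build_encoder(image_px=32, seed=3)
model = fit_readout(enc, resp, stim.category)

space, scores = build_object_space(resp)
L = np.log10(stim.sizes_cm)
axis = int(np.argmax([abs(np.corrcoef(scores.values[:, i], L)[0, 1])
                      for i in range(space.n_retained)])) + 1

res = ablate_recognition(model, space, axis, resp, stim.category,
                         stimuli=stim, n_null_reps=100, seed=4)
print(f"size axis: PC{axis}")
print(f"top-1 accuracy, full responses:   {res.acc_full:.3f}")
print(f"top-1 accuracy, axis removed:     {res.acc_ablated:.3f}")
print(f"accuracy drop {res.drop:+.3f}, p = {res.p:.4g} against "
      f"{len(res.null_drops)} baseline-axis removals")
print("\nCategories here partly follow size, so deleting the size axis "
      "impairs the frozen readout\nfar beyond what removing a generic "
      "baseline direction does.")
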