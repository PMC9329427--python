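"""Find the size axis of an object space with dropout statistics.

Activations contain a planted axis whose scores follow log10(real-world
size).  PCA builds the object space; each retained axis is removed in turn
and the drop in ideal-observer correspondence is summarized by the dropout
index DI = z(R) - z(r_i) (Fisher z).  Significance comes from untrained
encoders viewing the same stimuli with permuted rank labels, pooled across
axes, Bonferroni-corrected.
"""

import numpy as np

from sizeaxis import (build_object_space, dropout_significance,
                      generate_planted_activations, generate_size_stimuli)
from sizeaxis.synthetic import PlantedGroundTruth

stim = generate_size_stimuli(image_px=32, seed=0)
truth = PlantedGroundTruth.default(n_channels=64, n_latent=10, seed=1, beta=2.0)
resp = generate_planted_activations(stim, 64, truth, seed=2)

res = dropout_significance(resp, stim.ranks, stimuli=stim,
                           n_null_reps=200, alpha=0.05, seed=3)

print(f"reference correspondence R = {res.reference_r:.3f}")
print(f"retained axes: {res.n_retained}; "
      f"Bonferroni threshold p <= {0.05 / res.n_retained:.4f}")
print("axis   DI      r_after_removal   p (pooled null)   significant")
order = np.argsort(res.di)[::-1][:5]
for i in order:
    print(f"  {i+1:<4} {res.di[i]:+.3f}   {res.removed_r[i]:+.3f}            "
          f"{res.p_corrected[i]:.4f}          {bool(res.significant[i])}")
print(f"\nsignificant axes: {res.significant_axes()} "
      "(exactly the planted one: removing it abolishes the size structure;"
      "\n no other axis matters, mirroring one-axis size coding)")
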