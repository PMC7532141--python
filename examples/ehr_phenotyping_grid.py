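"""Grid irregular EHR episodes and score a simple phenotype ranking.

Synthetic ICU episodes observe 76 catalog features at Poisson times; two
latent condition labels each shift a disjoint block of three features after
a random onset.  Episodes are bucketed onto the 76 x 256 grid (2 h bins,
last observation per bin, forward fill) and a mean-of-affected-features
score is ranked with the three AUROC aggregations.
"""

import numpy as np

from chronodense import SynthSpec, auroc, ehr_tensorize, gen_ehr_multilabel
from chronodense.preprocessing import EHR_FEATURE_CATALOG

spec = SynthSpec(task="ehr-multilabel", n_samples=200, n_classes=2, seed=3)
episodes, labels = gen_ehr_multilabel(spec, effect_size=1.5, obs_rate_per_hour=0.05)
print(f"{len(episodes)} episodes, label prevalences {labels.mean(axis=0)}")

grids = np.stack([ehr_tensorize(ep) for ep in episodes])
print(f"gridded tensor: {grids.shape} (episodes x features x 2 h bins)")

# score each label by the time-mean of its three affected catalog features
scores = np.stack([grids[:, 3 * k : 3 * (k + 1), :].mean(axis=(1, 2))
                   for k in range(2)], axis=1)
for mode in ("micro", "macro", "weighted"):
    print(f"AUROC ({mode}): {auroc(scores, labels, mode):.3f}")
print("AUROC well above 0.5 confirms the label-linked step changes survive "
      "the 2 h binning; the full model consumes the same 76 x 256 tensors "
      "with a multi-label sigmoid head.")
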