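"""Recover the per-transition-type statistics by EM from synthetic events.

Samples 5000 (force, distance) events from the five-component mixture,
perturbs every mean by +10%, and lets EM walk back.  The fitted means
should land close to the generating values; the overlapping components
(types 1 and 4) keep the largest residuals.
"""

import numpy as np

from fibrinpull import default_components, model_from_components
from fibrinpull.em import recover_from_synthetic

truth = model_from_components(default_components())
model = recover_from_synthetic(n=5000, seed=0, perturbation=0.1)

print(f"converged in {model.n_iter} EM iterations\n")
print("type  mu_f fit  mu_f true   mu_x fit  mu_x true   prior fit  prior true")
for j in range(5):
    print(
        f"  {int(model.type_ids[j])}   {model.mu_f[j]:8.1f}  {truth.mu_f[j]:8.1f} "
        f"  {model.mu_x[j]:8.2f}  {truth.mu_x[j]:8.1f}   {model.priors[j]:8.3f} "
        f"  {truth.priors[j]:8.2f}"
    )
dev_f = np.abs(model.mu_f - truth.mu_f)
print(
    f"\nlargest mean-force deviation {dev_f.max():.1f} pN "
    f"({100 * (dev_f / truth.mu_f).max():.1f}%): the early-stopped EM keeps a "
    "small residual of the perturbed start where components overlap."
)
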