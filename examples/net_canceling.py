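"""The net-canceling demonstration at desk scale.

One pathway affects survival with +beta in males and -beta in females; a
sex-pooled analysis sees the two effects cancel.  The comparison trains the
sex-routed network and a sex-blind ablation (single shared pathway layer,
identical budget) on that dataset and on a matched twin where the effect is
shared, and reports mean test C-indices.  Three seeds keep this example
quick; the acceptance script runs ten.
"""

import numpy as np

import spinnet as sp

result = sp.net_canceling_comparison(n=600, seeds=range(3), beta=1.0,
                                     task="survival")

for name in ("opposite", "shared"):
    spin = np.mean(result[name]["spin"])
    abl = np.mean(result[name]["ablation"])
    print(f"{name:>8}-effect data: sex-routed C={spin:.3f}  "
          f"sex-blind C={abl:.3f}  gap={spin - abl:+.3f}")
print("\nUnder opposite effects the pooled model has no recoverable signal "
      "(C near 0.5); the sex-routed model can use each branch's sign. "
      "With beta=+/-1 the per-pathway signal is weak (~0.26 sd), so gaps "
      "are small at this sample size.")
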