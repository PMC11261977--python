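"""Simulate a gold-on-silicon test pattern and map its SE yield two ways.

Builds a squares phantom (background eta 1.82 ~ silicon, squares 2.75 ~
gold under a 30 keV He beam), simulates per-pixel measurements at dose 21
ions/pixel, and compares the conventional estimate (summed voltage only)
with the ion-count-aided one.  The printed standard deviations over
single-material pixels measure imaging noise: the count-aided map is
visibly tighter at identical dose.
"""

import numpy as np

from icam import ModelParams, estimate_map, make_phantom, simulate_image

rng = np.random.default_rng(1)
phantom = make_phantom("squares", (128, 128), eta_background=1.82, eta_foreground=2.75)
params = ModelParams(dose=21.0, yield_eta=1.82, c_mu=0.163, c_sigma=0.097)

sim = simulate_image(phantom, params, rng)
conv = estimate_map(sim["v"], None, params, "conventional")
ica = estimate_map(sim["v"], sim["m_tilde"].astype(float), params, "ica")

for label, eta_true in (("silicon", 1.82), ("gold", 2.75)):
    mask = phantom.eta_map == eta_true
    c, i = conv.eta_values[mask], ica.eta_values[mask]
    print(f"{label:8s} true eta {eta_true:.2f}: "
          f"conventional {c.mean():.3f} +/- {c.std():.3f}, "
          f"count-aided {i.mean():.3f} +/- {i.std():.3f}, "
          f"variance ratio {c.var() / i.var():.2f}")
print("Both maps are unbiased; the variance ratio is the noise reduction "
      "from counting detected ions, larger at the higher yield.")
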