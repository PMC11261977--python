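"""How much dose does counting ions save, and how robust is the estimate?

Computes the Fisher-information ratio between count-aided and conventional
measurements as a function of detector non-ideality c_sigma/c_mu, at dose
21 ions/pixel.  The ratio equals the predicted dose-reduction factor.
Also prints the sensitivity of each estimator to a 10% dose
misspecification.
"""

import numpy as np

from icam import fi_ratio_curve, fi_ratio_ideal, lambda_sensitivity
from icam.estimate import lambda_sensitivity_conventional

grid = np.array([0.1, 0.3, 0.6, 1.0, 1.5])
for eta in (2.75, 1.82):
    curve = fi_ratio_curve(eta, grid, dose=21.0, c_mu=0.163)
    vals = ", ".join(f"{r:.2f}@{g:.1f}" for g, r in zip(grid, curve.ratio))
    print(f"eta={eta}: FI ratio (dose-reduction factor) {vals}")
    print(f"         ideal-detector limit (c_sigma -> 0): {fi_ratio_ideal(eta):.2f}")

s = lambda_sensitivity(2.75, 0.10) * 100
print(f"10% dose error moves the count-aided estimate by {s:.1f}% at eta=2.75,")
print(f"but the conventional estimate by {lambda_sensitivity_conventional(0.10)*100:.0f}%: "
      "count aiding also buys calibration robustness.")
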