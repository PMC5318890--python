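"""Fit the from-scratch boosted-tree engine and recover a known truth.

A small synthetic regression with one thresholded driver, one weak driver
and one pure-noise column: the model should rank them correctly and its
partial dependence should show the step. (Reduced tree count so the example
runs in a few seconds; the pipeline default is 1500 trees.)
"""

import numpy as np
import pandas as pd

from lakehealth.boosting import (GBMConfig, fit_gbm, partial_dependence,
                                 relative_influence)

rng = np.random.default_rng(3)
n = 400
X = pd.DataFrame({
    "driver": rng.uniform(0, 10, n),
    "weak": rng.normal(size=n),
    "noise": rng.normal(size=n),
})
y = np.where(X["driver"] > 5, 3.0, 0.0) + 0.4 * X["weak"] \
    + rng.normal(0, 0.3, n)

model = fit_gbm(X, y, GBMConfig(n_trees=300, learning_rate=0.05, seed=0))
print(f"Cross-validation selected iteration {model.best_iteration} "
      f"of {len(model.trees)}.")
print("\nRelative influence (%):")
print(relative_influence(model).round(1).to_string())

pdp = partial_dependence(model, X, ["driver"], grid=np.array([3.0, 7.0]))
lo, hi = pdp["partial_dependence"].to_numpy()
print(f"\nPartial dependence on 'driver': {lo:.2f} at 3.0 -> {hi:.2f} at 7.0")
print("The model recovers the step of ~3 across the threshold at 5, ranks")
print("the true driver far above the weak one, and leaves the pure-noise")
print("column near zero influence - the behavior the full pipeline relies on.")
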