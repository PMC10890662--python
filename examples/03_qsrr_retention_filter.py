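"""QSRR retention-index filtering of isobaric Glc-GA candidates.

For the worked channel at m/z 563.2963 two peaks (RI 718.97 and 760.66)
share seven structure-compatible candidates.  A candidate is retained when
its experimental RI is below the predicted RI of the DMED-labeled parent
GA plus the model's cross-validated error (69.5832).
"""

import numpy as np

from glcga import eq1_filter, fit_qsrr, loocv_rmse, ri_differences
from glcga.synth_data import predicted_ri_table

predictions = predicted_ri_table()
names = sorted(predictions, key=predictions.get)
pred = [predictions[n] for n in names]

for label, ri_exp in (("compound 1", 718.97), ("compound 2", 760.66)):
    diffs = ri_differences(pred, ri_exp)
    kept = [eq1_filter(ri_exp, p) for p in pred]
    print(f"{label}: experimental RI {ri_exp}")
    for n, d, k in zip(names, diffs, kept):
        print(f"  {n:>6}: predicted-experimental = {d:8.2f}  -> {'retain' if k else 'exclude'}")

# the regression machinery behind the threshold: a 13-standard linear QSRR
rng = np.random.default_rng(0)
X = rng.normal(size=(13, 4))
y = 650.0 + X @ np.array([25.0, -12.0, 8.0, 40.0]) + rng.normal(0, 5.0, 13)
model = fit_qsrr(X, y, descriptor_names=["logP", "PSA", "nHBD", "MRefr"])
print(f"\nQSRR demo fit on 13x4 descriptors: training RMSE {model.training_rmse:.2f}, "
      f"LOO-CV RMSE {loocv_rmse(X, y):.2f} RI units")
print("Exclusions above are exactly the candidates whose predicted RI sits more "
      "than 69.5832 units below the measured value; positive deviations always retain.")
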