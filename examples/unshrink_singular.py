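"""The un-shrunk limit exists even for a singular correlation matrix.

Three maximally correlated variables have a rank-one sample correlation;
the classical partial correlation is undefined, yet the shrinkage -> 0
limit is exactly 1/2. Simply dividing the shrunk value by (1 - lambda)
does not recover it.
"""

import numpy as np

from unshrunk import analytic_unshrunk_limit, lambda_profile, shrunk_partial_correlation, spline_unshrink
from unshrunk.shrinkage import ShrinkageModel, _sorted_eigh
from unshrunk.toys import all_ones_correlation

R = all_ones_correlation(3)
vals, vecs = _sorted_eigh(R)
model = ShrinkageModel(R, vals, vecs, ["a", "b", "c"])

for lam in (1 / 3, 2 / 3):
    shrunk = shrunk_partial_correlation(model, lam).values[0, 1]
    print(f"lambda={lam:.3f}: shrunk pcor={shrunk:.3f}, "
          f"naive rescale by 1/(1-lambda) -> {shrunk / (1 - lam):.3f}  (limit is 0.5)")

analytic = analytic_unshrunk_limit(model)
print(f"analytic limit (null-space projector): {analytic.P0.values[0, 1]:.6f}")

spline = spline_unshrink(lambda_profile(model))
print(f"spline extrapolation of the Fisher-z profile: {spline.P0.values[0, 1]:.6f}")
print("both routes agree with the exact limit 1/2; the naive re-scaling does not")
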