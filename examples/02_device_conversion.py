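"""Convert power vectors between the two biometers.

Applies the published IOLMaster700 -> Anterion conversion for the
corneal back surface to a typical measurement, inverts it exactly, and
cross-validates a freshly fitted model on a synthetic paired cohort.
"""

import numpy as np

from keravec import (
    PUBLISHED_MODELS,
    PopulationParams,
    PowerVector,
    apply_conversion,
    cross_validate,
    generate_cohort,
    invert_conversion,
)
from keravec.pipeline import derive_power_columns

pv_z = PowerVector(veq=-5.79, v0=-0.25, v45=-0.05)  # back surface, device Z

fwd = PUBLISHED_MODELS[("back", "z_to_h")]
pv_h = apply_conversion(fwd, pv_z)
pv_back = apply_conversion(invert_conversion(fwd), pv_h)
print(f"device Z measurement        : {np.round(pv_z.as_array(), 4)}")
print(f"predicted on device H       : {np.round(pv_h.as_array(), 4)}")
print(f"back through exact inverse  : {np.round(pv_back.as_array(), 4)}")

cohort = derive_power_columns(generate_cohort(PopulationParams(n=854, seed=42)))
x = cohort[["veqp_z", "v0p_z", "v45p_z"]].to_numpy()
y = cohort[["veqp_h", "v0p_h", "v45p_h"]].to_numpy()
report = cross_validate(x, y, train_fraction=0.7, seed=42)
print(
    f"\n70/30 cross-validation on {report.n_train}+{report.n_test} synthetic eyes:"
    f"\n  test Euclidean-norm error : {report.test_norm.mean:.4f}"
    f" +/- {report.test_norm.sd:.4f} dpt"
    f"\n  train                     : {report.train_norm.mean:.4f}"
    f" +/- {report.train_norm.sd:.4f} dpt"
)
print(
    "\nThe predicted H vector is ~0.35 dpt more negative in veq (the\n"
    "systematically steeper back surface); similar train and test errors\n"
    "show the affine model does not overfit."
)
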