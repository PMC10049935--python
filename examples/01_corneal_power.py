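"""Total corneal power of a toric cornea via the thick-lens matrix chain.

Builds a cornea with crossed front/back astigmatism axes, decomposes
each surface into a power vector, combines them with the Gullstrand
formula on 2x2 power matrices and prints the resulting total power
vector next to the naive thin-lens sum.
"""

import numpy as np

from keravec import (
    Keratometry,
    RefractiveIndices,
    keratometric_power,
    surface_power_vector,
    total_power_vector,
)

idx = RefractiveIndices()

front = Keratometry(r1=7.81, r2=7.65, axis=7.0)    # flat meridian near horizontal
back = Keratometry(r1=7.08, r2=6.74, axis=173.0)   # back axis slightly crossed
cct = 0.5544                                        # central corneal thickness, mm

pv_front = surface_power_vector(front, 1.0, idx.n_cornea)
pv_back = surface_power_vector(back, idx.n_cornea, idx.n_aqueous)
pv_total = total_power_vector(front, back, cct, idx)

print(f"keratometric power K12      : {keratometric_power(front, idx):7.3f} dpt")
print(f"front surface  (veq,v0,v45) : {np.round(pv_front.as_array(), 3)}")
print(f"back surface   (veq,v0,v45) : {np.round(pv_back.as_array(), 3)}")
print(f"thick-lens total            : {np.round(pv_total.as_array(), 3)}")
thin = pv_front.as_array() + pv_back.as_array()
print(f"thin-lens sum (cct ignored) : {np.round(thin, 3)}")
print(
    "\nThe total equivalent power sits ~1.2 dpt below the keratometric\n"
    "reading because the real back surface subtracts power that the\n"
    "keratometer index only approximates; the thickness term adds back\n"
    f"{pv_total.veq - thin[0]:.3f} dpt relative to the thin-lens sum."
)
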