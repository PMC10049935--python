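"""IOL power for emmetropia from one eye's biometry, on both devices.

Shows how the systematic inter-device differences (deeper ACD, steeper
back surface on device H) translate into a clinically relevant IOL
power difference when identical formula constants are used.
"""

from keravec import EyeModel, Keratometry, LensConstants, iol_power_for_target

constants = LensConstants()  # ELP = ACD + 0.30 LT + 0.20; Cooke-adjusted AL

eye_z = EyeModel(
    al=23.8503, cct=0.5544, acd=3.1523, lt=4.6477,
    front=Keratometry(7.8186, 7.6784), back=Keratometry(7.0797, 6.7369),
)
# same eye as seen by device H: ACD +0.120 mm, CCT -0.0078 mm,
# back surface 0.397 mm steeper, front surface essentially unchanged
eye_h = EyeModel(
    al=23.8358, cct=0.5466, acd=3.2723, lt=4.6869,
    front=Keratometry(7.8182, 7.6780), back=Keratometry(6.6827, 6.3399),
)

for tag, eye in (("Z", eye_z), ("H", eye_h)):
    res = iol_power_for_target(eye, constants, target_seq=0.0)
    print(
        f"device {tag}: ELP {res.elp:6.3f} mm, adjusted AL {res.adjusted_al:6.3f} mm,"
        f" IOLP {res.iolp:7.3f} dpt"
    )

dz = iol_power_for_target(eye_z, constants).iolp
dh = iol_power_for_target(eye_h, constants).iolp
print(
    f"\nIOLP difference (H - Z): {dh - dz:+.3f} dpt\n"
    "Most of this comes from the steeper back surface (lower total\n"
    "corneal power) and the deeper ACD of device H; without re-optimised\n"
    "constants the two devices are not interchangeable."
)
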