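"""Wall shear stress in the microfluidic culture device.

T = 5µQ/(w·h²) for water at a typical perfusion rate; reported in Pa and
dyn/cm² because published culture-safety bounds use either unit.
"""

from organoidqpi.pipeline import DeviceGeometry, shear_stress

geom = DeviceGeometry(
    viscosity=1.0e-3,        # Pa·s (water)
    flow_rate=1.667e-9,      # m³/s  (100 µL/min)
    channel_width=2.0e-3,    # m
    channel_height=2.5e-3,   # m
)
out = shear_stress(geom)
print(f"shear stress: {out['pa']:.3e} Pa = {out['dyn_per_cm2']:.3e} dyn/cm²")
# ~6.7e-3 dyn/cm² — orders of magnitude below levels reported to perturb
# cell behavior, so perfusion at this rate is mechanically benign.
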