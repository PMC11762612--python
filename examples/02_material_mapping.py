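"""Map CT attenuation to bone elasticity with the Dalstra relations.

Each bone element's HU value becomes an apparent density (linear law, capped
at 1.8 g/cm^3) and then a Young's modulus (power law), clamped to the
200-6530 MPa range of elderly bone and snapped to a 1266-bin material
catalog.
"""

import numpy as np

import pelvifem as pf
from pelvifem.materials import MappingConstants

C = MappingConstants()
print("calibration anchors:")
print(f"  HU=0    -> rho = {pf.hu_to_density(0.0, C):.5f} g/cm^3 (intercept)")
print(f"  HU=2000 -> rho = {pf.hu_to_density(2000.0, C):.5f} g/cm^3")
print(f"  rho=1.0 -> E   = {pf.density_to_modulus(1.0, C):.1f} MPa")
print(f"  HU=2000 -> E   = "
      f"{pf.density_to_modulus(pf.hu_to_density(2000.0, C), C):.1f} MPa")
print(f"  rho=1.8 -> E   = {pf.density_to_modulus(1.8, C):.1f} MPa "
      "(clamped at the range maximum)")
print(f"catalog: {C.n_bins} materials of {C.bin_width} MPa width "
      f"over [{C.E_min}, {C.E_max}] MPa\n")

mesh, hu = pf.build_phantom()
field = pf.assign_materials(mesh, hu)
bone = field.bin_id >= 0
print(f"phantom bone elements: {int(bone.sum())}, "
      f"{field.n_bins_used} material bins in use")
print(f"bone modulus range on this phantom: "
      f"{field.E[bone].min():.0f} - {field.E[bone].max():.0f} MPa")
print("cartilage/symphysis surrogate: E = 50 MPa, nu = 0.45; "
      "implants: E = 110000 MPa (titanium), nu = 0.3")
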