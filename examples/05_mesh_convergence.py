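"""Mesh-convergence protocol: refine until peak stresses change < 5%.

The ring is fixed at the upper sacrum, a bipedal stance is applied as
upward hip reactions, bone is uniform at 6000 MPa, and the robust peak
principal tension/compression is tracked across a refinement that
discretizes the *same* snapped geometry (5 mm then 2.5 mm elements).

Note: the fine solve factors ~500k degrees of freedom; allow a couple of
minutes.
"""

import pelvifem as pf

result = pf.convergence_study()      # default sizes (5.0, 2.5) mm
print(result.rows.to_string(index=False,
                            float_format=lambda v: f"{v:.4f}"))
print(f"\naccepted (<{result.threshold:.0%} change in both peaks): "
      f"{result.accepted}")
print("peaks are 99.5% volume-quantile principal stresses over bone at "
      "least 7.5 mm from any constraint, so they converge despite the "
      "faceted phantom's corner singularities.")
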