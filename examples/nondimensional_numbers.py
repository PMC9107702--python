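"""Flow-regime estimates: Darcy and Womersley numbers.

The Darcy number compares Brinkman (viscous) to Darcy (drag) resistance at
the wall-motion length scale; the Womersley bound compares fluid inertia to
viscous drag.  Da spanning ~1e-3 to ~1 justifies keeping the Brinkman term;
Wo ~ 2e-5 justifies neglecting fluid inertia.
"""

from pvsporo import nondimensional_estimates

est = nondimensional_estimates()
print(f"Darcy number range : {est['Da_min']:.3e} .. {est['Da_max']:.3e}")
print(f"Womersley bound    : {est['Wo_bound']:.3e}")
print()
print("Da_min ~ 0.9e-3 (ECS permeability at a 1.5 um wall stroke):")
print("  drag and Brinkman shear are not separable a priori -> use")
print("  Darcy-Brinkman rather than plain Darcy.")
print("Wo << 1: the fluid responds quasi-statically to vasodilation;")
print("  inertia is negligible at these scales.")
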