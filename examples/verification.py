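"""Solver verification against closed-form references.

* Terzaghi consolidation (1D series solution) — couples elasticity,
  Darcy drag and incompressibility in the linear regime;
* Darcy-Brinkman channel flow (rigid porous channel, exact profile);
* steady manufactured-solution convergence rates for the P2/P2/P1
  discretization.
"""

from pvsporo.oracles import (run_brinkman_channel, run_mms_convergence,
                             run_terzaghi)

tz = run_terzaghi()
print("Terzaghi consolidation, L2 pressure error vs analytic series:")
for Tv, err in tz["errors"].items():
    print(f"  T_v = {Tv:4}: {100 * err:5.2f}%")

bc = run_brinkman_channel()
print(f"\nBrinkman channel profile, max relative error: "
      f"{100 * bc['max_rel_error']:.2f}%")

mms = run_mms_convergence(ns=(8, 16, 32))
print("\nManufactured-solution convergence orders "
      "(expected ~3 / ~2 / ~2):")
print(f"  displacement {mms['order_u']:.2f}, filtration velocity "
      f"{mms['order_w']:.2f}, pressure {mms['order_p']:.2f}")
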