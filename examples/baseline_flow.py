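"""Baseline CSF current: 0.01 mmHg across the subarachnoid space.

Builds the two-domain mesh, ramps the SAS pressure difference over 0.1 s,
settles to a steady state, and reports the flowrates through the open
boundaries and the peak SAS speed (the driving pressure was chosen so this
is of order 20 um/s next to the arteriole).  Writes a VTK snapshot and a
flowrate CSV under scratch/.
"""

from pathlib import Path

import numpy as np

from pvsporo import SolverConfig, VasodilationModel
from pvsporo.io import write_flowrates_csv, write_vtk

outdir = Path("scratch/baseline")
outdir.mkdir(parents=True, exist_ok=True)

model = VasodilationModel(resolution="tiny",
                          config=SolverConfig(dt=0.05))
base = model.run_baseline()

print("mesh:", {k: v for k, v in model.mesh.summary().items()
                if k in ("cells", "p2_nodes", "pressure_dofs")})
print(f"steady after {len(base.times) - 1} steps "
      f"({base.times[-1]:.2f} s simulated)")
for tag, Q in base.flowrates.items():
    print(f"  Q_{tag:>11} = {Q[-1]:+.3e} m^3/s  (outward positive)")

sas = model.mesh.X2[:, 2] > 150e-6
peak = np.linalg.norm(base.w[-1], axis=1)[sas].max() * 1e6
print(f"peak SAS filtration speed: {peak:.1f} um/s "
      "(calibration target: ~20 um/s)")

write_flowrates_csv(outdir / "flowrates.csv", base)
write_vtk(outdir / "baseline.vtk", model.mesh, point_data={
    "v_flt": base.w[-1], "u_s": base.u[-1]})
print(f"wrote {outdir}/baseline.vtk and flowrates.csv")
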