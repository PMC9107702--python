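# pvsporo

A finite-deformation poroelastic (mixture-theory) model of the paravascular
space (PVS) of a penetrating cortical arteriole, the subarachnoid space
(SAS) and the brain parenchyma, built to study a mechanism of glymphatic
transport: **temporally asymmetric vasodilation (functional hyperemia)
rectifies oscillatory CSF flow into net convection from the PVS into the
brain extracellular space (ECS)**.

Intended for researchers in perivascular/glymphatic fluid mechanics and
computational biomechanics who want an inspectable, pure-Python
implementation of the coupled model — every operator from the neo-Hookean
skeleton stress to the porous-porous interface jump conditions is plain
`numpy`/`scipy` code.

## The model in brief

Two subdomains, each an incompressible biphasic mixture (solid skeleton +
CSF/ISF) in ALE form on the reference configuration:

| | fluid-filled spaces (PVS + SAS) | parenchyma |
|---|---|---|
| fluid fraction ζ_Rf | 0.8 | 0.2 awake / 0.3 sleep |
| permeability k_s | 2·10⁻¹⁴ m² (PVS), 2·10⁻¹² m² (SAS) | 2·10⁻¹⁵ m² (4·10⁻¹⁵ sleep) |
| skeleton shear modulus μ_s | 20 Pa | 2 kPa |

Per domain: solid momentum with effective stress P_s = μ_s(F − F⁻ᵀ), fluid
momentum with Darcy drag (J−ζ_Rs)(μ_f/k_s)v_flt and a Brinkman shear term,
the incompressibility constraint F⁻ᵀ:∇(v_s + v_flt) = 0, and phase-split
traction (jump) conditions across the PVS–parenchyma interface.
Discretization: P2/P2/P1 mixed elements, BDF2 in time, consistent stress
tangent, sparse LU + iterative refinement.  Forcing: a prescribed radial
wall motion — a symmetric (Gaussian) pulse or an asymmetric
(gamma-variate, fast-rise/slow-return) hyperemic pulse, one event per
10 s; plus a 0.01 mmHg pressure difference across the SAS and a flow
resistance at the deep end of the PVS.

Transport is quantified by time-averaged Peclet numbers against amyloid-β
diffusion (Pe_r radial, into the ECS; Pe_a axial, along the PVS) and by
60 s passive-particle tracking (243 particles advected in the
computational frame, dX/dt = F⁻¹(v_f − v_s)).

See `docs/methods.md` for the full formulation, the numerical choices and
the desk-scale caveats.

## Worked example

```python
from pvsporo import (SolverConfig, VasodilationModel, make_waveform,
                     radial_peclet_field)
from pvsporo.particles import (FieldSampler, advect,
                               classify_and_aggregate, seed_particles)

model = VasodilationModel(resolution="tiny",
                          config=SolverConfig(dt=0.1, picard_tol=1e-5,
                                              picard_max=3))
model.run_baseline()                      # 0.01 mmHg SAS current, steady
out = model.run_transient(make_waveform("asymmetric", "awake"))
print(radial_peclet_field(model.form, out)["max"])

ens = advect(seed_particles(model.spec),
             FieldSampler(model.form, out, period=10.0), T_total=60.0)
print(classify_and_aggregate(ens, model.spec)["summary"])
```

Running `python examples/rectification_particles.py` (which does the above
for both waveforms) prints, at the coarse `tiny` preset:

```
 symmetric: max time-avg radial Pe =   6.24   axial Pe = -0.0145
            after 60 s: 16.5% of PVS fluid in the ECS, 7.4% in the SAS, 76.1% still in the PVS
asymmetric: max time-avg radial Pe =  12.54   axial Pe = +0.0875
            after 60 s: 23.9% of PVS fluid in the ECS, 5.8% in the SAS, 70.4% still in the PVS

asymmetric / symmetric: radial-Pe ratio 2.01, ECS-fraction ratio 1.45
```

Reading: the *time-averaged* radial Peclet number — oscillatory flow
cancels in the average, so this is pure rectified transport — is twice as
large for the hyperemic waveform, and more PVS fluid ends up in the brain
after one minute, while both waveforms lose a similar share to the SAS.
(At this resolution the Pe_r magnitudes and the symmetric-case penetration
run high, compressing the fraction ratio; mechanistic orderings, not
magnitudes, are the desk-scale product — see the methods note.)

Other examples: `baseline_flow.py` (SAS current + VTK output),
`lag_experiment.py` (the pressure-vs-displacement forcing lag that powers
the rectification), `waveform_gallery.py`, `verification.py` (Terzaghi /
Brinkman / manufactured-solution checks), `nondimensional_numbers.py`.

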