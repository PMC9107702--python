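"""Material parameters of the two-phase (solid skeleton + CSF/ISF) mixture.

The model has two subdomains:

* domain 1 — the fluid-filled spaces: paravascular space (PVS) of a
  penetrating arteriole plus the subarachnoid space (SAS).  Mostly fluid
  (reference fluid volume fraction 0.8) with a very soft connective-tissue
  skeleton (20 Pa shear modulus).
* domain 2 — brain parenchyma: extracellular space (ECS) fluid fraction 0.2
  awake (0.3 in slow-wave sleep) in a 2 kPa neo-Hookean skeleton.

Both phases are intrinsically incompressible with true density 1000 kg/m^3;
the skeleton drains/imbibes fluid so the mixture is compressible in the
poroelastic sense.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class MixtureParams:
    """Per-domain material constants of the biphasic mixture (SI units).

    Attributes
    ----------
    rho_f_star : fluid true density [kg/m^3]
    rho_s_star : solid true density [kg/m^3]
    mu_f       : fluid dynamic viscosity [Pa s]
    mu_s       : solid (skeleton) shear modulus [Pa]
    k_s        : Darcy permeability [m^2]; may be overridden pointwise by a
                 spatial field (see :mod:`pvsporo.geometry`)
    zeta_Rf    : reference (undeformed) fluid volume fraction [-]
    """

    rho_f_star: float
    rho_s_star: float
    mu_f: float
    mu_s: float
    k_s: float
    zeta_Rf: float

    def __post_init__(self):
        for name in ("rho_f_star", "rho_s_star", "mu_f", "mu_s", "k_s"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.zeta_Rf < 1.0:
            raise ValueError("zeta_Rf must lie in (0, 1)")

    @property
    def zeta_Rs(self) -> float:
        """Reference solid volume fraction; zeta_Rf + zeta_Rs = 1 exactly."""
        return 1.0 - self.zeta_Rf


#: Fluid-filled spaces (PVS value of permeability; the SAS portion of domain 1
#: uses 2e-12 m^2 via the spatial permeability field).
PVS_SAS = MixtureParams(
    rho_f_star=1000.0, rho_s_star=1000.0, mu_f=1e-3,
    mu_s=20.0, k_s=2e-14, zeta_Rf=0.8,
)

#: Brain parenchyma, awake state.
PARENCHYMA_AWAKE = MixtureParams(
    rho_f_star=1000.0, rho_s_star=1000.0, mu_f=1e-3,
    mu_s=2000.0, k_s=2e-15, zeta_Rf=0.2,
)

#: Brain parenchyma in slow-wave sleep: ECS volume fraction 0.2 -> 0.3 and
#: permeability 2e-15 -> 4e-15 m^2.
PARENCHYMA_SLEEP = replace(PARENCHYMA_AWAKE, zeta_Rf=0.3, k_s=4e-15)


def parenchyma(mode: str = "awake", k_s: float | None = None) -> MixtureParams:
    """Parenchyma parameters for ``mode`` in {'awake', 'sleep'}.

    ``k_s`` overrides the ECS permeability (used by the permeability sweep).
    """
    if mode == "awake":
        p = PARENCHYMA_AWAKE
    elif mode == "sleep":
        p = PARENCHYMA_SLEEP
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if k_s is not None:
        p = replace(p, k_s=k_s)
    return p


@dataclass(frozen=True)
class TransportConstants:
    """Constants of the reference solute used for Peclet numbers.

    The reference solute is amyloid-beta; the reference length is the
    arteriole-to-venule distance a metabolite must traverse.
    """

    D_ab: float = 1.4e-6 * 1e-4   # amyloid-beta diffusivity, 1.4e-6 cm^2/s in m^2/s
    lam: float = 1.6              # ECS tortuosity; D_eff = D_ab / lam^2
    L_AV: float = 150e-6          # arteriole-to-venule distance [m]
    t_PVS: float = 8e-6           # largest PVS thickness [m]

    def __post_init__(self):
        if min(self.D_ab, self.lam, self.L_AV, self.t_PVS) <= 0:
            raise ValueError("transport constants must be positive")

    @property
    def D_eff_ecs(self) -> float:
        """Tortuosity-reduced effective diffusivity in the ECS [m^2/s]."""
        return self.D_ab / self.lam**2


#: Nominal arteriolar radius used to scale wall motion [m].
R0 = 10e-6
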