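"""Scale-dependent viscosity model of the crowded cytoplasm.

A probe of hydrodynamic radius ``r_p`` diffusing through cytoplasm does not
experience one viscosity: small solutes feel nearly the solvent (water)
viscosity while ribosome-sized particles feel a viscosity tens of thousands
of times larger.  The model used here interpolates between those limits with
a stretched exponential of an effective radius,

    ln(eta_eff / eta_0) = (R_eff / xi) ** a,
    R_eff ** -2 = r_p ** -2 + Rh_env ** -2,

where ``xi`` is the correlation length of the cytoplasm (roughly the average
gap between protein surfaces), ``Rh_env`` is the hydrodynamic radius of the
largest crowders (nucleoid DNA loops in *E. coli*), and ``a`` is a
dimensionless exponent of order one.  Dilute-solution diffusion follows the
Stokes--Sutherland--Einstein relation, and the in-vivo coefficient is the
dilute one divided by the effective viscosity ratio.

Canonical units throughout: radii in nm, temperature in K, viscosity in
Pa*s, diffusion coefficients in um^2/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BOLTZMANN_K",
    "WATER_VISCOSITY_310K",
    "SdvrcParams",
    "Environment",
    "Molecule",
    "MoleculeClass",
    "effective_radius",
    "ln_viscosity_ratio",
    "macroscopic_viscosity_ratio",
    "stokes_einstein_D0",
    "radius_from_D0",
    "predict_Dcyto",
]

#: Boltzmann constant, J/K (CODATA exact value).
BOLTZMANN_K = 1.380649e-23

#: Dynamic viscosity of pure water at 310 K, Pa*s (standard tables).
WATER_VISCOSITY_310K = 6.913e-4

#: Conversion m^2/s -> um^2/s.
_M2_TO_UM2 = 1.0e12

MoleculeClass = str
MOLECULE_CLASSES = (
    "protein",
    "rna",
    "dna_linear",
    "dna_circular",
    "dna_supercoiled",
    "small_molecule",
)


@dataclass(frozen=True)
class SdvrcParams:
    """Fitted length scales of one cell type's cytoplasm.

    Parameters
    ----------
    xi : float
        Correlation length, nm.  Average distance between protein surfaces;
        probes smaller than ``xi`` feel near-water viscosity.
    Rh_env : float
        Hydrodynamic radius of the biggest crowders, nm.  Sets the scale at
        which viscosity saturates at its macroscopic value.
    a : float
        Dimensionless stretching exponent, of order one.
    """

    xi: float
    Rh_env: float
    a: float

    def __post_init__(self) -> None:
        if not (self.xi > 0):
            raise ValueError(f"xi must be positive, got {self.xi}")
        if not (self.Rh_env > 0):
            raise ValueError(f"Rh_env must be positive, got {self.Rh_env}")
        if not (self.Rh_env > self.xi):
            raise ValueError(
                f"Rh_env ({self.Rh_env}) must exceed xi ({self.xi}): the "
                "crowder radius is necessarily larger than the inter-protein gap"
            )
        if not (0 < self.a < 2):
            raise ValueError(f"exponent a must lie in (0, 2), got {self.a}")


@dataclass(frozen=True)
class Environment:
    """Thermodynamic conditions entering the Stokes--Sutherland--Einstein law.

    Defaults describe the cytoplasmic measurements this package calibrates
    against: body temperature and the viscosity of pure water at 310 K.
    """

    T: float = 310.0
    eta0: float = WATER_VISCOSITY_310K
    kB: float = BOLTZMANN_K

    def __post_init__(self) -> None:
        if not (self.T > 0):
            raise ValueError(f"temperature must be positive, got {self.T}")
        if not (self.eta0 > 0):
            raise ValueError(f"solvent viscosity must be positive, got {self.eta0}")


@dataclass
class Molecule:
    """A query molecule: a radius, or a mass plus a molecule class.

    ``r_p`` (nm) is used directly when present; otherwise the class-specific
    radius--mass scaling law converts ``M`` (Da).  Small molecules have no
    scaling law — their van der Waals radii must be supplied explicitly.
    """

    name: str = ""
    r_p: float | None = None
    M: float | None = None
    molecule_class: MoleculeClass = "protein"

    def __post_init__(self) -> None:
        if self.molecule_class not in MOLECULE_CLASSES:
            raise ValueError(
                f"unknown molecule class {self.molecule_class!r}; "
                f"expected one of {MOLECULE_CLASSES}"
            )
        if self.r_p is not None and not (self.r_p > 0):
            raise ValueError(f"r_p must be positive, got {self.r_p}")
        if self.M is not None and not (self.M > 0):
            raise ValueError(f"M must be positive, got {self.M}")


def _check_positive(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(arr > 0):
        raise ValueError(f"{name} must be strictly positive")


def effective_radius(r_p, Rh_env):
    """Effective radius governing the viscosity felt by a probe.

    Harmonic-in-squares combination ``(r_p**-2 + Rh_env**-2)**-0.5``: the
    smaller of probe and crowder radius dominates, so viscosity growth
    saturates once the probe outgrows the crowders.  Accepts scalars or
    arrays (nm); returns the same shape.
    """
    _check_positive("r_p", r_p)
    _check_positive("Rh_env", Rh_env)
    r_p = np.asarray(r_p, dtype=float)
    out = (r_p**-2.0 + np.asarray(Rh_env, dtype=float) ** -2.0) ** -0.5
    return out if out.ndim else float(out)


def ln_viscosity_ratio(r_p, params: SdvrcParams):
    """ln(eta_eff/eta_0) felt by a probe of radius ``r_p`` nm.

    Vanishes as r_p -> 0 (probe feels the solvent) and saturates at
    ``(Rh_env/xi)**a`` (the macroscopic viscosity) as r_p -> infinity.
    """
    r_eff = effective_radius(r_p, params.Rh_env)
    out = (np.asarray(r_eff) / params.xi) ** params.a
    return out if out.ndim else float(out)


def macroscopic_viscosity_ratio(params: SdvrcParams) -> float:
    """Bulk cytoplasm viscosity over water viscosity, ``exp[(Rh_env/xi)**a]``.

    This is the supremum of ``eta_eff/eta_0`` over probe size: what a probe
    much larger than the largest crowders experiences.  Parameter triples
    whose exponent exceeds float range yield ``inf``.
    """
    try:
        return math.exp((params.Rh_env / params.xi) ** params.a)
    except OverflowError:
        return math.inf


def stokes_einstein_D0(r_p, env: Environment = Environment()):
    """Dilute-solution diffusion coefficient, um^2/s.

    Stokes--Sutherland--Einstein: ``D0 = kB*T / (6*pi*eta0*r_p)`` for a
    sphere of hydrodynamic radius ``r_p`` nm in a solvent of viscosity
    ``eta0``.
    """
    _check_positive("r_p", r_p)
    r_m = np.asarray(r_p, dtype=float) * 1e-9
    out = env.kB * env.T / (6.0 * math.pi * env.eta0 * r_m) * _M2_TO_UM2
    return out if out.ndim else float(out)


def radius_from_D0(D0, env: Environment = Environment()):
    """Hydrodynamic radius (nm) from a dilute-solution DC (um^2/s).

    Exact inverse of :func:`stokes_einstein_D0`.
    """
    _check_positive("D0", D0)
    d_si = np.asarray(D0, dtype=float) / _M2_TO_UM2
    out = env.kB * env.T / (6.0 * math.pi * env.eta0 * d_si) * 1e9
    return out if out.ndim else float(out)


def predict_Dcyto(r_p, params: SdvrcParams, env: Environment = Environment()):
    """Cytoplasmic diffusion coefficient of a probe of radius ``r_p`` nm.

    ``D_cyto = D0 * eta0/eta_eff = D0 * exp(-ln_viscosity_ratio)``; always
    at most the dilute-solution value and strictly decreasing in probe size.
    Returns um^2/s.
    """
    d0 = stokes_einstein_D0(r_p, env)
    out = np.asarray(d0) * np.exp(-np.asarray(ln_viscosity_ratio(r_p, params)))
    return out if out.ndim else float(out)
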