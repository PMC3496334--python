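"""Proteome-wide diffusion-coefficient databases.

Builds a table of predicted cytoplasmic diffusion coefficients for every
protein species in a proteome annotation.  The diffusing species is not
always the bare polypeptide: subunits of a quaternary complex diffuse as
the assembled oligomer (masses of all chains summed), and membrane or
periplasmic proteins cross the cytoplasm either as folded single chains
(TAT pathway) or as unfolded chains complexed with an export chaperone,
SecB or trigger factor (Sec pathway).  About 45% of the *E. coli* proteome
is part of some complex and ~30% is membrane-bound, which is what the
synthetic-proteome generator emulates.

Also provides the distribution analyses: the proteome mass histogram is
well described by a log-normal, and pushing that density through the
strictly monotone mass -> radius -> DC map gives the closed-form density of
cytoplasmic diffusion coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import Environment, SdvrcParams, ln_viscosity_ratio, stokes_einstein_D0
from .radii import get_scaling_law, radius_from_mass

__all__ = [
    "SEC_PARTNER_MASS_DA",
    "ProteinRecord",
    "DcRecord",
    "MassDistribution",
    "Species",
    "LinkageError",
    "assemble_species",
    "build_dc_table",
    "dc_table_frame",
    "fit_lognormal_mass",
    "dc_distribution_density",
    "dcyto_from_mass",
    "synth_proteome",
]

#: Chain masses of the Sec-pathway export chaperones, Da.
SEC_PARTNER_MASS_DA = {"SecB": 17_300.0, "Tig": 48_200.0}

LOCALIZATIONS = ("cytoplasmic", "membrane", "periplasmic")
PATHWAYS = ("none", "TAT", "Sec")


class LinkageError(ValueError):
    """A subunit reference cannot be resolved within the record set."""


@dataclass
class ProteinRecord:
    """One proteome annotation row.

    ``subunits`` lists (chain accession, copy number) pairs describing the
    quaternary complex this chain belongs to; empty means monomer.
    Non-cytoplasmic proteins must name their translocation pathway, and Sec
    substrates their chaperone partner.
    """

    accession: str
    chain_mass: float
    name: str = ""
    localization: str = "cytoplasmic"
    subunits: list[tuple[str, int]] = field(default_factory=list)
    pathway: str = "none"
    sec_partner: str | None = None

    def __post_init__(self) -> None:
        if not (self.chain_mass > 0):
            raise ValueError(f"{self.accession}: chain mass must be positive")
        if self.localization not in LOCALIZATIONS:
            raise ValueError(f"{self.accession}: unknown localization {self.localization!r}")
        if self.pathway not in PATHWAYS:
            raise ValueError(f"{self.accession}: unknown pathway {self.pathway!r}")
        if (self.pathway != "none") != (self.localization != "cytoplasmic"):
            raise ValueError(
                f"{self.accession}: a translocation pathway is required exactly "
                "for non-cytoplasmic proteins"
            )
        if self.pathway == "Sec":
            if self.sec_partner not in SEC_PARTNER_MASS_DA:
                raise ValueError(
                    f"{self.accession}: Sec substrate needs sec_partner in "
                    f"{sorted(SEC_PARTNER_MASS_DA)}, got {self.sec_partner!r}"
                )
        for chain, copies in self.subunits:
            if copies < 1:
                raise ValueError(f"{self.accession}: copy number must be >= 1 ({chain})")


@dataclass(frozen=True)
class Species:
    """One diffusing species: an accession, its form, and the total mass."""

    accession: str
    form: str  # monomer | oligomer | sec_complex | tat_monomer
    M_total: float


@dataclass(frozen=True)
class DcRecord:
    """One database row: species identity plus the full prediction chain."""

    accession: str
    form: str
    M_total: float
    r_p: float
    D0: float
    ln_ratio: float
    Dcyto: float


@dataclass(frozen=True)
class MassDistribution:
    """Log-normal mass distribution: shape ``sigma`` and arithmetic mean (kDa).

    The median follows as ``M_mean * exp(-sigma**2 / 2)``.
    """

    sigma: float
    M_mean: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")
        if not (self.M_mean > 0):
            raise ValueError("mean mass must be positive")

    @property
    def median_kda(self) -> float:
        return self.M_mean * np.exp(-self.sigma**2 / 2.0)

    def pdf(self, M_kda):
        """Density over mass in kDa."""
        return stats.lognorm.pdf(M_kda, s=self.sigma, scale=self.median_kda)

    def sample(self, n: int, rng: np.random.Generator):
        """Draw ``n`` masses in kDa."""
        return self.median_kda * np.exp(self.sigma * rng.standard_normal(n))


def assemble_species(
    records: list[ProteinRecord],
    include_monomer_forms: bool = False,
) -> list[Species]:
    """Determine the diffusing species for each proteome record.

    Cytoplasmic monomers diffuse at their chain mass; subunits of a complex
    as the assembled oligomer (sum of copy number x chain mass over all
    referenced chains); TAT substrates as folded single chains; Sec
    substrates complexed with one chaperone chain (SecB or Tig).

    With ``include_monomer_forms=True`` every oligomeric cytoplasmic record
    additionally yields its monomer species — the convention of a database
    listing each protein in all of its forms, which is why such databases
    hold more records than there are proteins.  The default (one species per
    record) conserves mass: total species mass equals total chain mass
    weighted by copies plus added chaperone mass.
    """
    by_acc = {r.accession: r for r in records}
    out: list[Species] = []
    for rec in records:
        if rec.localization == "cytoplasmic":
            if rec.subunits:
                total = 0.0
                for chain, copies in rec.subunits:
                    try:
                        total += copies * by_acc[chain].chain_mass
                    except KeyError:
                        raise LinkageError(
                            f"{rec.accession}: subunit chain {chain!r} not present "
                            "in the record set"
                        ) from None
                if include_monomer_forms:
                    out.append(Species(rec.accession, "monomer", rec.chain_mass))
                out.append(Species(rec.accession, "oligomer", total))
            else:
                out.append(Species(rec.accession, "monomer", rec.chain_mass))
        elif rec.pathway == "TAT":
            out.append(Species(rec.accession, "tat_monomer", rec.chain_mass))
        else:  # Sec; validated in ProteinRecord
            partner = SEC_PARTNER_MASS_DA[rec.sec_partner]
            out.append(Species(rec.accession, "sec_complex", rec.chain_mass + partner))
    return out


def build_dc_table(
    species: list[Species],
    params: SdvrcParams,
    env: Environment = Environment(),
) -> list[DcRecord]:
    """Predict cytoplasmic DCs for a list of species.

    Per species: hydrodynamic radius from the protein scaling law on the
    total mass, dilute-solution DC from Stokes--Sutherland--Einstein, the
    viscosity ratio from the reference curve, and their product.
    """
    law = get_scaling_law("protein")
    out = []
    for sp in species:
        try:
            r_p = radius_from_mass(sp.M_total, law)
            d0 = stokes_einstein_D0(r_p, env)
            lnr = ln_viscosity_ratio(r_p, params)
        except ValueError as exc:
            raise ValueError(f"{sp.accession} ({sp.form}): {exc}") from exc
        out.append(
            DcRecord(
                accession=sp.accession,
                form=sp.form,
                M_total=sp.M_total,
                r_p=r_p,
                D0=d0,
                ln_ratio=lnr,
                Dcyto=d0 * float(np.exp(-lnr)),
            )
        )
    return out


def dc_table_frame(records: list[DcRecord]) -> pd.DataFrame:
    """DcRecords as a DataFrame with the canonical output columns."""
    return pd.DataFrame(
        {
            "accession": [r.accession for r in records],
            "form": [r.form for r in records],
            "M_total_da": [r.M_total for r in records],
            "radius_nm": [r.r_p for r in records],
            "D0_um2s": [r.D0 for r in records],
            "ln_ratio": [r.ln_ratio for r in records],
            "Dcyto_um2s": [r.Dcyto for r in records],
        }
    )


def fit_lognormal_mass(masses_da) -> MassDistribution:
    """Maximum-likelihood log-normal fit to a set of masses (Da).

    Returns the shape parameter and the arithmetic mean mass in kDa.
    """
    m = np.asarray(masses_da, dtype=float)
    if m.size < 2:
        raise ValueError("need at least 2 masses")
    if not np.all(m > 0):
        raise ValueError("masses must be strictly positive")
    logm = np.log(m)
    sigma = float(np.std(logm))  # MLE of the log-normal shape
    if sigma < 1e-12:  # identical masses up to float rounding
        raise ValueError("all masses equal: degenerate (zero-width) distribution")
    return MassDistribution(sigma=sigma, M_mean=float(np.mean(m)) / 1000.0)


def dcyto_from_mass(M_da, params: SdvrcParams, env: Environment = Environment()):
    """Cytoplasmic DC of a protein of mass ``M_da`` (strictly decreasing map)."""
    r = radius_from_mass(M_da, "protein")
    return stokes_einstein_D0(r, env) * np.exp(-np.asarray(ln_viscosity_ratio(r, params)))


def _dcyto_derivative_wrt_mass(M_da, params: SdvrcParams, env: Environment):
    """Analytic dDcyto/dM for the change-of-variables density (negative)."""
    law = get_scaling_law("protein")
    r = law.C * M_da**law.alpha
    dr_dM = law.C * law.alpha * M_da ** (law.alpha - 1.0)
    rh, xi, a = params.Rh_env, params.xi, params.a
    r_eff = (r**-2.0 + rh**-2.0) ** -0.5
    g = (r_eff / xi) ** a
    dg_dr = a * g / r_eff * (r_eff**3 / r**3)
    D = stokes_einstein_D0(r, env) * np.exp(-g)
    dD_dr = -D * (1.0 / r + dg_dr)
    return dD_dr * dr_dM


def dc_distribution_density(
    dist: MassDistribution,
    params: SdvrcParams,
    env: Environment = Environment(),
    D_grid=None,
):
    """Density of cytoplasmic DCs implied by a log-normal mass distribution.

    Change of variables through the strictly decreasing composite map
    mass -> radius -> Dcyto: ``f_D(D) = f_M(M(D)) * |dM/dD|``.  ``D_grid``
    is in um^2/s and must lie strictly inside the attainable range (every
    positive mass maps to a positive DC below the zero-mass limit).
    Returns the density evaluated on the grid.
    """
    D_grid = np.asarray(D_grid, dtype=float)
    if np.any(D_grid <= 0):
        raise ValueError("DC grid must be positive")

    # invert the monotone map on a wide log-mass grid: masses 1 Da .. 10^12 Da
    logM = np.linspace(0.0, 27.6, 4000)
    M = np.exp(logM)
    D_of_M = dcyto_from_mass(M, params, env)
    if np.any(D_grid >= D_of_M[0]) or np.any(D_grid <= D_of_M[-1]):
        raise ValueError(
            "DC grid outside the range attainable by the mass->DC map "
            f"({D_of_M[-1]:.3g}, {D_of_M[0]:.3g}) um^2/s"
        )
    # D decreases with M, so reverse for interpolation
    logM_of_D = np.interp(np.log(D_grid), np.log(D_of_M[::-1]), logM[::-1])
    M_of_D = np.exp(logM_of_D)

    f_M_da = dist.pdf(M_of_D / 1000.0) / 1000.0  # density per Da
    dD_dM = _dcyto_derivative_wrt_mass(M_of_D, params, env)
    return f_M_da / np.abs(dD_dM)


def synth_proteome(
    n: int,
    dist: MassDistribution | None = None,
    oligomer_fraction: float = 0.45,
    membrane_fraction: float = 0.30,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Generate a synthetic proteome annotation table.

    Emulates a curated bacterial proteome export: log-normal chain masses,
    ``oligomer_fraction`` of the records annotated as homo-oligomers
    (2-6 copies) and ``membrane_fraction`` as membrane proteins routed
    through TAT or Sec (Sec substrates get a SecB or Tig partner).
    Fractions follow the *E. coli* figures by default: ~45% of the proteome
    in complexes, ~30% membrane.  Counts are exact (rounded from the
    fractions), assignment is shuffled, everything is reproducible from the
    seed.
    """
    if n < 1:
        raise ValueError("need at least one protein")
    if not (0 <= oligomer_fraction <= 1 and 0 <= membrane_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if dist is None:
        dist = MassDistribution(sigma=0.8, M_mean=40.0)

    n_mem = round(n * membrane_fraction)
    n_olig = round(n * oligomer_fraction)
    if n_olig > n - n_mem:
        raise ValueError(
            "oligomer_fraction and membrane_fraction jointly exceed the "
            "proteome: oligomers are drawn from cytoplasmic records"
        )

    rng = np.random.default_rng(seed)
    masses_da = dist.sample(n, rng) * 1000.0
    order = rng.permutation(n)
    membrane_idx = set(order[:n_mem])
    oligomer_idx = set(order[n_mem : n_mem + n_olig])

    records: list[ProteinRecord] = []
    for i in range(n):
        acc = f"SYN{i:05d}"
        if i in membrane_idx:
            if rng.random() < 0.5:
                rec = ProteinRecord(
                    accession=acc, chain_mass=masses_da[i],
                    localization="membrane", pathway="TAT",
                )
            else:
                partner = "SecB" if rng.random() < 0.5 else "Tig"
                rec = ProteinRecord(
                    accession=acc, chain_mass=masses_da[i],
                    localization="membrane", pathway="Sec", sec_partner=partner,
                )
        elif i in oligomer_idx:
            copies = int(rng.choice([2, 2, 3, 4, 4, 6]))
            rec = ProteinRecord(
                accession=acc, chain_mass=masses_da[i], subunits=[(acc, copies)],
            )
        else:
            rec = ProteinRecord(accession=acc, chain_mass=masses_da[i])
        records.append(rec)
    return records
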