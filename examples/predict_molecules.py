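"""Predict cytoplasmic diffusion coefficients for individual molecules.

Uses the recovered published E. coli calibration and the class-specific
radius-mass scaling laws.  A molecule is specified either by hydrodynamic
radius (small molecules: van der Waals radius) or by molecular weight.
"""

from sdvrc import (
    Molecule,
    ecoli_reference_calibration,
    ln_viscosity_ratio,
    predict_Dcyto,
    resolve_radius,
    stokes_einstein_D0,
)

params = ecoli_reference_calibration().params

molecules = [
    Molecule(name="ATP", r_p=0.43, molecule_class="small_molecule"),
    Molecule(name="GFP", M=27_000, molecule_class="protein"),
    Molecule(name="LacI tetramer", M=4 * 38_600, molecule_class="protein"),
    Molecule(name="70S ribosome", M=2_500_000, molecule_class="protein"),
    Molecule(name="GFP mRNA", M=6_000_000, molecule_class="rna"),
]

print(f"{'molecule':<16}{'r_p (nm)':>9}{'D0 (um2/s)':>12}{'eta_eff/eta0':>14}{'Dcyto (um2/s)':>15}")
for mol in molecules:
    r = resolve_radius(mol)
    d0 = stokes_einstein_D0(r)
    lnr = ln_viscosity_ratio(r, params)
    dc = predict_Dcyto(r, params)
    print(f"{mol.name:<16}{r:>9.2f}{d0:>12.3g}{2.718281828**lnr:>14.1f}{dc:>15.3g}")

# D0 is the dilute-solution (water) coefficient; the viscosity ratio grows
# steeply with size, so the ribosome is slowed ~400x while ATP barely
# notices the crowding.
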