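# sdvrc — in-vivo diffusion coefficients from scale-dependent viscosity

The bacterial cytoplasm is a crowded fluid whose *apparent* viscosity
depends on who is moving through it: water and metabolites feel roughly the
viscosity of water, while ribosome-sized particles feel a medium tens of
thousands of times thicker. `sdvrc` packages this observation into a
quantitative tool: a **scale-dependent viscosity reference curve** (sdVRC)
calibrated from a small panel of in-vivo probe measurements, from which the
cytoplasmic diffusion coefficient (DC) of *any* molecule — protein, RNA,
DNA or small molecule — follows from its hydrodynamic radius alone, up to
whole-proteome DC databases.

It is aimed at quantitative cell biologists and modellers who need mobility
numbers for reaction–diffusion models, FCS/FRAP experiment design, or
binding inference, without measuring every species individually.

## The model

The effective viscosity felt by a probe of hydrodynamic radius $r_p$ is a
stretched exponential of an effective radius:

$$\ln\frac{\eta_\mathrm{eff}}{\eta_0} = \left(\frac{R_\mathrm{eff}}{\xi}\right)^a,
\qquad R_\mathrm{eff}^{-2} = r_p^{-2} + R_h^{-2},$$

with three parameters characterizing one cell type's cytoplasm: $\xi$, the
average gap between protein surfaces (~0.5 nm in *E. coli*); $R_h$, the
hydrodynamic radius of the largest crowders (nucleoid DNA loops, ~40 nm);
and a dimensionless exponent $a$ of order one. The in-vivo DC then follows
from the Stokes–Sutherland–Einstein relation:

$$D_\mathrm{cyto} = \frac{k_B T}{6\pi\eta_0 r_p}\,
  e^{-(R_\mathrm{eff}/\xi)^a}.$$

Radii are obtained from molecular weights by class-specific power laws
$r_p = C\,M^\alpha$ (globular proteins: $C=0.0514$, $\alpha=0.392$, $M$ in
Da; separate constants for RNA and linear/circular/supercoiled DNA). For
proteome databases, subunits of a complex diffuse as the assembled oligomer
(chain masses summed), and membrane/periplasmic proteins cross the
cytoplasm as folded chains (TAT pathway) or complexed with the SecB or
trigger-factor chaperone (Sec pathway).

## Worked example

```python
from sdvrc import (fit_sdvrc, load_ecoli_probes, macroscopic_viscosity_ratio,
                   ecoli_reference_calibration, predict_Dcyto)

# calibrate from the packaged 31-probe literature panel for E. coli
fit = fit_sdvrc(load_ecoli_probes())
print(f"{macroscopic_viscosity_ratio(fit.params):,.0f}")   # 32,224

# the recovered published calibration, and per-molecule predictions
params = ecoli_reference_calibration().params
print(f"{predict_Dcyto(0.43, params):.0f}")    # 308   (ATP, um^2/s)
print(f"{predict_Dcyto(2.8, params):.1f}")     # 10.2  (GFP)
print(f"{predict_Dcyto(16.6, params):.3f}")    # 0.049 (70S ribosome)
```

The first number is the macroscopic (bulk) cytoplasm-to-water viscosity
ratio implied by the fit — the cytoplasm is ~30,000× thicker than water at
large scales, even though GFP only feels a ~12× slowdown. The predictions
span four orders of magnitude in DC from a 0.43 nm metabolite to the
ribosome, all from one three-parameter curve.

The `examples/` directory has one short script per capability: curve
fitting, single-molecule prediction, proteome databases, probe-panel
design, and binding analysis. A thin CLI wraps the same functions:

```sh
sdvrc fit --builtin-ecoli --out params.json
sdvrc predict --mass-da 27000 --class protein --params params.json
sdvrc synth-proteome --n 1000 --seed 1 --out proteome.tsv
sdvrc build-db --proteome proteome.tsv --params params.json --out db.tsv
```

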