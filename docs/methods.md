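# Methods

## Model

A probe of hydrodynamic radius `r_p` moving through cytoplasm experiences
an effective viscosity interpolating between the solvent (water) viscosity
and the macroscopic cytoplasm viscosity:

    ln(eta_eff / eta_0) = (R_eff / xi)^a,     R_eff^-2 = r_p^-2 + Rh_env^-2.

`R_eff` is the harmonic-in-squares combination of the probe radius and the
crowder radius: whichever is smaller controls the hydrodynamics, so the
slowdown saturates once the probe outgrows the largest crowders.  The three
parameters are properties of one cell type's cytoplasm:

| parameter | meaning | *E. coli* value | unit |
|---|---|---|---|
| `xi` | average gap between protein surfaces; below it a probe feels near-water viscosity | ~0.5 | nm |
| `Rh_env` | hydrodynamic radius of the biggest crowders (nucleoid DNA loops) | ~40 | nm |
| `a` | stretching exponent | ~0.53 | — |

No multiplicative prefactor is used inside the exponential (`b = 1`): only
three parameters are fitted, and the calibration data cannot distinguish a
prefactor from a rescaled `xi`.

Dilute-solution coefficients follow Stokes–Sutherland–Einstein,
`D0 = kB*T/(6*pi*eta0*r_p)`, with defaults `T = 310 K` and
`eta0 = 6.913e-4 Pa*s` (pure water at 310 K, standard viscosity tables);
both are configurable through `Environment`.  Canonical internal units are
nm, Da, µm²/s, Pa·s and K; conversions happen only at the I/O boundary.

Radius–mass scaling laws `r_p = C*M^alpha` use masses in **Daltons**; the
decisive consistency check is that `0.0514 * 27000^0.392 = 2.8 nm`
reproduces GFP's radius, which kDa masses would not.  Small molecules have
no scaling law — their van der Waals radii must be given explicitly.

## Curve fitting

`fit_sdvrc` minimizes unweighted squared residuals in `ln(eta_eff/eta_0)`
space.  Fitting in ln space weights every decade of DC equally (the data
span ten decades); points are unweighted because per-point uncertainties
are rarely published.  Bounds `xi ∈ [0.05, 5]`, `Rh_env ∈ [5, 500]`,
`a ∈ [0.1, 1.5]` nm bracket the physically meaningful region; default start
`(1, 30, 0.5)`; five deterministic jittered starts serve as a
non-convergence fallback (best rss wins, ties to the smallest `xi`).
Standard errors come from the Gauss–Newton covariance at the optimum; the
"maximum error" envelope evaluates the curve at the corners of
`params ± 1 stderr` (plus the centre), which deliberately ignores parameter
correlations and is therefore conservative.  Duplicate probes are retained
as independent points.

### Two calibrations, and why they differ

The package distinguishes:

1. **The probe-panel refit** — `fit_sdvrc(load_ecoli_probes())` on the 31
   packaged literature measurements.  It converges to
   `(xi=0.34, Rh_env=72, a=0.44)` with a macroscopic viscosity ratio of
   ~32,000.
2. **The reference calibration** — `ecoli_reference_calibration()`, which
   recovers the original study's unrounded parameter triple by fitting the
   curve to the published per-molecule prediction table (each printed
   `(r_p, Dcyto)` pair converts exactly to a ln-viscosity measurement).
   It reproduces every published prediction to ≤3% and rounds to the
   published two-digit values `xi=0.51`, `a=0.53`.

The two differ because the fitting objective has a long, shallow valley:
the probe data scatter by ±0.5 ln units (±40–60% in DC) and cluster around
3 nm, so `Rh_env` and `a` trade off almost freely (rms residual 0.55 vs
0.59 ln units across the valley).  Individual parameters are weakly
identified by 31 noisy points — which is precisely the package's
probe-panel design message.  `Rh_env` is also weakly identified by the
prediction table (it stops at 16.6 nm, below the crowder scale), so its
value from calibration (2) carries a large uncertainty; the curve itself is
pinned wherever data exist.  Use calibration (2) to reproduce published
per-molecule numbers; use (1) when the probe measurements themselves are
the ground truth.

## Proteome databases

The diffusing species per annotation record: cytoplasmic monomer → chain
mass; complex subunit → sum of `copies × chain mass` over all referenced
chains (unresolved references fail loudly rather than defaulting to
monomer); TAT substrate → its own chain (exported folded); Sec substrate →
chain plus **one** chaperone chain (SecB 17.3 kDa or trigger factor
48.2 kDa — partner stoichiometry is not annotated, so a single chain is the
minimal assumption, configurable via `SEC_PARTNER_MASS_DA`).
`include_monomer_forms=True` additionally emits the monomer row of every
oligomeric record, mirroring databases that list each protein in all forms
(hence more records than proteins); the default one-species-per-record mode
conserves total mass exactly, which the tests exploit.

Proteome mass histograms are fitted by a log-normal (MLE; reported as shape
`sigma` plus arithmetic mean in kDa).  The DC density follows by exact
change of variables through the strictly decreasing map
mass → radius → DC, with the analytic derivative of the composite map; the
map is inverted on a 4000-point log-mass grid spanning 1 Da–10¹² Da.

The synthetic proteome generator emulates a curated bacterial proteome
export: log-normal chain masses (default `sigma=0.8`, mean 40 kDa — a
realistic breadth and scale for bacterial chain masses; the published
histogram's printed parameters are not available), 45% oligomeric records
(homo-oligomers of 2–6 copies) and 30% membrane records split between TAT
and Sec, the fractions reported for *E. coli*.  Counts are exact by
construction; assignment and masses derive from one seeded generator.  It
does **not** emulate hetero-oligomer linkage graphs, periplasmic/membrane
mass biases, or annotation errors — so closure tests on it validate the
pipeline's bookkeeping and the distribution mathematics, not the biology of
any real proteome.

## Probe-panel design simulation

Synthetic panels place `n` probes exactly log-uniformly over the
experimentally accessible range (0.16–203.9 nm).  Noise model: Gaussian
relative error of 5% on the radius (as derived from a measured `D0`), and
Gaussian noise of sd 0.2 on `ln(eta_eff/eta_0)` — the latter sized to the
±40–60% scatter of the literature calibration data, configurable.  Each
panel is refitted and scored at the target radius (default 2.8 nm, GFP).

Two error measures are reported per panel size:

- `mean_rel_err` — the **headline accuracy**: the relative half-width
  `(D_hi − D_lo)/(2 D_central)` of the maximum-error envelope of the refit
  at the target radius.  This is "the error of the calculated DC" that a
  calibration of that size supports: ~20% at 20 probes, ~40% at 6, ~10% at
  100 (10 replicates).  The same measure applied to the 31-point literature
  panel gives ~60%, consistent with the ±40–60% scatter of those data.
- `mean_truth_dev` — the realized deviation `|D_pred − D_truth|/D_truth`
  from the generating curve, systematically smaller (~5% at 20 probes)
  because noise averages out near well-covered radii.  First-order error
  propagation with the full covariance sits in between (~7%); the envelope
  ignores correlations and is the conservative, reportable figure.

Failed fits are excluded and counted, not imputed.  Default replicate count
is 10; the monotonicity test uses 50 replicates at the grid extremes, which
keeps the whole suite in seconds on one CPU.

## Binding analysis

Two-state model only: `D_eff = f_free*D_free + (1−f_free)*D_bound`, exactly
invertible for the bound fraction; no on/off kinetics.  The
cytoplasm-exploration time uses `t = V^(2/3)/(6D)` — the time for the 3-D
mean-squared displacement `6Dt` to reach the squared characteristic length
`L = V^(1/3)`.  The prefactor convention is isolated in one function
(`exploration_time`) so an alternative (e.g. narrow-escape style estimates)
is a one-line change.  Default cell volume 1 µm³, configurable.

## Numerical notes and limitations

- Domain validation is strict: non-positive radii/masses/DCs raise
  `ValueError` rather than propagating NaNs; `SdvrcParams` enforces
  `Rh_env > xi > 0` and `0 < a < 2`.
- `macroscopic_viscosity_ratio` returns `inf` when the exponent exceeds
  float range (possible for extreme parameter triples, not for fitted
  ones).
- The model covers 3-D cytoplasmic diffusion only: no membrane (2-D)
  diffusion, no anomalous/confined exponents, no motor transport.
- The curve is calibrated per cell type (and plausibly per organelle);
  *E. coli* numbers do not transfer elsewhere, though the functional form
  does.
- Published headline database counts for the full *E. coli* proteome
  depend on a specific annotation snapshot and are not regenerated here;
  the database builder is validated on synthetic proteomes instead.
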