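# Methods

`asdkit` models the solubility (solid–liquid equilibrium, SLE) and
miscibility (liquid–liquid / amorphous–amorphous equilibrium, LLE) of a
small-molecule drug in a polymer matrix, the core thermodynamic question
behind amorphous solid dispersion (ASD) formulation. The reference
system shipped with the package is crystalline ibuprofen (IBU) paired
with four pharmaceutical polymers — Kollidon VA64, Kollidon 17PF, HPMCAS
(AS-LMP grade) and Eudragit EPO — whose thermophysical records
(`data/compounds.json`) and PC-SAFT parameters (`data/pcsaft.json`) are
tabulated from published characterization of exactly these grades.

## Conventions

All temperatures are Kelvin internally, energies J/mol, heat capacities
J/(mol·K), densities g/cm³. Input files may carry °C (converted at
ingest). Compositions exist on three bases — mass fraction `w`, mole
fraction `x` (whole-molecule; each polymer is one pseudo-component at
its nominal Mw) and volume fraction `φ` (from the pycnometric
densities, taken temperature-independent) — converted exactly at module
boundaries and round-tripping to 1e−12. Fit quality is reported as
AARD = (100/N)·Σ|T_meas−T_pred|/T_meas and its signed counterpart ARD
(positive ARD: the model under-predicts on average).

## Group-contribution screening

Fedors (δt² = ΣE/ΣV) and Hoftyzer–van Krevelen / Just–Breitkreutz
(δd = ΣFd/ΣV, δp = √(ΣFp²)/ΣV, δh = √(ΣEh/ΣV)) solubility parameters
are computed over per-molecule group inventories. Screening quantities:
Δδt (signed, drug − polymer; |Δδt| < 7 MPa½ read as "soluble", > 10 as
"immiscible"), the Bagley distance R_av = √(4Δδv² + Δδh²) in the
(δv, δh) plane, and a δ-derived interaction parameter
χ = V₀(δ_API−δ_poly)²/(RT), dimensionless, with the lattice-site volume
V₀ defaulting to the drug's molar volume (the conventional choice of
sizing the site by the smaller molecule; exposed as a parameter).

The bundled coefficient tables and inventories are **illustrative**
transcriptions assembled so the pipeline runs end to end; fragments with
negative tabulated volume increments are merged into composite groups so
every table row keeps V > 0. Numbers computed from them demonstrate the
machinery, not a validated chemistry — the math and schema are the
contribution, the tables are editable data.

## Flory–Huggins analysis

The lattice model uses the drug as reference site and chain length
m = (Mw_p/ρ_p)/(Mw_a/ρ_a) (≈287 for IBU–Kollidon VA64, ≈48 for
IBU–Kollidon 17PF). Melting-point depression obeys

    1/T − 1/Tm = −(R/Δ_fus H)[ln φ + (1−1/m)(1−φ) + χ(1−φ)²]

with χ(T) = A + B/T (A < 0, B > 0 is UCST behavior: demixing on
cooling). Three χ extraction routes are provided: algebraic inversion
per observation, a through-origin slope fit of the linearized relation
against φ_p², and ordinary least squares of per-point χ on 1/T to get
(A, B). Outlier exclusion (viscosity plateaus, high-loading
nonlinearity) is explicit and user-driven through the dataset's
`excluded` indices — no automatic detection.

Because χ is linear in 1/T, the saturation temperature has a *closed
form* (the relation is linear in 1/T); a bracketed Brent solve of the
same equation is retained as a validation route. A formal solution
slightly above Tm flags compositions whose melt activity exceeds the
crystal's — an incipient-demixing signature where the observable end-set
plateaus at Tm.

The mixing free energy per lattice site is
g(φ) = φ ln φ + ((1−φ)/m) ln(1−φ) + χφ(1−φ). (One published rendering
of the combinatorial term carries a typographical duplication of the
leading φ; the standard form above is used, which reproduces the
pure-component limits and the common-tangent construction.) The
spinodal is the quadratic 2χmφ² − (2χm+m−1)φ + m = 0; the critical
point — located numerically from the discriminant and checked in tests
against the closed forms φ_polymer,c = 1/(1+√m), χ_c = (1+1/√m)²/2 —
collapses both boundaries. The binodal solves the common-tangent
conditions g′(a) = g′(b), g(b)−g(a) = g′(a)(b−a) in log-composition
variables, seeded by a coarse lower-convex-hull pass and verified in
tests against a fine-grid (1e−5) hull oracle; a literal
first-derivative-zero mode (which locates extrema of g, not
coexistence) is kept behind `method="derivative"` for comparison.

## Kyeremateng empirical fit

T_s = −A·e^{bx} + Tm + C with x the drug load in **% w/w** (0–100), a
unit the equation itself leaves implicit; b ≈ −0.05 per % w/w is the
literature consensus scale. One-step fitting fixes C = 0 and b = −0.05
(A is then linear least squares); a `free_b` variant frees b. Two-step
fitting stages (A, b | C=0) then (C | A, b), and by default finishes
with a joint three-parameter polish started from the staged estimates —
the staged estimates alone cannot recover a C ≠ 0 truth exactly, while
the polished fit is exact on noise-free data; `polish=False` yields the
literal staged numbers, which remain recorded on the fit either way.
All stages run on the physical branch (A ≥ 0, b ≤ 0) with deterministic
initialization (A₀ from the fixed-b linear solution at each start,
b₀ ∈ {−0.03, −0.05, −0.08}), which also guarantees the nested-model
property that the free-b stage never fits worse than the constrained
one-step. C is reported as a fitting parameter with a sign, nothing
more. Note the fitted exponential reaches the pure-drug melting point
only to within its tail A·e^{100b} (≈0.1–0.3 K for typical fits) — the
thermodynamic models pass through (100 %, Tm) exactly.

## PC-SAFT equation of state

The residual Helmholtz energy a_res = a_hc + a_disp + a_assoc combines
the Boublík–Mansoori hard-sphere mixture plus chain connectivity, the
second-order dispersion perturbation with the standard universal model
constants, and Wertheim first-order association. Combining rules:
σ_ij = (σ_i+σ_j)/2, ε_ij = √(ε_iε_j)(1−k_ij) with k_ij(T) = k_int +
k_slope·T correcting cross-dispersion only; cross-association by
Wolbach–Sandler (arithmetic-mean ε_assoc, geometric-mean κ with the σ
correction), which activates induced association between the
self-associating acid and the non-self-associating polymers. Tabulated
site counts N_assoc are split equally into donors and acceptors
(fractional halves allowed — conventions differ across the literature
the parameter sets come from, so the split is isolated in one place);
by that symmetry one unbonded-site fraction per component suffices,
solved by damped Newton with positivity backtracking and a globally
convergent successive-substitution fallback, to 1e−12.

Density (1 bar reference everywhere; the liquid regime is insensitive
to it) is the largest packing-fraction root η ∈ (0, 0.74) of
P(η) = P, by a deterministic descending scan plus Brent refinement,
warm-started from neighboring states inside iterative solvers.
Derivatives for Z = 1 + ρ∂a/∂ρ and for the chemical potentials
μᵢ_res/kT = a + (Z−1) + ∂a/∂xᵢ − Σxⱼ∂a/∂xⱼ are complex-step
derivatives — exact to machine precision through the holomorphic term
algebra including the association Newton solve — and are cross-checked
against central finite differences in the tests. Activity coefficients
are γᵢ = φᵢ(mixture)/φᵢ(pure i) at the same (T, P), with the pure
subcooled liquid as reference at every temperature (no glass
correction below Tg; the EOS is continued analytically). Hard limits
validated in tests: Carnahan–Starling Z at m = 1, ideal gas as ρ→0,
a_assoc ≡ 0 when κ = 0, γ = 1 at pure limits (enforced exactly by the
normalization identity), Gibbs–Duhem along composition paths with the
residual normalized by the term magnitudes (the polymer's ln γ is
O(10³), so an absolute residual is meaningless).

SLE follows x·γ(x) = exp[−Δ_fus H/(RT)(1−T/Tm) − ΔCp/R(1−Tm/T +
ln(Tm/T))], solved for x by damped fixed point in log-composition (the
smallest root — the stable-solution branch — with a log-grid bisection
fallback that doubles as the independent oracle route), or for T at
fixed composition by bracketed root finding on the isotherm residual —
the quantity melting-point-depression data actually report. When the
drug activity at the gross composition exceeds the crystal's even at
Tm, the composition sits inside a demixing region whose drug-rich phase
is essentially pure, and the observable end-set plateaus at Tm; the
temperature solver returns Tm there. LLE solves the two isoactivity
equations in (ln x₁^L1, ln x₂^L2) with spinodal-window-straddling
starts and continuation in temperature; the spinodal window itself
comes from the sign of a finite-difference second derivative of the
mixing Gibbs energy.

k_ij fitting minimizes the AARD between observed end-set temperatures
and model saturation temperatures over a deterministic coarse grid
(step 0.005 on [−0.05, 0.15]) followed by a local fine grid
(step 0.001), which bounds the discretization error at half a fine
step; a temperature-linear mode refines (k_int, k_slope) by
Nelder–Mead from the constant optimum. Saturation temperatures below a
150 K floor are clamped there, which penalizes that k_ij without
aborting the search. Model curves are cached per k_ij value so noise
replicates of one composition design share the expensive evaluations.

## Glass-transition models

Gordon–Taylor Tg = (w_a Tg_a + K w_p Tg_p)/(w_a + K w_p) with K either
from the Simha–Boyer rule K = (ρ_a Tg_a)/(ρ_p Tg_p) — implemented
exactly in this drug-over-polymer form, Kelvin mandatory — or fitted;
Kwei adds q·w_a·w_p (q in K; negative q, the hydrogen-bonding
signature, pulls the curve below Gordon–Taylor at mid compositions).
Fits run least squares first, then a deterministic Nelder–Mead pass
minimizing the AARD itself, seeded from the nested model's optimum and
never accepted if worse than the seed. Fitting to the reported metric
makes the reported diagnostics the optimum of that metric and gives
the nested chain AARD(Kwei) ≤ AARD(fitted GT) ≤ AARD(Simha–Boyer) by
construction.

## Synthetic data

Real melting-point-depression tables for these blends are not publicly
archived, so every fitting stage is validated by parameter recovery on
synthetic datasets: drug loads 0.30–0.95 w/w in 0.05 steps (the
standard DSC blend design), end-set noise N(0, 0.5² K²) — typical
end-set repeatability — and Kwei-generated Tg data with 1 K noise at
the same compositions plus noise-free pure endpoints (pure references
are measured separately and far more precisely). Generators: the FH
relation at a chosen (A, B), the Kyeremateng curve at (A, b, C), or
the full EOS SLE at a chosen k_ij. Seeded runs are bit-reproducible.
What the generators do *not* emulate — viscosity-driven end-set
plateaus, heating-rate artifacts, composition-dependent χ — is exactly
what the dataset `excluded` mechanism exists for in real data, so
passing recovery tests demonstrates estimator correctness, not
robustness to those artifacts.

## Phase-diagram assembly

Curves from all fitted models are resampled onto a drug-load (% w/w)
canvas: SLE per model, FH and EOS binodal/spinodal domes, and a blend-
Tg overlay. The EOS SLE is computed on a 41-point model grid and
interpolated (the curve is smooth; refinement tests show < 0.05 K
canvas sensitivity). Region labels at (w, T): `stable solution` below
the solubility limit, `supersaturated` above it (metastable against
crystallization), `LLE metastable` between binodal and spinodal,
`LLE unstable` inside the spinodal, with a `(glassy)` qualifier below
the blend Tg. The "Tg − 50 K" storage heuristic is deliberately left
as an optional plot annotation, not a region. `max_stable_loading`
scans a 2001-point composition grid at fixed T.

## Problem sizes and determinism

Default sizes: 14-point MPD designs; 200 noise replicates for χ-slope
recovery, 50 for k_ij, 8 for Kyeremateng nesting; 10 random states for
derivative consistency; 101×101 canvases for classifier checks. All
stochastic checks derive their generators from a single seed; all
solvers use deterministic bracketing and initialization, so repeated
runs are bit-identical.

## Known limitations

- χ carries no composition dependence; deviations from χ–1/T linearity
  at high drug loading must be handled by excluding points.
- Polymers are single homosegment pseudo-components at nominal Mw —
  no polydispersity, no copolymer-specific PC-SAFT, no moisture or
  ternary systems, no vapor–liquid equilibrium.
- Below-Tg states are analytic continuations of the melt EOS; kinetics
  (nucleation, relaxation) are outside scope, so "metastable" is a
  thermodynamic label, not a shelf-life prediction.
- The group-contribution tables are illustrative; quantitative δ values
  require a curated table and validated per-molecule fragmentation.
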