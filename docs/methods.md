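# Methods

## Scattering model

A vesicle is modelled as a spherical core filled with the water/ethanol
solvent, wrapped by `N` identical symmetric bilayers.  Each bilayer is a
mirrored six-slab electron-density profile — head | chain | methyl | methyl
| chain | head — with shell thicknesses `R1, R2, R3` (nm, per leaflet) and
densities `ρ1, ρ2, ρ3` (e/nm³); total bilayer thickness `2(R1+R2+R3)`.
Averaging that quantity over the three formulation presets gives 3.63 nm, a
typical fluid phosphatidylcholine bilayer.  The solvent density is a linear
volume mix of water (330 e/nm³) and ethanol (285 e/nm³); core and external
solvent share it, which is what makes the high-water liposome formulation
nearly contrast-matched and weakly scattering.

Core radii follow a Schultz (gamma) law with mean `R0` and relative
dispersion `ξ = 1/√(z+1)`.  Below `ξ = 10⁻³` the distribution is treated as
a delta; otherwise moments and averages use either the closed-form gamma
moments or quadrature (below).

### Structure factor

Bilayer repeat positions follow a one-dimensional paracrystal with
cumulative (second-kind) disorder: nearest-neighbour spacings are i.i.d.
with mean `c` and standard deviation `g_c·c`.  For Gaussian spacings the
per-bilayer-normalised structure factor is

    S(Q) = 1 + (2/N) Σ_{k=1}^{N-1} (N−k) cos(kQc) |φ(Q)|^k,
    φ(Q) = exp(−Q²c²g_c²/2).

This is the exact expectation of `|Σ_n e^{iQx_n}|²/N`, hence non-negative,
equal to `N` at `Q = 2π/c` in the `g_c → 0` limit, identically 1 for
`N = 1`, and → 1 at large `Q`.  The fitted overall scale absorbs any
N-dependent prefactor convention.

The Monte-Carlo oracle (`synthetic.mc_stack_sf`) samples the stack
directly and averages the coherent sum.  Its default sampler rejects
non-positive spacings to keep every realization physical.  That truncation
has mass `Φ(−1/g_c)`: negligible below `g_c ≈ 0.3`, but ~2% at `g_c = 0.5`
and ~13% at `g_c = 0.9`, where it shifts the mean spacing upward and the
estimate visibly departs from the Gaussian closed form (3–25% depending on
`N`).  `truncate_positive=False` samples the untruncated Gaussian law the
closed form integrates over and reproduces it to ≲1% at 10⁵ realizations
for all tested `(N, g_c)`.  The tests therefore check the closed form
against the truncated sampler at weak disorder and against the Gaussian
sampler at strong disorder, and additionally assert that the truncation
bias is real — it is a property of the disorder model, not a numerical
artifact.

### Intensity, two evaluation modes

`separated` (default, used for fitting):

    I(Q) = s · N · 8π²/Q² · (⟨R_b²⟩ A_c(Q)² + C(Q)²) · S(Q) + b

with `A_c(Q) = 2∫₀^{t/2} Δρ(z) cos(Qz) dz` the flat-bilayer amplitude,
`C(Q) = 2∫₀^{t/2} z Δρ(z) sin(Qz) dz` its first-moment transform, and
`⟨R_b²⟩` the mean-square mid-stack bilayer radius under the Schultz law.
The decomposition `F_sphere = (4π/Q)[R A_c sin(QR) + C cos(QR)]` is exact
for a slab profile on a sphere, so once size polydispersity damps the
`sin²(QR)` fringes (e.g. `ξ ≥ 0.1` at `R0` of a few hundred nm over
`Q ≥ 0.1` nm⁻¹) this factorisation *is* the size-averaged unilamellar
intensity — the two modes then agree to machine precision at `N = 1`, and
to ~0.03% at `R0 = 200` nm.  The `C²` term matters near the zeros of
`A_c`, where dropping it produces several-percent errors.  For `N > 1` the
factorisation additionally assumes all bilayers sit at a common effective
radius, which is accurate for `c·N ≪ R0`.

`exact_sphere` evaluates the coherent multishell amplitude (boundary sum of
`3VΔρ (sin x − x cos x)/x³` terms) per Schultz node and averages `|F|²`.
The node count is chosen automatically — about 8 nodes per `sin(QR)` period
across the distribution's essential support (quantiles 10⁻¹² to 1−10⁻¹²),
capped at 20001 — so the fringe damping is resolved rather than aliased.
In this mode the intensity is *not* paracrystal-damped (the stack is a
perfect lattice per realization); it serves as the geometric ground truth
for the unilamellar limit and for contrast bookkeeping.

### Schultz quadrature

`schultz_nodes` maps Gauss–Legendre nodes onto the quantile span above and
weights them by the density, renormalising to unit mass.  51 nodes
reproduce `⟨R⟩` and the intensity-relevant `⟨R⁶⟩` to ≤ 4·10⁻⁹ relative for
`ξ ≤ 0.3`.  Generalized Gauss–Laguerre rules were rejected because the
shape parameters implied by small dispersion (z ~ 10⁴ at ξ = 0.01) make the
recurrence numerically fragile.

## Bragg-peak location

`find_bragg_peak` estimates a smooth background by fitting a quadratic to
log₁₀I vs log₁₀Q inside the search window, iteratively masking the
candidate peak region so the reflection does not bias the fit.  A candidate
is accepted only if it (i) rises ≥ 0.05 decades above the background,
(ii) is localised — its above-half-maximum span stays inside the window and
covers ≤ 35% of it — and (iii) coincides with a genuine local maximum of
the measured intensity within the excess-positive region.  Criterion (iii)
is what rejects the shoulders of deep form-factor minima (the bilayer
`A_c(Q)` zero near 1.05 nm⁻¹ sits inside the natural search window and
otherwise masquerades as a broad excess bump) while steep backgrounds are
handled by (i)–(ii).  The apex is refined by a parabola over the
above-half-maximum points on the linear Q axis, where lamellar reflections
are locally symmetric.  On the default 200-point log grid the recovered
position is within one grid step (≲2%) of `2π/c`; the residual bias comes
from the decaying form-factor envelope under the peak and is inherent to
reading a peak off `I(Q)`.

## Fitting and uncertainties

The objective is σ-weighted least squares, `χ² = Σ((I_i − I_model,i)/σ_i)²`,
minimised by bounded trust-region least squares (lmfit/`least_squares`);
residuals are clipped to ±10¹⁰⁰ so degenerate σ → 0 inputs stay finite.
The default free set is `{scale, background, R1, R2, R3, c, g_c}`: in
separated mode `R0` and `ξ` enter only through a scale-degenerate prefactor
and are therefore not identifiable from a single curve — they are fixed at
their preset values unless the user frees them deliberately.  Electron
densities and the solvent composition are fixed by default.  `N` is
discrete; when freed it is optimised over the integers inside its bounds
with a continuous fit per candidate.  Optional seeded multi-start
(`n_starts`) mitigates local minima; the returned χ² never exceeds that of
the initial model.

Parameter uncertainties follow a parametric perturbation procedure: each
replicate redraws every observed intensity from `N(I_obs,i, σ_i)`
(perturbing around the *observed* values), refits from the same start, and
the per-parameter mean and standard deviation over 20 replicates (default)
are reported.  Per-replicate generators are spawned from one master seed,
so enlarging the replicate set extends rather than reshuffles it.
Non-converged replicates are excluded, counted and warned about.

On synthetic curves with 1% relative noise (the regime the fitting tests
use), `R1, R2, R3, c` are recovered with mean relative bias well under 1%
across 10 independent datasets, and the truth falls within mean ± 3 s.d.
of the replicate statistics for ≈99% of parameter/seed combinations.

## Synthetic data

`generate_curve` evaluates the forward model on a 200-point log-spaced grid
over 0.1–5 nm⁻¹ (the instrument's nominal range; the density is a free
choice) and adds Gaussian noise with `σ_i = max(rel·I_i, floor)`,
`rel = 0.02` by default with a 10⁻⁶ floor.  The relative-σ form matches the
perturbation model used for uncertainties; true experimental error
magnitudes are not published for these measurements, so 2% is a stand-in
judged typical for well-exposed synchrotron 1-D profiles, not a reported
value.  Presets transcribe the reported central structural parameters per
formulation; `scale = 10⁻⁸` and `background = 0.05` are plumbing chosen to
put intensities at O(10–10³) with a visible high-Q floor.  What the
generator does *not* emulate: instrument resolution smearing, absolute
calibration, inter-particle interference, detector artifacts, and any
intensity mixture of coexisting uni- and multilamellar populations — so
passing tests demonstrate the estimator chain is self-consistent, not that
real beamline curves are free of those effects.

## Size metrics

DLS-style metrics act directly on known radius ensembles: scattering
weight `w ∝ R⁶` (Rayleigh regime; the thin-shell Mie correction is
ignored), decay rate `Γ ∝ 1/R` (Stokes–Einstein).  Then
Z-average diameter `= 2ΣR⁶/ΣR⁵` (intensity-weighted harmonic mean) and
dispersity index `= ⟨Γ²⟩_w/⟨Γ⟩_w² − 1 = ΣR⁴ΣR⁶/(ΣR⁵)² − 1`, which is
scale-invariant and zero for monodisperse input.  Powers are computed on
max-normalised radii to avoid overflow.  The regularised inversion a real
correlator performs is out of scope, and commercial instruments use
proprietary estimators, so comparisons with measured dispersity indices
are qualitative.

## Conventions and open choices

* `c` is the centre-to-centre repeat of adjacent bilayers; the first-order
  reflection sits at `2π/c`.  Reported spacings for these systems mix
  conventions (a fitted `c` of 14 nm alongside a Bragg-derived repeat of
  7.22 nm, consistent with a two-bilayer repeat or a second-order
  reflection); this package does not resolve that ambiguity — tests that
  need the observed 7.22 nm repeat set `c = 7.22` explicitly.
* Q is nm⁻¹ internally; Å⁻¹ files are converted (×10) at read time behind
  an explicit flag.
* Structure factor normalised per bilayer (`S → 1` at large Q).
* Uncertainty statistics average integer-N fits, so a replicate mean of N
  need not be an integer.

## Known limitations

* No resolution smearing or absolute-intensity calibration.
* Separated mode assumes thin shells relative to the vesicle radius; below
  `R0 ≈ 100` nm or for very thick stacks the exact-sphere mode should be
  preferred and fitting cost rises accordingly.
* The exact-sphere mode models a perfect lattice within each vesicle;
  paracrystalline disorder is available only through the separated mode.
* Monodisperse (`ξ → 0`) large vesicles retain `sin(QR0)` fringes in
  exact-sphere mode that the separated mode deliberately averages away;
  mode-agreement checks therefore require `ξ` large enough to damp them.
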