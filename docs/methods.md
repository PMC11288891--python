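# Methods

## Burial-pattern scanning

A β-strand bound in a deep scaffold cleft alternates between core-facing
(solvent-inaccessible) and solvent-facing side chains. A window of a target
protein is compatible with a given binding slot when every buried position
holds one of {F, A, M, I, L, V, S, T, Y, G} and no internal position is
proline (proline is tolerated at the first or last position of the window,
where the strand can fray). The scanner evaluates every frame of length
*n* (stride 1, `L − n + 1` frames), reports all matches including
overlapping ones, and is checked against two independently written oracles
(a direct per-window rule transcription and a character-class regex).

Design choices:

* **Masks are data, not code.** The buried mask of a real design is read
  off its structure; it is supplied as a `Template`. The bundled defaults
  are the idealized alternating masks ({0,2,4,6} for n=8; {0,2,4,6,8} and
  {1,3,5,7} for n=9), i.e. both registers of a fully alternating strand.
* The proline rule applies to exposed positions; a buried proline is
  already excluded by the allowed set.
* Scanning is forward-frame only by default; a `reverse=True` flag scans
  the reversed sequence (a strand can in principle bind in either
  direction) and labels those matches. Hairpin slots are scanned as two
  independent single-strand windows joined by a configurable loop gap
  (2–6 residues by default); this is an interpretation, flagged as such.
* Coordinates are 0-based half-open in the API and 1-based inclusive in
  TSV reports.

On the bundled Aβ42 fixture the default templates match only in the
C-terminal `GAIIGLMVGGVVIA` region — the amyloid core — with window
lengths of 8 and 9.

## 1:1 binding models

All concentrations are molar and times seconds internally; CSV columns
declare units in their names (`_s`, `_M`) and are validated on read.

* **Depletion quadratic.** For totals L, B and dissociation constant Kd,
  the complex concentration is the physical root
  `C = [(L+B+Kd) − sqrt((L+B+Kd)² − 4LB)]/2`, evaluated as
  `2LB/(s + sqrt(s² − 4LB))` to avoid cancellation when Kd dominates.
  Verified against bisection on the mass balance over random systems.
* **BLI kinetics.** Association `R(t) = Req(1 − e^{−(kon·C+koff)t})` with
  `Req = Rmax·C/(C+Kd)`; dissociation `R0·e^{−koff t}` with R0 taken from
  the model's association endpoint (so the fit is internally consistent
  across phases). The closed forms are verified against numerical
  integration of the binding ODE. Fits are **global** — one (kon, koff,
  Rmax) across all analyte concentrations — which is what makes koff and
  kon separately identifiable from partial association curves.
* **Steady state.** Langmuir isotherm, appropriate for BLI where the
  analyte is in excess and does not deplete.
* **MDS.** Fraction bound = C/L with C from the exact quadratic; with a
  radius readout the observed radius is the fraction-weighted mean of the
  free and complex radii, fitted jointly with Kd by default.

All fits use trust-region least squares (`scipy.optimize.least_squares`)
in log-Kd (and log-rate) space with five log-spaced multi-starts to avoid
local minima; standard errors come from the Jacobian at the optimum.
Non-convergence raises an explicit error. Designs where every
concentration is ≫ or ≪ the fitted Kd are flagged non-identifiable in the
diagnostics rather than silently reported.

## Aggregation model

The two-moment system (fibril number P, fibril mass M, free monomer
m = m_total − M):

```
dP/dt = kn·m^nc + k2·m^n2·M
dM/dt = 2·k₊·m·P
```

with default reaction orders nc = n2 = 2, the standard choice for Aβ42,
and the factor 2 for growth at both fibril ends (both configurable). The
system is integrated numerically (LSODA, rtol 1e−10) rather than through
the closed-form integrated rate laws: numerics handle seeded and inhibited
cases uniformly, and the early-time limit `M(t) ≈ kn·k₊·m_total^(nc+1)·t²`
(k2 = 0, unseeded) is retained as an analytic test oracle only. Mass
conservation (m + M = m_total to 1e−6 relative) and monotonicity of M and
P are asserted as invariants over random parameter draws.

**Half-time.** t½ is the first crossing of half the fibril-mass plateau,
located by linear interpolation between samples. The plateau is the mean
of the final 10% of points; a curve is accepted as complete only if the
two halves of that tail differ by < 2% of the plateau (segment means, so
the criterion is robust to measurement noise). Incomplete curves raise an
explicit error. `simulate_auto` picks its horizon from the characteristic
proliferation rates κ = sqrt(2k₊k2·m^(n2+1)) and λ = sqrt(2k₊kn·m^nc),
doubling until the plateau criterion is met.

**Inhibitor coupling.** Following the sequestration assumption, the
monomer–binder equilibrium is solved once at t = 0 with the depletion
quadratic and bound monomer is removed for the whole reaction (no
re-equilibration during aggregation); simulating with an inhibitor is
therefore *exactly* (bit-identically) simulating the uninhibited system at
the reduced monomer concentration, which is asserted in the tests.
Secondary-nucleation suppression multiplies k2 by a factor in (0, 1],
either tabulated per binder concentration (log-linear interpolation
between knots, anchored to factor 1 at zero binder) or parametric,
`1/(1 + [I]/K_I)`. Saturating (Michaelis-type) secondary nucleation and
dynamic re-equilibration are deliberately not enabled by default.

**Rate-constant defaults.** The generator defaults kn = 3×10⁻⁴ M⁻¹s⁻¹,
k₊ = 3×10⁶ M⁻¹s⁻¹, k2 = 1×10⁴ M⁻²s⁻¹ are order-of-magnitude,
literature-style values for Aβ42: at 2 µM monomer they give
secondary-nucleation-dominated sigmoids with t½ ≈ 2 h and a half-time
scaling exponent γ = d log t½ / d log m ≈ −1.5, the signature of the
n2 = 2 secondary pathway. They are conventions of the synthetic study,
not fitted constants, and every recovery test carries its own ground
truth.

## ThT inference pipeline

ThT fluorescence is modeled as affine in fibril mass, `F = a·M + b`, with
per-trace constants. Normalization subtracts the mean of the first 5
points and divides by the plateau amplitude — the trace's own (mean of the
last 5 points) when the trace has flattened, otherwise the mean
uninhibited amplitude is borrowed and the trace flagged. Flat traces are
flagged `no_aggregation`. Normalization is idempotent and invariant to
(a, b).

Because normalized curves are invariant to the rescaling P → k₊P, only the
products `kn·k₊` and `k2·k₊` are identifiable from ThT data; the
uninhibited fit estimates exactly these two (orders held at 2), seeded
from the observed half-time via κ. Model curves for self-normalized traces
are M(t)/M(end); for borrowed-plateau traces they are M(t)/m_total of the
full monomer pool, matching the borrowed scale.

The inhibition fit is sequential, mirroring the experimental logic:
uninhibited rates first, then — holding those and the independently
measured binder Kd fixed — one k2 factor per binder concentration (or a
single K_I in parametric mode). Conditions where the predicted bound
monomer fraction exceeds 0.9 are excluded from fitting and flagged: in
that regime the trajectory is dominated by the sequestration approximation
and the factor is not meaningfully constrained. The
sequestration-only prediction is computed with factor ≡ 1 and reported
with per-concentration residuals, so the insufficiency of monomer trapping
alone is a number, not a narrative.

**Potency.** The summary potency metric is the binder concentration at
which t½ is increased by 50% (configurable), found by Brent root-finding
on log₁₀[I] over 1 pM–1 mM; if the slowdown is never reached in that
range the result is "not reached" rather than an extrapolation.

## Synthetic data

The generators emulate the assay designs the pipeline targets: ThT read
every 165 s at 2 µM monomer, 3 replicates, binder titrations spanning
0–2 µM, run for 12× the uninhibited half-time (plate runs monitor far
beyond the control half-time, and this horizon leaves strongly inhibited
conditions unfinished, exercising the borrowed-plateau path); BLI
association/dissociation of 600 s each at 0.25–4× Kd; MDS with 10 nM
labeled monomer and 12 binder concentrations log-spaced 1 nM–10 µM in
triplicate. Noise is additive Gaussian: 2% of plateau amplitude (ThT), 1%
of Rmax (BLI) and 0.03 on the fraction-bound scale (MDS) — conventions,
since instrument noise magnitudes are not part of the model. A top-level
seed spawns independent substreams per trace, so output is byte-identical
under a fixed seed and stable under adding conditions.

What the generators do **not** emulate: instrument artifacts beyond
optional linear BLI drift, well-to-well amplitude variation beyond the
per-trace affine map, fibril sedimentation or surface effects, and any
deviation of real aggregation from the two-moment model (fragmentation,
saturated secondary nucleation, oligomer intermediates). Passing recovery
tests therefore demonstrates the estimators are correct and well
calibrated *under the stated model*, not that the model exhausts real
ThT data.

## Problem sizes

The test suite and acceptance script are sized for a single CPU: Monte
Carlo recoveries use 25–50 seeds, property sweeps use 10³–10⁴ random
draws, and ThT datasets use three binder concentrations at three
replicates. These sizes make the medians stable to well within the
tolerances asserted.

## Known limitations

* Uninhibited fitting holds nc = n2 = 2 fixed; joint order estimation is
  out of scope.
* The borrowed-plateau rule assumes comparable ThT response per unit
  fibril mass across wells of one plate.
* BLI fitting has no mass-transport limitation term and no ≥2-site model.
* The exclusion threshold for sequestration-dominated conditions (bound
  fraction > 0.9) is a convention; results near the threshold should be
  inspected.
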