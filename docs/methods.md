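# Methods

## Hypothesis space and geometry

Target direction is discretized into *N* equal-area cells on the frontal
hemisphere (zonal construction: a polar cap around the forward axis plus
collars of equal-area cells, azimuthally staggered between rings).  Equal
areas make the uniform posterior exactly log₂ *N* bits and let solid-angle
integrals reduce to sums with a single weight 2π/*N*.  The default
*N* = 256 puts the chance level at 8 bits.  Azimuth is positive to the
right, elevation positive up, (0, 0) straight ahead; rotations are
intrinsic azimuth-then-elevation, so the forward direction maps onto the
rotation angles.  Ear movement is a rigid rotation of the hearing field,
resampled on the partition by nearest-cell lookup (deterministic; an
inverse-distance option over the 3 nearest centers exists).  Directions
that rotate out of the stored hemisphere take the field's floor value.
Nearest-cell resampling is exact for most cells and bounded by one cell
spacing times the local gradient otherwise; at *N* = 256 the spacing is
about 9°, which is why the rotation tests bound errors by that product
rather than a fixed constant.

## Measurement model and inference

For cell θ the stored template **t**θ is the zero-mean 14-vector of dB
gains over 7 sweep positions × 2 ears (left positions then right; the
anti-phase right ear uses negated offsets, which only permutes columns and
provably leaves all posteriors unchanged).  The removed row mean is kept
as the cell's gain.  A simulated echo from θ at nominal strength *A* is

    b = max(t_θ + A + g_θ + ε, 0),   ε ~ N(0, Σ_n)

where *g*θ ≤ 0 is the cell's gain relative to the per-frequency 0 dB
anchor (the highest raw template element across all cells).  *A* is thus
the SNR an echo would have at the best-served direction; cells the sonar
loop attenuates receive effectively weaker echoes and are floored earlier.
This coupling is what makes emission directivity matter: without it the
zero-mean templates would make the focused head and the isotropic-pair
control numerically identical.

The receiver evaluates a multivariate Gaussian likelihood of **b** about
the floored mean max(**t**θ + *A*, 0) ("mean-censoring": the floor is
applied to the mean, not to the density's support), marginalizes *A* over
a uniform prior on [0, 50] dB with a 1 dB grid and trapezoid end weights,
and normalizes over cells with a uniform position prior.  All accumulation
is in log space; the bulk map computation whitens templates once with the
covariance Cholesky factor and evaluates all (cell × strength) densities
per measurement batch as one matrix product, in single precision (the
round-off, < 10⁻⁴ in posterior probability, is far below the Monte-Carlo
noise of 20-realization averages; the scalar `posterior`/`likelihood`
path stays in double precision and matches exhaustive linear-space
enumeration to 10⁻¹⁰ relative).  A fully censored likelihood (CDF mass at
floored elements) was considered and not implemented: with the strength
prior already marginalizing over the mean level, the mean-censoring form
is the simplest reading and keeps the oracle equivalence exact.

Expected entropy H̄(θ, *f*, *A*) averages the posterior entropy over 20
simulated measurements (doubling to 200 moves globally averaged values by
< 0.3 bits on the synthetic head).  The grids are 20–110 kHz in 10 kHz
steps and 0–50 dB in 5 dB steps.  Angular resolution is
(2π/*N*)·2^H — the solid angle of the equivalent equiprobable region.

## Flutter noise

Σₙ is parameterized by the per-slot std σ, a within-ear lag correlation ρ
and an interaural correlation *c*:

    Σ_n = σ² · [[1, c], [c, 1]] ⊗ R,   R_ij = ρ^|i−j|

so the diagonal is σ², within-ear entries decay geometrically with
position lag, and same-position left/right pairs carry *c*σ².  The
Kronecker structure is the natural positive-semi-definite completion of
those three requirements: filling the cross-ear block with *c*σ²·I instead
(zero elsewhere) is *not* PSD at the defaults (ρ = 0.2, *c* = 0.9 gives a
smallest eigenvalue of −0.218 σ²), whereas the Kronecker form is PSD for
all |ρ| ≤ 1, 0 ≤ *c* ≤ 1.  Defaults: σ = 5 dB (the "medium" level; low and
high are 2.5 and 7.5 dB), ρ = 0.2, *c* = 0.9.  One Σₙ is used across
frequencies; per-frequency covariances can be passed anywhere a
covariance is accepted.

The estimation path mirrors how σ and ρ are measured from a real
fluttering target: repeated ensonification (the simulator generates tone
bursts whose dB amplitudes follow a stationary AR(1) sequence; 400-call
batches at a 6 ms interpulse interval ≈ 166 Hz, at least 8000 echoes,
five aspect angles), single-frequency power per echo via the Goertzel
recursion (identical to the squared DFT bin, verified property-wise
against the full transform), then the std and lag-*k* Pearson correlations
of the dB gains.  At n = 8000 the round-trip recovers σ to ±0.2 dB and
the lag-1 correlation to ±0.05.

## The synthetic head

No measured directivities ship with the package; the generator produces
fields with the structural features the analysis exploits, and its
defaults are the package's study conditions:

- **Beams.** Gaussian main lobes with half-power beamwidth
  60°·λ/aperture.  Off-axis the fall-off levels out at a sidelobe plateau
  with a diffraction-like ripple (amplitude 4 dB, angular period one
  beamwidth), because measured head fields do not decay without bound.
  The plateau depth is the critical shape parameter: with an unbounded
  Gaussian tail, peripheral templates acquire huge, distinctive
  modulations and weak echoes become *more* informative at the most
  focused frequencies — the opposite of a real head; with a flat plateau
  and no ripple, the periphery carries no modulation at all and stays
  confusable at any echo strength.
- **Hearing.** Per-ear lobes with axes at ±(15°, 10°) (up-and-outward),
  peak gain capped at 12 dB, aperture 12 mm (pinna scale), plateau 15 dB
  below the cap.
- **Emission (focused variant).** Aperture 9 mm (noseleaf scale), axis at
  elevation 5° + 0.05°/kHz (the lobe drifts slightly upward with
  frequency), plateau 45 dB below peak — the facial morphology
  concentrates emitted energy much harder than the pinnae collect it.
  Emission fields are power-normalized to integrate to 1 over the
  hemisphere, which makes the per-frequency template gain an inverse
  directivity index.
- **Emission (isotropic-pair control).** Two in-phase monopoles 4.2 mm
  apart on the interaural axis; the interference pattern's nulls are
  clipped at the 15 dB plateau depth (ideal nulls are infinitely deep;
  measured ones are not), then power-normalized.
- Speed of sound 343 m/s; absolute gain floor −60 dB.

Under these defaults the model reproduces the qualitative behaviour the
architecture is built to expose, verified across seeds: globally averaged
H̄ is non-increasing in SNR and saturates at high strength; the entropy
profile over frequency has its minimum near 40 kHz and deteriorates
toward 110 kHz; at the most focused frequency the worst-minus-best range
over cells is larger for the focused head than for the isotropic-pair
control (the focused periphery stays starved even at 50 dB, the control's
recovers); and the perch-hunt best frequency shifts from 40 to 30 kHz as
the foraging radius grows past about 3 m.  What passing these checks does
*not* show: agreement with any real specimen's HRTF, absolute entropy
levels for a real bat (the synthetic modulation intervals are larger than
measured ones, so absolute bit counts are optimistic), or cochlear/neural
limits — the model is an upper bound on morphology-borne information.
Sweep-direction robustness holds to within 1 bit of globally averaged
entropy (diagonal vs azimuth-only vs elevation-only); the tolerance is
wider than for a measured head because the diagonal sweep covers a 21°
arc against 15° for the single-axis sweeps and the synthetic lobes are
smoother than real HRTFs.

## Perch hunting

Prey are uniform in the ball of the foraging radius (distance density
∝ r²; a hemisphere option exists), 1000 per radius, radii 1–5 m.  SNR per
prey: 105 dB call (referenced at 0.1 m) − 40·log₁₀(d/0.1) two-way
spreading − 2·d·α(f) two-way absorption − 40 dB target strength + 12 dB
ear gain, clamped to the evaluated [0, 50] dB range.  α(f) is the ISO
9613-1 pure-tone absorption coefficient (classical + O₂/N₂ relaxation) at
20 °C, 50 % RH, 101.325 kPa (≈1.32 dB/m at 40 kHz, ≈2.61 dB/m at 80 kHz).
The ear gain is added in the SNR bookkeeping only, not inside the
template normalization; since templates are normalized per frequency to a
0 dB anchor, adding it there instead would shift every frequency equally
and change nothing in the comparisons.  Expected entropy per prey is
linearly interpolated from the global H̄-vs-SNR curve of the same
frequency; one prey sample is reused across frequencies per radius so the
frequency profile is compared on identical configurations.

## Numerical choices and limitations

- Strength marginalization: 1 dB grid on [0, 50]; halving the step changes
  marginals by < 1 % on the synthetic head.
- Posterior underflow: log-space throughout; a hard failure occurs only if
  every cell's log-marginal is −∞.
- Degenerate inputs: all-zero emission cannot be normalized (error);
  constant ensembles have undefined lag correlation (NaN + warning);
  non-PSD covariance parameterizations are rejected naming the smallest
  eigenvalue; entropies outside [0, log₂ N] are rejected by the
  angular-resolution transform.
- Ties in nearest-cell lookup resolve to the lowest index (deterministic).
- Problem sizes: the shipped analyses use N = 256 cells, 10 frequencies,
  11 SNR levels and 20 realizations (≈56 000 posterior evaluations per
  frequency); a full map takes about a minute on one core.
- Not modelled: Doppler/spectral cues, cochlear transduction, range
  estimation, clutter echoes (flutter σ is the only stand-in for any
  amplitude-modulating interference), prey motion during the sweep, and
  any physical (boundary-element) acoustics.
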