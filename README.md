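# pinnasonar

An information-theoretic model of sound-source localization by moving
pinnae in constant-frequency (CF) echolocating bats, for computational
bioacousticians and sensory ecologists who want to quantify — in bits —
how much a head's directional acoustics tells the animal about where an
echo came from, as a function of call frequency, echo strength and target
flutter.

## The model

Horseshoe bats emit narrowband CF calls and twitch their pinnae in
anti-phase while receiving echoes.  Because each pinna's directional
sensitivity rotates rigidly with it, the sweep imprints a
direction-specific amplitude modulation on the echo at each eardrum.
Localization is treated as Bayesian template matching over a discrete
hypothesis space: the frontal hemisphere is split into *N* equal-area
cells (default *N* = 256, so total ignorance is log₂ *N* = 8 bits), and
for each cell θ and frequency *f* the expected binaural modulation
pattern — the *template* **t**θ, 7 ear positions × 2 ears = 14 dB values,
stored zero-mean — is derived from the product of the emission directivity
and the per-ear hearing directivity (the AHRTF).

A received echo of unknown mean strength *A* (dB above the detection
floor, i.e. its SNR) is modelled as

&nbsp;&nbsp;&nbsp;&nbsp;**b** = max(**t**θ + *A* + **ε**, 0),&nbsp;&nbsp;&nbsp;**ε** ~ 𝒩(0, Σₙ)

where the elementwise maximum is the detection floor and Σₙ is a
structured 14×14 covariance describing flutter noise: per-slot std σ
(default 5 dB, estimated from fluttering-insect echoes via Goertzel
single-bin spectral power), geometrically decaying within-ear lag
correlations (0.2) and a high interaural correlation (0.9).  The receiver
computes the Gaussian likelihood per cell, marginalizes *A* over a uniform
prior on [0, 50] dB, and forms the posterior *p*(θ|**b**) with a uniform
position prior.  The Shannon entropy *H* = −Σ *p* log₂ *p* of that
posterior, Monte-Carlo averaged over 20 simulated echoes, is the expected
residual uncertainty H̄(θ, *f*, *A*); (2π/*N*)·2^H converts it to an
effective solid angle of ambiguity.

Two study conditions close the loop with behaviour: a two-isotropic-source
control emitter (monopole pair at the 4.2 mm nostril spacing) isolates the
contribution of the facial morphology, and a perch-hunting Monte Carlo
maps 1000 random prey positions per foraging radius (1–5 m) to echo SNR via
the sonar equation — 105 dB call at 0.1 m, two-way spherical spreading,
ISO 9613-1 atmospheric absorption, −40 dB target strength, 12 dB ear
gain — and reads the expected entropy off the H̄-vs-SNR curves.

Measured directivities are not shipped; a parametric synthetic head
(wavelength-scaled Gaussian lobes with bounded sidelobe plateaus, laterally
offset ear axes, frequency-dependent focusing) generates fields with the
structural features the analysis exploits.  Measured HRTFs can be imported
from CSV/NetCDF/SOFA instead.

## Worked example

`examples/05_perch_hunting.py` builds templates at four frequencies,
computes the entropy map at medium flutter noise and runs the perch-hunt
Monte Carlo:

```
absorption (dB/m): {30.0: 0.94, 40.0: 1.32, 60.0: 1.98, 80.0: 2.61}
radius_m        1.0   3.0   5.0
frequency_khz
30.0           2.85  3.99  4.44
40.0           2.50  4.01  4.57
60.0           3.64  4.97  5.42
80.0           4.17  5.03  5.26
radius 1 m: best frequency 40 kHz (2.50 bits)
radius 3 m: best frequency 30 kHz (3.99 bits)
radius 5 m: best frequency 30 kHz (4.44 bits)
```

Each table entry is the mean posterior entropy (bits) about prey direction
over 1000 random prey in the patch: lower is better, 8 bits would be
total ignorance.  At close range the 40 kHz templates win; as the patch
grows, atmospheric absorption — which rises steeply with frequency —
shifts the optimum down to 30 kHz.  The other examples cover the
partition and field synthesis (`01`), template summaries (`02`),
flutter-noise estimation (`03`) and the entropy map with its
angular-resolution reading (`04`).

A thin CLI wraps the same pipeline:
`pinnasonar run --seed 1 --out myrun/` writes fields, templates, the
entropy map (CSV + NetCDF), perch-hunt tables and a manifest sufficient to
reproduce the run bit-for-bit; see `pinnasonar --help` for the individual
stages.

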