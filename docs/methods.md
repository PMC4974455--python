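# Methods

This note records the models, conventions, parameter defaults and numerical
choices behind `rnoise`, and what the synthetic benchmark does and does not
establish about real data.

## Quality factors

All factors are computed in the measurement (time) domain. For observed
points `m_i`, back-calculated points `s_i` (inverse transform of the model
spectrum evaluated at the sampled grid positions) and a pure-noise
reference `d_j`:

- `R = Σ‖m_i − s_i‖ / Σ‖m_i‖`, where `‖·‖` is the hypercomplex vector
  length (complex modulus in 1-D; √(RR²+RI²+IR²+II²) for a 2-D plane).
- `R_noise = mean‖m_i − s_i‖ / mean‖d_j‖`.

**Mean normalization.** The working, free and noise sets generally differ
in size, so a ratio of plain sums is only well-defined for matched sets.
Numerator and denominator are therefore each normalized by their own point
count. When the noise reference shares the parent schedule, it is
restricted to the matching working/free positions; otherwise the full
noise set is used. Both paths have the same expectation. This resolution of
the size-mismatch question is a package choice, documented rather than
asserted as canonical.

Internally all factors are stored as fractions; percentages appear only at
presentation time. A report of a scan snapshot carries the four factors,
the set sizes, the control-parameter label (threshold, λ, or iteration),
and optionally the composite score and the RMSD to a reference spectrum.
Multi-plane summaries are per-factor means and sample standard deviations
(n−1; sd = 0 for a single plane by convention).

## Transforms

Unitary (1/√N) DFT convention throughout, so Parseval holds symmetrically
and the factors are independent of the normalization choice. No
apodization, zero-filling beyond the acquisition grid, phase correction or
linear prediction: window functions would bias the time-domain comparison
that the factors are built on.

**Hypercomplex planes.** A 2-D plane carries four real quadrature
components (RR, RI, IR, II) per time point. The transform is applied axis
by axis, with each axis's quadrature pair acting as that axis's
real/imaginary parts. This keeps the transform linear, unitary and exactly
invertible, which `back_calculate` needs in order to score models against
plane measurements. The conventional complex projection
`(RR − II) + i(RI + IR)` is available for display only; a projection-based
spectrum container would lose half the components and make back-calculation
ill-posed, which is why the full four-component array is the canonical
representation here.

The point-spread function is the transform of the schedule's 0/1
indicator, scaled to peak value 1 at zero offset. A spectrum-domain
component of amplitude `c` at bin `k` contributes `c·(n/N)·PSF(shifted to
k)` to the dirty spectrum, where `n/N` is the sampling density.

## Working/free split

`round(free_fraction · n)` positions (round half away from zero) drawn
uniformly without replacement with numpy's PCG64 generator; the generator
name is recorded in split metadata so splits stay reproducible across
releases. The split is drawn once per schedule (not per plane). The free
fraction defaults to 20% for the 1-D study; robustness of the
`R_noise_free` minimum is checked over 10–30%.

## Reconstruction engines

**CLEAN.** Iteratively: locate the maximum-magnitude point of the residual
dirty spectrum (complex modulus; ties break to the lowest index), add
`gain × amplitude / (n/N)` to the model at that point, remove the
component's response from the residual, stop when the maximum falls below
the stopping threshold. Gain defaults to 0.1 (classic practice). The
residual is maintained in the measured time domain, which is algebraically
identical to subtracting the shifted PSF from the residual spectrum but
keeps the conservation identity (model response + residual = dirty
spectrum) exact to rounding. A threshold scan continues one iteration
state across descending thresholds — indistinguishable from independent
runs because the threshold only decides when to stop. A guard raises if the
residual norm ever exceeds twice its initial value. Only the model is
scored and returned; residuals are never folded in.

**IST.** Starting from the dirty spectrum of the working set, each
iteration soft-thresholds the residual spectrum (magnitude reduced by the
threshold, floor 0, phase kept — the part of the spectrum above the
threshold line) and accumulates the extraction into a model. The composite
reconstruction takes the model's back-calculation at unmeasured and free
positions and re-imposes the measured working values by copy; its
working-set residual is therefore exactly zero, and its snapshot factors
are evaluated directly on those time-domain values (pushing them through
an extra transform round-trip would only add float noise to an identity).
At free positions the reconstruction equals the model back-calculation, so
the free-set factors of model and reconstruction coincide exactly.

Threshold schedule default: geometric decay over the run (1,500
iterations) from 0.9× the dirty-spectrum maximum down to 1/50 of the noise
floor, with the floor estimated as the mean magnitude of the pure-noise
reference (the unitary transform keeps time- and frequency-domain noise
levels equal). The deep endpoint is chosen so that the model's working-set
residual falls essentially to zero by the end of the run and the
late-iteration overfitting regime is fully developed; with a silent noise
reference (noiseless simulations) the endpoint falls back to 1e−7 of the
starting threshold. The model's `R_noise_work` decreases over the run up to
ripples below 0.1% of its current value; such sub-resolution upticks are
inherent to discrete threshold extraction (they appear in both the
cumulative-model and replace-model formulations) and are allowed for by
the monotonicity checks.

**Variational engines.** Both minimize `C(S) = regularizer(S) + λ·RMSD(s, m)`
over model spectra, with RMSD the root-mean-square point-wise residual
magnitude at the working positions. `λ = 0` reduces to the bare
regularizer (for l1 the minimizer is the zero spectrum, score exactly 0);
large λ enforces near-complete agreement with the working data. The RMSD is
smoothed as `√(ms + ε)` with `ε = 1e−12` so scoring has a finite gradient
at zero residual.

- *l1*: regularizer `Σ|S_j|`. Because the data term is an unsquared norm,
  it acts as an exact penalty — above a finite λ the minimizer agrees with
  the data exactly — and its gradient has constant norm with unbounded
  curvature at zero residual, where smoothed-gradient methods stall.
  The solver is therefore the Chambolle–Pock primal–dual splitting
  (τ = σ = 0.99; the sampling-restricted unitary transform has operator
  norm 1): the primal prox is complex soft thresholding, the dual prox of
  the data term is a Euclidean-ball projection of radius λ/√n. On the
  noiseless benchmark it recovers all amplitudes to machine precision;
  at large λ it reaches the minimum-l1 data-consistent model.
- *MaxEnt*: regularizer `−E(S)` with the Gibbs entropy on magnitudes,
  `E(S) = −Σ [u ln u − u]`, `u = |S_j|/σ_e`, smoothed near zero with
  `δ = 1e−8·σ_e`. The functional is pluggable (the `entropy` hook) so
  spin-system-specific forms can be substituted. Solver: gradient descent
  with Armijo backtracking. The entropy scale σ_e defaults to 1 and is set
  in the benchmark to 0.1× the dirty-spectrum median magnitude, keeping the
  entropy's preferred image well below the noise floor.

Convergence for both: relative score change below 1e−8 for 10 consecutive
iterations; hitting the iteration cap (default 4,000) returns the
best-so-far model flagged non-converged.

**λ ladder.** Default: 33 log-spaced values over [1e−2, 1e5] (≈4.7 per
decade). The exact-penalty character of the RMSD data term compresses the
entire zero-model → exact-fit transition into less than a decade of λ, and
a coarser ladder cannot localize the `R_noise_free` minimum inside that
window. Scans are cold-started per λ by default (bit-reproducible);
warm starts are available and agree within the convergence tolerance.
Because l1 and MaxEnt weight their regularizers differently, absolute λ
values are not comparable between the two engines — only curve shapes are.

## Synthetic benchmark

The 1-D study: nine exponentially decaying complex signals, amplitudes
geometric from 64 down to 1, frequencies evenly spaced −4,000…4,000 Hz, on
a 1,024-point grid, 30% uniformly random sampling, 80/20 working/free
split, plus a pure-noise dataset of the same amplitude on the same
schedule. Defaults that the study design leaves open, fixed once here:

- spectral width 10,000 Hz (dwell 100 μs), so ±4,000 Hz sits in-band;
- decay rate 100 s⁻¹ for every signal (≈32 Hz linewidth);
- white-noise σ = 0.5 per quadrature component, putting the weakest signal
  at a frequency-domain SNR of a few — low enough that overfitting of noise
  spikes is observable in the scans;
- signal phases 0 by default (`random_phase=True` draws them from a
  dedicated stream).

All randomness flows from one master seed split into named streams
(signal-phase, noise, schedule, split), so each component can be varied
independently and runs are bit-reproducible. Derived integer seeds are
kept below 2³¹.

2-D fixtures: hypercomplex planes with cosine-modulated decaying signals
in three variants — strong (default amplitudes), weak (same layout scaled
so the largest amplitude is 5× the noise σ, mimicking leakage from a
neighbouring plane), and pure noise. Strong and weak planes from one seed
share peak positions and noise realization.

**What the benchmark does not emulate:** realistic chemical-shift
distributions, rolling baselines, t₁-noise, temperature drift, or
correlated (non-white) noise; schedules are uniform random, not
cosine-weighted ring patterns. Passing tests therefore demonstrate the
internal consistency and the overfitting-detection behaviour of the
factors under idealized conditions, not performance on any particular
experimental system.

## Problem sizes used in the test suite

The suite runs the full 1,024-point benchmark: 1,500-iteration IST runs,
33-point λ-scans for l1 and MaxEnt (plus 10/20/30% free-fraction
variants), and a 30-step CLEAN threshold scan, with small grids
(128–256 points) for solver unit tests. These sizes were chosen to match
the study design exactly while keeping the whole suite interactive
(well under a minute of reconstruction time).

## Known limitations

- Reconstruction engines are 1-D; planes are supported for simulation,
  transforms and scoring only.
- The MaxEnt entropy functional and scale are one defensible choice among
  several in use; conclusions drawn from MaxEnt scans here are
  shape-qualitative, not λ-quantitative.
- `R_noise_free` at its minimum is not 1 on the benchmark (≈3.7): at 30%
  sampling with visible noise the best reachable reconstruction still
  carries residual aliasing error above the noise at held-out positions.
  The factor ranks reconstructions; only an ideal reconstruction would
  reach unity.
- The divergence guard in CLEAN is a safety net for pathological gains;
  within the valid gain range (0, 1] the residual l2 norm is
  non-increasing by construction.
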