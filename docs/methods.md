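# Methods

## The single-cell network

The clock in every cell is a revised form of the compact De Caluwé *et al.*
(2016) model: 9 ODEs for the mRNA and protein of four lumped gene pairs —
CL (CCA1/LHY), P97 (PRR9/PRR7), P51 (PRR5/TOC1), EL (ELF4/LUX) — and the
dark-accumulating protein *P* with dynamics `dP/dt = q(1−P)D − L_sens·L·P`,
`q = 0.3 h⁻¹`.  Light enters in six places: acute activation of CL and P97
transcription at dawn via *P*, light-driven EL transcription, light-boosted
CL translation, and light/dark switching of CL mRNA and of the P97, P51 and
EL protein degradation rates.  The dark indicator is strict: `D = 1` iff
`L = 0`, so fluctuating daytime intensities (always ≥ 0.5) never engage the
dark-specific rates.  The revisions relative to the original network are a
CL→P97 repression (constant K5b) replacing the original activation, CL
self-repression (K0), and dark-enhanced P51 protein degradation
(`d3L < d3D`).

The revised network has exactly 34 named rate and scaling constants; `q` is
a structural literal carried in the parameter table but never fitted or
perturbed.

### Parameter provenance and calibration

The packaged default table starts from the published base values of the
original compact model and re-derives the constants tied to the revised
interactions — K0, K4, K5, K5b, d3L — together with the P51-loop constants
K6, K7, k3 and the CL-loop scales K1, K2, by calibrating against the revised
model's reference single-cell behaviour
(`plantclock.fitting.REFERENCE_BENCHMARKS`): free-running periods 25.5 h
(LL) and 27.4 h (DD), entrained mRNA peak phases ZT −0.3 / 6.0 / 11.8 /
9.7 h for CL / P97 / P51 / EL, and CL amplitudes.  Calibration minimizes a
weighted squared mismatch (periods and phases weighted as ~0.05 h,
amplitudes ~0.07–0.2) by a shrinking-box Sobol search
(`fitting.calibrate_reference`).  The shipped defaults reproduce every
benchmark to ≤ 0.1 h except the LL amplitude of CL (0.65 vs 0.9), a known
limitation: the reachable set of the free constants pins the LL limit cycle
at the lower amplitude.  A weaker limit cycle has a larger phase response to
light perturbations, which is the package's leading explanation for its
timing-error estimate under noisy light running ~0.2 h above the reference
value (see "Timing error" below).

## Scoring pipeline (fitting module)

The scoring protocol is 60 d 12:12 LD → 60 d LL → 60 d DD, single cell,
`L_sens = 1`, discarding the first 55 d of each condition.  Solutions are
*rhythmic* when the chi-square periodogram peak is significant at 1% and the
rhythmicity floors hold: every assessed variable stays ≥ 0.1 with a
peak-to-trough range of at least 10% of its maximum.  The floors are applied
to the transcriptionally active gene variables only — all eight under LL;
the CL, P97, P51 pairs under DD — because EL transcription is strictly
light-driven (the EL pair is structurally zero in darkness) and *P*
saturates flat in both constant conditions, so a literal "all variables"
floor would reject every solution including the reference one.

*Entrainment* is declared when the last two LD-cycle CL peak phases agree to
< 0.1 h (mod 24).  The *phase shift* Δ at LD→LL transfer is the first LL CL
peak time minus the time extrapolated from the last entrained peak by one
LL period, mapped to (−12, 12].  The cost function sums: a large penalty
(10⁶) for arrhythmic or unentrained solutions; period penalties
`2(τ−c)²/(0.1c)²` outside the LL [24, 25] and DD [25, 28] bands (centres
24.5, 26.5); ZT penalties `(ZT−target)²/(0.1·24)²` outside ±1 h of CL 1.5,
P97 6, P51 12, EL 9; and Δ²/(0.1·24)².  `optimize` runs a Sobol scan
(default 256 points) over the free constants in [0.1, 10]⁴ followed by
simulated annealing with log-space Gaussian proposals (step 0.08) and
geometric cooling (0.97/step), deterministic given its seed.

The ±5% sensitivity analysis perturbs the 34 named constants uniformly and
independently, runs LL and DD (60 d, discard 55), and tabulates the
periodogram period and the max−min CL mRNA amplitude per draw; draws with a
non-significant periodogram are excluded and counted.  Amplitude is defined
as max − min over the analysis window (the half-range convention would halve
it; max − min reproduces the reference DD amplitude).

## Spatial model

The default template is 800 cells: two 10×15 cotyledon blocks flanking a
5×20 hypocotyl column, a 5×70 root and a 5×10 root tip, 4-connected; all
geometry is configurable and every analysis is geometry-parameterized.
τ is drawn once per cell from its region's N(1, σ) (σ = 0.059, 0.028,
0.073, 0.089 for cotyledon, hypocotyl, root, root tip; draws floored at
0.05) and multiplies d/dt of the full per-cell equation — so it scales the
coupling term too, exactly as the coupled equations are written.  Growth
appends one row at the tip every 24 h; the tip keeps constant size, its
uppermost row is relabelled to root (L_sens drops to 0.65; τ is retained —
the cell persists, only its regional identity changes), and new cells copy
the state of the adjacent interior row to avoid spurious transients and
draw fresh τ from the root-tip distribution.

Local coupling adds `J_local(c̄ᵢ − cᵢ)` to the configured species' equation,
with `c̄ᵢ` the mean over existing neighbours only (a corner cell averages
over 2 — no padding; passive sharing has no flux through the boundary).
Global coupling averages over all N cells including self, which makes the
summed coupling contribution exactly zero.  Long-distance coupling adds
`J_long(c̄_EL,hypocotyl − c_EL,i)` to the EL protein equation of root-tip
cells, sourced from the mean over all hypocotyl cells.

## Light environments

Time 0 is dawn.  Noisy LD daytime intensity is a piecewise-constant process:
interval lengths i.i.d. exponential (mean 2.4 h), deviations i.i.d. uniform
on [−0.5, 0.5], so instantaneous intensity is uniform on [0.5, 1.5] and its
expectation is 1.  Each cell mixes a shared and a private track,
`L = 1 − [λξ_g + (1−λ)ξ_i]`; at intermediate λ the intensity distribution
is the convolution of the scaled uniforms (triangular-like), which is the
only consistent reading of the mixture formula.  Tracks are redrawn at each
dawn (the night-time value of a track is never consumed); dawn and dusk
themselves are never perturbed and night light is exactly 0.  All streams
descend from one protocol seed through `SeedSequence` keys (stream, cell,
day), so any cell's trace is reproducible independently of iteration order,
and cells created by growth extend the scheme without disturbing existing
streams.

## Numerics

The forcing is piecewise-constant, so the vector field is smooth between
light switch times and discontinuous at them.  Integrators therefore never
step across a switch: the single-cell path restarts an adaptive stiff-capable
solver (LSODA, rtol 1e-8 / atol 1e-10) at every dawn, dusk and fluctuation
breakpoint; the lattice and ensemble paths advance with classical RK4 on
the union of all cells' switch times, capped at 0.1 h (lattice) / 0.2 h
(ensembles).  With reaction rates of order 1 h⁻¹ the RK4 local error at
these caps is far below analysis resolution — fixed-step and adaptive
solutions agree to < 1e-5 in state and ~1e-5 h in peak times, and halving
the caps changes reported periods by ≪ 0.01 h.  States are projected onto
the non-negative orthant after each step; this acts only within round-off
(degradation is proportional to the variable itself).  Default initial
condition: every variable at 0.1.

Output is recorded on a uniform 0.1 h grid.  Peak times are refined to
sub-sample precision by a parabola through the three samples around each
maximum.

## Rhythm analysis

Peak detection follows the imaging pipeline: local maxima above the
windowed-series mean, minimum separation 19 h with tallest-first greedy
suppression (the canonical findpeaks behaviour; a prominence-ranked variant
differs only in contrived ties).  Troughs are peaks of the negated series
with the mirrored threshold.  The chi-square periodogram uses all samples
(incomplete folds included, which keeps the statistic comparable across
candidate periods), a candidate grid at the 0.1 h sampling resolution,
ranking by exceedance over the χ² significance line, and a Bonferroni
correction over the candidate grid so the family-wise false-positive rate
stays at the nominal 1%.  Series shorter than two cycles of the longest
candidate are flagged non-assessable.  A series is classified rhythmic when
at least two peaks pass the detection rules in the analysis window.

Final-peak maps restrict detection to ±12 h of the expected time — the last
peak of the template-mean signal, found with the 19-h rule but no height
threshold (under weak coupling the desynchronizing mean decays and late
peaks would otherwise be discarded).  Ties resolve to the greatest height,
except P51/TOC1, which consistently double-peaks and resolves to the
earliest.  ROI series average 5×3-cell blocks, one per region, anchored by
default at mid-cotyledon, sub-shoulder hypocotyl, mid-root and distal tip
(positions are configurable — the imaging ROIs have no exact lattice
analogue).  Space–time matrices average all cells in each lattice row, so
the cotyledon shoulder collapses onto the axis by the same row mean.

### Timing error

`E = (1/N) Σ_h |T_idealized(h) − T_noisy(h)|` over per-cell final peak (or
trough) times between matched noisy and idealized runs (same τ field,
coupling and protocol skeleton).  The absolute value is deliberate: signed
averaging would cancel to ≈ 0 while the quantity is reported as a positive
error with a small replicate SD.  Cells lacking a defined peak in either
run are excluded and counted.  The timing-error protocol is 10 d of 12:12
LD (noise from day 0); E is stationary in protocol length for entrained
cells.  At the reference conditions (J_local = 0, λ = 0, 9 replicates) the
package computes E ≈ 0.68 h for P97 peaks and ≈ 0.40 h for troughs.  The
per-cell error median (≈ 0.45 h) matches the reference scale; the peak mean
is inflated by a ~4–5% tail of large-τ root and root-tip cells that do not
cleanly 1:1-entrain at L_sens = 0.65 and whose final-peak identity can jump
between cycles under noise.  Troughs are immune because dark degradation
re-synchronizes them each night — the same mechanism that makes EL troughs
exactly synchronous.

## What the synthetic fixtures do and do not show

`fixtures.make_fixture` produces sinusoidal grids (known periods/phases),
noisy oscillators (sinusoid + linear trend + Gaussian noise) and a
two-wave space–time tent profile.  These validate the estimators —
periodogram accuracy, peak selection, final-peak maps, E bookkeeping —
against closed-form truth.  They do not emulate clock waveform asymmetry,
growth, or amplitude decay under desynchronization, so estimator behaviour
on those features is exercised only by the ODE-driven tests.

## Scaled-down test conditions

The emergent-property tests run the full 800-cell template for wave,
synchrony and long-distance checks (single seeds, deterministic), and a
reduced 234-cell seedling with 2 replicates for the coupling–noise sweeps;
the unit-level fitting tests use shortened scoring protocols (8-day phases)
after verifying that observables stabilize well before the reference
55-day discard.  The acceptance script runs the reference problem sizes:
full template, 9 replicates, 2,000 sensitivity sets.

## Known limitations

* The base parameter table is a reconstruction of the original compact
  model's published values plus calibrated revised constants; the LL
  amplitude shortfall and the timing-error peak inflation discussed above
  are its visible consequences.
* No stochastic chemical kinetics (τ generates between-cell, not
  within-cell, variability), no transport delays, and no secondary phloem
  unloading sites.
* Entrainment of extreme-τ cells at low light sensitivity is fragile;
  region-level entrainment is robust.
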