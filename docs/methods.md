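# Methods

## Kinetic model

The nucleotide-incorporation cycle is reduced to a minimal unicyclic
scheme: dNTP binding (k_on·[dNTP], reverse k_off), a lumped
condensation-plus-chemistry step (k_cat, treated as the single rate
limiting forward step), PPi release (k_ppi, fast), and — in the
Brownian-ratchet variant — a reversible mechanical translocation
(k_T, k_−T) located after PPi release and before dNTP binding. PPi
release is treated as irreversible: raising PPi a thousandfold has no
measurable effect on velocity in this system, so product rebinding is
omitted throughout. Exactly one step per model carries the load
dependence, with Bell/Arrhenius kinetics k(F) = k(0)·e^{F·d/kBT}.

Sign conventions, fixed once for the whole package: loads are signed with
aiding positive and hindering negative; forward rates couple through +d,
backward rates through −d. The Michaelis–Menten decomposition
1/V_max = a + b·e^{−F·d_b/kBT} and K_M/V_max = r + s·e^{−F·d_s/kBT}
therefore grows under hindering load (F < 0), matching the orientation of
plotted force–velocity data.

The closed forms for all three models were derived by King–Altman
reduction of the corresponding 2-, 3- and 4-state cycles; the module
keeps an independent numerical route (`unicycle_steady_state`, a direct
linear solve of the master equation with the normalization row appended)
that the tests compare against the closed forms at 1e−8 relative over
randomized parameter sets. The 3-state ratchet cycle lumps k_ppi into
k_cat's exit; the solver accepts the explicit 4-state cycle when PPi
release is to be resolved. With the lumped cycle the identity
M_bound = v/k_cat is exact, which is what makes the occupancy estimate at
the detachment velocity (v = 7 nt/s, k_cat = 120 s⁻¹ → ~6% bound / ~94%
free) a one-line consequence of the model.

Default thermal energy is kBT = 4.075 pN·nm (22 °C); it is an explicit
argument everywhere because part of the original experiments ran at
28 °C. Default parameter set (`PHI29_COEFFS` / `PHI29_RATES`): a = 0.0084
s, b = 0.0015 s, r = 0.19 s·μM, s = 0.12 s·μM, d_b = 0.35 nm, d_s = 0.40
nm, equivalently k_on = 5 μM⁻¹s⁻¹, k_cat = 120 s⁻¹, k_T(0) = 670 s⁻¹,
k_−T(0) = 420 s⁻¹ — the published best-fit values for the Phi29 DNA
polymerase. k_off defaults to 0 (the data constrain only r ≈ 1/k_on;
the exact factor (1 + k_off/k_cat) is retained and exposed). k_ppi
defaults to 10⁴ s⁻¹, the top of the literature range, consistent with
lumping.

The rupture-force prediction inverts v(F, [dNTP]) = v_detach (default
7 nt/s, the empirical velocity at which polymerase–DNA detachment occurs)
by bracketed root finding on [−200, 0] pN; the velocity is strictly
increasing in F so the root is unique. Below the concentration where the
zero-load velocity already sits under v_detach (≈2 μM at the defaults)
the function returns a documented no-root value rather than raising.

## DNA elasticity

Distance-to-nucleotide conversion uses per-nucleotide equilibrium
extensions: dsDNA by the high-force extensible worm-like chain
interpolation x/L = 1 − ½√(kBT/FP) + F/S (P = 50 nm, S = 1200 pN,
L = 0.34 nm/bp) and ssDNA by the same entropic interpolation without the
stretch term (P = 0.75 nm, L = 0.59 nm/nt). These are standard literature
values for ~physiological ionic strength; all are configurable. The
entropic interpolation turns nonphysical below ~kBT/4P (≈1.4 pN for
ssDNA); the contour fraction is clipped there and the conversion is
documented as unreliable below a few pN — all analyses in this package
operate at ≥3 pN. The spacing rule follows the experimental geometry:
under opposing load, primer extension consumes single-stranded template
(ss spacing) while strand displacement shortens the duplex side (ds
spacing); under aiding load the downstream duplex grows in both modes
(ds spacing).

## Synthetic data

The generator exists to emulate the statistical structure of the real
measurements, with defaults fixed at the study conditions: 60 Hz
sampling; Gaussian measurement noise of 2 nm SD per sample (a typical
dual-trap figure); template of 229 nt ssDNA + 3487 bp dsDNA;
load-independent off-pathway pauses injected as Poisson arrivals
(0.05 s⁻¹) with exponentially distributed durations (mean 1 s) that
freeze the enzyme's active clock; detachment criterion 7 nt/s. The pause
rates are not quantified in the source data beyond a 0.4–0.8 s detection
resolution; the chosen defaults make detection non-trivial without
dominating the traces, and are configurable. Stepping itself is exact
Gillespie simulation of the 3-state ratchet cycle; the mechanical
position moves at translocation events (so at zero dNTP the enzyme hops
between two positions and the cycle never closes).

The ramp ("no feedback") schedule integrates the cycle per 1/60 s step
with the load updated from trap stiffness (default 0.1 pN/nm) times the
accumulated tether shortening, and terminates with a flagged detachment
when the stepping velocity smoothed over 2 s of active time first falls
below v_detach. The termination monitor runs on the noise-free stepping
record: with 2 nm noise the 50-point slope estimator has an SD of ~4
nt/s, and a first-passage rule on the noisy signal would trigger far
above the true 7 nt/s crossing. The detector in the analysis layer sees
only the noisy data. Because even the true stepping rate fluctuates
(~25% SD in a 2 s window near 7 nt/s), first passage still fires a few
pN before the deterministic crossing at ≈49 pN; simulated detachments
cluster at 44–48 pN.

Force–velocity tables are drawn directly around the closed-form velocity
with 8% relative Gaussian noise and n = 8 replicates per condition
(SEM = sd/√n), emulating per-condition trace averaging. The default grid
spans −30…+20 pN × {5, 10, 50, 100, 200, 500} μM; recovery studies use a
7-force design (−30…−5 step 5, plus +20 pN) spanning the experimental
hindering range with one aiding point. What the generator does *not*
emulate: drift and low-frequency instrument noise, sequence-dependent
kinetics, exonuclease excursions, bead-hydrodynamics correlations in the
noise, and force-dependent pause structure. Passing tests therefore
validate the estimators under idealized stationary noise, not under
every instrumental pathology of real traces.

## Trace analysis

Instantaneous velocities are centered sliding-window least-squares slopes
over 50 samples. The source protocol states both "0.7 s" and "50 points"
for a 60 Hz record, which disagree (50 points = 0.83 s); the
implementation follows the 50-point definition and exposes the window in
points. Velocity histograms use 5 nt/s bins and are fitted by nonlinear
least squares with a two-Gaussian model — one component seeded at zero
(pauses), one at the robust positive mode — as histogram fitting is what
the figure-level protocol implies; mixture weights are the
amplitude×width products normalized to 1. The zero component's mean is
bounded to ±1.5 bins and its width to 4 bins so it cannot absorb the
active peak's tail; on fit failure a flagged single-component fallback is
returned. Pauses are maximal runs of |v| below a threshold (default: the
midpoint of the two mixture means) lasting ≥0.4 s. The pause-excised
average rate compresses time across the detected pause intervals and
refits a single slope, which is equivalent to fitting the concatenated
active segments.

## Inference

Global fits minimize Σ[(v_model − v)/SEM]² with rates parameterized in
log space (positivity) and coupling distances bounded in [0, 2] nm, using
trust-region least squares from ≥10 starting points (one data-driven
heuristic start plus lognormal/uniform jitters) — the a/b and r/s
amplitude splits are weakly identified when the force dependence is
shallow, and multi-start avoids the exchange degeneracy. SEMs of zero
(noiseless data) fall back to unit weights. Derived rates are computed
from the fitted coefficients through the exact algebraic dictionary, so
the reported k_cat, k_T(0), K_δ(0), ΔG_trans = −ln K_δ and δ satisfy the
closure relations identically. Uncertainties: covariance-based standard
errors (delta method on the log parameters) and seeded case-resampling
bootstrap percentile intervals.

Model discrimination fits all three models and ranks by
AIC = χ² + 2k. In addition, two signature tests mirror the qualitative
argument of the original analysis: the weighted-regression slope of
log(1/V_max(F)) and of log(K_M(F)/V_max(F)) versus force, from per-force
Michaelis–Menten fits, with significance from a parametric bootstrap
(velocities redrawn as N(v, SEM); the table carries one averaged record
per condition, so case resampling within conditions is impossible). The
log is taken of the full quantity rather than of the
plateau-subtracted excess (1/V_max − a): under the power-stroke nulls the
excess is centered at zero and its logarithm is undefined for roughly
half the bootstrap draws, whereas flatness of the full log quantity is an
equivalent and well-defined null. A flat log(1/V_max) identifies the
binding power stroke; a flat log(K_M/V_max) identifies the PPi-release
power stroke in its fast-release regime; force dependence of both is the
ratchet's fingerprint.

## Problem sizes and numerical choices

Simulated trace studies use 8 traces of 1000–1500 nt per condition
(mirroring the N = 8 traces per histogram of the experimental velocity
distributions); recovery and discrimination studies use 50 synthetic
datasets at the 7×6 design. The cycle solver is an O(N³) dense solve
(N ≤ 4 here). Root finding uses Brent's method at 1e−6 pN tolerance.
Gillespie runs are capped at 400 events per nucleotide plus 10⁵; hitting
the cap returns a partial log flagged `stalled` (the zero-dNTP case).
Seeds propagate through `numpy.random.default_rng` exclusively; identical
configurations produce identical outputs.

## Known limitations

- The exonuclease-transfer branch, sequence/mismatch-dependent kinetics
  and strand-displacement base-pair opening mechanics are out of scope;
  velocities are single-valued functions of (F, [dNTP]).
- Detachment is phenomenological (the empirical 7 nt/s criterion), not a
  molecular bond model; aiding-geometry detachment is not modeled.
- The two-Gaussian histogram fit degrades when pauses are so rare that
  the zero peak holds a handful of samples; pooling several traces (as
  done throughout) is the intended usage.
- Only the three canonical coupling placements are presets; other cycle
  topologies can be expressed through the generic solver but have no
  closed forms here.
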