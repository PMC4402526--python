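# ratchetkin

Mechano-chemical kinetics of processive DNA replication under load.

`ratchetkin` is a toolkit for single-molecule biophysicists analyzing
optical-tweezers experiments on replicative DNA polymerases (the model
system is the bacteriophage Phi29 DNA polymerase replicating a template
with a 229 nt single-stranded stretch followed by a 3487 bp duplex). It
answers the question: *at which point of the nucleotide-incorporation
cycle does the enzyme move, and how does an external load change the
reaction?*

## The model

The incorporation cycle is a unicyclic Markov scheme with a single
load-coupled step. Each load-dependent rate follows the Bell/Arrhenius
form *k(F) = k(0)·e^{F·d/k_BT}*, with *F* the signed load (aiding > 0)
and *d* the coupling distance. Three coupling hypotheses are implemented:

1. **Binding power stroke** — translocation driven by dNTP binding;
   predicts a force-independent *V*_max.
2. **PPi-release power stroke** — translocation driven by pyrophosphate
   release; predicts a force-independent *K*_M/*V*_max when the reverse
   catalytic rate is much slower than PPi release.
3. **Brownian ratchet** — the dNTP/PPi-free enzyme diffuses between pre-
   and post-translocated positions (forward/backward rates *k*_T, *k*_−T
   over distances *d*_T, *d*_−T); binding of the incoming dNTP rectifies
   the motion. Both *V*_max and *K*_M/*V*_max become load dependent:

```
1/V_max(F)        = a + b·e^{−F·d_b/k_BT}
K_M(F)/V_max(F)   = r + s·e^{−F·d_s/k_BT}
v(F, [dNTP])      = V_max·[dNTP]/(K_M + [dNTP])
```

with the algebraic dictionary *a* = 1/*k*_cat, *b* = 1/*k*_T(0),
*r* ≃ 1/*k*_on, *s*/*r* = *k*_−T(0)/*k*_T(0), *d*_b = *d*_T,
*d*_s = *d*_T + *d*_−T = δ (the mechanical step size). Every closed form
is cross-checked against a brute-force steady-state solve of the cycle's
master equation.

On top of the kinetics sit: a worm-like-chain elasticity layer converting
tether-length changes to nucleotides; a Gillespie simulator producing
realistic noisy 60 Hz traces (constant-force and force-ramp schedules,
off-pathway pauses, detachment); trace analysis (sliding-window
velocities, two-Gaussian velocity mixtures, pause detection, pause-excised
rates); and global force-velocity fitting with multi-start weighted least
squares, bootstrap uncertainties and AIC model discrimination.

## Worked example

Simulate a force-velocity dataset at the experimental design and refit it:

```bash
$ ratchetkin simulate --kind fv --seed 1 --out run1
$ ratchetkin fit run1/fv_dataset.tsv --bootstrap 50 --seed 2
model 3: weighted RSS = 70.37, AIC = 82.37
parameter          value          se
a               0.008281     0.00011
b               0.001691    0.000122
r                 0.1854     0.00393
s_coef            0.1259     0.00482
d_b               0.3394      0.0107
d_s               0.3917      0.0059
derived cycle quantities:
  k_cat                120.8
  k_T0                 591.5
  k_mT0                401.6
  k_on                 5.394
  d_T                 0.3394
  d_mT               0.05231
  delta               0.3917
  K_delta0             1.473
  dG_trans_kBT       -0.3872
```

The fit recovers the generating coefficients: a catalytic rate
*k*_cat ≈ 120 s⁻¹, a forward translocation rate several times faster, a
step size δ ≈ 0.4 nm (the B-DNA rise), and a translocation free energy of
a fraction of *k*_BT — the signature of a thermal ratchet. Model ranking
and the power-stroke signature tests:

```bash
$ ratchetkin discriminate run1/fv_dataset.tsv --seed 3
model 3: AIC = 82.37 (RSS 70.37)
model 2: AIC = 2516 (RSS 2504)
model 1: AIC = 6507 (RSS 6497)
log(1/Vmax) vs F: slope -0.02289 CI (-0.02351, -0.02213) -> force-dependent
log(KM/Vmax) vs F: slope -0.04985 CI (-0.05044, -0.04913) -> force-dependent
```

Both Michaelis-Menten parameters are load dependent, which rules out both
power-stroke models. Predictions from the reference coefficients:

```bash
$ ratchetkin predict
k_cat=119/s k_T0=667/s k_mT0=421/s delta=0.40 nm
rupture force @ 2 uM: no root (v0 <= v_detach)
rupture force @ 10 uM: 22.1 pN
rupture force @ 500 uM: 49.3 pN
```

i.e. at saturating dNTP the enzyme keeps replicating against ~50 pN of
hindering load before the 7 nt/s detachment criterion is reached —
about 17 pN·nm (~4 k_BT) of work per incorporated nucleotide.

`ratchetkin simulate --kind trace` and `ratchetkin analyze` provide the
trace-level workflow (instantaneous velocities, velocity-distribution
peaks, pauses, rates with/without pauses).

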