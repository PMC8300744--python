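# Methods

## Reaction scheme and model

The package models DPPH• bleaching by an antioxidant AOH as two
irreversible second-order steps:

    AOH + DPPH•  --k1-->  AO• + DPPH-H
    AO• + DPPH•  --k2-->  products

with rate laws

    d[DPPH•]/dt = −k1[AOH][DPPH•] − k2[AO•][DPPH•]
    d[AOH]/dt   = −k1[AOH][DPPH•]
    d[AO•]/dt   = +k1[AOH][DPPH•] − k2[AO•][DPPH•]

The side-reaction products are lumped into one inert species `p2`, so the
antioxidant balance [AOH] + [AO•] + [p2] = AOH₀ is an explicit invariant.
DPPH-H is not tracked (it never feeds back). The scheme assumes a single
effective antioxidant species — an extract is treated as one pseudo-compound
— and no reverse reactions, solvent effects or photobleaching.

Internal units are molar and seconds everywhere; µM and minutes appear only
at I/O boundaries and in reports (k1 is reported in 10³ M⁻¹s⁻¹, matching
bench convention).

### Simulation

`simulate_decay` integrates the scheme with LSODA (stiff-capable,
adaptive), rtol 1e-8, atol 1e-12 M. Trial states inside the solver may dip
a few times atol below zero; the right-hand side clips them rather than
failing, and output values in (−10·atol, 0) are snapped to 0. Anything more
negative is treated as a solver defect and surfaces as an error. For the
one-reaction scheme the mixed second-order integrated rate law

    [DPPH•](t) = D₀(D₀−A₀) / (D₀ − A₀·exp(−(D₀−A₀)k1 t))

(equal-concentration case: 1/(1/c₀ + k1 t)) serves as an independent
analytic oracle; the test suite requires ODE-vs-closed-form agreement below
1e-9 M across random parameter draws.

## Estimation

### Measurement model

Absorbance at 515 nm converts to concentration by Beer–Lambert,
c = A/(ε·l), with ε = 10,870 M⁻¹cm⁻¹ (methanol) and l = 1 cm by default.
100 µM DPPH• therefore starts near 1.09 AU. Negative absorbance is clipped
to zero with a warning.

### Fitting

`DPPHKineticsEstimator` minimises the unweighted sum of squared residuals
between simulated and observed [DPPH•](t). Free parameters: (k1, AOH₀) for
the simple scheme, (k1, k2, AOH₀) for the side scheme; the integer-n scan
pins AOH₀ and frees only the rate constants. The initial DPPH• is fixed to
the nominal 100 µM by default; `fix_dpph0=False` reads it off the first
point instead, absorbing mixing dead-time.

Parameters are optimised as log10 values (k2 as log10(k2 + 1e-3) so that
k2 = 0 is reachable) under bounds k1 ∈ [1, 1e8], k2 ∈ [0, 1e6] M⁻¹s⁻¹,
AOH₀ ∈ (0, 20×AOH_known]. A trust-region reflective least-squares solver
(ftol = xtol = 1e-12) runs from 5 starts: one heuristic (k1 = 10³, k2 = 10,
AOH₀ = half the observed DPPH• loss) plus a seeded Latin-hypercube draw
over the log-bound box; the lowest-SSR solution wins. Starts that diverge
(integration failure at extreme rates) are discarded; only if every start
fails does the fit raise. Parameters landing on a bound trigger a warning.

Goodness of fit is R² = 1 − SSR/SStot about the observed mean, computed on
the concentration trace; negative values (worse than the mean) are reported
as-is, and a constant observed series is an error rather than R² = 1.

### Stoichiometric factors

Two routes, which agree within 1% when the simple reaction runs to
completion under radical excess:

* ratio definition: n = AOH₀(fitted)/AOH(known);
* graphical: n = (DPPH•(0) − DPPH•(t_end))/AOH(known), with a warning when
  the final slope still exceeds 1% of the initial slope (no plateau).

Panel aggregate n is the mean over the two lowest antioxidant
concentrations — only there is DPPH• in enough excess for n to reflect
stoichiometry rather than radical limitation — rounded half-up to one
decimal (half-up, not banker's: the reported one-decimal values depend on
it). The integer scan refits with AOH₀ = n·AOH_known for each candidate n
and returns the R²-maximising n, ties breaking toward the smaller value
with a warning.

### Model selection

The simple scheme is nested in the side scheme (k2 = 0), so the choice uses
an extra-sum-of-squares F-test with 1 numerator degree of freedom at
α = 0.05, plus a practical floor: the side model is only accepted when
k2̂ > 0.5 M⁻¹s⁻¹ (below the smallest side-reaction constant worth
reporting). Whether residuals should be weighted is unknown for this assay;
unweighted least squares is assumed.

### Rate–concentration trend

The fitted k1 falls as the antioxidant concentration rises; 1/k1 is close
to linear in concentration. `inverse_rate_regression` reports the OLS
slope, intercept and R² of that line. The package fits k1 per trace and
reports the trend without modelling its mechanistic origin.

## Synthetic data

The generator is the exact inverse of the estimation chain:
`simulate_decay` → Beer–Lambert → additive Gaussian noise N(0, σ²) on the
absorbance, clipped at 0 AU, seeded. Defaults emulate the standard
protocol: 100 µM DPPH•, antioxidant series 10–800 µM, 1 Hz sampling, 3–5
minute windows, σ = 0.003 AU (≈0.3% of the ~1.1 AU start — chosen so that
fitted-parameter scatter stays well inside the ~20% replicate variability
typical of the assay; the true instrument noise is a configuration value,
not a claim). Ground truth is emitted as a JSON sidecar next to every
synthetic trace.

What the generator does **not** emulate: instrument drift, mixing
dead-time, photobleaching, multi-species extract mixtures, or any
concentration dependence of k1 itself (each trace is generated at one k1).
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the stated noise model, not robustness to un-modelled
instrument effects in real data.

## Exact-mass annotation

Candidate products are enumerated from the antioxidant's elemental
composition: monomer M, quinone M−2H, dimers 2M−2H (and the deeper 2M−4H
dehydrogenation, kept only in methanol-adduct form, where it is observed
for chlorogenic acid); each base may couple covalently with DPPH at
hydrogen offsets δ ∈ {−1, 0, +1} relative to the plain sum — H-transfer
and radical-recombination pathways differ by H₂, and observed adducts occur
at more than one offset — and any species may additionally gain CH₃OH
(solvent) and/or HCOOH (eluent additive). Candidates are de-duplicated by
composition.

Theoretical m/z uses monoisotopic atomic masses (NIST table via pyteomics)
and **includes the electron mass** (0.00054858 Da): [M−H]⁻ = M − m_H + m_e,
[M]•⁻ = M + m_e. Both ion types are tried for every candidate because
negative-mode spectra of these products mix deprotonated molecules with
radical anions (DPPH itself ionises as [M]•⁻). Matching takes the
minimum-|ppm| candidate within a 5 ppm default tolerance — observed
theoretical-vs-experimental gaps in this product family are ≤ ~1.5 ppm.

Known limitations: one published product, "oxidized Trolox" at m/z
265.1082, carries an internally inconsistent formula as printed (C14H18 ≈
186 Da) and is flagged rather than reproduced (M+O oxidation, which would
fit, is outside the enumeration rules); isotope patterns, retention times
and MS² fragments are out of scope.

## Problem sizes and determinism

Recovery tests use 1 Hz traces of 3–5 simulated minutes (181–301 points),
the scale of a real cuvette run. The noisy-recovery property uses 50
replicates at σ = 0.003 AU with 2 optimizer starts per fit — the heuristic
start plus one drawn — which the noiseless benchmarks show is sufficient
for this 3-parameter problem. All randomness (noise streams, multi-start
draws) flows from explicit integer seeds; repeated runs are bit-identical.
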