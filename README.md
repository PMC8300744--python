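# dpphkin

Stoichio-kinetic analysis of the DPPH• radical-scavenging assay.

The DPPH assay is the workhorse spectrophotometric test of antioxidant
activity: the stable purple radical DPPH• (2,2-diphenyl-1-picrylhydrazyl)
absorbs at 515 nm, and its absorbance decays as an antioxidant AOH donates
hydrogen atoms. Single-point summaries (EC50, % inhibition) discard the
kinetics entirely; `dpphkin` instead fits a mechanistic reaction scheme to
the whole decay trace:

    AOH + DPPH•  --k1-->  AO• + DPPH-H        (main scavenging step)
    AO• + DPPH•  --k2-->  products             (side reaction)

Both steps are second order. Fitting the simulated [DPPH•](t) to the
observed trace by nonlinear least squares yields the rate constants k1 (and
k2 when the side reaction is active), the effective initial antioxidant
concentration AOH₀, and from it the **stoichiometric factor**

    n = AOH₀(fitted) / AOH(known),

the number of DPPH• radicals quenched per antioxidant molecule. For an
extract, the same fit referenced to the Folin–Ciocalteu total-phenol
content (gallic-acid equivalents) gives the apparent factor n′.

The package also annotates the oxidation products seen in negative-mode
LC-MS: it enumerates quinones, dimers, covalent DPPH-coupling adducts and
methanol/formic-acid adducts from an elemental formula, computes exact
monoisotopic m/z for [M−H]⁻ and [M]•⁻ ions (electron mass included), and
matches observed m/z lists within a ppm tolerance.

Intended users: food chemists and natural-product researchers running DPPH
assays who want mechanism-aware rate constants and stoichiometries instead
of single-point inhibition numbers.

## Worked example

Simulate a gallic-acid-like decay (k1 = 1.13×10³ M⁻¹s⁻¹, k2 = 145 M⁻¹s⁻¹,
29 µM effective antioxidant vs 100 µM DPPH•, σ = 0.003 AU noise), then let
the estimator pick the scheme and recover the parameters:

```python
import dpphkin as dk

params = dk.RateParameters(k1=1.13e3, k2=145.0)
init   = dk.InitialState(dpph0=100e-6, aoh0=29e-6)
grid   = dk.TimeGrid.regular(180.0)           # 0-180 s at 1 Hz
trace  = dk.generate_trace(params, init, grid, dk.NoiseModel(sigma=0.003, seed=0))
conc   = dk.absorbance_to_concentration(trace)

est = dk.DPPHKineticsEstimator(model="auto", dpph0=100e-6,
                               aoh_known=10e-6, seed=0)
est.fit(conc.times, conc.dpph)
```

which prints (via the fitted attributes):

```
chosen model : side
k1           : 1.12e+03 M^-1 s^-1
k2           : 142 M^-1 s^-1
aoh0 (fit)   : 29.1 uM
n (fit ratio) : 2.91
R^2          : 0.9993
```

The automatic model choice kept the side reaction (nested F-test), the rate
constants come back within a few percent of the generating values at this
noise level, and n ≈ 2.9 says each antioxidant molecule quenched almost
three radicals — the signature of a trihydroxy phenol. Pinning AOH₀ at
integer multiples of the known 10 µM and refitting profiles the
stoichiometry directly:

```python
ctx  = dk.AssayContext(100e-6, 10e-6)
scan = dk.scan_integer_n(conc, ctx, range(1, 6), dk.FitConfig(seed=0))
```

```
scan profile : {1: -3.924, 2: 0.6702, 3: 0.9993, 4: 0.9934, 5: 0.9736}
best integer n: 3
```

Only n = 3 explains the trace.

The same workflow is available from the shell:

```sh
dpphkin simulate --out-dir traces --seed 1       # synthetic panel + ground truth
dpphkin fit traces/*.csv --model auto            # k1, k2, R^2, n per trace
dpphkin scan-n traces/panel_10uM.csv             # integer stoichiometry profile
dpphkin regress-k report.csv                     # 1/k1 vs concentration OLS
dpphkin annotate C7H6O5 peaks.csv                # exact-mass product annotation
```

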