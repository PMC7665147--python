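# gaitspec

Walking is nearly periodic, so a few seconds of raw tri-axial accelerometry
from a hip-worn device carry a harmonic signature of gait: energy
concentrated at the step frequency (cadence) and its integer and
half-integer multiples. How that energy is distributed across harmonics —
a heavy stomp versus a dispersed, compensatory stride — is information that
activity-count summaries throw away. `gaitspec` is a toolkit for
epidemiologists and biostatisticians who want to use that full spectral
signature as a predictor of continuous health outcomes such as age or BMI.

The package implements two connected pieces:

**1. Order-domain spectral pre-processing.** A raw walking bout sampled at
80 Hz is split into 10 s non-overlapping windows. Each window is reduced to
its vector magnitude `vm(t) = sqrt(x1² + x2² + x3²)`, tapered with Hanning
weights, and transformed to a magnitude spectrum |X(t, f; τ)| on a fixed
0–39.9 Hz grid (0.1 Hz steps). The cadence is the largest spectral peak in
1.2–4.0 Hz. Rescaling the frequency axis by the cadence (the *order*
domain, s = f / cadence) aligns every subject's harmonics at integer
multiples; spectra are averaged across windows, restricted to 546 points on
[0.3, 5.75], and scaled to equal 1 at the fundamental. Each subject ends up
with a 546-point spectrum plus two scalars, mean cadence and mean vector
magnitude count (VMC, the within-window mean absolute deviation of vm).

**2. Penalized scalar-on-function regression.** With response yᵢ, scalar
covariates xᵢ (intercept, male, cadence, VMC) and spectrum Wᵢ(·),

    yᵢ = xᵢᵀγ + ∫ Wᵢ(s) β(s) ds + εᵢ,    εᵢ ~ N(0, σ²_ε),

the coefficient function β is estimated by generalized ridge with the
decomposition penalty L = a(I − P_Q) + P_Q, where Q spans Gaussian bells at
cadence multiples 0.5, 1.0, …, 5.5 and P_Q = QQ⁺. Directions of β outside
the harmonic subspace are penalized a²-fold harder (default a = 2; a = 1 is
plain ridge). The tuning parameter λ is the REML-estimated variance ratio
σ²_ε/σ²_β of the equivalent linear mixed model, and pointwise 95% bands come
from the mixed-model covariance σ̂²_ε (XₒᵀXₒ + λLₒᵀLₒ)⁻¹.

Because cohort accelerometry is rarely shareable, the package includes a
synthetic-cohort generator that produces quasi-periodic walking signals
(harmonic comb + gravity + device noise) and responses drawn from the model
above with known γ and β — every stage is testable end to end without any
data download.

## Worked example

Simulate a 30-subject cohort whose true coefficient function is a single
bump at order 2.5 (height 50), preprocess it, and fit the model:

```bash
cat > cfg.yaml <<EOF
simulate:
  n_subjects: 30
  duration_s: 30.0
  sigma_eps: 0.02
seed: 2
EOF
gaitspec all --config cfg.yaml --out run/
```

which prints

```
lambda = 1e-06; significant multiples: [2.5]
```

and writes `run/summary.json`:

```json
{
  "n_subjects": 30,
  "lambda": 1.0000000000000004e-06,
  "sigma_eps2": 0.0010388306198929333,
  "significant_multiples": [2.5],
  "scalar_terms": {
    "intercept": 65.2380616718109,
    "male": -1.9997214761756652,
    "cadence": -4.99078510933976,
    "vmc": 9.443690033995662
  }
}
```

Read-out: at this low noise REML selects essentially no shrinkage
(λ = 10⁻⁶), the scalar coefficients recover the generating values
(65, −2, −5, 10) to within a few percent, and the only cadence multiple at
which the pointwise band excludes zero is 2.5 — exactly where the generating
bump was placed. `run/fit_report.csv` holds β̂(s) with its band on the
546-point grid and `run/beta_hat.png` plots it. The same stages are
available separately (`gaitspec simulate | preprocess | fit`) and as library
functions (`process_bout`, `assemble_design`, `fit_functional_model`, …).

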