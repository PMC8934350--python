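# levyrisk

A one-dimensional, parameter-free model of lifetime cancer risk in gene
expression space.

## The problem

Small portions of a tissue (a colon crypt, say) define *microstates* in gene
expression (GE) space: each biopsy is a point whose coordinates are per-gene
log2 fold changes ê = log₂(e/e_ref) relative to a geometric-mean reference
over healthy samples. Projected on the first principal axis of the sample
covariance — the "cancer axis" — normal samples cluster around the origin
with r.m.s. radius Rₙ while tumor samples form a distant cloud centered at
x̄₁ with radius Rₜ. For a microstate to become cancerous, its coordinate x₁
must travel the minimal walk length

    R = x̄₁ − Rₙ − Rₜ.

Per stem-cell generation the microstate fluctuates by at most the largest
PC1 loading, D = max|v₁ᵢ|. Two transport mechanisms compete:

* **Brownian**: steps δx₁ = D·r, r ~ U(−1, 1). The escape probability after
  t generations is Erfc(√2·R/(D√t)), giving the regression
  ln(risk/N_sc) = const + ln(D√t/R) − 2(R/(D√t))².
* **Lévy jumps**: rare (rate μ) jumps with a Pareto tail π(Δx₁) ∼ 1/|Δx₁|^ν.
  At ν = 2 the risk is N_sc·μ′·(D/R)·t, i.e.
  ln(risk/N_sc) = const + ln(D·t/R).

Time is counted in stem-cell generations, t = t₀ + m_sc·age, where
t₀ = log₂(N_sc) covers tissue development and m_sc·age the lifetime
turnover. On a compiled table of 8 tissues with complete data (geometry,
stem-cell counts N_sc, turnover rates m_sc, registry lifetime risks) the
Lévy regression has slope ≈ 0.82 — close to the predicted 1 — while the
Brownian regression is flat (slope ~ 10⁻⁵): small-amplitude expression
noise cannot produce the observed risks; rare large jumps can. The
rescaling ERS = (risk/N_sc)/(a_ref·t) with a_ref = 2×10⁻¹⁴ scores how much
a tissue's risk exceeds the pure replication-noise expectation.

The package is aimed at quantitative cancer-biology and biostatistics work:
it ships the compiled tissue table, the closed-form predictors, the OLS
regression machinery (Model/Results style), a stochastic Lévy-flight
simulator that validates the closed forms, and synthetic-data generators
for offline testing of the geometry pipeline.

## Worked example

```python
>>> from levyrisk import load_reference_table, TissueRiskRegression
>>> table = load_reference_table()          # 15 tissues, 8 complete
>>> res = TissueRiskRegression.from_table(table, model="levy").fit()
>>> print(res.summary())
Levy-model risk regression (ln(risk/N_sc) ~ predictor)
============================================================
tissues (8): BRCA, COAD, ESCA, HNSC, LIHC, LUAD, PRAD, THCA
slope        0.822897  (SE 0.332)
intercept   -22.3445  (SE 0.745)  [negative, consistent with rare jumps]
Pearson r    0.7108   r^2 0.5052
p-value     0.04812981789235412
```

The slope near 1 says the per-stem-cell risk is proportional to D·t/R, as
the rare-jump mechanism predicts; the negative intercept is the log of the
small effective jump rate μ′. The Brownian alternative on the same table:

```python
>>> TissueRiskRegression.from_table(table, model="brownian").fit().slope
2.1745027188739168e-05
```

— more than four orders of magnitude flatter than the Lévy fit, the model's headline
contrast. Extra risk scores from the command line:

```
$ levyrisk ers
tissue  ers       band
BRCA    1.4067    normal
COAD    1.8168    normal
ESCA    11.5714   high
...
```

COAD sits in the 1 < ERS < 6 band expected when replication noise alone
drives risk. (ERS values computed from this table differ from scores
computed from other risk compilations; the score is linear in the risk
input used.)

The same interface drives the simulator and generators, e.g.
`levyrisk simulate --config sim.yaml --out summary.json` or
`levyrisk synth table --spec spec.yaml --out table.tsv`; see
`levyrisk --help`.

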