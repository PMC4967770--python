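# irtcal

Psychometric calibration of ordinal mental-health questionnaires with
multidimensional item response theory.

## The problem

Population surveys routinely field several short self-report instruments —
a common-mental-disorder screen (GHQ-12, 12 four-category items), a mental
well-being scale (WEMWBS, 14 five-category items) and a health-related
quality-of-life profile (EQ-5D, 5 three-category items) — and policy
debates treat their scores as measures of different constructs.  Whether
they actually *are* different constructs is an empirical question: if one
dominant dimension explains most of the item covariance, the instruments
are largely interchangeable readouts of the same latent quantity.

`irtcal` implements the full analysis pipeline for answering that question
on pooled multi-wave survey data:

1. **Measurement model.** Samejima's logistic graded response model (GRM):
   for item *j* with ordered categories *c* = 0..C−1 and latent factor
   vector θ,

       P(Y_j ≥ c | θ) = σ( Σ_k a_jk θ_k − b_jc ),

   category probabilities being adjacent differences of these cumulative
   curves.  Standardized loadings use the λ = (a/1.7)/√(1 + Σ(a/1.7)²)
   bridge to the correlation metric.
2. **Estimation.** Full-information marginal maximum likelihood via
   Bock–Aitkin EM with Gauss–Hermite quadrature.  Missing responses —
   including *planned* missingness, where an entire instrument is absent
   from one survey wave — drop out of each person's likelihood (MAR).
   Bifactor models use dimension reduction (outer integral over the
   general factor × independent low-dimensional block integrals), so the
   six-factor model is tractable on a laptop.
3. **Candidate models.** Model 1: one factor for all 31 items.  Model 2:
   exploratory three-factor model, geomin-rotated (gradient projection).
   Model 3: confirmatory bifactor (general + one specific factor per
   instrument).  Model 4: model 3 plus two method factors (negatively
   worded GHQ items; social/interest WEMWBS items).
4. **Selection and validation.** BIC = −2LL + p·ln n and adjusted BIC =
   −2LL + p·ln((n+2)/24) on a person-disjoint estimation half; the winner
   is re-evaluated on the validation half with all parameters fixed
   (p = 0, BIC = −2LL) or with one freed variance per factor.
5. **Interpretation.** Salient-loading tables (|λ| ≥ 0.40), test/partial
   information functions I(θ) on the general dimension, and omega
   reliabilities: ω (all factors), ω_h (general only) and per-instrument
   ω_s (specific variance with the general factor partialled out).

A synthetic-data module generates study-shaped datasets with known truth —
three waves of 7255/7246/4789 respondents (19 290 pooled), the GHQ-12
absent from wave 2, up to two respondents per household, and a
household-aware sample split — so the whole pipeline can be exercised
end-to-end and checked against its generating parameters.

## Worked example

```python
import irtcal

plan = irtcal.default_plan(seed=11)          # study-shaped synthetic design
data, truth = irtcal.generate(plan)          # 19 290 persons, 31 items
est, val = irtcal.split_sample(data, seed=5)

spec = irtcal.model4_spec(data.codebook, max_iter=100, tol=0.01)
res = irtcal.fit_bifactor(est, spec)
print(res.n_params, res.converged, round(res.bic, 1))

omega = irtcal.omega_decomposition(res.loadings, spec, data.codebook)
print(omega.to_text())
```

Output from this exact run:

```
175 True 576040.9
omega   (all factors)    0.971
omega_h (general only)   0.816
GHQ-12     omega  0.953   omega_s  0.174
WEMWBS     omega  0.953   omega_s  0.328
EQ-5D      omega  0.853   omega_s  0.705
```

Reading: 175 free parameters (102 thresholds + 73 loadings), and the sum
score over all 31 items is almost entirely reliable (ω = 0.97) with most
of that due to the single general factor (ω_h = 0.82).  The GHQ-like items
carry almost no specific variance once the general factor is removed
(ω_s = 0.17), the WEMWBS-like items somewhat more, and the EQ-5D-like
items the most — i.e. only the quality-of-life instrument measures much of
anything beyond the shared dimension, which is the pattern the generator
builds in.

The same analysis, end to end, from a shell:

```bash
irtcal run-all --seed 11 --out results/demo          # or: python -m irtcal.cli
```

writes `comparison.csv` (model ranking), `crossval.csv`, per-model loading
tables with salience flags, `omega.json`/`omega.txt`,
`information_curves.csv` (total and per-instrument partial information on
the standardized general dimension) and a `manifest.json` recording the
seed and config hash.

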