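# watergrade

Surface-water quality assessment for river monitoring data: **which
indicators matter**, and **what class is this water**?

River monitoring records carry seven routine indicators — dissolved oxygen
(DO, mg/L), temperature (°C), turbidity (NTU), ammonia nitrogen (NH₃-N,
mg/L), permanganate index (COD_Mn, mg/L), pH and total dissolved solids
(TDS, mg/L) — and China's surface-water standard GB3838-2002 grades each
sample into six ordinal categories (I, II, III, IV, V, poor V). `watergrade`
implements a two-stage assessment method for analysts working with such
data:

1. **Weighted grey relational analysis for indicator selection.** Grey
   relational analysis scores how closely each (min-max normalized)
   indicator series x_j tracks the quality-class series x₀ through the grey
   relational coefficient

   s_j(i) = (Δmin + ρ·Δmax) / (Δ_j(i) + ρ·Δmax),  Δ_j(i) = |x₀(i) − x_j(i)|,

   with ρ = 0.5 and Δmin/Δmax pooled over all indicators and samples.
   Instead of the classical equal-weight average, each indicator's mean
   coefficient is weighted by a **combination weight**
   ω_j = (α_j + β_j)/2, where α comes from an AHP pairwise comparison matrix
   on Saaty's 1–9 scale (subjective, with consistency-ratio checking) and β
   from CRITIC (objective: column dispersion σ_j times conflict
   Σ_l (1 − r_jl)). Indicators are ranked by the weighted relational degree
   r(j) = ω_j · mean_i s_j(i) and the top q (default 4) become model inputs.

2. **PSO-tuned one-vs-one multiclass SVM.** One soft-margin binary SVM per
   class pair — k(k−1)/2 = 15 classifiers for six classes — votes on each
   sample; ties fall back to summed decision values, then the lowest class.
   The RBF kernel exp(−‖x−y‖²/r²) has its hyperparameters (C, r) tuned by a
   particle swarm (c₁ = 1.6, c₂ = 2, inertia ω = 0.9 − 0.4·t/T_max)
   minimizing the stratified 5-fold cross-validated error rate on the
   training split.

Evaluation reports accuracy, macro precision/recall and RMSE on the ordinal
class encoding I..poor V → 1..6. Because national monitoring data are not
redistributable, the package includes a first-class synthetic generator
whose indicator ranges match published monitoring summaries and whose labels
are induced by the GB3838-2002 class limits, so the whole method is testable
end to end.

## Worked example

```python
from watergrade import RunConfig, SynthConfig, run

report = run(RunConfig(
    synth=SynthConfig(n_per_class=100, seed=33),   # 600 samples, 6 classes
    swarm_size=50, t_max=50, tol=1e-3, patience=10, seed=7,
))
print(", ".join(report.selected))
print(report.kernel)
print(report.evaluation.to_dict())
```

prints

```
tds, codmn, do, nh3n
KernelSpec(kind='rbf', C=96.68..., r=0.07443..., d=None)
{'accuracy': 1.0, 'precision_macro': 1.0, 'recall_macro': 1.0,
 'precision_micro': 1.0, 'recall_micro': 1.0, 'rmse': 0.0}
```

The selection stage recovers exactly the four indicators that carry class
bands in the standard (TDS, COD_Mn, DO, NH₃-N) — the ones that actually
determine the labels — and the tuned classifier grades all 120 held-out
samples correctly (RMSE 0 on the ordinal scale). The `examples/` directory
has one short script per capability: generation + grading, indicator
selection, swarm tuning, and the full workflow.

A thin CLI wraps the same API:

```sh
watergrade synth --out river.csv --n-per-class 100 --seed 1
watergrade select --input river.csv --q 4
watergrade run --config config.yaml --outdir artifacts/
```

Every run writes a `manifest.json` from which it can be replayed
byte-identically.

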