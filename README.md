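# scarmorph

Fiber morphometry and machine-learning classification of label-free
multiphoton skin-tissue images.

Keloid scars invade healthy skin beyond the original wound margin, and
deciding where scar tissue ends matters for treatment. Multiphoton
microscopy images the two main extracellular-matrix fiber systems without
staining — collagen via second-harmonic generation (SHG) and elastin via
two-photon excited fluorescence (TPEF) — and the fiber architecture differs
sharply between normal dermis (long, continuous fibers), keloid scar
(short, discrete, disordered fibers) and the scar-adjacent border (highly
ordered fibers). `scarmorph` turns paired SHG/TPEF images into a
quantitative diagnosis pipeline for researchers working on scar
morphometry:

- **28 features per sample** (14 per channel): morphology — density,
  fiber length, fiber width, and alignment `k` from a semicircular
  von Mises fit f(θ; μ, k) = e^{k cos 2(θ−μ)} / (π I₀(k)) to the
  FFT-derived orientation distribution; 6 intensity-histogram statistics;
  4 gray-level co-occurrence (GLCM) statistics.
- **MRMR feature ranking**: greedy maximization of
  I(xⱼ; c) − (1/|S|) Σ_{xᵢ∈S} I(xⱼ; xᵢ) with plug-in mutual information
  on quantile-binned features, plus the 28 nested top-n subsets.
- **Classification**: a one-vs-rest linear SGD model (modified-Huber
  loss, elastic-net penalty, α = 0.001, constant learning rate
  η₀ = 0.01) with fold-wise standardization, leave-one-out
  cross-validation, a repeat-averaged accuracy sweep over the 28
  subsets, and per-class one-vs-rest ROC/AUC.
- **A synthetic cohort simulator** that reproduces the study design
  (16 scar + 10 normal sections, adjacent regions from 8 specimens, 2–3
  imaged regions per section) with class-specific fiber geometry, so the
  entire pipeline is testable and reproducible without patient data.

`MRMRRanker` follows the scikit-learn estimator contract
(`fit`/`transform`, `ranking_`, `relevance_`) and composes with sklearn
pipelines; the classifier stage is a sklearn `Pipeline` built from
`SGDConfig`. See `docs/methods.md` for the models, defaults and
limitations.

## Worked example

```python
import scarmorph as sm
from scarmorph.features import build_cohort_table, FEATURE_NAMES
from scarmorph.classify import SGDConfig, loo_evaluate, roc_auc
from scarmorph.mrmr import discretize, mrmr_rank

cohort = sm.generate_cohort(sm.CohortDesign(master_seed=1))   # 34 samples
table = build_cohort_table(cohort)                            # 34 x 28 + labels

print(table.groupby("class_label")[["E-length", "E-alignment"]].mean().round(2))

ranking = mrmr_rank(discretize(table, bins=4))
print("top-ranked feature:", ranking.ranked_features[0])

acc, scores = loo_evaluate(table, FEATURE_NAMES, SGDConfig(), seed=7)
aucs = {c: r["auc"] for c, r in roc_auc(scores).items()}
print(f"LOO accuracy: {acc:.3f}, one-vs-rest AUCs: {aucs}")
```

prints

```
             E-length  E-alignment
class_label
adjacent        62.56         5.21
normal          51.57         2.04
scar            33.13         0.50
top-ranked feature: C-density
LOO accuracy: 1.000, one-vs-rest AUCs: {'adjacent': 1.0, 'normal': 1.0, 'scar': 1.0}
```

Reading the numbers: simulated scar elastin is fragmented (traced length
33.1 px vs 51.6 px in normal tissue) and disordered (alignment k = 0.50
vs 2.04), while the adjacent border is strongly ordered (k = 5.21) — the
qualitative signature of keloid tissue. On this synthetic cohort the
classes separate completely, so leave-one-out accuracy and all three
one-vs-rest AUCs are 1.0; that validates the pipeline wiring, not
clinical performance (see `docs/methods.md`).

The same run is available from the shell:

```
scarmorph run --seed 1 --outdir results/demo
```

which writes the cohort TIFFs with `manifest.csv`, `features.csv`,
`ranking.csv`, the subset-sweep table, per-class ROC curves,
`report.json` and `run_meta.json`. Stages can be run separately
(`scarmorph simulate / extract / rank / evaluate`) and compose to
byte-identical artifacts given the same seed.

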