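# painfeat

Automated recognition of heat-pain intensity from biopotential recordings.

Clinically, pain is still assessed by self-report, which fails for sedated,
ventilated or cognitively impaired patients. A machine-learning surrogate
measure can be built from autonomic and muscular signals: facial and
trapezius electromyography (EMG), skin conductance level (SCL) and the
electrocardiogram (ECG) all respond to noxious heat in a graded way.
`painfeat` implements a complete, reproducible pipeline for this problem:

1. **Protocol simulation** — a seeded generator emulating a calibrated
   heat-pain experiment: per subject, four temperature levels (T1 = pain
   threshold … T4 = pain tolerance) each applied 20 times in randomized
   order with 4 s plateaus and 8–12 s pauses, plus 20 stimulus-free
   baseline (B) stretches; five channels with class-dependent physiology
   (EMG burst gains, phasic skin-conductance responses, RR-interval
   shortening) and realistic nuisance structure (non-response trials,
   spontaneous responses, per-subject baseline scales).
2. **Preprocessing** — zero-phase Butterworth filters (EMG 20–250 Hz, ECG
   0.1–250 Hz), empirical-mode-decomposition denoising of the EMG,
   Hilbert-envelope burst detection, cutting of labelled 5.5 s windows and
   R-peak / RR-interval extraction.
3. **Feature extraction** — 159 features per window over seven mathematical
   groups (40 amplitude, 24 frequency, 24 stationarity, 20 entropy,
   8 linearity, 19 variability, 24 similarity), with similarity measured
   against the subject's mean baseline signal, followed by per-person
   z-normalization.
4. **Feature selection** — removal of static and sentinel-carrying columns,
   greedy pruning of features correlated at |r| ≥ 0.95, then forward
   selection wrapped around an RBF-SVM scored by 3-fold cross-validated
   accuracy (stops at the first round with no strict improvement).
5. **Classification and validity** — RBF-SVM with an exhaustive grid search
   over C = 2⁻⁵, 2⁻³, …, 2¹⁵ and γ = 2⁻¹⁵, 2⁻¹³, …, 2³ on a stratified
   75/25 split; evaluation reports the confusion matrix, accuracy,
   per-class sensitivity/specificity (one-vs-others) and Cramér's V
   (V = √(χ²/(n·(min(r,c)−1)))) with its interpretation band.

## Worked example

```python
from painfeat.pipeline import PipelineConfig, build_feature_matrix
from painfeat.classify import PainClassificationTask, SplitSpec
from painfeat.simulate import SimConfig

cfg = PipelineConfig(sim=SimConfig(n_subjects=10, rng_seed=7),
                     keep_classes=("B", "T1", "T4"))
matrix = build_feature_matrix(cfg)          # 600 windows x 159 features
task = PainClassificationTask(matrix, "B_vs_T4", split=SplitSpec(rng_seed=7))
print(task.fit().summary())
```

```
Pain classification task: B_vs_T4
==============================================
train / test vectors     300 / 100
selected features        2
SVM (C, gamma)           (0.03125, 0.5)
CV accuracy (train)      1.0000
test accuracy            0.9900
Cramer's V               0.9802 (very strong)
----------------------------------------------
class   sensitivity   specificity
B           0.9800        1.0000
T4          1.0000        0.9800
----------------------------------------------
selected: SCL_Frequency_ZeroCrossings, SCL_Frequency_MeanFrequency
```

Read: of 100 held-out windows, 99 % are classified correctly; baseline vs.
pain tolerance separates almost perfectly on this synthetic dataset —
here via skin-conductance frequency features, which pick up the smooth
phasic response riding on the noisy tonic trace. The same pipeline on
`"B_vs_T1"` (pain threshold) is markedly harder — around 0.65–0.85
accuracy across seeds (0.67, V = 0.35 on this one) — reproducing the
expected difficulty ordering of the levels.

The same stages are scriptable from the shell:

```bash
painfeat simulate  --config cfg.yaml --out data/
painfeat extract   --in data/ --out features.tsv
painfeat train-eval --features features.tsv --task B_vs_T4 --out report.json
painfeat run-all   --config cfg.yaml --out run/
```

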