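# landcnn

Simulation-based landscape-genetics model selection: which landscape
features — terrain steepness, rivers, Late-Quaternary habitat shifts,
environmental niche suitability — shaped gene flow in a set of sampled
populations, or does plain geographic distance explain the data?

The package is written for landscape geneticists who want to compare
spatially explicit hypotheses with a supervised-learning workflow instead
of summary-statistic regression.  Each hypothesis (model) is a weighted
combination of predictor rasters composed into a resistance surface;
least-cost distances `x` among demes become per-generation migration rates
via the cubic decay

    m_ij = d · (1 / x_ij)^3,

with a dispersal scalar `d`.  SNP data are simulated under an island-split
coalescent (an ancestral population splits into 39 demes 21,000 generations
ago; epoch-wise migration matrices track time-varying landscapes), encoded
as deterministic binary images (rows = haploid sequences grouped by deme,
columns = SNPs sorted by minor-allele frequency, major allele 0 / minor 1),
and classified by a small convolutional network (conv 3×1 → pool 3×1 →
conv 3×1 → pool 3×1 → dense 100 → dense 40 → softmax over the 12 candidate
models; Adam, cross-entropy, batch 100, 10 epochs).  The trained classifier
assigns an empirical image a probability for each landscape model, and its
reliability is reported through a confusion matrix, per-model
precision/recall and a five-bin softmax calibration table.

Everything runs on synthetic landscapes — no downloads, no GIS stack —
while keeping the full-scale study design (39 demes, 9 sampled with 52
individuals, 4364 SNPs) available.  See `docs/methods.md` for the model,
priors and numerical conventions.

## Worked example

The numbered scripts under `analysis/` run the pipeline at a reduced scale
(12 demes, 6 sampled, 500 SNPs, 3 contrasted models: distance vs. strong
slope vs. strong rivers):

```bash
python analysis/01_generate_landscape.py --seed 1   # demes + 5 predictor stacks
python analysis/02_build_migration.py    --seed 1   # 12 models -> schedules
python analysis/03_simulate_corpus.py    --seed 1   # 300 labeled SNP images
python analysis/04_train_classifier.py   --seed 1   # train/evaluate/predict
python analysis/05_sampling_design.py    --seed 11  # sampling-scheme study
python analysis/06_summary_stats.py      --seed 1   # F_ST, He/Ho, PCA check
```

`04_train_classifier.py` prints (seed 1):

```
Trained on 240 images, tested on 60.
Overall accuracy: 75.0%
Confusion (rows=true, %):
      1      2     3
1  80.0    0.0  20.0
2   0.0  100.0   0.0
3  55.0    0.0  45.0
Stand-in empirical dataset (simulated under model 3): selected model 3
with probabilities {'1': 0.4169, '2': 0.008, '3': 0.5751}
```

Model 2 (slope) is recovered perfectly — a strong slope field reshapes
every pairwise distance.  Models 1 (distance) and 3 (rivers) partially
overlap because a narrow channel changes only the deme pairs it separates.
The held-out image, treated as an "empirical" dataset, is assigned to its
true generating model.

`05_sampling_design.py` shows why sampling design matters (seed 11):

```
scheme ( 9 demes,  2 seq/deme): accuracy  29.6%
scheme ( 9 demes, 20 seq/deme): accuracy  55.6%
scheme (12 demes,  2 seq/deme): accuracy  33.3%
scheme (12 demes, 20 seq/deme): accuracy  59.3%
```

— accuracy rises with both the number of sampled demes and the sequences
per deme, the same ordering the full-scale study reports.

`06_summary_stats.py` confirms the migration model behaves: mean pairwise
F_ST falls monotonically as the dispersal scalar rises (0.990 at d = 0.02
down to 0.858 at d = 0.30 on the reduced layout), and an
isolation-by-distance dataset projects inside the PCA cloud of 30 datasets
simulated under the same model.

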