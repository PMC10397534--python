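# combosyn

Multitask, multimodal prediction of drug-pair synergy in cancer cell lines.

Anticancer drug combinations can inhibit tumour growth more selectively than
single agents, but the space of candidate pairs is far too large to screen
experimentally.  `combosyn` is a deep-learning tool that predicts whether a
pair of drugs acts synergistically in a given cell line, for computational
chemists and bioinformaticians prioritising combination screens.  It consumes
five plain-text tables:

1. a synergy triple table — `(drug1, drug2, cell line)` with a continuous
   synergy score (e.g. ZIP) and/or a binary label,
2. a drug catalog mapping drug ids to SMILES strings,
3. a protein–protein interaction (PPI) edge list,
4. a cell–protein association matrix `Cpc` (proteins × cells),
5. a drug–target interaction (DTI) table of known **active** pairs.

## Model

Each drug's SMILES string is tokenized, segmented into overlapping patches
(patch size 40, overlap ratio ½ by default) and encoded by a shared
transformer into a vector **o**<sub>F</sub>.  The PPI graph is embedded with
biased random walks + skip-gram (node2vec), reduced to `Pc` protein clusters
by k-means, and mapped through self-attention + MLP into the drug space,
giving cluster representations **o**<sub>pm</sub>.  A drug's binding-affinity
profile is **o**<sub>B</sub> = σ(**o**<sub>pm</sub> **o**<sub>F</sub>), one
affinity per protein cluster.  Binding profiles are fused with each other and
with the cell line's cluster-level protein vector, and a final MLP outputs
the synergy probability *o*.

Training is multitask:

```
L = L_synergy + λ₁·L_toxic + λ₂·L_compactness + λ₃·L_descriptive
```

* `L_synergy` — binary cross-entropy of *o* against the synergy label
  (scores are binarised at the conventional ZIP threshold of 10, strict);
* `L_toxic` — mean of **o**<sub>B,d1</sub>·**o**<sub>B,d2</sub>/Pc, penalising
  overlapping target profiles of the two paired drugs (overlapping exposure
  is associated with toxicity; safe synergistic pairs bind disjoint targets);
* `L_descriptive` + `L_compactness` — a one-class pair for the DTI task,
  usable when only active drug–target pairs are labelled: cross-entropy on
  active affinities plus the variance of the drug-feature batch.

The ablation variants (`transformer`, `transformer_toxic`,
`transformer_dti`, `full`) are pure weight masks of the λ's.

There is no GPU framework dependency: the network runs on a compact numpy
reverse-mode autodiff engine (`combosyn.autodiff` / `combosyn.nn`) with Adam,
single-threaded and bit-reproducible under a seed.

## Worked example

A synthetic study with a planted, recoverable mechanism (drugs bind protein
modules; a pair is synergistic in a cell iff both drugs hit the cell's active
modules with disjoint target sets; 5% label noise):

```python
from combosyn import (SynthConfig, generate_dataset, SynergyModel,
                      ModelConfig, make_kfold)

study = SynthConfig(n_samples=2000, n_drugs=40, n_proteins=200,
                    n_clusters_true=10, label_noise=0.05, seed=1)
bundle, truth = generate_dataset(study)

model = SynergyModel(bundle, ModelConfig.tiny())
plan = make_kfold(bundle.samples, k=5, seed=1)
train_idx, test_idx = plan.folds[0]
results = model.fit(train_idx=train_idx, test_idx=test_idx, seed=1)
print(results.summary())
```

prints

```
Synergy model fit
=================
variant:        full
seed:           1
train samples:  1600
epochs run:     50 (best at 41)
final train loss: 0.4462
best val synergy loss: 0.3454
test samples:   400
  ACC     0.8000
  Recall  0.7733
  F1      0.7688
  AUC-ROC 0.8681
  AUC-PR  0.7967
```

The model recovers the planted rule well above chance on the held-out fold
(AUC-ROC 0.87 against a 0.95 noise ceiling); `results.loss_frame()` exposes
the per-epoch loss components, and
`model.cross_validate(plan)` pools metrics over all folds.  Leave-one-cell-
line-out evaluation (`make_loco`), grid search over the printed
hyperparameter grids (`GridSpec`), and paired t-test model comparison
(`compare_models`) follow the same pattern.

## Command line

```bash
combosyn synth --seed 1 --out data/           # write the five input files
combosyn prepare   --config cfg.yaml --seed 1 --out prep/
combosyn train     --config cfg.yaml --seed 1 --out run/
combosyn evaluate  --config cfg.yaml --seed 1 --out ev/ --protocol loco
combosyn ablate    --config cfg.yaml --seed 1 --out ab/
combosyn gridsearch --config cfg.yaml --seed 1 --out gs/ --axes patch_size,overlap_ratio
```

The YAML config names the five input paths under `data:` and may override
any block of `ModelConfig` (see `docs/methods.md`).

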