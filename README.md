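# debatch

Autoencoder-based batch-effect removal for multi-batch LC-MS expression
matrices, with batch-mixing and QC evaluation metrics, a batch-disjoint
repeated-holdout protocol, hyperparameter search, and a synthetic-data
generator for end-to-end testing.

The model zoo crosses two autoencoder types with five batch-effect-removal
strategies, giving ten families:

| | plain | batch-mapping adversarial | DANN | inverse triplet | reverse triplet |
|---|---|---|---|---|---|
| deterministic | `ae` | `ae-bmadv` | `ae-dann` | `ae-invtriplet` | `ae-revtriplet` |
| variational | `vae` | `vae-bmadv` | `vae-dann` | `vae-invtriplet` | `vae-revtriplet` |

All networks are single-hidden-layer encoder/decoder pairs with linear
label and batch classifier heads on the bottleneck `z`. The composite
objective is

```
L_total = L_rec + nu * L_classif + beta * KLD + gamma * L_BE
```

where `L_BE` is the strategy-specific batch-effect loss (adversarial
cross-entropy behind a gradient reversal layer, the GRL-free min–max
variant with a learned per-batch bottleneck offset, or an inverse/reverse
batch triplet loss). Networks run on a small numpy reverse-mode autodiff
engine (`debatch.autograd`), so no deep-learning framework is required.

## Library quick start

```python
import debatch as db

# simulate a 6-batch, 2-class dataset with a strong additive batch effect
m, truth = db.generate(db.SimulationSpec(n_batches=6, samples_per_batch=40,
                                         n_features=200, batch_additive_sd=3.0,
                                         noise_sd=1.0, seed=0))

spec = db.NormalizationSpec.from_name("standard_per_batch")
pre = db.preprocess(m, spec)                       # log1p + normalization
split = db.repeated_holdout(m, n_repeats=1, seed=0)[0]

cfg = db.ModelConfig.for_family("ae-dann", n_features=200, n_classes=2,
                                n_batches=6, layer1=64, layer2=16,
                                gamma=10.0, warmup_epochs=50,
                                normalization=spec, seed=0)
model = db.build_model(cfg)
state = db.fit(model, pre, split, scenario=2,
               tc=db.TrainerConfig(max_epochs=100, patience=100))

z = model.encode(pre.values).z
report = db.evaluate_representation(z, m)          # nBE / ARI / AMI (+ QC)
print(state.best_valid_mcc, report.nbe)
```

Training follows the two-scenario protocol: an unsupervised warmup on the
whole dataset (reconstruction, KLD, batch-effect loss), then either
scenario 1 (autoencoder frozen, only the label classifier trained) or
scenario 2 (alternating unsupervised and supervised epochs with gradients
flowing through the encoder). Early stopping monitors validation MCC
(default patience 100, max 1000 epochs, minibatch 32); class imbalance is
handled by inverse-frequency weighted sampling.

## CLI

```bash
debatch generate --out-dir data/ --n-batches 6 --batch-additive-sd 3 --seed 0
debatch split    --matrix data/matrix.tsv --annotations data/annotations.tsv \
                 --n-repeats 5 --out splits.json
debatch train    --matrix data/matrix.tsv --annotations data/annotations.tsv \
                 --family ae-dann --scenario 2 --out-dir runs/dann --seed 0
debatch evaluate --matrix data/matrix.tsv --annotations data/annotations.tsv \
                 --checkpoint runs/dann/checkpoint_repeat0.json --out report.json
```

`train` writes per-repeat evaluation reports (`reports.tsv`), a
mean ± sd summary (`summary.tsv`), loss curves, JSON checkpoints, and the
fully resolved run configuration (`config.json`). Passing
`--hyperopt-trials N` runs a seeded hyperparameter search (GP surrogate
with random fallback) over learning rate, weight decay, dropout, warmup
epochs, layer widths, label smoothing, and the conditional margin / beta
/ gamma weights plus the six normalization variants.

## File formats

* **Matrix**: delimited text (TSV default, comma autodetected), first row
  feature IDs, first column sample IDs. Empty cells are read as 0
  (zero-coded missing values); negative entries are rejected.
* **Annotations**: columns `sample_id`, `batch`, `label`, `is_qc` (0/1).
* **Checkpoints / reports**: JSON.
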