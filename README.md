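# meth4c

Prediction of DNA N4-methylcytosine (4mC) sites from 41-nt
cytosine-centred sequence windows.

The package encodes each window into a 292-dimensional feature space built
from five encoder families, ranks the dimensions by boosted-tree split
importance, selects a best-performing subset by backward elimination with
cross-validated SVM scoring, and trains an RBF-kernel SVM with calibrated
probability outputs.

| Block  | Dimensions | Encoder |
|--------|-----------|---------|
| OHB    | D1–D164   | per-position one-hot bits (A/G/T/C bit order) |
| SNF    | D165–D205 | cumulative nucleotide density |
| KNF    | D206–D225 | k-mer frequencies, k ∈ {1, 2} |
| KSNPF  | D226–D273 | k-spaced pair frequencies, k ∈ {1, 2, 3} |
| PseDNC | D274–D292 | dinucleotide composition + λ=3 tier correlations |

PseDNC uses a shipped table of 38 standardized dinucleotide
physico-chemical properties (`src/meth4c/data/dinucleotide_properties.tsv`);
pass your own table via `PseDncParams(property_table=...)` to substitute it.

## CLI

```bash
# synthetic benchmark-like data
meth4c simulate --n-pos 500 --n-neg 500 --effect 0.6 --seed 7 --out sim/

# encode, rank, select, train, predict
meth4c encode --pos sim/pos.fa --neg sim/neg.fa --out features.tsv
meth4c rank --features features.tsv --out ranking.tsv
meth4c select --features features.tsv --ranking ranking.tsv --folds 10 --out selection/
meth4c train --features features.tsv --subset selection/retained.txt --out model.bin
meth4c predict --model model.bin --fasta query.fa --out calls.tsv

# window extraction from a long sequence, CV and independent testing
meth4c scan --fasta gene.fa --out windows.fa
meth4c cv --features features.tsv --folds 10 --out cv.tsv
meth4c eval --train-pos tp.fa --train-neg tn.fa \
            --test-pos sp.fa --test-neg sn.fa --out report.tsv
```

Positive and negative windows are supplied as separate FASTA files; all
windows must be 41 nt (configurable via `--window-length`) with a central
C. Lowercase input is upper-cased; other non-ACGT characters are rejected
(opt-in skip mode in the API). Coordinates in window ids are 1-based.

## Python API

```python
import meth4c as m

samples = m.read_fasta("pos.fa", label=1)
fv = m.encode_all(samples[0])              # 292-dim FeatureVector
frame = m.encode_samples(samples)          # feature table (DataFrame)

ranking = m.rank_features(m.train_ranker(X, y, seed=42))
result = m.backward_eliminate(X, y, ranking, cv_folds=10, seed=0)
config = m.grid_search(X[:, result.best_subset], y, cv_folds=10, seed=0)
model = m.train(X[:, result.best_subset], y, config, seed=0)
proba, labels = m.predict(model, X_new[:, result.best_subset])
```

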