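# citevae

Joint embedding and clustering of paired CITE-seq data: a variational
autoencoder that integrates a cell's RNA expression profile (high-
dimensional, sparse) with its antibody-derived-tag (ADT) surface-protein
counts (low-dimensional, dense) into one latent representation suitable
for K-means clustering of cell populations.

The model encodes each modality with its own linear + ReLU encoder behind
a learnable z-score *feature alignment* layer, fuses the two embeddings
with softmax-normalized *adaptive fusion weights* (initialized at exactly
0.5/0.5), refines the fused features with multi-head self-attention over
feature-token subspaces, maps them to a Gaussian posterior N(μ, σ²I)
sampled via the reparameterization trick z = μ + σε, and reconstructs
both modalities through a symmetric attention-equipped decoder. Training
is coarse-to-fine: 50 epochs of reconstruction-only pretraining

    L_pre = L_rec^RNA + L_rec^ADT,   L_rec = ½ (X − X̂)²

followed by 100 epochs of the joint objective

    L_train = L_rec^RNA + L_rec^ADT + α·KL[N(μ, σ²) ‖ N(0, 1)],  α = 1e-4

with Adam at lr 0.01 (defaults: 200 hidden units, 100 latent dimensions,
4 attention heads, top-500 highly variable genes). Clusterings are scored
against truth labels with ARI, NMI, AMI and Hungarian-mapped accuracy
(ACC). The network and its gradients run on a small reverse-mode autodiff
engine over numpy included in the package — no deep-learning framework is
required. See `docs/methods.md` for the full model description.

Intended users: computational biologists who want a transparent,
dependency-light reference implementation of attention-based CITE-seq
integration, with a simulator for controlled benchmarking.

## Worked example

Everything is reproducible from a seed; no downloads are needed — the
built-in simulator generates cluster-structured paired counts.

```python
import numpy as np
from citevae import (SimConfig, simulate_cite_seq, preprocess,
                     ModelConfig, fit, evaluate_all, kmeans_latent, ari)

# 1000 cells, 5 populations; ADT informative, RNA sparse/noisy (PBMC-like)
pair = simulate_cite_seq(SimConfig(seed=1))
data = preprocess(pair)             # filter -> HVG -> normalize -> log+scale

state, latent = fit(data, ModelConfig(seed=1))
print("fusion weights  w_r=%.3f  w_a=%.3f" % (latent.w_r, latent.w_a))

report = evaluate_all(latent.z, pair.labels, seed=1)
print({k: round(v, 3) for k, v in report.items() if k in ("ari", "nmi", "ami", "acc")})

raw = np.hstack([data.Xr, data.Xa])
print("raw concat K-means ARI: %.3f" % ari(kmeans_latent(raw, 5, seed=1), pair.labels))
```

Output (about half a minute on one CPU core):

```
fusion weights  w_r=0.432  w_a=0.568
{'ari': 0.941, 'nmi': 0.922, 'ami': 0.921, 'acc': 0.976}
raw concat K-means ARI: 0.579
```

The fusion weights have shifted toward the ADT modality (w_a = 0.57),
which carries the cleaner cluster signal in this dataset; K-means on the
learned 100-dimensional latent recovers the five populations almost
perfectly (ARI 0.94), while K-means on the raw concatenated matrix is
badly diluted by the 500 noisy RNA dimensions (ARI 0.58).

The same run from the shell:

```sh
citevae simulate --out data/ --seed 1
citevae fit --rna data/rna_matrix.mtx --adt data/adt_matrix.mtx \
            --out-latent latent.csv --seed 1
citevae evaluate --latent latent.csv --labels data/labels.txt --seed 1
```

Ablations from the shell: `--fusion concat` (concatenation instead of
adaptive fusion), `--no-attention`, `--no-alignment`.

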