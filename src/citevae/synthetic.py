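"""Simulated paired CITE-seq datasets with known cluster structure.

The generator emulates the qualitative contrast between the two
modalities: RNA counts are high-dimensional, negative-binomial and
heavily zero-inflated by dropout, while ADT counts are low-dimensional,
dense and only moderately overdispersed. Both modalities share one
cluster assignment; per-modality informativeness can be switched off to
produce datasets where only one modality carries the cluster signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite

from .io_preprocess import RawOmicsPair

__all__ = ["SimConfig", "simulate_cite_seq", "fixture_suite", "write_dataset"]


@dataclass
class SimConfig:
    """Simulation parameters.

    separation is the log-fold scale of cluster-specific mean shifts;
    dispersions are negative-binomial shape parameters (smaller = noisier);
    rna_dropout is the probability a measured RNA count is zeroed.
    """

    n_cells: int = 1000
    n_genes: int = 500
    n_adt: int = 30
    K: int = 5
    separation: float = 0.5
    rna_dispersion: float = 2.0
    adt_dispersion: float = 3.0
    rna_dropout: float = 0.7
    rna_marker_frac: float = 0.1
    rna_base_logmean: float = 1.0
    rna_informative: bool = True
    adt_informative: bool = True
    n_batches: int = 1
    batch_shift: float = 0.0
    seed: int = 0

    def validate(self) -> "SimConfig":
        if not (self.n_cells >= self.K >= 1):
            raise ValueError("need n_cells >= K >= 1")
        if not 0 <= self.rna_dropout <= 1 or not 0 <= self.rna_marker_frac <= 1:
            raise ValueError("rna_dropout and rna_marker_frac must be probabilities")
        if min(self.rna_dispersion, self.adt_dispersion, self.separation + 1) <= 0:
            raise ValueError("dispersions must be positive, separation non-negative")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        return self


def _assign(n: int, k: int, rng) -> np.ndarray:
    """Near-uniform group sizes with no empty group."""
    groups = np.arange(n) % k
    rng.shuffle(groups)
    return groups


def _nb_counts(log_mu: np.ndarray, theta: float, rng) -> np.ndarray:
    mu = np.exp(log_mu)
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p).astype(np.float64)


def simulate_cite_seq(config: SimConfig) -> RawOmicsPair:
    """Draw one paired dataset; deterministic given config.seed.

    Per-cluster per-gene log-means are baseline + separation * signature
    with standard-normal signatures (zeroed for a non-informative
    modality). RNA: NB(rna_dispersion) then Bernoulli dropout. ADT:
    NB(adt_dispersion), no dropout, higher baseline. Optional additive
    per-batch log-shifts model a technical batch effect.
    """
    config.validate()
    root = np.random.default_rng(config.seed)
    (labels_rng, batch_rng, base_rng, sig_rng,
     shift_rng, rna_rng, drop_rng, adt_rng) = root.spawn(8)

    labels = _assign(config.n_cells, config.K, labels_rng)
    batches = _assign(config.n_cells, config.n_batches, batch_rng)

    base_rna = base_rng.normal(config.rna_base_logmean, 1.0, config.n_genes)
    base_adt = base_rng.normal(np.log(50.0), 0.5, config.n_adt)

    # RNA cluster signal is concentrated in a marker-gene subset; the
    # (small, targeted) ADT panel is informative across the board
    sig_rna = sig_rng.normal(0.0, 1.0, (config.K, config.n_genes))
    sig_rna *= sig_rng.random((1, config.n_genes)) < config.rna_marker_frac
    sig_adt = sig_rng.normal(0.0, 1.0, (config.K, config.n_adt))
    if not config.rna_informative:
        sig_rna[:] = 0.0
    if not config.adt_informative:
        sig_adt[:] = 0.0

    log_mu_rna = base_rna + config.separation * sig_rna  # (K, genes)
    log_mu_adt = base_adt + config.separation * sig_adt

    cell_log_rna = log_mu_rna[labels]
    cell_log_adt = log_mu_adt[labels]
    if config.n_batches > 1 and config.batch_shift > 0:
        shifts_rna = shift_rng.normal(0.0, config.batch_shift,
                                      (config.n_batches, config.n_genes))
        shifts_adt = shift_rng.normal(0.0, config.batch_shift,
                                      (config.n_batches, config.n_adt))
        cell_log_rna = cell_log_rna + shifts_rna[batches]
        cell_log_adt = cell_log_adt + shifts_adt[batches]

    rna = _nb_counts(cell_log_rna, config.rna_dispersion, rna_rng)
    if config.rna_dropout > 0:
        rna *= drop_rng.random(rna.shape) >= config.rna_dropout
    adt = _nb_counts(cell_log_adt, config.adt_dispersion, adt_rng)

    width = len(str(config.n_cells))
    return RawOmicsPair(
        rna_counts=rna,
        adt_counts=adt,
        cell_ids=[f"cell_{i:0{width}d}" for i in range(config.n_cells)],
        gene_ids=[f"gene_{j}" for j in range(config.n_genes)],
        adt_ids=[f"adt_{j}" for j in range(config.n_adt)],
        labels=labels,
        batches=batches,
    )


# canonical fixtures used throughout the test suite; seeds are frozen
FIXTURE_CONFIGS = {
    "default5": SimConfig(seed=1),
    "adt_only": SimConfig(rna_informative=False, seed=2),
    "rna_only": SimConfig(adt_informative=False, seed=3),
    "batchy": SimConfig(n_batches=2, batch_shift=0.5, seed=4),
    "tiny": SimConfig(n_cells=12, n_genes=30, n_adt=8, K=3, separation=1.0,
                      rna_dropout=0.2, rna_marker_frac=0.5, seed=5),
}


def fixture_suite(names=None) -> dict:
    """Generate the canonical named fixtures (all seeds frozen)."""
    selected = FIXTURE_CONFIGS if names is None else {
        n: FIXTURE_CONFIGS[n] for n in names
    }
    return {name: simulate_cite_seq(replace(cfg)) for name, cfg in selected.items()}


def write_dataset(pair: RawOmicsPair, outdir: str, format: str = "mtx"):
    """Write a dataset in the formats the readers accept.

    mtx: <modality>_matrix.mtx (features x cells) + _barcodes.tsv +
    _features.tsv per modality. csv: <modality>.csv with barcode index and
    feature-name header. Labels/batches as one integer per line.
    """
    os.makedirs(outdir, exist_ok=True)
    if format == "mtx":
        for name, X, feats in [
            ("rna", pair.rna_counts, pair.gene_ids),
            ("adt", pair.adt_counts, pair.adt_ids),
        ]:
            mmwrite(os.path.join(outdir, f"{name}_matrix.mtx"),
                    sp.csr_matrix(X.T))
            _write_lines(os.path.join(outdir, f"{name}_barcodes.tsv"), pair.cell_ids)
            _write_lines(os.path.join(outdir, f"{name}_features.tsv"), feats)
        rna_path = os.path.join(outdir, "rna_matrix.mtx")
        adt_path = os.path.join(outdir, "adt_matrix.mtx")
    elif format == "csv":
        import pandas as pd

        for name, X, feats in [
            ("rna", pair.rna_counts, pair.gene_ids),
            ("adt", pair.adt_counts, pair.adt_ids),
        ]:
            pd.DataFrame(X, index=pair.cell_ids, columns=feats).to_csv(
                os.path.join(outdir, f"{name}.csv")
            )
        rna_path = os.path.join(outdir, "rna.csv")
        adt_path = os.path.join(outdir, "adt.csv")
    else:
        raise ValueError(f"unknown format {format!r}")

    paths = {"rna": rna_path, "adt": adt_path, "labels": None, "batches": None}
    if pair.labels is not None:
        paths["labels"] = os.path.join(outdir, "labels.txt")
        _write_lines(paths["labels"], pair.labels)
    if pair.batches is not None:
        paths["batches"] = os.path.join(outdir, "batches.txt")
        _write_lines(paths["batches"], pair.batches)
    return paths


def _write_lines(path: str, values):
    with open(path, "w") as fh:
        for v in values:
            fh.write(f"{v}\n")
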