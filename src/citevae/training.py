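"""Losses and the coarse-to-fine optimization schedule.

Phase 1 (pretrain) minimizes the reconstruction loss alone for
``pretrain_epochs`` epochs; phase 2 (train) adds the KL regularizer
weighted by alpha for ``train_epochs`` more. Both use Adam at the
configured learning rate. Training is full-batch up to 8192 cells and
switches to shuffled 1024-cell mini-batches beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import as_tensor
from .io_preprocess import ProcessedOmicsPair, RawOmicsPair, preprocess
from .model import ModelConfig, ModelState, forward, forward_eval, init_state

__all__ = [
    "LossReport",
    "recon_loss",
    "kl_loss",
    "Adam",
    "pretrain",
    "train",
    "fit",
]

FULL_BATCH_LIMIT = 8192
MINI_BATCH = 1024


@dataclass
class LossReport:
    epoch: int
    phase: str  # "pretrain" | "train"
    rec_rna: float
    rec_adt: float
    kl: float
    total: float
    w_r: float
    w_a: float


def recon_loss(Xr, Xr_hat, Xa, Xa_hat):
    """Half squared reconstruction error per modality.

    Per modality: 1/2 * mean over all entries of the squared error, so
    the two modalities contribute on a comparable scale regardless of
    their (very different) feature counts.
    """
    Xr, Xa = as_tensor(Xr), as_tensor(Xa)
    Xr_hat, Xa_hat = as_tensor(Xr_hat), as_tensor(Xa_hat)
    if Xr.shape != Xr_hat.shape or Xa.shape != Xa_hat.shape:
        raise ValueError(
            f"shape mismatch: RNA {Xr.shape} vs {Xr_hat.shape}, "
            f"ADT {Xa.shape} vs {Xa_hat.shape}"
        )
    diff_r = Xr - Xr_hat
    diff_a = Xa - Xa_hat
    return (diff_r * diff_r).mean() * 0.5, (diff_a * diff_a).mean() * 0.5


def kl_loss(mu, logvar):
    """Closed-form KL(N(mu, sigma^2) || N(0, I)), averaged over cells.

    Per cell the divergence is 1/2 * sum_d (mu_d^2 + sigma_d^2 - 1 -
    log sigma_d^2); the report is the mean of that sum over the batch.
    """
    mu, logvar = as_tensor(mu), as_tensor(logvar)
    per_cell = (mu * mu + logvar.exp() - 1.0 - logvar).sum(axis=-1)
    return per_cell.mean() * 0.5


class Adam:
    """Adam with the standard (0.9, 0.999) moments and bias correction."""

    def __init__(self, named_params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(named_params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {name: np.zeros_like(p.data) for name, p in self.params}
        self.v = {name: np.zeros_like(p.data) for name, p in self.params}

    def step(self):
        self.t += 1
        for name, p in self.params:
            if p.grad is None:
                continue
            g = p.grad
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            m_hat = self.m[name] / (1 - self.b1 ** self.t)
            v_hat = self.v[name] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for _, p in self.params:
            p.grad = None


def _batches(n: int, rng) -> list[np.ndarray]:
    if n <= FULL_BATCH_LIMIT:
        return [np.arange(n)]
    order = rng.permutation(n)
    return [order[i:i + MINI_BATCH] for i in range(0, n, MINI_BATCH)]


def _run_phase(
    state: ModelState,
    data: ProcessedOmicsPair,
    config: ModelConfig,
    phase: str,
    epochs: int,
    optimizer: Adam,
    rng,
) -> list[LossReport]:
    dtype = np.dtype(config.dtype)
    Xr = np.asarray(data.Xr, dtype=dtype)
    Xa = np.asarray(data.Xa, dtype=dtype)
    use_kl = phase == "train"
    reports = []
    for epoch in range(1, epochs + 1):
        sums = {"rec_rna": 0.0, "rec_adt": 0.0, "kl": 0.0, "total": 0.0}
        n_seen = 0
        w_r = w_a = 1.0
        for idx in _batches(Xr.shape[0], rng):
            mu, logvar, _z, Xr_hat, Xa_hat, w_r, w_a = forward(
                Xr[idx], Xa[idx], state, mode="train", rng=rng
            )
            rec_r, rec_a = recon_loss(Xr[idx], Xr_hat, Xa[idx], Xa_hat)
            kl = kl_loss(mu, logvar)
            loss = rec_r + rec_a
            if use_kl:
                loss = loss + kl * config.alpha
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at {phase} epoch {epoch}: "
                    f"rec_rna={float(rec_r.data)} rec_adt={float(rec_a.data)} "
                    f"kl={float(kl.data)}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            w = len(idx)
            n_seen += w
            sums["rec_rna"] += float(rec_r.data) * w
            sums["rec_adt"] += float(rec_a.data) * w
            sums["kl"] += float(kl.data) * w
            sums["total"] += float(loss.data) * w
        reports.append(LossReport(
            epoch=epoch, phase=phase,
            rec_rna=sums["rec_rna"] / n_seen,
            rec_adt=sums["rec_adt"] / n_seen,
            kl=sums["kl"] / n_seen,
            total=sums["total"] / n_seen,
            w_r=w_r, w_a=w_a,
        ))
    return reports


def pretrain(
    state: ModelState, data: ProcessedOmicsPair, config: ModelConfig, rng=None
) -> tuple[ModelState, list[LossReport]]:
    """Reconstruction-only phase (coarse)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    opt = Adam(state.named_parameters(), lr=config.lr)
    reports = _run_phase(state, data, config, "pretrain", config.pretrain_epochs, opt, rng)
    return state, reports


def train(
    state: ModelState, data: ProcessedOmicsPair, config: ModelConfig, rng=None
) -> tuple[ModelState, list[LossReport]]:
    """Joint reconstruction + alpha * KL phase (fine)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    opt = Adam(state.named_parameters(), lr=config.lr)
    reports = _run_phase(state, data, config, "train", config.train_epochs, opt, rng)
    return state, reports


def fit(
    raw: RawOmicsPair,
    config: ModelConfig | None = None,
    d: int = 500,
    target_sum: float = 1e4,
    return_reports: bool = False,
):
    """Preprocess, initialize, pretrain, train, and extract the latent.

    The evaluation-mode latent (z = mu, no dropout) is what downstream
    clustering consumes. One config seed drives initialization, dropout,
    sampling and shuffling, so runs are exactly reproducible.
    """
    config = (config or ModelConfig()).validate()
    data = raw if isinstance(raw, ProcessedOmicsPair) else preprocess(raw, d, target_sum)
    root = np.random.default_rng(config.seed)
    init_rng, pre_rng, train_rng = root.spawn(3)
    state = init_state(config, data.Xr.shape[1], data.Xa.shape[1], rng=init_rng)
    _, pre_reports = pretrain(state, data, config, rng=pre_rng)
    _, train_reports = train(state, data, config, rng=train_rng)
    dtype = np.dtype(config.dtype)
    latent, _, _ = forward_eval(
        np.asarray(data.Xr, dtype=dtype), np.asarray(data.Xa, dtype=dtype), state
    )
    if return_reports:
        return state, latent, pre_reports + train_reports
    return state, latent


def write_loss_log(reports: list[LossReport], path: str):
    """CSV log: epoch, phase, rec_rna, rec_adt, kl, total, w_r, w_a."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "phase", "rec_rna", "rec_adt", "kl", "total", "w_r", "w_a"])
        for r in reports:
            writer.writerow([r.epoch, r.phase, r.rec_rna, r.rec_adt, r.kl, r.total, r.w_r, r.w_a])
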