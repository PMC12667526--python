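"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately naive — loop-based, enumeration-based or
Monte-Carlo — and shares no code with the package implementation.
"""

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

def loop_attention(y, Wq, Wk, Wv, Wo, ln_gamma, ln_beta, L, n_head, eps=1e-5):
    """Scaled dot-product attention computed cell-by-cell with loops."""
    y = np.asarray(y, dtype=np.float64)
    B, D = y.shape
    d_l = D // L
    d = d_l // n_head
    out = np.zeros_like(y)
    for b in range(B):
        tokens = y[b].reshape(L, d_l)
        q_full = tokens @ Wq
        k_full = tokens @ Wk
        v_full = tokens @ Wv
        merged = np.zeros((L, d_l))
        for h in range(n_head):
            sl = slice(h * d, (h + 1) * d)
            q, k, v = q_full[:, sl], k_full[:, sl], v_full[:, sl]
            for i in range(L):
                logits = np.array([q[i] @ k[j] / math.sqrt(d) for j in range(L)])
                logits -= logits.max()
                w = np.exp(logits) / np.exp(logits).sum()
                merged[i, sl] = sum(w[j] * v[j] for j in range(L))
        out[b] = (merged @ Wo).reshape(D)
    res = y + out  # no dropout in the oracle
    norm = np.zeros_like(res)
    for b in range(B):
        row = res[b]
        norm[b] = (row - row.mean()) / np.sqrt(row.var() + eps)
    return norm * ln_gamma + ln_beta


# ---------------------------------------------------------------------------
# clustering metrics
# ---------------------------------------------------------------------------

def pair_counting_ari(pe, pt):
    """ARI by O(n^2) enumeration of sample pairs."""
    pe, pt = np.asarray(pe), np.asarray(pt)
    n = len(pe)
    a = b = c = d = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_e = pe[i] == pe[j]
            same_t = pt[i] == pt[j]
            if same_e and same_t:
                a += 1
            elif same_e:
                b += 1
            elif same_t:
                c += 1
            else:
                d += 1
    total = a + b + c + d
    index = a
    expected = (a + b) * (a + c) / total if total else 0.0
    maximum = ((a + b) + (a + c)) / 2.0
    if maximum == expected:
        return 1.0 if index == maximum else 0.0
    return (index - expected) / (maximum - expected)


def _entropy(labels):
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return -np.sum(p * np.log(p))


def mutual_information(pe, pt):
    pe, pt = np.asarray(pe), np.asarray(pt)
    n = len(pe)
    mi = 0.0
    for i in np.unique(pe):
        for j in np.unique(pt):
            nij = np.sum((pe == i) & (pt == j))
            if nij == 0:
                continue
            ni = np.sum(pe == i)
            nj = np.sum(pt == j)
            mi += (nij / n) * np.log(n * nij / (ni * nj))
    return mi


def direct_nmi(pe, pt):
    """MI normalized by the arithmetic mean of the label entropies."""
    h_e, h_t = _entropy(pe), _entropy(pt)
    mean_h = (h_e + h_t) / 2.0
    if mean_h == 0:
        return 1.0
    return mutual_information(pe, pt) / mean_h


def permutation_emi(pe, pt, n_shuffles=10_000, seed=0):
    """Monte-Carlo expected MI under random label permutation.

    Returns (mean, standard error).
    """
    rng = np.random.default_rng(seed)
    pe = np.asarray(pe).copy()
    values = np.empty(n_shuffles)
    for s in range(n_shuffles):
        rng.shuffle(pe)
        values[s] = mutual_information(pe, pt)
    return values.mean(), values.std(ddof=1) / math.sqrt(n_shuffles)


def exhaustive_acc(pe, pt):
    """Best-map accuracy by exhausting all one-to-one cluster mappings."""
    pe, pt = np.asarray(pe), np.asarray(pt)
    e_vals = list(np.unique(pe))
    t_vals = list(np.unique(pt))
    big = max(len(e_vals), len(t_vals))
    best = 0
    # pad the smaller side with dummy ids so mappings stay one-to-one
    targets = t_vals + [None] * (big - len(t_vals))
    sources = e_vals + [None] * (big - len(e_vals))
    for perm in itertools.permutations(targets):
        hits = 0
        for src, dst in zip(sources, perm):
            if src is None or dst is None:
                continue
            hits += np.sum((pe == src) & (pt == dst))
        best = max(best, hits)
    return best / len(pe)


def monte_carlo_kl(mu, logvar, n_samples=100_000, seed=0):
    """Sampling estimate of KL(N(mu, sigma^2) || N(0, I)), mean over rows.

    Returns (estimate, standard error).
    """
    rng = np.random.default_rng(seed)
    mu = np.asarray(mu, dtype=np.float64)
    logvar = np.asarray(logvar, dtype=np.float64)
    sigma = np.exp(logvar / 2.0)
    draws = np.empty(n_samples)
    for s in range(n_samples):
        x = mu + sigma * rng.standard_normal(mu.shape)
        log_q = (-0.5 * ((x - mu) / sigma) ** 2 - 0.5 * np.log(2 * np.pi) - logvar / 2).sum(axis=-1)
        log_p = (-0.5 * x ** 2 - 0.5 * np.log(2 * np.pi)).sum(axis=-1)
        draws[s] = (log_q - log_p).mean()
    return draws.mean(), draws.std(ddof=1) / math.sqrt(n_samples)
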