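"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (explicit loops, textbook formulas,
exhaustive enumeration) and shares no code with the package paths it
checks.
"""

import itertools
import math

import numpy as np


def naive_dft_cross(x: np.ndarray, y: np.ndarray, taper: np.ndarray, nfft: int):
    """Textbook O(n^2) DFT cross-product of two demeaned, tapered segments.

    Returns the full complex cross-spectrum X_xy(f) = X(f) * conj(Y(f))
    at the nonnegative DFT frequencies of an nfft-point transform.
    """
    x = (x - x.mean()) * taper
    y = (y - y.mean()) * taper
    n = len(x)
    n_freq = nfft // 2 + 1
    out = np.empty(n_freq, dtype=complex)
    for k in range(n_freq):
        xs = sum(x[t] * np.exp(-2j * np.pi * k * t / nfft) for t in range(n))
        ys = sum(y[t] * np.exp(-2j * np.pi * k * t / nfft) for t in range(n))
        out[k] = xs * np.conj(ys)
    return out


def dwpli_bruteforce(imag_parts) -> float:
    """dwPLI by explicit summation over all ordered trial pairs j != k."""
    imag_parts = np.asarray(imag_parts, dtype=float)
    num = 0.0
    den = 0.0
    n = len(imag_parts)
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            num += imag_parts[j] * imag_parts[k]
            den += abs(imag_parts[j] * imag_parts[k])
    if den == 0.0:
        return 0.0
    return num / den


def restricted_growth_strings(n: int, max_blocks: int | None = None):
    """All set partitions of n elements as label arrays (first-occurrence
    order, labels 0..k-1), optionally with at most ``max_blocks`` blocks."""
    labels = np.zeros(n, dtype=int)

    def rec(i, k):
        if i == n:
            yield labels.copy()
            return
        lim = k + 1 if (max_blocks is None or k < max_blocks) else k
        for c in range(lim):
            labels[i] = c
            yield from rec(i + 1, max(k, c + 1))

    yield from rec(1, 1)


def exhaustive_max_q(b: np.ndarray, two_mu: float, max_blocks: int | None = None):
    """Global maximum of sum_{g_u = g_v} B_uv / 2mu by exhaustive search.

    Returns (q_max, labels).  Feasible for <= 12 elements (optionally with
    a block-count cap).
    """
    n = b.shape[0]
    best_q = -np.inf
    best_labels = None
    batch = []

    def flush():
        nonlocal best_q, best_labels
        if not batch:
            return
        arr = np.stack(batch)
        mask = arr[:, :, None] == arr[:, None, :]
        qs = np.einsum("pij,ij->p", mask, b) / two_mu
        i = int(np.argmax(qs))
        if qs[i] > best_q:
            best_q = float(qs[i])
            best_labels = arr[i].copy()
        batch.clear()

    for labels in restricted_growth_strings(n, max_blocks):
        batch.append(labels)
        if len(batch) >= 20000:
            flush()
    flush()
    return best_q, best_labels


def t_one_sample_direct(x: np.ndarray, popmean: float = 0.0):
    """Textbook one-sample t: t = (xbar - mu) / (s / sqrt(n)), two-sided p
    from the t distribution survival function (via scipy's distribution,
    which is not the code path under test)."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, dtype=float)
    n = len(x)
    s = x.std(ddof=1)
    t_val = (x.mean() - popmean) / (s / math.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t_val), df=n - 1)
    return t_val, p


def by_adjust_direct(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli adjusted values by the hand step-up formula:
    adj_(i) = min_{j >= i} min(1, p_(j) * m * c(m) / j), c(m) = sum 1/i."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    c_m = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(p)
    raw = p[order] * m * c_m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def mean_pairwise_similarity(labelings, sim_fn) -> np.ndarray:
    """Brute-force mean similarity of each labeling to all the others."""
    n = len(labelings)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                sim[i, j] = sim_fn(labelings[i], labelings[j])
    return sim.sum(axis=1) / (n - 1)


def allegiance_loops(labels: np.ndarray) -> np.ndarray:
    """Layer-by-layer co-assignment counting with explicit loops, / L."""
    n_layers, n = labels.shape
    p = np.zeros((n, n))
    for s in range(n_layers):
        for i in range(n):
            for j in range(n):
                if labels[s, i] == labels[s, j]:
                    p[i, j] += 1.0
    return p / n_layers


def flexibility_loops(labels: np.ndarray) -> np.ndarray:
    """Transition counting with explicit loops, / (L - 1)."""
    n_layers, n = labels.shape
    out = np.zeros(n)
    for i in range(n):
        g = 0
        for s in range(1, n_layers):
            if labels[s, i] != labels[s - 1, i]:
                g += 1
        out[i] = g / (n_layers - 1)
    return out
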