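"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as straightforward loops from definitions, kept
deliberately separate from the package's (vectorized / library-backed) code
paths.
"""

import math

import numpy as np


def mean_loop(v):
    total = 0.0
    for x in v:
        total += x
    return total / len(v)


def var_loop(v):
    mu = mean_loop(v)
    return mean_loop([(x - mu) ** 2 for x in v])


def sd_loop(v):
    return math.sqrt(var_loop(v))


def skew_loop(v):
    mu = mean_loop(v)
    m2 = mean_loop([(x - mu) ** 2 for x in v])
    m3 = mean_loop([(x - mu) ** 3 for x in v])
    return 0.0 if m2 == 0 else m3 / m2**1.5


def shannon_loop(v):
    energy = sum(x * x for x in v)
    if energy == 0:
        return 0.0
    out = 0.0
    for x in v:
        p = x * x / energy
        if p > 0:
            out -= p * math.log(p)
    return out


def sure_threshold_scan(v):
    """Exhaustive SURE minimization over candidates {0} U {|y_i|}."""
    v = np.asarray(v, dtype=float)
    sigma = float(np.median(np.abs(v - np.median(v)))) / 0.6745
    if sigma == 0:
        sigma = float(np.std(v))
    if sigma == 0:
        return 0.0
    y = v / sigma
    n = y.size
    candidates = [0.0] + sorted(abs(x) for x in y)
    best_t, best_risk = None, None
    for t in candidates:
        n_small = sum(1 for x in y if abs(x) <= t)
        risk = n - 2.0 * n_small + sum(min(x * x, t * t) for x in y)
        if best_risk is None or risk < best_risk - 1e-12:
            best_risk, best_t = risk, t
    return best_t * sigma


def sure_entropy_loop(v):
    eps = sure_threshold_scan(v)
    return sum(min(x * x, eps * eps) for x in v)


def welch_curve_loop(v, nperseg, noverlap):
    """Segment-averaged Hamming periodogram curve, density scaling, fs = 1."""
    v = np.asarray(v, dtype=float)
    # periodic Hamming window, built from its definition
    window = 0.54 - 0.46 * np.cos(2.0 * np.pi * np.arange(nperseg) / nperseg)
    step = nperseg - noverlap
    segments = []
    start = 0
    while start + nperseg <= v.size:
        segments.append(v[start : start + nperseg])
        start += step
    scale = 1.0 / (window * window).sum()
    psds = []
    for seg in segments:
        spec = np.fft.rfft(seg * window)
        p = scale * np.abs(spec) ** 2
        p[1:-1] *= 2.0  # one-sided (nperseg even: last bin is Nyquist)
        psds.append(p)
    return np.mean(psds, axis=0)


def welch_mean_loop(v, nperseg, noverlap):
    return float(welch_curve_loop(v, nperseg, noverlap).mean())


def anova_ss_loop(values, labels):
    """One-way ANOVA F from the sum-of-squares decomposition."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    grand = mean_loop(values)
    ssb = 0.0
    ssw = 0.0
    for c in classes:
        g = values[labels == c]
        gm = mean_loop(g)
        ssb += len(g) * (gm - grand) ** 2
        ssw += sum((x - gm) ** 2 for x in g)
    dfb = len(classes) - 1
    dfw = len(values) - len(classes)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


def svd_block_rep_power_iteration(block, n_iter=500):
    """Rank-1 SVD representative of a one-column block via power iteration.

    For the n x 1 matrix b: sigma = ||b||, u = b/||b||; the scalar
    representative is sign(mean(b)) * sigma / sqrt(n) (+ on a zero mean).
    """
    b = np.asarray(block, dtype=float).reshape(-1, 1)
    ata = b.T @ b  # 1x1
    x = np.ones(1)
    for _ in range(n_iter):
        x = ata @ x
        norm = np.linalg.norm(x)
        if norm == 0:
            return 0.0
        x = x / norm
    sigma = math.sqrt(float(ata[0, 0]))
    rep = sigma / math.sqrt(b.size)
    return rep if b.mean() >= 0 else -rep


def metrics_counting_loop(counts):
    """(accuracy, sensitivity, specificity) percent; class 0 = negative."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    tn = counts[0, 0]
    fp = sum(counts[0, j] for j in range(1, counts.shape[1]))
    tp = sum(counts[i, i] for i in range(1, counts.shape[0]))
    fn = sum(
        counts[i, j]
        for i in range(1, counts.shape[0])
        for j in range(counts.shape[1])
        if j != i
    )
    acc = 100.0 * (tp + tn) / total
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return acc, sens, spec
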