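"""Brute-force reference implementations, independent of the package code."""

import numpy as np


def classify_oracle(onset, offset, n_frames, frame_interval_s):
    """Literal transcription of the four protrusion-class rules."""
    last = n_frames - 1
    persistence_s = (offset - onset + 1) * frame_interval_s
    if onset == 0 and offset == last:
        return "static"
    if onset > 0 and offset == last and persistence_s >= 180.0:
        return "stabilized"
    if onset == 0 and offset < last and persistence_s >= 180.0:
        return "collapsed"
    return "transient"


def upgma_heights(rows):
    """Average-linkage merge heights over 1 − Pearson distances, recomputing
    every cluster-pair distance from scratch at each step."""
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    pair = {
        (i, j): 1.0 - np.corrcoef(rows[i], rows[j])[0, 1]
        for i in range(n)
        for j in range(i + 1, n)
    }

    def cluster_dist(a, b):
        return np.mean([pair[tuple(sorted((i, j)))] for i in a for j in b])

    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best, best_h = None, None
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                h = cluster_dist(clusters[ids[x]], clusters[ids[y]])
                if best_h is None or h < best_h:
                    best, best_h = (ids[x], ids[y]), h
        heights.append(best_h)
        clusters[next_id] = clusters.pop(best[0]) + clusters.pop(best[1])
        next_id += 1
    return np.array(heights)


def welch_oracle(a, b):
    """Welch t statistic, Welch–Satterthwaite df and two-tailed p by formula."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def dense_gaussian_conv(img, sigma, truncate=4.0):
    """Direct 2-D convolution with a separable truncated Gaussian kernel and
    symmetric (reflective) padding."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    padded = np.pad(img, radius, mode="symmetric")
    h, w = img.shape
    out = np.empty_like(img, dtype=float)
    for y in range(h):
        for x_ in range(w):
            out[y, x_] = (padded[y : y + 2 * radius + 1, x_ : x_ + 2 * radius + 1] * kernel).sum()
    return out
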