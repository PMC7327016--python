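"""Independent brute-force oracles, written before and kept independent of
the vectorized implementations they check."""

import math

import numpy as np


def brute_force_pair_feature(tf, g, metric):
    """Double-loop graph-distance feature: all i<j point distances."""
    k = len(tf)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            dx, dy = tf[i] - tf[j], g[i] - g[j]
            if metric == "euclidean":
                out.append(math.sqrt(dx * dx + dy * dy))
            else:
                out.append(abs(dx) + abs(dy))
    return np.array(out)


def brute_force_auc(scores, labels):
    """Concordant-pair counting with half credit for ties."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
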