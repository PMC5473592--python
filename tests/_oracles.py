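"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own log-gamma formulas: rarefaction
statistics are obtained by exhaustively enumerating every equally likely
subsample of labelled reads.
"""

from itertools import combinations

import numpy as np


def enumerate_subsample_richness(counts, n):
    """Mean and population variance of richness over all C(N, n) subsamples.

    Reads are labelled individually; every n-subset of read labels is
    equally likely under sampling without replacement.
    """
    labels = [i for i, c in enumerate(counts) for _ in range(int(c))]
    rich = [
        len({labels[j] for j in comb})
        for comb in combinations(range(len(labels)), n)
    ]
    rich = np.asarray(rich, dtype=float)
    return float(rich.mean()), float(rich.var())


def partitions(n, max_part=None):
    """All integer partitions of n (as non-increasing tuples)."""
    if max_part is None:
        max_part = n
    if n == 0:
        yield ()
        return
    for k in range(min(n, max_part), 0, -1):
        for rest in partitions(n - k, k):
            yield (k,) + rest


def silhouette_by_hand(dm, labels):
    """Direct evaluation of s(i) = (b-a)/max(a,b) from a distance matrix.

    Singleton-cluster points score 0.
    """
    labels = list(labels)
    k = len(labels)
    scores = []
    for i in range(k):
        own = [j for j in range(k) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([dm[i][j] for j in own])
        b = min(
            np.mean([dm[i][j] for j in range(k) if labels[j] == other])
            for other in set(labels) - {labels[i]}
        )
        scores.append((b - a) / max(a, b))
    return scores
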