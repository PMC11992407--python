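"""Independent brute-force oracles used to validate the metric implementations.

Everything here is O(n^2) pair enumeration or direct Counter-based entropy,
deliberately sharing no code with dropstab.metrics.
"""

import itertools
import math
from collections import Counter

import numpy as np


def pair_counts(a, b):
    """(n_TP, n_TN, n_pairs) by explicit enumeration of all cell pairs."""
    n = len(a)
    tp = tn = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        if same_a and same_b:
            tp += 1
        elif not same_a and not same_b:
            tn += 1
    return tp, tn, n * (n - 1) // 2


def rand_index(a, b):
    tp, tn, pairs = pair_counts(a, b)
    return (tp + tn) / pairs


def adjusted_rand_index(a, b):
    """ARI from pair counts; expectation from marginal same-pair counts."""
    n = len(a)
    pairs = n * (n - 1) / 2
    index = pair_counts(a, b)[0]
    same_a = sum(1 for i, j in itertools.combinations(range(n), 2)
                 if a[i] == a[j])
    same_b = sum(1 for i, j in itertools.combinations(range(n), 2)
                 if b[i] == b[j])
    expected = same_a * same_b / pairs
    maximum = (same_a + same_b) / 2
    if maximum == expected:
        return 1.0
    return (index - expected) / (maximum - expected)


def _entropy(labels):
    n = len(labels)
    return -sum((c / n) * math.log(c / n) for c in Counter(labels).values())


def _conditional_entropy(target, given):
    """H(target | given) by direct summation over joint frequencies."""
    n = len(target)
    joint = Counter(zip(given, target))
    marg = Counter(given)
    h = 0.0
    for (g, _t), c in joint.items():
        h -= (c / n) * math.log(c / marg[g])
    return h


def homogeneity(truth, pred):
    h_c = _entropy(truth)
    if h_c == 0.0:
        return 1.0
    return 1.0 - _conditional_entropy(truth, pred) / h_c


def completeness(truth, pred):
    return homogeneity(pred, truth)


def v_measure(truth, pred, beta=1.0):
    h = homogeneity(truth, pred)
    c = completeness(truth, pred)
    if h == 0.0 or c == 0.0:
        return 0.0
    return (1 + beta) * h * c / (beta * h + c)


def random_partition_pair(rng, max_n=200):
    """A random pair of labelings over the same cells."""
    n = int(rng.integers(10, max_n + 1))
    ka = int(rng.integers(1, 9))
    kb = int(rng.integers(1, 9))
    return rng.integers(0, ka, n), rng.integers(0, kb, n)
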