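"""Independent brute-force oracles used to freeze expected values.

These enumerate or simulate directly from definitions and share no code
with the estimators they check.
"""

import itertools
from collections import Counter

import numpy as np


def enumerate_subsample_stats(counts, m):
    """Mean distinct-clone count and mean plug-in entropy over every
    without-replacement subsample of size m (exhaustive enumeration)."""
    population = [i for i, c in enumerate(counts) for _ in range(c)]
    richness_vals = []
    entropy_vals = []
    for combo in itertools.combinations(range(len(population)), m):
        tally = Counter(population[i] for i in combo)
        richness_vals.append(len(tally))
        p = np.array(list(tally.values()), dtype=float) / m
        entropy_vals.append(float(-(p * np.log(p)).sum()))
    return float(np.mean(richness_vals)), float(np.mean(entropy_vals))


def partitions_max_parts(n, max_parts, _largest=None):
    """All multisets of positive integers summing to n with at most max_parts parts."""
    if _largest is None:
        _largest = n
    if n == 0:
        yield ()
        return
    if max_parts == 0:
        return
    for first in range(min(n, _largest), 0, -1):
        for rest in partitions_max_parts(n - first, max_parts - 1, first):
            yield (first,) + rest
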