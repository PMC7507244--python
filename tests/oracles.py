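"""Naive reference implementations used as independent oracles.

Everything here is written with explicit loops over zones/pairs so the
tests compare the library against an implementation that shares no code
path with it.
"""

from __future__ import annotations

import math


def naive_ectasia_index(zones) -> float:
    sup = list(zones[:15])
    inf = list(zones[15:])
    return 100.0 * min(inf) / (sum(sup) / len(sup))


def naive_ectasia_index_max(zones) -> float:
    sup = list(zones[:15])
    inf = list(zones[15:])
    return 100.0 * min(inf) / max(sup)


def naive_profile_variation(zones) -> float:
    mean = sum(zones) / len(zones)
    return math.sqrt(sum((t - mean) ** 2 for t in zones) / len(zones))


def naive_profile_deviation(zones, pattern) -> float:
    return math.sqrt(sum((t - p) ** 2 for t, p in zip(zones, pattern)) / len(zones))


def naive_zonal_statistics(zones):
    sup = list(zones[:15])
    inf = list(zones[15:])
    return (
        sum(zones) / len(zones),
        sum(sup) / len(sup),
        sum(inf) / len(inf),
        min(inf),
        max(sup),
    )


def naive_fisher_score(values, labels) -> float:
    classes = sorted(set(labels))
    assert len(classes) == 2
    a = [v for v, l in zip(values, labels) if l == classes[0]]
    b = [v for v, l in zip(values, labels) if l == classes[1]]
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    va = sum((x - ma) ** 2 for x in a) / (len(a) - 1)
    vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
    return (ma - mb) ** 2 / (va + vb)


def naive_pairwise_auc(scores, labels) -> float:
    """Exhaustive concordant-pair counting, ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
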