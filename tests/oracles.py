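"""Brute-force information-theory oracle, independent of the package's code.

Materializes full joint probability tables with ``collections.Counter`` and
evaluates the defining sums directly; used to cross-check the plug-in
estimators on randomized instances.
"""

import math
from collections import Counter


def _joint(*variables):
    n = len(variables[0])
    counts = Counter(zip(*variables))
    return {k: v / n for k, v in counts.items()}


def _marginal(p, axes):
    out = {}
    for k, v in p.items():
        key = tuple(k[a] for a in axes)
        out[key] = out.get(key, 0.0) + v
    return out


def oracle_entropy(x):
    p = _joint(x)
    return -sum(v * math.log2(v) for v in p.values() if v > 0)


def oracle_mutual_information(x, c):
    p = _joint(x, c)
    px = _marginal(p, (0,))
    pc = _marginal(p, (1,))
    return sum(
        v * math.log2(v / (px[(k[0],)] * pc[(k[1],)])) for k, v in p.items() if v > 0
    )


def oracle_conditional_mi(x, c, z):
    p = _joint(x, c, z)
    pxz = _marginal(p, (0, 2))
    pcz = _marginal(p, (1, 2))
    pz = _marginal(p, (2,))
    total = 0.0
    for (a, b, w), v in p.items():
        if v > 0:
            total += v * math.log2(v * pz[(w,)] / (pxz[(a, w)] * pcz[(b, w)]))
    return total


def oracle_interaction_information(xj, xi, c):
    return oracle_conditional_mi(xj, c, xi) - oracle_mutual_information(xj, c)
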