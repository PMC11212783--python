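"""Independent brute-force oracles used only by the tests.

These are deliberately written in plain Python with naive algorithms
(exhaustive enumeration, hand-rolled mid-ranks) so that they share no code
path with the package implementations they check.
"""

from itertools import combinations, permutations

import numpy as np


def _sign(v: float) -> float:
    return (v > 0) - (v < 0)


def _a(z1, z2, z3, z4) -> float:
    return _sign(abs(z1 - z2) + abs(z3 - z4) - abs(z1 - z3) - abs(z2 - z4))


def tau_star_enumeration(x, y) -> float:
    """Sign-covariance U-statistic by full ordered-quadruple enumeration:
    averages the kernel over all 24 orderings of every quadruple.

    Values are mid-rank transformed first; the kernel is a function of the
    order pattern only, and rank arithmetic keeps the sign exact.
    """
    x = midranks(x)
    y = midranks(y)
    n = len(x)
    total = 0.0
    count = 0
    for quad in combinations(range(n), 4):
        s = 0.0
        for i, j, k, l in permutations(quad):
            s += _a(x[i], x[j], x[k], x[l]) * _a(y[i], y[j], y[k], y[l])
        total += s / 24.0
        count += 1
    return total / count


def concordance_counts(x, y):
    """Concordant/discordant/tied pair counts by explicit double loop."""
    n = len(x)
    C = D = Tx = Ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0:
                Tx += 1
            if dy == 0:
                Ty += 1
            if dx * dy > 0:
                C += 1
            elif dx * dy < 0:
                D += 1
    return C, D, Tx, Ty


def midranks(v):
    """Mid-ranks with tie averaging, built from sorting alone."""
    v = list(map(float, v))
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def multilevel_spearman_reference(u, v, groups) -> float:
    """Rank both columns, subtract group means of the ranks, correlate."""
    ru = midranks(u)
    rv = midranks(v)
    keys = {}
    for g in groups:
        keys.setdefault(g, []).append(None)
    means_u = {g: np.mean([ru[i] for i in range(len(groups))
                           if groups[i] == g]) for g in keys}
    means_v = {g: np.mean([rv[i] for i in range(len(groups))
                           if groups[i] == g]) for g in keys}
    eu = np.array([ru[i] - means_u[groups[i]] for i in range(len(groups))])
    ev = np.array([rv[i] - means_v[groups[i]] for i in range(len(groups))])
    den = np.sqrt((eu ** 2).sum() * (ev ** 2).sum())
    if den == 0:
        return float("nan")
    return float((eu * ev).sum() / den)


def plain_spearman(u, v) -> float:
    ru = np.array(midranks(u))
    rv = np.array(midranks(v))
    ru -= ru.mean()
    rv -= rv.mean()
    return float((ru * rv).sum()
                 / np.sqrt((ru ** 2).sum() * (rv ** 2).sum()))
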