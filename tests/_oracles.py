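"""Independent brute-force oracles used across the test suite.

Deliberately written with plain Python loops and explicit sums so they
share no code path with the implementations they check.
"""


def brute_force_moments(counts, bin_width_ps, t0_ps=0.0):
    """Direct-summation DTOF moments (N, mean, variance)."""
    n = 0.0
    s1 = 0.0
    s2 = 0.0
    for i, c in enumerate(counts):
        t = t0_ps + i * bin_width_ps
        n += c
        s1 += t * c
        s2 += t * t * c
    mean = s1 / n
    return n, mean, s2 / n - mean * mean


def brute_force_cnr(series, task_mask):
    """(mean task - mean rest) / rest SD via explicit frame masks."""
    task = [x for x, m in zip(series, task_mask) if m]
    rest = [x for x, m in zip(series, task_mask) if not m]
    mt = sum(task) / len(task)
    mr = sum(rest) / len(rest)
    var = sum((x - mr) ** 2 for x in rest) / len(rest)
    return (mt - mr) / var**0.5


def brute_force_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5
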