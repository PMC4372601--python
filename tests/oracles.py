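"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with plain Python loops and
from-scratch formulas, sharing no code path with the package.
"""

from __future__ import annotations

import itertools
import math


def oracle_trimmed_stats(blanks, trim_fraction=0.05, sd_multiplier=2.0):
    """Sort, slice floor(trim*n) per tail, recompute mean/SD by hand."""
    xs = sorted(float(b) for b in blanks)
    k = math.floor(trim_fraction * len(xs))
    kept = xs[k:len(xs) - k] if k else xs
    n = len(kept)
    mean = sum(kept) / n
    var = sum((v - mean) ** 2 for v in kept) / (n - 1)
    sd = math.sqrt(var)
    return mean, sd, mean + sd_multiplier * sd


def oracle_normalize_scan(blanks, probe_ids, intensities,
                          trim_fraction=0.05, sd_multiplier=2.0,
                          target_median=25.0):
    """Straight-line composition of the four per-array steps.

    Returns (values dict with absent -> 0.0, present dict of flags).
    """
    mean, _sd, threshold = oracle_trimmed_stats(blanks, trim_fraction,
                                                sd_multiplier)
    present = {}
    corrected = {}
    for pid, inten in zip(probe_ids, intensities):
        if inten > threshold:
            present[pid] = True
            corrected[pid] = inten - mean
        else:
            present[pid] = False
    vals = sorted(corrected.values())
    if not vals:
        raise ValueError("no present probe")
    mid = len(vals) // 2
    med = vals[mid] if len(vals) % 2 else (vals[mid - 1] + vals[mid]) / 2
    scale = target_median / med
    values = {pid: (corrected[pid] * scale if present[pid] else 0.0)
              for pid in probe_ids}
    return values, present


def _u_statistic(a, b):
    """Smaller Mann-Whitney U, midranks via direct pair counting."""
    u_a = 0.0
    for x in a:
        for y in b:
            if x > y:
                u_a += 1.0
            elif x == y:
                u_a += 0.5
    return min(u_a, len(a) * len(b) - u_a)


def oracle_mwu(a, b):
    """Exact two-sided Mann-Whitney by full enumeration of labelings."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    pooled = a + b
    n_a = len(a)
    u_obs = _u_statistic(a, b)
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        sel = set(idx)
        aa = [pooled[i] for i in range(len(pooled)) if i in sel]
        bb = [pooled[i] for i in range(len(pooled)) if i not in sel]
        total += 1
        if _u_statistic(aa, bb) <= u_obs + 1e-12:
            extreme += 1
    return u_obs, min(1.0, extreme / total)


def _midranks(xs):
    order = sorted(range(len(xs)), key=lambda i: xs[i])
    ranks = [0.0] * len(xs)
    i = 0
    while i < len(xs):
        j = i
        while j + 1 < len(xs) and xs[order[j + 1]] == xs[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def oracle_spearman(x, y):
    """Midrank Spearman rho with exact permutation p (full n! enumeration)."""
    rx = _midranks([float(v) for v in x])
    ry = _midranks([float(v) for v in y])
    rho = _pearson(rx, ry)
    n = len(x)
    extreme = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if abs(_pearson(rx, [ry[i] for i in perm])) >= abs(rho) - 1e-12:
            extreme += 1
    return rho, extreme / total
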