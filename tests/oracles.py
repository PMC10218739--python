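"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the package implementation.
"""

from itertools import permutations
from math import comb, log

import numpy as np


def pair_categories(ref, obt):
    """O(n^2) pair categorization by direct enumeration."""
    ts = td = fd = fs = 0
    n = len(ref)
    for i in range(n):
        for j in range(i + 1, n):
            same_r = ref[i] == ref[j]
            same_o = obt[i] == obt[j]
            if same_r and same_o:
                ts += 1
            elif not same_r and not same_o:
                td += 1
            elif same_r and not same_o:
                fd += 1
            else:
                fs += 1
    return ts, td, fd, fs


def rand_index(ref, obt):
    ts, td, fd, fs = pair_categories(ref, obt)
    return (ts + td) / comb(len(ref), 2)


def partitions_into_blocks(n, C):
    """All set partitions of n items into exactly C non-empty blocks,
    as label tuples (restricted growth strings)."""
    out = []

    def rec(labels, next_label):
        i = len(labels)
        if i == n:
            if next_label == C:
                out.append(tuple(labels))
            return
        # pruning: remaining items must be able to open the missing blocks
        if next_label + (n - i) < C:
            return
        for lab in range(min(next_label + 1, C)):
            rec(labels + [lab], max(next_label, lab + 1))

    rec([], 0)
    return out


def stirling2_enumeration(n, C):
    return len(partitions_into_blocks(n, C))


def mean_rand_index_fnc(ref, C):
    """Mean RI of a fixed reference against every C-block partition."""
    parts = partitions_into_blocks(len(ref), C)
    return sum(rand_index(ref, p) for p in parts) / len(parts)


def plugin_mi(ref, obt):
    """Plug-in MI from joint label frequencies, natural log."""
    ref = list(ref)
    obt = list(obt)
    n = len(ref)
    rs, os_ = sorted(set(ref)), sorted(set(obt))
    mi = 0.0
    for r in rs:
        pr = ref.count(r) / n
        for o in os_:
            nij = sum(1 for a, b in zip(ref, obt) if a == r and b == o)
            if nij == 0:
                continue
            po = obt.count(o) / n
            pro = nij / n
            mi += pro * log(pro / (pr * po))
    return mi


def permutation_mean_mi(ref, obt):
    """Exact E[MI] under the permutation model by full enumeration (n <= ~7)."""
    obt = list(obt)
    vals = [plugin_mi(ref, perm) for perm in permutations(obt)]
    return float(np.mean(vals))
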