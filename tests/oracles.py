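"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's run-length machinery: they scan epoch
by epoch (or merge interval by interval) so that agreement with the library
is a genuine cross-check, not a tautology.
"""

import math

import numpy as np

W, S, M = 0, 1, 2


def naive_flip_pass(states, target, into, min_epochs):
    """One smoothing pass by explicit scanning."""
    states = list(states)
    n = len(states)
    out = list(states)
    i = 0
    while i < n:
        if states[i] != target:
            i += 1
            continue
        j = i
        while j < n and states[j] == target:
            j += 1
        left = states[i - 1] if i > 0 else None
        right = states[j] if j < n else None
        neighbours = [x for x in (left, right) if x is not None]
        if (j - i) < min_epochs and neighbours and all(x == into for x in neighbours):
            for k in range(i, j):
                out[k] = into
        i = j
    return out


def naive_smooth(states, epoch_len, min_bout_minutes):
    min_epochs = int(round(min_bout_minutes * 60 / epoch_len))
    once = naive_flip_pass(states, W, S, min_epochs)
    return naive_flip_pass(once, S, W, min_epochs)


def naive_windows(states, epoch_len, max_gap_minutes):
    """Iterated pairwise merging of sleep runs until a fixed point.

    Returns a list of (start_epoch, end_epoch, st_hours, wt_hours).
    """
    runs = []
    i, n = 0, len(states)
    while i < n:
        if states[i] == S:
            j = i
            while j < n and states[j] == S:
                j += 1
            runs.append([(i, j)])
            i = j
        else:
            i += 1
    max_gap_epochs = max_gap_minutes * 60 / epoch_len
    changed = True
    while changed:
        changed = False
        for k in range(len(runs) - 1):
            prev_end = runs[k][-1][1]
            nxt_start = runs[k + 1][0][0]
            gap = states[prev_end:nxt_start]
            if (nxt_start - prev_end) <= max_gap_epochs and all(s == W for s in gap):
                runs[k] = runs[k] + runs[k + 1]
                del runs[k + 1]
                changed = True
                break
    out = []
    for group in runs:
        i0, i1 = group[0][0], group[-1][1]
        st = sum(b - a for a, b in group) * epoch_len / 3600.0
        wt = (i1 - i0) * epoch_len / 3600.0 - st
        out.append((i0, i1, st, wt))
    return out


def naive_qp(x, k):
    """Chi-square periodogram statistic at a single fold length, by loops."""
    n = len(x)
    mbar = sum(x) / n
    cols = {}
    for i, v in enumerate(x):
        cols.setdefault(i % k, []).append(v)
    ssb = sum(len(vs) * (sum(vs) / len(vs) - mbar) ** 2 for vs in cols.values())
    sst = sum((v - mbar) ** 2 for v in x)
    return n * ssb / sst


def naive_ari(a, b):
    """Adjusted Rand index straight from the contingency-table formula."""
    a, b = list(a), list(b)
    n = len(a)
    la, lb = sorted(set(a)), sorted(set(b))
    table = [[sum(1 for x, y in zip(a, b) if x == u and y == v) for v in lb] for u in la]

    def c2(m):
        return m * (m - 1) / 2

    sum_ij = sum(c2(nij) for row in table for nij in row)
    sum_i = sum(c2(sum(row)) for row in table)
    sum_j = sum(c2(sum(col)) for col in zip(*table))
    expected = sum_i * sum_j / c2(n)
    max_index = (sum_i + sum_j) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def naive_ward_merge_order(points):
    """Greedy Ward agglomeration via the merge-cost formula.

    Returns the list of frozensets merged at each step.
    """
    clusters = {i: ([p], 1) for i, p in enumerate(map(np.asarray, points))}
    members = {i: frozenset([i]) for i in clusters}
    order = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if j <= i:
                    continue
                pi, ni = clusters[i]
                pj, nj = clusters[j]
                ci = np.mean(pi, axis=0)
                cj = np.mean(pj, axis=0)
                cost = ni * nj / (ni + nj) * float(np.sum((ci - cj) ** 2))
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        _, i, j = best
        order.append(members[i] | members[j])
        clusters[next_id] = (clusters[i][0] + clusters[j][0], clusters[i][1] + clusters[j][1])
        members[next_id] = members[i] | members[j]
        for k in (i, j):
            del clusters[k], members[k]
        next_id += 1
    return order
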