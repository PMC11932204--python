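"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately written from the definitions, not by calling
the package's encoder/DP code paths: exhaustive enumeration of pairing
features, exhaustive search over monotone non-crossing pairings, and a naive
per-threshold precision-recall trapezoid.
"""

PAIR_TYPES = ("AU", "CG", "GC", "GU", "UA", "UG")
PAD = "-"
L = 25


def brute_force_feature_indices(mic: str, cts: str) -> set:
    """All set feature bits by direct enumeration of the layout definition."""
    tset = set(PAIR_TYPES)

    def ptype(i, j):
        if i >= L or j >= L or i < 0 or j < 0:
            return None
        p = mic[i] + cts[j]
        return p if p in tset else None

    out = set()
    for i in range(L):
        for j in range(L):
            t = ptype(i, j)
            if t is not None:
                out.add(i * 150 + j * 6 + PAIR_TYPES.index(t))
    for i in range(L):
        for d in range(-2, 3):
            j = i + d
            t1, t2 = ptype(i, j), ptype(i + 1, j + 1)
            if t1 is not None and t2 is not None:
                out.add(3750 + i * 180 + (d + 2) * 36
                        + PAIR_TYPES.index(t1) * 6 + PAIR_TYPES.index(t2))
    for i in range(L):
        for d in range(-1, 2):
            j = i + d
            ts = [ptype(i + a, j + a) for a in range(3)]
            if all(t is not None for t in ts):
                out.add(8250 + i * 648 + (d + 1) * 216
                        + PAIR_TYPES.index(ts[0]) * 36
                        + PAIR_TYPES.index(ts[1]) * 6
                        + PAIR_TYPES.index(ts[2]))
    return out


def _best_run_partition(run, lookup):
    """Best score of a maximal diagonal run split into segments of <= 3."""
    m = len(run)
    best = [0.0] * (m + 1)
    for end in range(1, m + 1):
        cands = []
        for k in (1, 2, 3):
            if end - k >= 0:
                i, j, _ = run[end - 1]
                types = tuple(t for _, _, t in run[end - k:end])
                cands.append(best[end - k] + lookup(i, j, types))
        best[end] = max(cands)
    return best[m]


def brute_force_optimal_weight(mic: str, cts: str, lookup) -> float:
    """Maximum total weight over all monotone non-crossing pairings.

    ``lookup(i, j, types)`` scores a consecutive-diagonal run ending at
    (i, j).  Position 0 of either strand never pairs.  Enumerates every
    antichain-free subset of candidate pairs; intended for short sequences
    embedded in pads.
    """
    tset = set(PAIR_TYPES)
    cands = [(i, j, mic[i] + cts[j])
             for i in range(1, L) for j in range(1, L)
             if mic[i] + cts[j] in tset]

    rows = sorted({i for i, _, _ in cands})
    best = 0.0
    # enumerate monotone selections row-subset by row-subset
    def recurse(idx, chosen_j, chosen):
        nonlocal best
        if chosen:
            best = max(best, _score_structure(chosen, lookup))
        for p in range(idx, len(cands)):
            i, j, t = cands[p]
            if chosen and (i <= chosen[-1][0] or j <= chosen[-1][1]):
                continue
            chosen.append(cands[p])
            recurse(p + 1, j, chosen)
            chosen.pop()

    recurse(0, -1, [])
    return best


def _score_structure(pairs, lookup) -> float:
    """Score a sorted monotone pairing: best partition of each maximal run."""
    total = 0.0
    run = [pairs[0]]
    for cur in pairs[1:]:
        prev = run[-1]
        if cur[0] == prev[0] + 1 and cur[1] == prev[1] + 1:
            run.append(cur)
        else:
            total += _best_run_partition(run, lookup)
            run = [cur]
    total += _best_run_partition(run, lookup)
    return total


def naive_pr_points(labels, probs, thresholds):
    """Per-threshold precision/recall computed with plain Python loops."""
    labels = list(labels)
    probs = list(probs)
    points = []
    for thr in thresholds:
        tp = sum(1 for y, p in zip(labels, probs) if p >= thr and y == 1)
        fp = sum(1 for y, p in zip(labels, probs) if p >= thr and y == 0)
        fn = sum(1 for y, p in zip(labels, probs) if p < thr and y == 1)
        precision = tp / (tp + fp) if tp + fp else 1.0
        recall = tp / (tp + fn) if tp + fn else 1.0
        points.append((precision, recall))
    return points


def naive_trapezoid_auprc(points) -> float:
    """Trapezoid sum over the (precision, recall) traversal order."""
    area = 0.0
    for (p0, r0), (p1, r1) in zip(points, points[1:]):
        area += (r1 - r0) * (p1 + p0) / 2.0
    return min(max(area, 0.0), 1.0)
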