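"""Independent brute-force re-implementations used as test oracles.

Everything here is written in plain Python with dictionaries and explicit
loops, deliberately sharing no code path with the package.
"""

import math
from itertools import permutations


def brute_coarse(x, s):
    return [sum(x[i * s : (i + 1) * s]) / s for i in range(len(x) // s)]


def brute_pattern_id(window):
    m = len(window)
    order = sorted(range(m), key=lambda i: (window[i], i))
    tup = tuple(i + 1 for i in order)
    catalogue = sorted(permutations(range(1, m + 1)))
    return catalogue.index(tup) + 1


def brute_profile(series, m, tau=1):
    """(probs, ranks, T) dicts keyed by pattern id, per the frequency-rank rule."""
    span = (m - 1) * tau
    ids = [
        brute_pattern_id(series[L : L + span + 1 : tau])
        for L in range(len(series) - span)
    ]
    T = math.factorial(m)
    counts = {i: 0 for i in range(1, T + 1)}
    for i in ids:
        counts[i] += 1
    probs = {i: counts[i] / len(ids) for i in counts}
    ordered = sorted(counts, key=lambda i: (-probs[i], i))
    ranks = {pid: r + 1 for r, pid in enumerate(ordered)}
    return probs, ranks, T


def brute_distance(prof1, prof2):
    probs1, ranks1, T = prof1
    probs2, ranks2, T2 = prof2
    assert T == T2
    h = {}
    for i in range(1, T + 1):
        e = 0.0
        for p in (probs1[i], probs2[i]):
            if p > 0:
                e -= p * math.log(p)
        h[i] = e
    sigma = sum(h.values())
    d = 0.0
    for i in range(1, T + 1):
        w = h[i] / sigma if sigma > 0 else 1.0 / T
        d += abs(ranks1[i] - ranks2[i]) * w
    return d / T


def brute_recording_opibs(segment_interval_lists, s, m, tau=1):
    profs = [
        brute_profile(brute_coarse(list(x), s), m, tau)
        for x in segment_interval_lists
        if len(x) // s >= (m - 1) * tau + 1
    ]
    ds = [brute_distance(profs[i], profs[i + 1]) for i in range(len(profs) - 1)]
    return sum(ds) / len(ds)


def brute_profile_from_probs(probs_by_id, T):
    """Rank a given probability map with the serial-number tie rule."""
    probs = {i: probs_by_id.get(i, 0.0) for i in range(1, T + 1)}
    ordered = sorted(probs, key=lambda i: (-probs[i], i))
    ranks = {pid: r + 1 for r, pid in enumerate(ordered)}
    return probs, ranks, T
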