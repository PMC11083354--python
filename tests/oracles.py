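"""Independent brute-force oracles used to check the package's numerics.

These deliberately use naive Python loops / exhaustive enumeration so they
share no code path with the implementations they verify.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations

import numpy as np


def bfs_components(mask: np.ndarray, connectivity: int = 26) -> list[set]:
    """Connected components by explicit breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 6:
        offsets = [o for o in _offsets() if sum(abs(v) for v in o) == 1]
    elif connectivity == 18:
        offsets = [o for o in _offsets() if sum(abs(v) for v in o) <= 2]
    else:
        offsets = _offsets()
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for off in offsets:
                w = tuple(v[a] + off[a] for a in range(3))
                if all(0 <= w[a] < mask.shape[a] for a in range(3)) \
                        and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(comp)
    return comps


def _offsets():
    return [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)]


def brute_center_of_mass(mask: np.ndarray, affine: np.ndarray) -> tuple:
    """Mean of voxel-center world coordinates by explicit summation."""
    total = [0.0, 0.0, 0.0]
    count = 0
    for idx in map(tuple, np.argwhere(np.asarray(mask, dtype=bool))):
        world = affine @ np.array([*idx, 1.0])
        for a in range(3):
            total[a] += world[a]
        count += 1
    return tuple(t / count for t in total)


def brute_min_distance(point_mm, zone_mask: np.ndarray, affine: np.ndarray) -> float:
    """Exhaustive scan over all zone voxels."""
    best = math.inf
    for idx in map(tuple, np.argwhere(np.asarray(zone_mask, dtype=bool))):
        world = (affine @ np.array([*idx, 1.0]))[:3]
        best = min(best, math.dist(point_mm, world))
    return best


def brute_fraction(tumor_mask, zone_mask) -> float:
    inter = n_t = 0
    tumor = np.asarray(tumor_mask, dtype=bool)
    zone = np.asarray(zone_mask, dtype=bool)
    for idx in map(tuple, np.argwhere(tumor)):
        n_t += 1
        if zone[idx]:
            inter += 1
    return 100.0 * inter / n_t


def logrank_table(times, events, group):
    """(O, E, V) for the indicated group via an explicit risk-set table."""
    times = list(map(float, times))
    events = list(map(bool, events))
    group = list(map(bool, group))
    o = e = v = 0.0
    for t in sorted({t for t, ev in zip(times, events) if ev}):
        at_risk = [i for i, ti in enumerate(times) if ti >= t]
        n = len(at_risk)
        n1 = sum(group[i] for i in at_risk)
        dead = [i for i, (ti, ev) in enumerate(zip(times, events)) if ev and ti == t]
        d = len(dead)
        d1 = sum(group[i] for i in dead)
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o, e, v


def exact_mwu_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all label assignments."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(idx_a):
        ua = 0.0
        for i in idx_a:
            for j in range(len(pooled)):
                if j in idx_a:
                    continue
                if pooled[i] > pooled[j]:
                    ua += 1
                elif pooled[i] == pooled[j]:
                    ua += 0.5
        return ua

    mid = n1 * (len(b)) / 2.0
    u_obs = u_stat(set(range(n1)))
    count = total = 0
    for comb in combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(set(comb)) - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
    return count / total


def permutation_mwu_p(a, b, n_resamples: int, rng: np.random.Generator) -> float:
    """Monte-Carlo permutation two-sided p for the Mann-Whitney U."""
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    n1 = len(a)
    ranks = rankdata(pooled)
    mid = n1 * (len(pooled) - n1) / 2.0

    def u_from_ranks(r1):
        return r1.sum() - n1 * (n1 + 1) / 2.0

    u_obs = u_from_ranks(ranks[:n1])
    perm = np.argsort(rng.random((n_resamples, pooled.size)), axis=1)[:, :n1]
    u_perm = ranks[perm].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return float((np.abs(u_perm - mid) >= abs(u_obs - mid) - 1e-9).mean())
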