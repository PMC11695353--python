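"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written with a different algorithmic route
from the package (flood fill instead of union-find, pairwise counting instead
of rank formulas, explicit enumeration instead of closed forms).
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    if connectivity == 6:
        return [o for o in offs if sum(map(abs, o)) == 1]
    if connectivity == 18:
        return [o for o in offs if sum(map(abs, o)) <= 2]
    return offs


def _flood_components(sup_coords: set[tuple[int, int, int]], connectivity: int):
    """Connected components of a voxel set via BFS flood fill."""
    offs = _offsets(connectivity)
    remaining = set(sup_coords)
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            x, y, z = frontier.pop()
            for dx, dy, dz in offs:
                nb = (x + dx, y + dy, z + dz)
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    frontier.append(nb)
        yield comp


def tfce_bruteforce(stat, mask, E, H, dh, connectivity):
    """Per-threshold flood-fill TFCE on a skeleton vector."""
    stat = np.maximum(np.asarray(stat, dtype=float), 0.0)
    coords = [tuple(c) for c in mask.voxel_coords]
    out = np.zeros(stat.shape)
    peak = stat.max()
    if peak <= 0:
        return out
    n_steps = int(math.floor(1.0 / dh + 1e-9))
    delta = peak * dh
    for i in range(1, n_steps + 1):
        h = i * delta
        sup_idx = [k for k in range(len(coords)) if stat[k] >= h]
        if not sup_idx:
            continue
        coord_to_idx = {coords[k]: k for k in sup_idx}
        for comp in _flood_components(set(coord_to_idx), connectivity):
            contrib = (len(comp) ** E) * (h ** H) * delta
            for c in comp:
                out[coord_to_idx[c]] += contrib
    return out


def pooled_tstat_oracle(a, b):
    """Pooled-variance two-sample t via scipy (b minus a convention)."""
    from scipy import stats

    return stats.ttest_ind(np.asarray(b), np.asarray(a), equal_var=True).statistic


def auc_pairwise(scores, labels):
    """AUC by explicit pair counting, ties worth one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def bh_stepup_oracle(p_values):
    """Literal step-up construction of BH adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return np.minimum(adjusted, 1.0)


def mannwhitney_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    a = list(a)
    b = list(b)
    pooled = a + b
    n_a = len(a)

    def u_stat(xs, ys):
        return sum(
            1.0 if x > y_ else (0.5 if x == y_ else 0.0) for x in xs for y_ in ys
        )

    u_obs = u_stat(a, b)
    mean_u = n_a * len(b) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return u_obs, count / total


def rank_auc(values, positive_mask):
    """Rank AUC of a score vector for separating a voxel subset."""
    from scipy.stats import rankdata

    values = np.asarray(values, dtype=float)
    positive_mask = np.asarray(positive_mask, dtype=bool)
    n_pos = int(positive_mask.sum())
    n_neg = int((~positive_mask).sum())
    r = rankdata(values)
    return (r[positive_mask].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
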