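"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (exhaustive enumeration, O(n^2)
pair counting, literal step-up rules) and shares no code with the package
internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage, stats


# ---------------------------------------------------------------------------
# graph metrics by exhaustive path / triangle enumeration
# ---------------------------------------------------------------------------


def _all_simple_paths(w: np.ndarray, s: int, t: int):
    """Yield (length, intermediate nodes) of every simple path s -> t with
    edge length 1/weight."""
    n = w.shape[0]

    def extend(node, visited, length):
        if node == t:
            yield length, frozenset(visited - {s, t})
            return
        for nxt in range(n):
            if w[node, nxt] > 0 and nxt not in visited:
                yield from extend(nxt, visited | {nxt}, length + 1.0 / w[node, nxt])

    yield from extend(s, {s}, 0.0)


def exhaustive_distances(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            lengths = [L for L, _ in _all_simple_paths(w, s, t)]
            if lengths:
                dist[s, t] = min(lengths)
    return dist


def exhaustive_betweenness(w: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Unnormalized betweenness: for each unordered pair, the fraction of
    minimum-length simple paths passing through each intermediate node."""
    n = w.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = list(_all_simple_paths(w, s, t))
        if not paths:
            continue
        dmin = min(L for L, _ in paths)
        shortest = [mid for L, mid in paths if L <= dmin + tol]
        sigma = len(shortest)
        for mid in shortest:
            for v in mid:
                bc[v] += 1.0 / sigma
    return bc


def _global_efficiency(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    if n < 2:
        return np.zeros(n)
    eff = np.zeros(n)
    for i in range(n):
        inv = [1.0 / dist[i, j] for j in range(n) if j != i and np.isfinite(dist[i, j])]
        eff[i] = sum(inv) / (n - 1)
    return eff


def exhaustive_nodal_metrics(w: np.ndarray) -> dict[str, np.ndarray]:
    """All six nodal metrics by direct enumeration."""
    n = w.shape[0]
    dist = exhaustive_distances(w)
    out = {
        "degree": (w > 0).sum(axis=1).astype(float),
        "strength": w.sum(axis=1),
        "global_efficiency": _global_efficiency(dist),
        "betweenness_centrality": exhaustive_betweenness(w),
    }
    loc = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) >= 2:
            sub = w[np.ix_(nbrs, nbrs)]
            loc[i] = _global_efficiency(exhaustive_distances(sub)).mean()
    out["local_efficiency"] = loc
    cc = np.zeros(n)
    wmax = w.max()
    if wmax > 0:
        wn = w / wmax
        for i in range(n):
            k = int((w[i] > 0).sum())
            if k < 2:
                continue
            total = 0.0
            for j in range(n):
                for h in range(n):
                    if j != i and h != i and j != h:
                        total += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
            cc[i] = total / (k * (k - 1))
    out["clustering_coefficient"] = cc
    return out


# ---------------------------------------------------------------------------
# TFCE fine-step integration
# ---------------------------------------------------------------------------


def tfce_fine_oracle(stat: np.ndarray, E: float, H: float, n_steps: int) -> np.ndarray:
    """Signed TFCE by literal threshold sweeping with per-threshold
    connected-component labelling (26-connectivity for 3D, 4 for 2D)."""

    def one_sided(pos):
        hmax = pos.max(initial=0.0)
        out = np.zeros_like(pos)
        if hmax <= 0:
            return out
        dh = hmax / n_steps
        struct = ndimage.generate_binary_structure(pos.ndim, pos.ndim if pos.ndim == 3 else 1)
        for k in range(1, n_steps + 1):
            h = k * dh
            mask = pos >= h
            if not mask.any():
                break
            labels, n_comp = ndimage.label(mask, structure=struct)
            for comp in range(1, n_comp + 1):
                sel = labels == comp
                out[sel] += sel.sum() ** E * h**H * dh
        return out

    stat = np.asarray(stat, dtype=float)
    return one_sided(np.clip(stat, 0, None)) - one_sided(np.clip(-stat, 0, None))


# ---------------------------------------------------------------------------
# AUC pair counting, BH step-up, pooled t, power
# ---------------------------------------------------------------------------


def pair_counting_auc(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        return float("nan")
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)


def stepup_fdr_oracle(pvalues, q) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    passed = p[order] <= (np.arange(1, m + 1) * q / m)
    mask = np.zeros(m, dtype=bool)
    if passed.any():
        k = int(np.flatnonzero(passed)[-1])
        mask[order[: k + 1]] = True
    return mask


def pooled_t_oracle(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return float((x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny)))


def ttest_power_oracle(d: float, n1: int, n2: int, alpha: float) -> float:
    """Two-sided two-sample t-test power from the noncentral t distribution."""
    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(
        stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    )


def min_detectable_d_oracle(n1, n2, power, alpha, grid_step=5e-4) -> float:
    for d in np.arange(grid_step, 5.0, grid_step):
        if ttest_power_oracle(d, n1, n2, alpha) >= power:
            return float(d)
    return float("inf")
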