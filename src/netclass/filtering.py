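"""Group-level mass-univariate statistics and multiple-comparison control.

This is the "filter" stage of the pipeline: two-sample t statistics per
element (voxel, ROI pair, nodal metric, or tract metric), threshold-free
cluster enhancement (TFCE) with max-statistic permutation FWE control for
spatially structured elements, Benjamini-Hochberg FDR for unstructured
ones, cluster-feature extraction, a minimum-detectable-effect power check,
and the median/MAD permutation test used for cohort descriptives.

TFCE integrates ``extent(h)^E * h^H * dh`` over thresholds ``0 < h <=
stat``, where extent is the size of the connected suprathreshold component
containing the element.  Two backends compute it: a numba union-find kernel
(default; components are grown incrementally while sweeping thresholds from
high to low) and a scipy.ndimage reference used for cross-checking.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestIndPower

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

__all__ = [
    "GroupDesign",
    "TFCEParams",
    "SelectionResult",
    "mass_univariate_t",
    "t_pvalues",
    "tfce_enhance",
    "permutation_fwe",
    "roi_matrix_tfce",
    "fdr_bh",
    "extract_cluster_features",
    "detectable_effect_filter",
    "permutation_median_test",
    "bonferroni",
]


@dataclass(frozen=True)
class GroupDesign:
    """Two-group contrast over a vector of per-subject labels."""

    labels: np.ndarray
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels))
        if (self.labels == self.group_a).sum() == 0:
            raise ValueError(f"group_a {self.group_a!r} has no subjects")
        if (self.labels == self.group_b).sum() == 0:
            raise ValueError(f"group_b {self.group_b!r} has no subjects")

    def masks(self) -> tuple[np.ndarray, np.ndarray]:
        return self.labels == self.group_a, self.labels == self.group_b


@dataclass
class TFCEParams:
    """TFCE and permutation-test parameters.

    Defaults are the standard published TFCE choices: E = 0.5, H = 2, 100
    integration steps (dh = h_max/100), 26-connectivity on 3D grids and
    4-connectivity on matrices.
    """

    extent_exponent: float = 0.5
    height_exponent: float = 2.0
    n_steps: int = 100
    dh: float | None = None
    connectivity: int = 26
    n_permutations: int = 1000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.extent_exponent < 0 or self.height_exponent < 0:
            raise ValueError("TFCE exponents must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class SelectionResult:
    """Outcome of a corrected mass-univariate contrast."""

    statistic: np.ndarray
    enhanced: np.ndarray | None
    pvalues: np.ndarray
    mask: np.ndarray
    method: str
    contrast: tuple[str, str]
    n_permutations: int = 0
    seed: int | None = None
    element_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any((self.pvalues < 0) | (self.pvalues > 1)):
            raise ValueError("p-values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# two-sample t statistics
# ---------------------------------------------------------------------------


def _pooled_t(xa: np.ndarray, xb: np.ndarray, warn: bool = True) -> np.ndarray:
    """Vectorized pooled-variance two-sample t over the last data layout
    (subjects on axis 0)."""
    na, nb = xa.shape[0], xb.shape[0]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va = xa.var(axis=0, ddof=1)
    vb = xb.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    degenerate = se == 0
    if warn and np.any(degenerate):
        warnings.warn(f"{int(degenerate.sum())} zero-variance elements; t set to 0")
    t = np.divide(ma - mb, se, out=np.zeros_like(se), where=~degenerate)
    return t


def mass_univariate_t(
    values: np.ndarray, design: GroupDesign, warn: bool = True
) -> np.ndarray:
    """Two-sample pooled-variance t per element.

    ``values`` is subjects x elements (any trailing shape); rows are matched
    to ``design.labels``.  Elements with zero pooled variance yield t = 0.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != design.labels.shape[0]:
        raise ValueError("values rows must match design labels")
    mask_a, mask_b = design.masks()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(
            f"contrast {design.group_a} vs {design.group_b}: both groups need >= 2 subjects"
        )
    return _pooled_t(values[mask_a], values[mask_b], warn=warn)


def t_pvalues(t: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p-values for t statistics with ``df`` degrees of freedom."""
    return 2.0 * stats.t.sf(np.abs(t), df)


# ---------------------------------------------------------------------------
# TFCE backends
# ---------------------------------------------------------------------------

_NEIGHBOR_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _connectivity_structure(ndim: int, connectivity: int) -> np.ndarray:
    if ndim == 3:
        rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
        if rank is None:
            raise ValueError("3D connectivity must be 6, 18 or 26")
    elif ndim == 2:
        rank = {4: 1, 8: 2}.get(connectivity)
        if rank is None:
            raise ValueError("2D connectivity must be 4 or 8")
    elif ndim == 1:
        rank = 1
    else:
        raise ValueError(f"unsupported dimensionality {ndim}")
    return ndimage.generate_binary_structure(ndim, rank)


def _neighbor_table(shape: tuple[int, ...], connectivity: int):
    """CSR-style (indices, indptr) table of grid neighbors for the union-find
    kernel; cached per (shape, connectivity)."""
    key = (shape, connectivity)
    if key in _NEIGHBOR_CACHE:
        return _NEIGHBOR_CACHE[key]
    struct = _connectivity_structure(len(shape), connectivity)
    offsets = np.argwhere(struct) - 1
    offsets = offsets[np.any(offsets != 0, axis=1)]
    coords = np.indices(shape).reshape(len(shape), -1).T
    n = coords.shape[0]
    nbr_lists: list[np.ndarray] = []
    counts = np.zeros(n, dtype=np.int64)
    per_voxel: list[list[int]] = [[] for _ in range(n)]
    dims = np.asarray(shape)
    for off in offsets:
        shifted_coords = coords + off
        valid = np.all((shifted_coords >= 0) & (shifted_coords < dims), axis=1)
        src = np.flatnonzero(valid)
        dst = np.ravel_multi_index(shifted_coords[valid].T, shape)
        for s, d in zip(src, dst):
            per_voxel[s].append(d)
    indptr = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        indptr[i + 1] = indptr[i] + len(per_voxel[i])
    indices = np.fromiter(
        itertools.chain.from_iterable(per_voxel), dtype=np.int64, count=indptr[-1]
    )
    _NEIGHBOR_CACHE[key] = (indices, indptr)
    return indices, indptr


if _HAVE_NUMBA:

    @njit(cache=True)
    def _uf_find(parent, v):
        root = v
        while parent[root] != root:
            root = parent[root]
        while parent[v] != root:
            parent[v], v = root, parent[v]
        return root

    @njit(cache=True)
    def _tfce_union_find(flat, order, nbr_idx, nbr_ptr, n_steps, dh, E, H):
        n = flat.size
        parent = np.full(n, -1, dtype=np.int64)
        size = np.ones(n, dtype=np.int64)
        out = np.zeros(n)
        ptr = 0
        for step in range(n_steps, 0, -1):
            h = dh * step
            while ptr < n and flat[order[ptr]] >= h:
                v = order[ptr]
                parent[v] = v
                for q in range(nbr_ptr[v], nbr_ptr[v + 1]):
                    u = nbr_idx[q]
                    if parent[u] >= 0:
                        ru = _uf_find(parent, u)
                        rv = _uf_find(parent, v)
                        if ru != rv:
                            if size[ru] < size[rv]:
                                ru, rv = rv, ru
                            parent[rv] = ru
                            size[ru] += size[rv]
                ptr += 1
            weight = h**H * dh
            for t in range(ptr):
                v = order[t]
                r = _uf_find(parent, v)
                out[v] += size[r] ** E * weight
        return out


def _tfce_positive_ndimage(stat, params: TFCEParams, dh, n_steps):
    struct = _connectivity_structure(stat.ndim, params.connectivity)
    out = np.zeros_like(stat)
    for k in range(1, n_steps + 1):
        h = dh * k
        mask = stat >= h
        if not mask.any():
            break
        labels, n_comp = ndimage.label(mask, structure=struct)
        if n_comp == 0:
            continue
        sizes = np.bincount(labels[mask])
        out[mask] += sizes[labels[mask]] ** params.extent_exponent * h**params.height_exponent * dh
    return out


def _tfce_positive(stat: np.ndarray, params: TFCEParams, backend: str) -> np.ndarray:
    """Enhance the non-negative part of a map; zeros stay zero."""
    hmax = float(stat.max(initial=0.0))
    if hmax <= 0:
        return np.zeros_like(stat)
    if params.dh is not None:
        dh = params.dh
        n_steps = int(np.ceil(hmax / dh - 1e-12))
    else:
        n_steps = params.n_steps
        dh = hmax / n_steps
    if backend == "ndimage" or not _HAVE_NUMBA:
        return _tfce_positive_ndimage(stat, params, dh, n_steps)
    flat = stat.ravel()
    order = np.argsort(flat, kind="stable")[::-1].astype(np.int64)
    nbr_idx, nbr_ptr = _neighbor_table(stat.shape, params.connectivity)
    out = _tfce_union_find(
        flat,
        order,
        nbr_idx,
        nbr_ptr,
        n_steps,
        dh,
        params.extent_exponent,
        params.height_exponent,
    )
    return out.reshape(stat.shape)


def tfce_enhance(
    stat: np.ndarray, params: TFCEParams | None = None, backend: str = "auto"
) -> np.ndarray:
    """Threshold-free cluster enhancement of a statistic map or matrix.

    Negative statistics are enhanced on the negated map and their sign is
    restored, so the output is signed like the input.  ``backend`` is
    ``"auto"`` (numba union-find when available), ``"fast"`` or
    ``"ndimage"``.
    """
    if params is None:
        params = TFCEParams()
    stat = np.asarray(stat, dtype=float)
    if not np.all(np.isfinite(stat)):
        raise ValueError("tfce_enhance: statistics must be finite")
    pos = _tfce_positive(np.clip(stat, 0.0, None), params, backend)
    neg = _tfce_positive(np.clip(-stat, 0.0, None), params, backend)
    return pos - neg


# ---------------------------------------------------------------------------
# permutation FWE with the max-statistic null
# ---------------------------------------------------------------------------


def _permutation_assignments(
    n: int, n_a: int, n_permutations: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Boolean membership matrix (permutations x subjects) for group A.

    Enumerates all distinct assignments (with a warning) when there are no
    more than ``n_permutations`` of them; otherwise draws random
    permutations.
    """
    total = comb(n, n_a)
    if total <= n_permutations:
        warnings.warn(
            f"only {total} distinct label assignments; enumerating all instead of "
            f"{n_permutations} random permutations"
        )
        assign = np.zeros((total, n), dtype=bool)
        for row, combo in enumerate(itertools.combinations(range(n), n_a)):
            assign[row, list(combo)] = True
        return assign, True
    assign = np.zeros((n_permutations, n), dtype=bool)
    for row in range(n_permutations):
        assign[row, rng.permutation(n)[:n_a]] = True
    return assign, False


def _perm_t_matrix(values: np.ndarray, assign: np.ndarray, warn: bool = False) -> np.ndarray:
    """Pooled t for every permutation at once: values (n, m), assign (P, n)."""
    n, m = values.shape
    n_a = int(assign[0].sum())
    n_b = n - n_a
    a = assign.astype(float)
    s1 = a @ values
    s2 = a @ values**2
    tot1 = values.sum(axis=0)
    tot2 = (values**2).sum(axis=0)
    ma = s1 / n_a
    mb = (tot1 - s1) / n_b
    ssa = s2 - n_a * ma**2
    ssb = (tot2 - s2) - n_b * mb**2
    pooled = (ssa + ssb) / (n_a + n_b - 2)
    se = np.sqrt(np.clip(pooled, 0.0, None) * (1.0 / n_a + 1.0 / n_b))
    return np.divide(ma - mb, se, out=np.zeros_like(se), where=se > 0)


def permutation_fwe(
    values: np.ndarray,
    design: GroupDesign,
    params: TFCEParams | None = None,
    seed: int = 0,
    backend: str = "auto",
    _enhance=None,
) -> SelectionResult:
    """TFCE + max-statistic permutation test with FWE control.

    ``values`` is subjects x grid (3D) or subjects x elements (1D).  The
    null distribution is the maximum |enhanced| statistic over elements for
    each label permutation; element-wise p-values use the add-one estimator
    and the mask keeps p <= alpha.
    """
    if params is None:
        params = TFCEParams()
    values = np.asarray(values, dtype=float)
    mask_a, mask_b = design.masks()
    both = mask_a | mask_b
    vals = values[both]
    is_a = mask_a[both]
    n = vals.shape[0]
    n_a = int(is_a.sum())
    if n_a < 2 or n - n_a < 2:
        raise ValueError("both groups need >= 2 subjects")
    shape = vals.shape[1:]
    flat = vals.reshape(n, -1)

    enhance = _enhance or (lambda t: tfce_enhance(t.reshape(shape), params, backend).ravel())

    obs_t = _pooled_t(flat[is_a], flat[~is_a], warn=False)
    obs_enh = enhance(obs_t)

    rng = np.random.default_rng(seed)
    assign, enumerated = _permutation_assignments(n, n_a, params.n_permutations, rng)
    t_perm = _perm_t_matrix(flat, assign)
    null_max = np.empty(assign.shape[0])
    for p in range(assign.shape[0]):
        null_max[p] = np.abs(enhance(t_perm[p])).max(initial=0.0)

    abs_obs = np.abs(obs_enh)
    exceed = (null_max[:, None] >= abs_obs[None, :]).sum(axis=0)
    if enumerated:
        pvals = exceed / assign.shape[0]
    else:
        pvals = (1.0 + exceed) / (1.0 + assign.shape[0])
    sig = pvals <= params.alpha
    return SelectionResult(
        statistic=obs_t.reshape(shape),
        enhanced=obs_enh.reshape(shape),
        pvalues=pvals.reshape(shape),
        mask=sig.reshape(shape),
        method="TFCE",
        contrast=(design.group_a, design.group_b),
        n_permutations=assign.shape[0],
        seed=seed,
    )


def _effect_pattern_order(t_matrix: np.ndarray) -> np.ndarray:
    """Order ROIs by agglomerative clustering (correlation distance, average
    linkage) of their effect-pattern rows."""
    r = t_matrix.shape[0]
    if r <= 2:
        return np.arange(r)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = pdist(t_matrix, metric="correlation")
    dist = np.nan_to_num(dist, nan=1.0)
    return np.asarray(leaves_list(linkage(dist, method="average")))


def roi_matrix_tfce(
    matrices: np.ndarray,
    design: GroupDesign,
    params: TFCEParams | None = None,
    seed: int = 0,
    backend: str = "auto",
) -> SelectionResult:
    """TFCE-FWE over ROI pairs of subject connectivity matrices.

    ROIs are reordered by hierarchical clustering of the observed t-matrix
    rows so that similarly affected regions are adjacent; TFCE then runs on
    the reordered matrix with 4-neighbor adjacency.  The observed ordering
    is held fixed across label permutations, keeping the enhancement
    operator identical under the null.
    """
    if params is None:
        params = TFCEParams(connectivity=4)
    matrices = np.asarray(matrices, dtype=float)
    if matrices.ndim != 3 or matrices.shape[1] != matrices.shape[2]:
        raise ValueError("matrices must be subjects x R x R")
    if not np.allclose(matrices, np.swapaxes(matrices, 1, 2)):
        raise ValueError("connectivity matrices must be symmetric")
    r = matrices.shape[1]
    mask_a, mask_b = design.masks()
    both = mask_a | mask_b
    flat = matrices[both].reshape(both.sum(), -1)
    is_a = mask_a[both]
    obs_t = _pooled_t(flat[is_a], flat[~is_a], warn=False).reshape(r, r)
    np.fill_diagonal(obs_t, 0.0)
    order = _effect_pattern_order(obs_t)
    inverse = np.argsort(order)
    mat_params = TFCEParams(
        extent_exponent=params.extent_exponent,
        height_exponent=params.height_exponent,
        n_steps=params.n_steps,
        dh=params.dh,
        connectivity=4,
        n_permutations=params.n_permutations,
        alpha=params.alpha,
    )

    def enhance(t_flat: np.ndarray) -> np.ndarray:
        t = t_flat.reshape(r, r)
        t = (t + t.T) / 2.0
        np.fill_diagonal(t, 0.0)
        reordered = t[np.ix_(order, order)]
        enh = tfce_enhance(reordered, mat_params, backend)
        return enh[np.ix_(inverse, inverse)].ravel()

    result = permutation_fwe(
        matrices.reshape(matrices.shape[0], -1),
        design,
        mat_params,
        seed=seed,
        backend=backend,
        _enhance=enhance,
    )
    result.statistic = result.statistic.reshape(r, r)
    result.enhanced = result.enhanced.reshape(r, r)
    result.pvalues = result.pvalues.reshape(r, r)
    result.mask = result.mask.reshape(r, r)
    np.fill_diagonal(result.mask, False)
    result.element_order = order
    return result


# ---------------------------------------------------------------------------
# FDR, cluster features, power filter, median test
# ---------------------------------------------------------------------------


def fdr_bh(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    pvalues = np.asarray(pvalues, dtype=float)
    if np.any((pvalues < 0) | (pvalues > 1)) or not np.all(np.isfinite(pvalues)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    reject, *_ = multipletests(pvalues.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(pvalues.shape)


def extract_cluster_features(
    maps: np.ndarray,
    mask: np.ndarray,
    min_size: int = 50,
    connectivity: int = 26,
    prefix: str = "cl",
) -> pd.DataFrame:
    """Average subject maps over connected mask components larger than
    ``min_size`` elements.

    Returns a subjects x features frame; each feature is named after the
    (rounded) component centroid, and columns are ordered by centroid so the
    naming is stable across runs.  An empty mask yields an empty frame with
    a warning.
    """
    maps = np.asarray(maps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if maps.shape[1:] != mask.shape:
        raise ValueError("mask shape must match map shape")
    if not mask.any():
        warnings.warn("empty significance mask; no cluster features extracted")
        return pd.DataFrame(index=range(maps.shape[0]))
    struct = _connectivity_structure(mask.ndim, connectivity)
    labels, n_comp = ndimage.label(mask, structure=struct)
    flat_maps = maps.reshape(maps.shape[0], -1)
    flat_labels = labels.ravel()
    features = {}
    for comp in range(1, n_comp + 1):
        idx = np.flatnonzero(flat_labels == comp)
        if idx.size <= min_size:
            continue
        centroid = np.unravel_index(idx, mask.shape)
        name = prefix + "_" + "_".join(str(int(round(c.mean()))) for c in centroid)
        features[name] = flat_maps[:, idx].mean(axis=1)
    if not features:
        warnings.warn(f"no mask component exceeded {min_size} elements")
        return pd.DataFrame(index=range(maps.shape[0]))
    return pd.DataFrame({k: features[k] for k in sorted(features)})


def detectable_effect_filter(
    n1: int, n2: int, power: float = 0.80, alpha: float = 0.05
) -> float:
    """Minimum detectable standardized effect d* of a two-sample t-test.

    Returns the smallest Cohen's d reaching the requested power at level
    ``alpha`` for group sizes ``n1``/``n2`` (noncentral-t computation);
    ``inf`` with a warning when the power is unreachable.  Callers compare
    d* against the medium-effect benchmark of 0.5 to flag underpowered
    contrasts.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    try:
        d = TTestIndPower().solve_power(
            effect_size=None, nobs1=n1, ratio=n2 / n1, alpha=alpha, power=power
        )
    except Exception:
        warnings.warn(f"power {power} unreachable for n1={n1}, n2={n2}")
        return float("inf")
    return float(np.atleast_1d(d)[0])


def permutation_median_test(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 5000,
    seed: int = 0,
) -> tuple[float, dict]:
    """Permutation test of the absolute group-median difference.

    Handles tied values gracefully (the reason to prefer it over rank
    tests); returns the add-one p-value plus median/MAD descriptives.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    observed = abs(np.median(x) - np.median(y))

    rng = np.random.default_rng(seed)
    total = comb(n, nx)
    if total <= n_permutations:
        stats_null = np.empty(total)
        for row, combo in enumerate(itertools.combinations(range(n), nx)):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            stats_null[row] = abs(np.median(pooled[sel]) - np.median(pooled[~sel]))
        p = float((stats_null >= observed - 1e-12).sum() / total)
    else:
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if abs(np.median(perm[:nx]) - np.median(perm[nx:])) >= observed - 1e-12:
                count += 1
        p = (1.0 + count) / (1.0 + n_permutations)
    descriptives = {
        "median_x": float(np.median(x)),
        "median_y": float(np.median(y)),
        "mad_x": float(stats.median_abs_deviation(x)),
        "mad_y": float(stats.median_abs_deviation(y)),
        "statistic": float(observed),
    }
    return p, descriptives


def bonferroni(pvalues: np.ndarray) -> np.ndarray:
    """Bonferroni adjustment across a family: min(1, m * p)."""
    pvalues = np.asarray(pvalues, dtype=float)
    return np.minimum(1.0, pvalues * pvalues.size)
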