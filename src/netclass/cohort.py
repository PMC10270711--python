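"""Synthetic multigroup imaging cohorts with planted connectivity effects.

This module generates cohorts that mimic the statistical structure a
multimodal brain-network classification study assumes: several clinical
groups (five frontotemporal-dementia variants plus healthy controls by
default), per-subject ROI BOLD time series drawn from group-specific
correlation structures, per-subject scalar voxel maps, FA-like structural
connectivity matrices with per-tract diffusion-metric tables, and
demographic/cognitive covariates whose group medians match published
clinical descriptives.  Effects are *planted*: a :class:`PlantedEffect`
names a target (an edge, a voxel cluster, a tract, or a node) and a
standardized effect size, and the generator records the realized targets in
a :class:`GroundTruth` object so that recovery of the planted signal can be
tested downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpecError",
    "PlantedEffect",
    "CovariatePlan",
    "CohortSpec",
    "GroundTruth",
    "Cohort",
    "generate_cohort",
    "simulate_covariates",
    "simulate_roi_timeseries",
    "simulate_voxel_maps",
    "simulate_structural",
    "base_roi_correlation",
    "base_fa_matrix",
    "nearest_correlation",
]

DEFAULT_GROUPS = ("HC", "bvFTD", "CBS", "nfvPPA", "PSP", "svPPA")
DEFAULT_SIZES = (99, 47, 38, 34, 42, 38)

VOXELMAP_METRICS = ("gcor", "lcor", "alff", "falff")
TRACT_METRICS = ("fa", "ad", "rd", "md", "nqa", "iso", "rdi")
CDR_LEVELS = np.array([0.0, 0.5, 1.0, 2.0, 3.0])

# MAD of a normal is 0.6745 sigma; published scales are median absolute deviations.
MAD_TO_SD = 1.4826


class CohortSpecError(ValueError):
    """Raised when a cohort specification is internally inconsistent."""


@dataclass(frozen=True)
class CovariatePlan:
    """Per-group location/scale plan for the demographic and cognitive covariates.

    Locations are medians; scales are median absolute deviations (converted
    internally to normal sigmas).  ``female_fraction`` parameterizes a
    Bernoulli draw for sex.
    """

    age: tuple[float, float]
    education: tuple[float, float]
    cdr: tuple[float, float]
    mmse: tuple[float, float]
    female_fraction: float


# Clinical descriptives (median, MAD) per group: age, education, CDR, MMSE,
# and percent female, for the six default groups.
DEFAULT_COVARIATES: dict[str, CovariatePlan] = {
    "HC": CovariatePlan((66.0, 4.45), (18.0, 2.97), (0.0, 0.0), (30.0, 0.0), 0.545),
    "bvFTD": CovariatePlan((62.0, 5.93), (15.5, 3.71), (1.0, 0.74), (25.0, 4.45), 0.383),
    "CBS": CovariatePlan((67.0, 8.15), (16.0, 2.97), (0.5, 0.37), (25.0, 4.45), 0.526),
    "nfvPPA": CovariatePlan((69.5, 8.90), (16.0, 2.97), (0.5, 0.0), (26.0, 2.97), 0.529),
    "PSP": CovariatePlan((68.5, 6.67), (16.0, 2.97), (0.5, 0.74), (26.0, 2.97), 0.50),
    "svPPA": CovariatePlan((64.0, 7.41), (16.0, 2.97), (1.0, 0.37), (24.5, 3.71), 0.447),
}


@dataclass(frozen=True)
class PlantedEffect:
    """A group-specific alteration planted into the synthetic data.

    Parameters
    ----------
    modality:
        ``"functional"`` (ROI-to-ROI correlation), ``"structural"`` (FA
        matrix or tract table), or ``"voxelmap"`` (scalar voxel maps).
    target:
        ``("edge", i, j)`` for connectivity matrices, ``("node", i)`` for
        every edge incident to node ``i``, ``("tract", t)`` for a tract row,
        or ``("voxel", (x, y, z), radius)`` for a spherical voxel cluster
        (radius in voxels; radius 0 is a single voxel).
    affected_groups:
        Non-empty subset of the cohort's group names.
    effect_size_d:
        Standardized mean shift (Cohen's d against the between-subject
        spread of the targeted measurement); negative values plant
        hypoconnectivity.
    metric:
        For voxelmap/tract targets, restrict the effect to one named metric
        (``None`` applies it to every metric).
    """

    modality: str
    target: tuple
    affected_groups: tuple[str, ...]
    effect_size_d: float
    metric: str | None = None


@dataclass
class CohortSpec:
    """Full specification of a synthetic cohort."""

    group_names: tuple[str, ...] = DEFAULT_GROUPS
    group_sizes: tuple[int, ...] = DEFAULT_SIZES
    n_roi: int = 116
    grid_dims: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    n_tracts: int = 40
    effect_plan: tuple[PlantedEffect, ...] = ()
    covariate_plan: Mapping[str, CovariatePlan] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    # Between-subject spread of edgewise Fisher-z connectivity beyond
    # sampling noise, of FA edges, and of tract metrics.
    sigma_subject_z: float = 0.05
    sigma_structural: float = 0.05
    sigma_tract: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_names = tuple(self.group_names)
        self.group_sizes = tuple(int(s) for s in self.group_sizes)
        self.effect_plan = tuple(self.effect_plan)
        self.validate()

    def validate(self) -> None:
        if len(set(self.group_names)) != len(self.group_names):
            raise CohortSpecError("group_names: labels must be unique")
        if len(self.group_sizes) != len(self.group_names):
            raise CohortSpecError("group_sizes: one size per group required")
        if any(s <= 0 for s in self.group_sizes):
            raise CohortSpecError("group_sizes: all sizes must be positive")
        if self.n_roi < 1:
            raise CohortSpecError("n_roi: must be >= 1")
        if len(self.grid_dims) != 3 or any(d <= 0 for d in self.grid_dims):
            raise CohortSpecError("grid_dims: three positive integers required")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise CohortSpecError("voxel_size_mm: must be positive")
        if self.n_timepoints < 20:
            raise CohortSpecError("n_timepoints: must be >= 20")
        if self.tr_seconds <= 0:
            raise CohortSpecError("tr_seconds: must be positive")
        if self.n_tracts < 1:
            raise CohortSpecError("n_tracts: must be >= 1")
        missing = [g for g in self.group_names if g not in self.covariate_plan]
        if missing:
            raise CohortSpecError(f"covariate_plan: missing groups {missing}")
        for k, eff in enumerate(self.effect_plan):
            self._validate_effect(k, eff)

    def _validate_effect(self, k: int, eff: PlantedEffect) -> None:
        where = f"effect_plan[{k}]"
        if eff.modality not in ("functional", "structural", "voxelmap"):
            raise CohortSpecError(f"{where}.modality: unknown modality {eff.modality!r}")
        if not eff.affected_groups:
            raise CohortSpecError(f"{where}.affected_groups: must be non-empty")
        unknown = [g for g in eff.affected_groups if g not in self.group_names]
        if unknown:
            raise CohortSpecError(f"{where}.affected_groups: unknown groups {unknown}")
        if not np.isfinite(eff.effect_size_d):
            raise CohortSpecError(f"{where}.effect_size_d: must be finite")
        kind = eff.target[0]
        if eff.modality == "voxelmap":
            if kind != "voxel":
                raise CohortSpecError(f"{where}.target: voxelmap effects need a voxel target")
            _, center, radius = eff.target
            if radius < 0:
                raise CohortSpecError(f"{where}.target: radius must be >= 0")
            if any(not (0 <= c < d) for c, d in zip(center, self.grid_dims)):
                raise CohortSpecError(f"{where}.target: cluster seed {center} outside grid")
            if eff.metric is not None and eff.metric not in VOXELMAP_METRICS:
                raise CohortSpecError(f"{where}.metric: unknown voxel metric {eff.metric!r}")
        elif kind == "edge":
            _, i, j = eff.target
            if i == j or not (0 <= i < self.n_roi and 0 <= j < self.n_roi):
                raise CohortSpecError(f"{where}.target: invalid edge ({i}, {j})")
        elif kind == "node":
            if not 0 <= eff.target[1] < self.n_roi:
                raise CohortSpecError(f"{where}.target: invalid node {eff.target[1]}")
        elif kind == "tract":
            if eff.modality != "structural":
                raise CohortSpecError(f"{where}.target: tract targets are structural")
            if not 0 <= eff.target[1] < self.n_tracts:
                raise CohortSpecError(f"{where}.target: invalid tract {eff.target[1]}")
            if eff.metric is not None and eff.metric not in TRACT_METRICS:
                raise CohortSpecError(f"{where}.metric: unknown tract metric {eff.metric!r}")
        else:
            raise CohortSpecError(f"{where}.target: unknown target kind {kind!r}")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def sigma_ref_z(self) -> float:
        """Expected between-subject SD of a measured Fisher-z edge."""
        return float(np.hypot(self.sigma_subject_z, 1.0 / np.sqrt(self.n_timepoints - 3)))


@dataclass
class GroundTruth:
    """Realized planted targets, one entry per planted effect."""

    entries: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"entries": self.entries}, indent=2, default=_jsonable)

    def targets(self, modality: str) -> list[dict]:
        return [e for e in self.entries if e["modality"] == modality]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class Cohort:
    """In-memory synthetic cohort: subject table plus per-subject imaging objects."""

    spec: CohortSpec
    subjects: pd.DataFrame
    roi_timeseries: dict[str, np.ndarray]
    voxel_maps: dict[str, dict[str, np.ndarray]]
    fa_matrices: dict[str, np.ndarray]
    tract_metrics: dict[str, pd.DataFrame]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects["subject_id"])

    def groups_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = dict(zip(self.subjects["subject_id"], self.subjects["group"]))
        return np.array([lookup[s] for s in ids])


# ---------------------------------------------------------------------------
# base structures (shared by every subject; fixed by the spec seed)
# ---------------------------------------------------------------------------


def _spec_rng(spec: CohortSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(stream,)))


def nearest_correlation(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive-definite correlation
    matrix (eigenvalue clipping followed by rescaling to unit diagonal)."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eps, None)
    cov = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def base_roi_correlation(spec: CohortSpec) -> np.ndarray:
    """Base ROI-to-ROI correlation from a random latent-factor model.

    ``C = cov2corr(L L' + D)`` with ``L`` an ``n_roi x k`` loading matrix, so
    positive definiteness holds by construction.
    """
    rng = _spec_rng(spec, 0)
    r = spec.n_roi
    k = max(2, r // 5)
    loadings = rng.normal(scale=0.6, size=(r, k))
    cov = loadings @ loadings.T + np.diag(rng.uniform(0.5, 1.5, size=r))
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def base_fa_matrix(spec: CohortSpec) -> np.ndarray:
    """Symmetric baseline FA-like connectivity in [0, 1] with zero diagonal."""
    rng = _spec_rng(spec, 1)
    r = spec.n_roi
    upper = rng.uniform(0.25, 0.75, size=(r, r))
    mat = np.triu(upper, 1)
    mat = mat + mat.T
    return mat


def _base_tract_table(spec: CohortSpec) -> np.ndarray:
    rng = _spec_rng(spec, 2)
    return rng.uniform(0.3, 0.7, size=(spec.n_tracts, len(TRACT_METRICS)))


# ---------------------------------------------------------------------------
# effect resolution
# ---------------------------------------------------------------------------


def _ball_indices(center, radius, dims) -> np.ndarray:
    """Flat indices of the Euclidean ball (in voxel units) clipped to the grid."""
    cx, cy, cz = center
    r = int(np.floor(radius))
    xs = np.arange(max(0, cx - r), min(dims[0], cx + r + 1))
    ys = np.arange(max(0, cy - r), min(dims[1], cy + r + 1))
    zs = np.arange(max(0, cz - r), min(dims[2], cz + r + 1))
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    dist2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
    keep = dist2 <= radius**2
    return np.ravel_multi_index((gx[keep], gy[keep], gz[keep]), dims)


@dataclass
class _ResolvedEffects:
    """Per-group additive deltas realized from the effect plan."""

    functional_z: dict[str, np.ndarray]        # group -> (R, R) Fisher-z shift
    structural: dict[str, np.ndarray]          # group -> (R, R) FA shift
    tract: dict[str, np.ndarray]               # group -> (n_tracts, 7) shift
    voxel: dict[str, dict[str, np.ndarray]]    # group -> metric -> flat shift map


def resolve_effects(spec: CohortSpec) -> tuple[_ResolvedEffects, GroundTruth]:
    r = spec.n_roi
    n_vox = int(np.prod(spec.grid_dims))
    res = _ResolvedEffects({}, {}, {}, {})
    truth = GroundTruth()

    def edge_pairs(target):
        if target[0] == "edge":
            return [(target[1], target[2])]
        node = target[1]
        return [(node, j) for j in range(r) if j != node]

    for eff in spec.effect_plan:
        entry = {
            "modality": eff.modality,
            "target": list(eff.target),
            "affected_groups": list(eff.affected_groups),
            "effect_size_d": float(eff.effect_size_d),
            "metric": eff.metric,
        }
        if eff.modality == "functional":
            shift = eff.effect_size_d * spec.sigma_ref_z
            pairs = edge_pairs(eff.target)
            for g in eff.affected_groups:
                delta = res.functional_z.setdefault(g, np.zeros((r, r)))
                for i, j in pairs:
                    delta[i, j] += shift
                    delta[j, i] += shift
            entry["edges"] = pairs
            entry["shift_z"] = shift
        elif eff.modality == "structural" and eff.target[0] == "tract":
            shift = eff.effect_size_d * spec.sigma_tract
            cols = (
                [TRACT_METRICS.index(eff.metric)]
                if eff.metric is not None
                else list(range(len(TRACT_METRICS)))
            )
            for g in eff.affected_groups:
                delta = res.tract.setdefault(
                    g, np.zeros((spec.n_tracts, len(TRACT_METRICS)))
                )
                delta[eff.target[1], cols] += shift
            entry["shift"] = shift
        elif eff.modality == "structural":
            shift = eff.effect_size_d * spec.sigma_structural
            pairs = edge_pairs(eff.target)
            for g in eff.affected_groups:
                delta = res.structural.setdefault(g, np.zeros((r, r)))
                for i, j in pairs:
                    delta[i, j] += shift
                    delta[j, i] += shift
            entry["edges"] = pairs
            entry["shift"] = shift
        else:  # voxelmap; background is unit-variance so the shift is d itself
            _, center, radius = eff.target
            idx = _ball_indices(center, radius, spec.grid_dims)
            metrics = [eff.metric] if eff.metric is not None else list(VOXELMAP_METRICS)
            for g in eff.affected_groups:
                per_metric = res.voxel.setdefault(g, {})
                for m in metrics:
                    shift_map = per_metric.setdefault(m, np.zeros(n_vox))
                    shift_map[idx] += eff.effect_size_d
            entry["voxel_indices"] = idx
            entry["shift"] = float(eff.effect_size_d)
        truth.entries.append(entry)
    return res, truth


# ---------------------------------------------------------------------------
# per-subject simulators
# ---------------------------------------------------------------------------


def simulate_covariates(
    spec: CohortSpec, group: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw demographic and cognitive covariates for ``n`` subjects of one group.

    Ages and education are normal around the configured median; sex is
    Bernoulli(female fraction) coded 1 = female; CDR is a latent normal
    snapped to the clinical scale {0, 0.5, 1, 2, 3}; MMSE is rounded and
    clipped to [0, 30].
    """
    if group not in spec.group_names:
        raise CohortSpecError(f"group: unknown group {group!r}")
    plan = spec.covariate_plan[group]

    def draw(loc_mad):
        loc, mad = loc_mad
        return loc + MAD_TO_SD * mad * rng.standard_normal(n)

    age = draw(plan.age)
    education = np.clip(draw(plan.education), 0.0, None)
    sex = (rng.random(n) < plan.female_fraction).astype(int)
    cdr_latent = draw(plan.cdr)
    cdr = CDR_LEVELS[np.argmin(np.abs(cdr_latent[:, None] - CDR_LEVELS[None, :]), axis=1)]
    mmse = np.clip(np.round(draw(plan.mmse)), 0.0, 30.0)
    return pd.DataFrame(
        {"age": age, "sex": sex, "education": education, "cdr": cdr, "mmse": mmse}
    )


def simulate_roi_timeseries(
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
    base: np.ndarray | None = None,
    delta_z: np.ndarray | None = None,
) -> np.ndarray:
    """Draw an ``n_timepoints x n_roi`` BOLD-like series for one subject.

    The subject's correlation is the base latent-factor structure shifted on
    the Fisher-z scale by the group's planted edge deltas plus subject-level
    edge noise, then projected back to the nearest positive-definite
    correlation matrix.
    """
    if group not in spec.group_names:
        raise CohortSpecError(f"group: unknown group {group!r}")
    if spec.n_roi == 1:
        return rng.standard_normal((spec.n_timepoints, 1))
    if base is None:
        base = base_roi_correlation(spec)
    z = np.arctanh(np.clip(base, -1 + 1e-9, 1 - 1e-9))
    np.fill_diagonal(z, 0.0)
    if delta_z is not None:
        z = z + delta_z
    if spec.sigma_subject_z > 0:
        noise = rng.standard_normal((spec.n_roi, spec.n_roi))
        noise = (noise + noise.T) / np.sqrt(2.0)
        np.fill_diagonal(noise, 0.0)
        z = z + spec.sigma_subject_z * noise
    corr = np.tanh(z)
    np.fill_diagonal(corr, 1.0)
    corr = nearest_correlation(corr)
    off = np.abs(corr - np.eye(spec.n_roi))
    if np.any(off >= 1.0):
        bad = np.argwhere(off >= 1.0)
        raise CohortSpecError(
            f"subject correlation not positive definite; offending edges {bad[:5].tolist()}"
        )
    chol = np.linalg.cholesky(corr)
    return rng.standard_normal((spec.n_timepoints, spec.n_roi)) @ chol.T


def simulate_voxel_maps(
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
    shifts: Mapping[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Surrogate scalar maps (one per raw functional metric) for one subject.

    Background voxels are i.i.d. standard normal; planted clusters are
    shifted additively for affected groups.
    """
    if group not in spec.group_names:
        raise CohortSpecError(f"group: unknown group {group!r}")
    maps = {}
    for m in VOXELMAP_METRICS:
        flat = rng.standard_normal(int(np.prod(spec.grid_dims)))
        if shifts is not None and m in shifts:
            flat = flat + shifts[m]
        maps[m] = flat.reshape(spec.grid_dims)
    return maps


def simulate_structural(
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
    base_fa: np.ndarray | None = None,
    base_tracts: np.ndarray | None = None,
    delta_fa: np.ndarray | None = None,
    delta_tract: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """FA-like connectivity matrix plus a 7-metric tract table for one subject."""
    if group not in spec.group_names:
        raise CohortSpecError(f"group: unknown group {group!r}")
    if base_fa is None:
        base_fa = base_fa_matrix(spec)
    if base_tracts is None:
        base_tracts = _base_tract_table(spec)
    noise = rng.standard_normal((spec.n_roi, spec.n_roi))
    noise = (noise + noise.T) / np.sqrt(2.0)
    fa = base_fa + spec.sigma_structural * noise
    if delta_fa is not None:
        fa = fa + delta_fa
    fa = np.clip(fa, 0.0, 1.0)
    np.fill_diagonal(fa, 0.0)

    tracts = base_tracts + spec.sigma_tract * rng.standard_normal(base_tracts.shape)
    if delta_tract is not None:
        tracts = tracts + delta_tract
    table = pd.DataFrame(tracts, columns=list(TRACT_METRICS))
    table.index.name = "tract"
    return fa, table


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def generate_cohort(spec: CohortSpec) -> tuple[Cohort, GroundTruth]:
    """Generate a full cohort and the ground truth of its planted effects.

    Identical specs (including seed) produce bit-identical cohorts; every
    subject draws from its own child random stream so the output does not
    depend on evaluation order.
    """
    spec.validate()
    effects, truth = resolve_effects(spec)
    base_corr = base_roi_correlation(spec) if spec.n_roi > 1 else None
    base_fa = base_fa_matrix(spec)
    base_tracts = _base_tract_table(spec)

    root = np.random.SeedSequence(entropy=spec.seed, spawn_key=(100,))
    subject_seeds = root.spawn(spec.n_subjects)
    cov_rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(101,)))

    rows = []
    roi_ts: dict[str, np.ndarray] = {}
    voxel_maps: dict[str, dict[str, np.ndarray]] = {}
    fa_mats: dict[str, np.ndarray] = {}
    tract_tabs: dict[str, pd.DataFrame] = {}

    idx = 0
    for group, size in zip(spec.group_names, spec.group_sizes):
        covs = simulate_covariates(spec, group, size, cov_rng)
        dz = effects.functional_z.get(group)
        dfa = effects.structural.get(group)
        dtr = effects.tract.get(group)
        vshift = effects.voxel.get(group)
        for k in range(size):
            sid = f"sub-{idx:04d}"
            rng = np.random.default_rng(subject_seeds[idx])
            roi_ts[sid] = simulate_roi_timeseries(spec, group, rng, base_corr, dz)
            voxel_maps[sid] = simulate_voxel_maps(spec, group, rng, vshift)
            fa_mats[sid], tract_tabs[sid] = simulate_structural(
                spec, group, rng, base_fa, base_tracts, dfa, dtr
            )
            rows.append({"subject_id": sid, "group": group, **covs.iloc[k].to_dict()})
            idx += 1

    subjects = pd.DataFrame(rows)
    subjects["sex"] = subjects["sex"].astype(int)
    cohort = Cohort(
        spec=spec,
        subjects=subjects,
        roi_timeseries=roi_ts,
        voxel_maps=voxel_maps,
        fa_matrices=fa_mats,
        tract_metrics=tract_tabs,
    )
    return cohort, truth
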