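"""Gaussian-process Bayesian optimization for hyperparameter search.

A probabilistic surrogate (GP with Matern-5/2 kernel on the unit-cube
rescaling of the search space, log-scaled where a parameter range is
declared logarithmic) plus an expected-improvement acquisition decide the
next point to evaluate.  The first few points are a seeded random design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

__all__ = ["ParamRange", "HyperparamSpace", "bayesian_optimize"]


@dataclass(frozen=True)
class ParamRange:
    """Bounded range of one hyperparameter; ``log`` ranges are searched on a
    logarithmic scale and ``integer`` ranges are rounded on evaluation."""

    low: float
    high: float
    log: bool = False
    integer: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.low) or not np.isfinite(self.high):
            raise ValueError("bounds must be finite")
        if not self.low < self.high:
            raise ValueError(f"lower bound must be below upper, got ({self.low}, {self.high})")
        if self.log and self.low <= 0:
            raise ValueError("log-scaled ranges need a positive lower bound")

    def from_unit(self, u: float):
        if self.log:
            value = np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low)))
        else:
            value = self.low + u * (self.high - self.low)
        return int(round(value)) if self.integer else float(value)


@dataclass
class HyperparamSpace:
    """Named collection of parameter ranges."""

    params: dict[str, ParamRange] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.params)

    @property
    def ndim(self) -> int:
        return len(self.params)

    def from_unit(self, u: np.ndarray) -> dict:
        return {name: rng.from_unit(ui) for (name, rng), ui in zip(self.params.items(), u)}


def _expected_improvement(gp, candidates: np.ndarray, best: float) -> np.ndarray:
    mu, sigma = gp.predict(candidates, return_std=True)
    imp = mu - best - 1e-3
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, imp / sigma, 0.0)
        ei = np.where(sigma > 0, imp * stats.norm.cdf(z) + sigma * stats.norm.pdf(z), np.maximum(imp, 0.0))
    return ei


def bayesian_optimize(
    objective,
    space: HyperparamSpace,
    n_iterations: int = 30,
    seed: int = 0,
    n_initial: int = 5,
    n_candidates: int = 1024,
) -> tuple[dict, list[dict]]:
    """Maximize ``objective(params) -> score`` over ``space``.

    Returns ``(best_params, history)`` where each history record carries the
    evaluated parameters, the score (None on failure), and the incumbent
    best score so far (non-decreasing by construction).  A failing objective
    evaluation is recorded and the search continues.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if space.ndim == 0:
        raise ValueError("empty hyperparameter space")
    rng = np.random.default_rng(seed)
    gp_seed = int(rng.integers(2**31 - 1))
    coords: list[np.ndarray] = []
    scores: list[float] = []
    history: list[dict] = []
    best_score = -np.inf
    best_params: dict | None = None

    for it in range(n_iterations):
        if it < min(n_initial, n_iterations) or len(scores) < 2:
            u = rng.random(space.ndim)
        else:
            gp = GaussianProcessRegressor(
                kernel=ConstantKernel(1.0, (1e-3, 1e3))
                * Matern(length_scale=0.3 * np.ones(space.ndim), nu=2.5,
                         length_scale_bounds=(1e-2, 1e2)),
                alpha=1e-6,
                normalize_y=True,
                n_restarts_optimizer=1,
                random_state=gp_seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(np.vstack(coords), np.asarray(scores))
            candidates = rng.random((n_candidates, space.ndim))
            ei = _expected_improvement(gp, candidates, max(scores))
            u = candidates[int(np.argmax(ei))]
        params = space.from_unit(u)
        try:
            score = float(objective(params))
        except Exception as exc:  # noqa: BLE001 - failed points are data, not fatal
            history.append({"params": params, "score": None, "error": str(exc),
                            "best_so_far": best_score if np.isfinite(best_score) else None})
            continue
        coords.append(u)
        scores.append(score)
        if score > best_score:
            best_score = score
            best_params = params
        history.append({"params": params, "score": score, "best_so_far": best_score})

    if best_params is None:
        raise RuntimeError("every objective evaluation failed")
    return best_params, history
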