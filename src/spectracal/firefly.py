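"""Binary firefly-algorithm wavelength selection.

Each firefly holds a continuous position in [0, 1]^W over the W spectral
channels; the binary mask scored for fitness is ``position > 0.5``
(threshold binarisation; sigmoid-sampling is available as an option).
Fitness is the leave-one-out RRMSECV of an ANN trained on the masked
channels — lower is brighter. Every generation each firefly moves toward
every brighter one with the canonical attraction kernel
``beta0 * exp(-gamma * r^2)`` (Euclidean r on the continuous positions)
plus a uniform random perturbation scaled by ``alpha``; positions are
clipped back to [0, 1].

The search is elitist: the best mask ever evaluated is returned, and the
run stops early when the best fitness improves by less than 1e-6
(absolute percentage points) over ``stagnation_window`` consecutive
generations — the "no significant improvement for 50 iterations" rule.

One member of the initial population is warm-started at the all-ones
(full-spectrum) mask, so the selected subset can never score worse than
the full-spectrum model under the same cross-validation budget. Fitness
values are cached per mask, which makes small search spaces (and the
brute-force comparisons in the test-suite) cheap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ann import AnnConfig, loo_cross_validate
from .exceptions import DomainError, ShapeError

__all__ = [
    "FaParams",
    "SelectionResult",
    "attraction",
    "fa_select",
    "grid_search_fa",
    "DEFAULT_GRID",
]

_IMPROVEMENT_EPS = 1e-6  # absolute % RRMSECV counted as "significant"

# canonical firefly-literature grid; the published supplementary grid is
# not available, so this stand-in spans the usual decades
DEFAULT_GRID = {"gamma": [0.1, 1.0, 10.0], "beta0": [0.5, 1.0, 2.0], "alpha": [0.1, 0.2, 0.5]}


@dataclass(frozen=True)
class FaParams:
    """Firefly-algorithm hyperparameters.

    ``min_selected`` defaults (when None) to ``n_hidden + 2`` of the ANN
    used for fitness, keeping the downstream network from collapsing to
    fewer inputs than neurons.
    """

    n_fireflies: int = 20
    max_generations: int = 100
    gamma: float = 1.0
    beta0: float = 1.0
    alpha: float = 0.2
    stagnation_window: int = 50
    min_selected: int | None = None
    seed: int = 0
    binarization: str = "threshold"  # or "sigmoid"

    def __post_init__(self):
        if self.n_fireflies < 2:
            raise DomainError("need at least 2 fireflies")
        if self.gamma <= 0 or self.beta0 <= 0 or self.alpha < 0:
            raise DomainError("gamma, beta0 must be > 0 and alpha >= 0")
        if self.stagnation_window < 1:
            raise DomainError("stagnation_window must be >= 1")
        if self.min_selected is not None and self.min_selected < 1:
            raise DomainError("min_selected must be >= 1")
        if self.binarization not in ("threshold", "sigmoid"):
            raise DomainError(f"unknown binarization {self.binarization!r}")


@dataclass
class SelectionResult:
    """Best wavelength mask found by one FA run."""

    mask: np.ndarray  # bool over grid columns
    best_rrmsecv: float
    history: list[float]  # best-so-far fitness per generation
    generations_run: int
    params: FaParams

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def to_dict(self) -> dict:
        return {
            "mask": "".join("1" if m else "0" for m in self.mask),
            "best_rrmsecv": self.best_rrmsecv,
            "history": list(self.history),
            "generations_run": self.generations_run,
            "params": {
                k: getattr(self.params, k)
                for k in ("n_fireflies", "max_generations", "gamma", "beta0", "alpha",
                          "stagnation_window", "min_selected", "seed", "binarization")
            },
        }


def attraction(beta0: float, gamma: float, r: float) -> float:
    """Canonical firefly attraction beta0 * exp(-gamma * r^2)."""
    if r < 0:
        raise DomainError("distance must be >= 0")
    return float(beta0 * np.exp(-gamma * r * r))


def _binarize(positions: np.ndarray, params: FaParams, rng) -> np.ndarray:
    if params.binarization == "threshold":
        return positions > 0.5
    prob = 1.0 / (1.0 + np.exp(-10.0 * (positions - 0.5)))
    return rng.random(positions.shape) < prob


def fa_select(X: np.ndarray, y: np.ndarray, params: FaParams, ann_config: AnnConfig,
              include_full_mask: bool = True) -> SelectionResult:
    """Run the binary firefly search over the columns of X.

    Masks with fewer than ``min_selected`` channels are infeasible and
    scored +inf. If every initial candidate is infeasible the
    initialisation is retried once with a shifted seed before failing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    W = X.shape[1]
    min_sel = params.min_selected if params.min_selected is not None else ann_config.n_hidden + 2
    if W < min_sel:
        raise ShapeError(f"only {W} columns but min_selected = {min_sel}")

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        if int(mask.sum()) < min_sel:
            return float("inf")
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = loo_cross_validate(X, y, ann_config, wavelength_mask=mask).rrmsecv
        return cache[key]

    for attempt in range(2):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(params.seed), attempt]).generate_state(2)
        )
        positions = rng.uniform(0.0, 1.0, size=(params.n_fireflies, W))
        if include_full_mask:
            positions[0] = 0.9  # binarises to the all-ones (full-spectrum) mask
        bin_rng = np.random.default_rng(
            np.random.SeedSequence([int(params.seed), attempt, 7]).generate_state(2)
        )
        masks = _binarize(positions, params, bin_rng)
        fits = np.array([fitness(m) for m in masks])
        if np.isfinite(fits).any():
            break
    else:
        raise DomainError("all initial fireflies infeasible after one retry")

    best_i = int(np.argmin(fits))
    best_fit = float(fits[best_i])
    best_mask = masks[best_i].copy()
    history: list[float] = []
    gens = 0
    stagnant = 0
    for gen in range(params.max_generations):
        gens = gen + 1
        for i in range(params.n_fireflies):
            for j in range(params.n_fireflies):
                if fits[j] < fits[i]:
                    r = float(np.linalg.norm(positions[i] - positions[j]))
                    beta = attraction(params.beta0, params.gamma, r)
                    positions[i] = (
                        positions[i]
                        + beta * (positions[j] - positions[i])
                        + params.alpha * (rng.uniform(size=W) - 0.5)
                    )
                    np.clip(positions[i], 0.0, 1.0, out=positions[i])
            masks[i] = _binarize(positions[i], params, bin_rng)
            fits[i] = fitness(masks[i])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit - 0.0:
            if best_fit - fits[gen_best] < _IMPROVEMENT_EPS:
                stagnant += 1
            else:
                stagnant = 0
            best_fit = float(fits[gen_best])
            best_mask = masks[gen_best].copy()
        else:
            stagnant += 1
        history.append(best_fit)
        if stagnant >= params.stagnation_window:
            break
    return SelectionResult(
        mask=best_mask,
        best_rrmsecv=best_fit,
        history=history,
        generations_run=gens,
        params=params,
    )


def grid_search_fa(X, y, grids: dict, ann_config: AnnConfig,
                   base_params: FaParams = FaParams()) -> tuple[FaParams, pd.DataFrame]:
    """Exhaustive FA-hyperparameter grid search.

    ``grids`` maps FaParams field names to candidate lists. Each cell
    runs :func:`fa_select` with a seed derived from the base seed and the
    cell index; ties in best RRMSECV break toward the smaller mask, then
    toward earlier grid order.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise DomainError("grids must be non-empty")
    keys = list(grids)
    rows = []
    best = None  # (rrmsecv, popcount, order, params)
    for order, combo in enumerate(itertools.product(*(grids[k] for k in keys))):
        cell_seed = int(np.random.SeedSequence([int(base_params.seed), 31, order]).generate_state(1)[0])
        params = replace(base_params, seed=cell_seed, **dict(zip(keys, combo)))
        result = fa_select(X, y, params, ann_config)
        rows.append(dict(zip(keys, combo), best_rrmsecv=result.best_rrmsecv,
                         n_selected=result.n_selected))
        key = (result.best_rrmsecv, result.n_selected, order)
        if best is None or key < best[0]:
            best = (key, params)
    return best[1], pd.DataFrame(rows)
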