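"""PLS-coefficient-based wavelength selection: CARS, BOSS and UVE.

All three selectors score wavelengths through the regression-coefficient
vector of PLS1 models fit on class codes and pick the variable set with
the lowest cross-validated RMSE:

* CARS (competitive adaptive reweighted sampling) shrinks the variable
  set over Monte-Carlo runs with an exponential-decay retention schedule
  and adaptive reweighted resampling proportional to |b|.
* BOSS (bootstrap soft shrinkage) draws weighted bootstrap variable
  subsets, ranks the resulting sub-models (model population analysis),
  and softly re-weights variables by the summed |b| over the best
  sub-models, never hard-zeroing a variable until its weight underflows.
* UVE (uninformative variable elimination) appends as many artificial
  noise variables as real ones, measures each coefficient's stability
  (mean/sd across CV folds) and discards real variables no more stable
  than the most stable noise variable.

Each selector is deterministic given (data, parameters, seed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from ._fastpath import cv_rmse_path
from .pls import _canonical_folds, _nipals_path, fit_pls, rmsecv

__all__ = [
    "SelectionResult",
    "cars_select",
    "uve_select",
    "boss_select",
    "encode_labels",
    "band_enrichment_pvalue",
]


def encode_labels(labels: Sequence, class_order: Sequence) -> np.ndarray:
    """Integer response codes 0..K-1 in the declared class order."""
    lut = {c: i for i, c in enumerate(class_order)}
    try:
        return np.asarray([lut[l] for l in labels], dtype=float)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in class order {list(class_order)}")


@dataclass
class SelectionResult:
    """Outcome of a wavelength-selection run."""

    method: str  # "CARS" | "BOSS" | "UVE"
    selected_idx: np.ndarray
    rmsecv_trajectory: np.ndarray
    best_iteration: int
    weights_history: np.ndarray
    seed: int
    n_variables: int
    extras: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_idx, dtype=int)
        object.__setattr__(self, "selected_idx", idx)
        object.__setattr__(
            self, "rmsecv_trajectory", np.asarray(self.rmsecv_trajectory, dtype=float)
        )
        if idx.size == 0:
            raise ValueError("selected_idx must be non-empty")
        if np.unique(idx).size != idx.size:
            raise ValueError("selected_idx contains duplicates")
        if idx.min() < 0 or idx.max() >= self.n_variables:
            raise ValueError("selected_idx out of grid bounds")


def _cv_cap(n: int, folds: int, n_vars: int, cap: int) -> int:
    """Largest usable component count for k-fold CV on this problem."""
    min_train = n - math.ceil(n / folds)
    return max(1, min(cap, n_vars, min_train - 1))


def cars_decay_schedule(p: int, n_runs: int) -> np.ndarray:
    """Retained-variable counts ceil(r_i * p), r_i = a*exp(-k*i).

    The decay constants solve the boundary conditions r_1 = 1 (keep all p
    variables on the first run) and r_{n_runs} = 2/p (keep two at the last).
    """
    if p < 3:
        raise ValueError("CARS needs at least 3 variables")
    if n_runs < 2:
        raise ValueError("CARS needs at least 2 Monte-Carlo runs")
    k = math.log(p / 2.0) / (n_runs - 1)
    i = np.arange(1, n_runs + 1)
    ratios = np.exp(-k * (i - 1))  # a*exp(-k*i) with a = exp(k)
    return np.ceil(ratios * p).astype(int)


def cars_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    n_runs: int = 100,
    folds: int = 5,
    seed: int = 0,
    max_components: int = 10,
    sample_fraction: float = 0.8,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Per run: fit PLS on a Monte-Carlo subset of the training samples,
    keep the scheduled top fraction of variables by |b| (enforced
    reduction), resample that set with probability proportional to |b|
    (adaptive reweighted sampling, with replacement then deduplicated),
    and record the subset's RMSECV.  The subset with minimal RMSECV wins.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    n, p = X.shape
    schedule = cars_decay_schedule(p, n_runs)
    rng = np.random.default_rng(seed)
    n_mc = max(2, int(math.floor(sample_fraction * n)))
    # one fixed fold assignment so per-run RMSECVs differ only in the subset
    fold_idx = _canonical_folds(X, y, folds, seed)
    # component count chosen once on the full variable set; reusing it for the
    # Monte-Carlo weighting fits keeps |b| from soaking up noise directions
    base_cap = _cv_cap(n, folds, p, max_components)
    n_comp = rmsecv(
        X, y, max_components=base_cap, folds=folds, seed=seed, fold_indices=fold_idx
    ).best_n_components

    current = np.arange(p)
    subsets: list[np.ndarray] = []
    trajectory: list[float] = []
    for i in range(n_runs):
        rows = rng.choice(n, size=n_mc, replace=False)
        comps = max(1, min(n_comp, current.size, n_mc - 1))
        if np.ptp(y[rows]) == 0.0:  # pathological Monte-Carlo draw
            continue
        model = fit_pls(X[np.ix_(rows, current)], y[rows], comps)
        weight = np.abs(model.b)

        keep = min(schedule[i], current.size)
        order = np.argsort(-weight, kind="stable")[:keep]  # ties -> lowest index
        reduced = current[np.sort(order)]
        w_red = weight[np.sort(order)]

        total = w_red.sum()
        prob = w_red / total if total > 0 else np.full(keep, 1.0 / keep)
        # p draws with replacement keep the expected unique count near the
        # schedule; dedup then yields the competing subset
        draws = rng.choice(reduced, size=p, replace=True, p=prob)
        subset = np.unique(draws)
        if subset.size < 2:
            break  # collapsed; truncate the trajectory here

        cv_cap = _cv_cap(n, folds, subset.size, max_components)
        cv = rmsecv(
            X[:, subset], y, max_components=cv_cap, folds=folds, seed=seed,
            fold_indices=fold_idx,
        )
        subsets.append(subset)
        trajectory.append(cv.best_rmsecv)
        current = subset

    if not subsets:
        raise RuntimeError("CARS produced no usable subset")
    best = int(np.argmin(trajectory))
    return SelectionResult(
        method="CARS",
        selected_idx=subsets[best],
        rmsecv_trajectory=np.asarray(trajectory),
        best_iteration=best,
        weights_history=schedule[: len(trajectory)],
        seed=seed,
        n_variables=p,
        extras={
            "retained_schedule": schedule,
            "subset_sizes": np.asarray([s.size for s in subsets]),
        },
    )


def uve_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    n_components: int | None = None,
    folds: int = 5,
    seed: int = 0,
    noise_scale: float = 1e-10,
    max_components: int = 10,
    n_repeats: int = 8,
) -> SelectionResult:
    """Uninformative variable elimination with appended noise variables.

    Noise columns are uniform [0, 1] scaled by ``noise_scale`` so they
    cannot influence the fit numerically while still yielding
    well-defined coefficients.  One coefficient vector is collected per
    left-out fold over ``n_repeats`` repetitions of the k-fold scheme
    (repeats make the fold-to-fold sd estimate stable enough that the
    max-over-noise cutoff is meaningful).  Stability
    c_j = mean(b_j) / sd(b_j); real variables with |c| above the largest
    noise |c| survive.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("UVE needs at least 2 variables")
    rng = np.random.default_rng(seed)
    noise = rng.uniform(0.0, 1.0, size=(n, p)) * noise_scale
    Xa = np.hstack([X, noise])

    if n_components is None:
        cv_cap = _cv_cap(n, folds, p, max_components)
        n_components = rmsecv(X, y, max_components=cv_cap, folds=folds, seed=seed).best_n_components

    coefs = np.zeros((n_repeats * folds, 2 * p))
    row = 0
    for rep in range(n_repeats):
        fold_idx = _canonical_folds(X, y, folds, seed + rep)
        for test in fold_idx:
            mask = np.ones(n, dtype=bool)
            mask[test] = False
            *_, B = _nipals_path(Xa[mask], y[mask], n_components)
            coefs[row] = B[n_components - 1]
            row += 1

    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1)
    zero_sd = sd == 0.0
    if zero_sd.any():
        warnings.warn(
            f"{int(zero_sd.sum())} coefficients have zero fold variance; "
            "stability set to signed infinity",
            RuntimeWarning,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        stability = np.where(zero_sd, np.sign(mean) * np.inf, mean / sd)
    cutoff = float(np.max(np.abs(stability[p:])))
    survivors = np.nonzero(np.abs(stability[:p]) > cutoff)[0]

    fallback_used = survivors.size == 0
    selected = survivors if not fallback_used else np.array([int(np.argmax(np.abs(stability[:p])))])
    cv_cap = _cv_cap(n, folds, selected.size, max_components)
    cv = rmsecv(X[:, selected], y, max_components=cv_cap, folds=folds, seed=seed)
    return SelectionResult(
        method="UVE",
        selected_idx=selected,
        rmsecv_trajectory=np.asarray([cv.best_rmsecv]),
        best_iteration=0,
        weights_history=stability[:p],
        seed=seed,
        n_variables=p,
        extras={
            "noise_stability": stability[p:],
            "cutoff": cutoff,
            "n_survivors": int(survivors.size),
            "fallback_used": fallback_used,
            "n_components": int(n_components),
        },
    )


def boss_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    n_bootstrap: int = 1000,
    folds: int = 5,
    seed: int = 0,
    best_fraction: float = 0.1,
    max_components: int = 5,
    max_iterations: int = 100,
    weight_floor: float = 1e-6,
) -> SelectionResult:
    """Bootstrap soft shrinkage.

    Iterates weighted bootstrap sampling of variable subsets, scores each
    sub-model by RMSECV, and redistributes weight proportionally to the
    summed |b| over the best ``best_fraction`` of sub-models.  A relative
    floor keeps downweighted variables alive (soft shrinkage) until their
    weight underflows.  Iterations stop when the best subset shrinks to a
    single variable; the iteration with minimal RMSECV provides the
    selected set.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("BOSS needs at least 2 variables")
    rng = np.random.default_rng(seed)
    fold_idx = _canonical_folds(X, y, folds, seed)
    fold_ids = np.empty(n, dtype=np.int64)
    for f, test in enumerate(fold_idx):
        fold_ids[test] = f
    min_train = n - max(len(f) for f in fold_idx)

    weights = np.full(p, 1.0 / p)
    trajectory: list[float] = []
    best_sets: list[np.ndarray] = []
    weights_hist: list[np.ndarray] = [weights.copy()]
    n_best = max(1, int(round(best_fraction * n_bootstrap)))

    for _ in range(max_iterations):
        # softly-shrunk variables stop being drawn once their weight decays
        # below the floor; the bootstrap draw count follows the active set
        active = int(np.count_nonzero(weights > weight_floor * weights.max()))
        n_draw = max(2, active)
        subsets: list[np.ndarray] = []
        scores = np.empty(n_bootstrap)
        comps_used = np.empty(n_bootstrap, dtype=int)
        for s in range(n_bootstrap):
            vars_s = np.unique(rng.choice(p, size=n_draw, replace=True, p=weights))
            comps = max(1, min(max_components, vars_s.size, min_train - 1))
            # k-fold RMSECV with the shared fold assignment (compiled path)
            curve = cv_rmse_path(
                np.ascontiguousarray(X[:, vars_s]), y, fold_ids, folds, comps
            )
            k_best = int(np.argmin(curve))
            subsets.append(vars_s)
            scores[s] = curve[k_best]
            comps_used[s] = k_best + 1

        order = np.argsort(scores, kind="stable")
        elite = order[:n_best]
        raw = np.zeros(p)
        for s in elite:
            model = fit_pls(X[:, subsets[s]], y, int(comps_used[s]))
            raw[subsets[s]] += np.abs(model.b)

        best_s = int(order[0])
        trajectory.append(float(scores[best_s]))
        best_sets.append(subsets[best_s])

        if raw.sum() == 0.0:
            break
        # soft shrinkage: variables missing from every elite sub-model keep a
        # geometrically decaying share of their previous weight rather than a
        # hard zero, until it underflows past the draw floor
        soft = raw / raw.sum() + 1e-4 * weights
        weights = soft / soft.sum()
        weights_hist.append(weights.copy())
        if subsets[best_s].size <= 1:
            break
        if np.count_nonzero(weights > weight_floor * weights.max()) <= 1:
            break

    best = int(np.argmin(trajectory))
    return SelectionResult(
        method="BOSS",
        selected_idx=best_sets[best],
        rmsecv_trajectory=np.asarray(trajectory),
        best_iteration=best,
        weights_history=np.asarray(weights_hist),
        seed=seed,
        n_variables=p,
        extras={"best_subset_sizes": np.asarray([s.size for s in best_sets])},
    )


def band_enrichment_pvalue(
    selected_idx: np.ndarray, band_idx: np.ndarray, n_variables: int
) -> float:
    """Hypergeometric tail p-value for selected variables landing in bands.

    Null: the ``len(selected_idx)`` selections are drawn uniformly without
    replacement from the ``n_variables`` grid positions.
    """
    selected = np.asarray(selected_idx)
    band = np.asarray(band_idx)
    k = int(np.isin(selected, band).sum())
    return float(hypergeom.sf(k - 1, n_variables, band.size, selected.size))
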