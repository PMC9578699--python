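"""Behavioural models of the breadth-depth trade-off and their fitting.

Six families predict the mean number of sampled alternatives M as a
function of capacity C: a depth model (M = 2), pure breadth (M = C), a
free-slope linear model (M = dC), a square-root model (M = sqrt(C)), a
free power law (M = C^w), and the ideal-observer policy (M = M_opt(C)).
Observed M values are linked to the prediction through one of two noise
models: a Gaussian with capacity-dependent spread sigma = a + bC, or a
binomial M ~ Binomial(n, p) with n = round(M(C)/p), so that the expected
M matches the model prediction.  Parameters are fitted by exhaustive
grid search of the log-likelihood; models are compared by fourfold
cross-validated log-likelihood (CVLL) and by AIC on the full data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binom

from .task import Environment, TrialRecord
from . import ideal

__all__ = [
    "FAMILIES",
    "FREE_FAMILY_PARAMS",
    "Grid",
    "DEFAULT_GRIDS",
    "ModelFamily",
    "FitResult",
    "CVResult",
    "FitFailureError",
    "mean_m",
    "gaussian_loglik",
    "binomial_loglik",
    "grid_fit",
    "cross_validate",
    "aic",
    "compare_models",
]

FAMILIES = ("depth", "pure_breadth", "linear", "square_root", "free_power", "optimal")

#: name of the free family parameter, if any
FREE_FAMILY_PARAMS: Mapping[str, Optional[str]] = {
    "depth": None,
    "pure_breadth": None,
    "linear": "d",
    "square_root": None,
    "free_power": "w",
    "optimal": None,
}

LOG_2PI = math.log(2.0 * math.pi)


class FitFailureError(RuntimeError):
    """Raised when no grid point yields a finite likelihood."""


@dataclass(frozen=True)
class Grid:
    """An inclusive arithmetic parameter grid."""

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0 or self.stop < self.start:
            raise ValueError(f"invalid grid {self}")

    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step))
        return np.round(self.start + self.step * np.arange(n + 1), 10)


# w and p grids follow the published fitting procedure; the Gaussian
# (a, b) bounds are as printed uninterpretable (they allow sigma <= 0 and
# an empty b grid), so symmetric bounds with the same 0.05 step are used
# and any grid point giving sigma <= 0 for some capacity is rejected.
# The linear slope d gets the same grid as w.
DEFAULT_GRIDS: Mapping[str, Grid] = {
    "w": Grid(0.05, 1.1, 0.05),
    "d": Grid(0.05, 1.1, 0.05),
    "p": Grid(0.01, 1.0, 0.01),
    "a": Grid(-3.0, 3.0, 0.05),
    "b": Grid(-1.0, 1.0, 0.05),
}


@dataclass(frozen=True)
class ModelFamily:
    """A model family plus any fixed free-parameter values."""

    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    optimal_curve: Optional[Mapping[int, int]] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "optimal" and self.optimal_curve is None:
            raise ValueError("optimal family requires an optimal_curve lookup")


def _mean_vector(
    family: str,
    params: Mapping[str, float],
    capacities: np.ndarray,
    optimal_curve: Optional[Mapping[int, int]],
) -> np.ndarray:
    if family == "depth":
        return np.full_like(capacities, 2.0, dtype=float)
    if family == "pure_breadth":
        return capacities.astype(float)
    if family == "linear":
        return params["d"] * capacities
    if family == "square_root":
        return np.sqrt(capacities)
    if family == "free_power":
        return capacities.astype(float) ** params["w"]
    if family == "optimal":
        assert optimal_curve is not None
        try:
            return np.array([float(optimal_curve[int(c)]) for c in capacities])
        except KeyError as exc:
            raise ValueError(f"capacity {exc} missing from optimal curve") from None
    raise ValueError(f"unknown family {family!r}")


def mean_m(model: ModelFamily, capacity: int) -> float:
    """The family's predicted mean number of sampled alternatives M(C)."""
    if capacity < 2:
        raise ValueError("capacity must be >= 2")
    return float(
        _mean_vector(
            model.family, model.params, np.array([capacity]), model.optimal_curve
        )[0]
    )


def _extract(trials: Sequence[TrialRecord]) -> Tuple[np.ndarray, np.ndarray]:
    c = np.array([t.capacity for t in trials], dtype=float)
    m = np.array([t.allocation.m for t in trials], dtype=float)
    return c, m


def gaussian_loglik(
    trials: Sequence[TrialRecord],
    model: ModelFamily,
    a: float,
    b: float,
    mu: float = 0.0,
) -> float:
    """Sum of log normal densities of observed M around M(C) + mu.

    The spread grows linearly with capacity, sigma = a + bC; parameters
    giving any sigma <= 0 are rejected with -inf.
    """
    c, m = _extract(trials)
    mean = _mean_vector(model.family, model.params, c, model.optimal_curve) + mu
    sigma = a + b * c
    if np.any(sigma <= 0):
        return -np.inf
    resid = m - mean
    return float(np.sum(-0.5 * LOG_2PI - np.log(sigma) - resid**2 / (2 * sigma**2)))


def binomial_loglik(
    trials: Sequence[TrialRecord],
    model: ModelFamily,
    p: float,
    mu: float = 0.0,
) -> float:
    """Binomial-noise log-likelihood of observed M.

    Per trial, n = round((M(C) + mu) / p) clamped to >= 1 so that the
    expected M matches the model's prediction; trials with M > n are
    impossible events and contribute -inf.
    """
    if not 0 < p <= 1:
        raise ValueError("binomial p must lie in (0, 1]")
    c, m = _extract(trials)
    mean = _mean_vector(model.family, model.params, c, model.optimal_curve) + mu
    n = np.maximum(np.rint(mean / p), 1.0)
    return float(np.sum(binom.logpmf(m, n, p)))


def aic(total_loglik: float, n_free_params: int) -> float:
    """Akaike information criterion, 2k - 2 LL."""
    return 2.0 * n_free_params - 2.0 * total_loglik


@dataclass(frozen=True)
class FitResult:
    family: str
    noise_kind: str
    params: Dict[str, float]
    loglik: float
    n_free_params: int
    n_trials: int

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.n_free_params)


@dataclass(frozen=True)
class CVResult:
    family: str
    noise_kind: str
    params: Dict[str, float]
    train_loglik: float
    fold_logliks: Tuple[float, ...]
    cvll: float
    n_excluded_folds: int
    aic: float


def _family_param_dicts(
    family: str, grids: Mapping[str, Grid]
) -> List[Dict[str, float]]:
    name = FREE_FAMILY_PARAMS[family]
    if name is None:
        return [{}]
    return [{name: float(v)} for v in grids[name].values()]


def _noise_loglik_table(
    noise_kind: str,
    mean: np.ndarray,
    m_obs: np.ndarray,
    c_obs: np.ndarray,
    grids: Mapping[str, Grid],
    mu: float,
) -> Tuple[List[Dict[str, float]], np.ndarray]:
    """Log-likelihood for every noise-parameter combination (vectorized)."""
    if noise_kind == "binomial":
        p_vals = grids["p"].values()
        n = np.maximum(np.rint((mean + mu)[None, :] / p_vals[:, None]), 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = binom.logpmf(m_obs[None, :], n, p_vals[:, None]).sum(axis=1)
        return [{"p": float(p)} for p in p_vals], ll
    if noise_kind == "gaussian":
        a_vals = grids["a"].values()
        b_vals = grids["b"].values()
        aa, bb = np.meshgrid(a_vals, b_vals, indexing="ij")
        aa, bb = aa.ravel(), bb.ravel()
        sigma = aa[:, None] + bb[:, None] * c_obs[None, :]
        valid = np.all(sigma > 0, axis=1)
        resid = m_obs - (mean + mu)
        ll = np.full(len(aa), -np.inf)
        if valid.any():
            s = sigma[valid]
            ll[valid] = np.sum(
                -0.5 * LOG_2PI - np.log(s) - resid[None, :] ** 2 / (2 * s**2),
                axis=1,
            )
        return [{"a": float(a), "b": float(b)} for a, b in zip(aa, bb)], ll
    raise ValueError(f"unknown noise kind {noise_kind!r}")


def grid_fit(
    trials: Sequence[TrialRecord],
    family: str,
    noise_kind: str,
    grids: Optional[Mapping[str, Grid]] = None,
    *,
    mu: float = 0.0,
    optimal_curve: Optional[Mapping[int, int]] = None,
) -> FitResult:
    """Exhaustive grid-search maximum-likelihood fit.

    Ties are broken toward the smallest parameter vector in lexicographic
    order (family parameter first, then noise parameters).
    """
    if len(trials) == 0:
        raise ValueError("cannot fit an empty trial set")
    grids = dict(DEFAULT_GRIDS, **(grids or {}))
    c_obs, m_obs = _extract(trials)
    best_ll = -np.inf
    best_params: Optional[Dict[str, float]] = None
    for fp in _family_param_dicts(family, grids):
        mean = _mean_vector(family, fp, c_obs, optimal_curve)
        noise_dicts, ll = _noise_loglik_table(
            noise_kind, mean, m_obs, c_obs, grids, mu
        )
        i = int(np.argmax(ll))  # first occurrence = smallest noise params
        if ll[i] > best_ll:
            best_ll = float(ll[i])
            best_params = {**fp, **noise_dicts[i]}
    if best_params is None or not np.isfinite(best_ll):
        pid = trials[0].participant_id
        raise FitFailureError(
            f"no finite likelihood on the grid for participant {pid!r} "
            f"({family}/{noise_kind})"
        )
    n_free = (1 if FREE_FAMILY_PARAMS[family] else 0) + (
        2 if noise_kind == "gaussian" else 1
    )
    return FitResult(family, noise_kind, best_params, best_ll, n_free, len(trials))


def _loglik_at(
    trials: Sequence[TrialRecord],
    family: str,
    noise_kind: str,
    params: Mapping[str, float],
    mu: float,
    optimal_curve: Optional[Mapping[int, int]],
) -> float:
    model = ModelFamily(
        family,
        {k: v for k, v in params.items() if k in ("d", "w")},
        optimal_curve,
    )
    if noise_kind == "binomial":
        return binomial_loglik(trials, model, params["p"], mu)
    return gaussian_loglik(trials, model, params["a"], params["b"], mu)


def _capacity_stratified_folds(
    trials: Sequence[TrialRecord], n_folds: int, rng: np.random.Generator
) -> List[List[int]]:
    """Non-overlapping test partitions, balanced within each capacity."""
    by_cap: Dict[int, List[int]] = {}
    for i, t in enumerate(trials):
        by_cap.setdefault(t.capacity, []).append(i)
    folds: List[List[int]] = [[] for _ in range(n_folds)]
    offset = 0
    for cap in sorted(by_cap):
        idx = rng.permutation(by_cap[cap])
        for j, i in enumerate(idx):
            folds[(j + offset) % n_folds].append(int(i))
        offset += len(idx)
    return folds


def cross_validate(
    trials: Sequence[TrialRecord],
    family: str,
    noise_kind: str,
    grids: Optional[Mapping[str, Grid]] = None,
    n_folds: int = 4,
    rng: Optional[np.random.Generator] = None,
    *,
    mu: float = 0.0,
    optimal_curve: Optional[Mapping[int, int]] = None,
) -> CVResult:
    """Fourfold cross-validated log-likelihood of one family/noise pair.

    Each fold fits on 75% of the trials (capacity-stratified split) and
    evaluates the held-out 25%.  CVLL is the mean of the finite fold
    log-likelihoods; folds with -inf test likelihood (impossible events
    under binomial noise) are excluded and counted.
    """
    if len(trials) < n_folds:
        raise ValueError(f"need at least {n_folds} trials")
    rng = rng if rng is not None else np.random.default_rng(0)
    folds = _capacity_stratified_folds(trials, n_folds, rng)
    fold_lls: List[float] = []
    for test_idx in folds:
        test_set = set(test_idx)
        train = [t for i, t in enumerate(trials) if i not in test_set]
        test = [trials[i] for i in test_idx]
        fit = grid_fit(
            train, family, noise_kind, grids, mu=mu, optimal_curve=optimal_curve
        )
        fold_lls.append(
            _loglik_at(test, family, noise_kind, fit.params, mu, optimal_curve)
        )
    finite = [x for x in fold_lls if np.isfinite(x)]
    if not finite:
        pid = trials[0].participant_id
        raise FitFailureError(
            f"all {n_folds} folds gave non-finite test likelihood for "
            f"participant {pid!r} ({family}/{noise_kind})"
        )
    full = grid_fit(
        trials, family, noise_kind, grids, mu=mu, optimal_curve=optimal_curve
    )
    return CVResult(
        family=family,
        noise_kind=noise_kind,
        params=full.params,
        train_loglik=full.loglik,
        fold_logliks=tuple(fold_lls),
        cvll=float(np.mean(finite)),
        n_excluded_folds=len(fold_lls) - len(finite),
        aic=full.aic,
    )


def _optimal_curve_for(
    env_label: str, capacities: Sequence[int], n_suppliers: int
) -> Dict[int, int]:
    env = Environment.from_label(env_label)
    return {
        e.capacity: e.m_opt
        for e in ideal.optimal_curve(env, sorted(set(capacities)), n_suppliers)
    }


def compare_models(
    trials: Sequence[TrialRecord],
    noise_kinds: Sequence[str] = ("binomial", "gaussian"),
    families: Sequence[str] = FAMILIES,
    grids: Optional[Mapping[str, Grid]] = None,
    n_folds: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """CVLL and AIC for every family x noise kind, per participant x environment.

    Returns a tidy frame with one row per (participant, environment,
    family, noise); participants whose folds all fail for some model are
    kept as flagged rows (``ok = False``) rather than dropped silently.
    """
    groups: Dict[Tuple[str, str], List[TrialRecord]] = {}
    for t in trials:
        groups.setdefault((t.participant_id, t.environment), []).append(t)
    curve_cache: Dict[Tuple[str, Tuple[int, ...], int], Dict[int, int]] = {}
    rows = []
    for gi, (key, group) in enumerate(sorted(groups.items())):
        pid, env_label = key
        caps = tuple(sorted({t.capacity for t in group}))
        n_sup = group[0].allocation.n_suppliers
        ckey = (env_label, caps, n_sup)
        if ckey not in curve_cache:
            curve_cache[ckey] = _optimal_curve_for(env_label, caps, n_sup)
        curve = curve_cache[ckey]
        for family in families:
            for noise_kind in noise_kinds:
                rng = np.random.default_rng([seed, gi])
                row = {
                    "participant_id": pid,
                    "environment": env_label,
                    "family": family,
                    "noise": noise_kind,
                }
                try:
                    cv = cross_validate(
                        group,
                        family,
                        noise_kind,
                        grids,
                        n_folds=n_folds,
                        rng=rng,
                        optimal_curve=curve,
                    )
                except FitFailureError:
                    row.update(
                        cvll=np.nan,
                        aic=np.nan,
                        train_loglik=np.nan,
                        n_excluded_folds=n_folds,
                        ok=False,
                    )
                else:
                    row.update(
                        cvll=cv.cvll,
                        aic=cv.aic,
                        train_loglik=cv.train_loglik,
                        n_excluded_folds=cv.n_excluded_folds,
                        ok=True,
                    )
                    for pname, pval in cv.params.items():
                        row[f"param_{pname}"] = pval
                rows.append(row)
    return pd.DataFrame(rows)


def select_family(comparison: pd.DataFrame) -> pd.DataFrame:
    """Best family per (participant, environment, noise) by CVLL.

    Exact CVLL ties go to the family with fewer free parameters, then to
    alphabetical order, so a nested family never displaces its simpler
    special case on equal evidence.
    """
    n_free = {f: (1 if FREE_FAMILY_PARAMS[f] else 0) for f in FAMILIES}
    df = comparison[comparison["ok"]].copy()
    df["_nfree"] = df["family"].map(n_free)
    df = df.sort_values(
        ["participant_id", "environment", "noise", "cvll", "_nfree", "family"],
        ascending=[True, True, True, False, True, True],
    )
    best = df.groupby(
        ["participant_id", "environment", "noise"], as_index=False
    ).first()
    return best.drop(columns=["_nfree"])
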