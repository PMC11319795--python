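"""Regularized canonical correlation between muscle ultrasound and sway.

The association analysis links a block X of standardized ultrasound
parameters (default: EI, MT, ASM, IDM, Entropy) to a block Y of
height-normalized anterior-posterior sway SDs in the four standing
conditions.  Because n is small relative to p + q, the canonical problem is
ridge-regularized: the first canonical pair solves the eigenproblem

    (Sxx + λx I)^-1 Sxy (Syy + λy I)^-1 Syx wx = ρ² wx

with λ selected by leave-one-out cross-validation (Pearson correlation of
held-out canonical scores).  Significance is assessed by permuting the rows
of X only (sway left untouched) and comparing the observed canonical r to
its permutation distribution.  A pooled follow-up correlates the
sign-corrected mean of the standardized ultrasound variables with the mean
standardized sway across conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

__all__ = [
    "PreprocConfig",
    "RCCAResult",
    "PooledAssociation",
    "DEFAULT_LAMBDA_GRID",
    "preprocess",
    "fit_rcca",
    "select_lambda_loo",
    "permutation_test",
    "pool_and_correlate",
    "run_cca_analysis",
]

#: 13 log-spaced ridge penalties shared by both blocks
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 3, 13))


@dataclass(frozen=True)
class PreprocConfig:
    """Column-wise preprocessing: z-score, winsorize at ±winsor_sd, then
    optionally residualize on age and re-standardize."""

    winsor_sd: float = 2.5
    age_covariate: bool = True
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.winsor_sd <= 0:
            raise ValueError("winsor_sd must be positive")


@dataclass(frozen=True)
class RCCAResult:
    wx: np.ndarray
    wy: np.ndarray
    r: float
    lambda_x: float
    lambda_y: float
    perm_p: float | None = None
    n_perm: int = 0
    seed: int | None = None
    lambda_reselected_per_perm: bool = False


@dataclass(frozen=True)
class PooledAssociation:
    pooled_us: np.ndarray
    pooled_sway: np.ndarray
    pearson_r: float
    p: float


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _zscore(col: np.ndarray, name: str) -> np.ndarray:
    sd = col.std(ddof=1)
    if sd == 0:
        raise ValueError(f"column {name!r} has zero variance")
    return (col - col.mean()) / sd


def preprocess(block: np.ndarray, ages: np.ndarray | None = None,
               cfg: PreprocConfig = PreprocConfig(),
               names: list[str] | None = None) -> np.ndarray:
    """Standardize, winsorize, and (optionally) age-residualize each column.

    Order follows the analysis convention: z-score first, clamp |z| >
    winsor_sd to the ±winsor_sd bounds, then replace each column by the
    residuals of its least-squares regression on age and re-standardize so
    the CCA inputs are unit-variance.
    """
    X = np.array(block, dtype=float)
    if X.ndim != 2:
        raise ValueError("block must be 2-D (subjects x variables)")
    names = names or [f"var{j}" for j in range(X.shape[1])]
    out = np.empty_like(X)
    if cfg.age_covariate:
        if ages is None:
            raise ValueError("age correction requested but no ages supplied")
        A = np.column_stack([np.ones(len(X)), np.asarray(ages, dtype=float)])
    for j in range(X.shape[1]):
        col = X[:, j]
        if cfg.standardize:
            col = _zscore(col, names[j])
        col = np.clip(col, -cfg.winsor_sd, cfg.winsor_sd)
        if cfg.age_covariate:
            beta, *_ = np.linalg.lstsq(A, col, rcond=None)
            col = col - A @ beta
            col = _zscore(col, names[j])
        out[:, j] = col
    return out


# ---------------------------------------------------------------------------
# ridge-regularized CCA
# ---------------------------------------------------------------------------

def _rcca_factors(X: np.ndarray, Y: np.ndarray, lambda_x: float, lambda_y: float):
    """Precompute (Sxx+λI)^-1/2 and (Syy+λI)^-1 for repeated Sxy updates."""
    n = len(X)
    Sxx = X.T @ X / (n - 1)
    Syy = Y.T @ Y / (n - 1)
    A = Sxx + lambda_x * np.eye(X.shape[1])
    B = Syy + lambda_y * np.eye(Y.shape[1])
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValueError("non-finite covariance matrix")
    evals, evecs = linalg.eigh(A)
    if evals.min() <= 0:
        raise ValueError("regularized X covariance not positive definite")
    A_isqrt = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    B_inv = linalg.inv(B)
    return A_isqrt, B_inv


def _rcca_core(X, Y, Sxy, A_isqrt, B_inv, sign_anchor: int | None):
    M = A_isqrt @ Sxy @ B_inv @ Sxy.T @ A_isqrt
    evals, evecs = linalg.eigh(M)
    v = evecs[:, -1]
    wx = A_isqrt @ v
    wy = B_inv @ Sxy.T @ wx
    nx, ny = np.linalg.norm(wx), np.linalg.norm(wy)
    if nx == 0 or ny == 0:
        raise ValueError("degenerate canonical weights")
    wx, wy = wx / nx, wy / ny
    u, w = X @ wx, Y @ wy
    r = float(np.corrcoef(u, w)[0, 1])
    if r < 0:  # flip Y weights so the canonical correlation is reported in [0, 1]
        wy, r = -wy, -r
    anchor = sign_anchor if sign_anchor is not None else int(np.argmax(np.abs(wx)))
    if wx[anchor] < 0:
        wx, wy = -wx, -wy
    return wx, wy, r


def fit_rcca(X: np.ndarray, Y: np.ndarray, lambda_x: float, lambda_y: float,
             sign_anchor: int | None = None) -> RCCAResult:
    """First ridge-regularized canonical pair of preprocessed blocks X, Y.

    Weights are unit-norm; r = corr(X wx, Y wy) reported in [0, 1] by sign
    convention.  ``sign_anchor`` is the X-column index forced to a positive
    weight (use the MT column in the ultrasound block); when None, the
    largest-magnitude weight is made positive.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if len(X) != len(Y):
        raise ValueError("X and Y must have the same number of subjects")
    n = len(X)
    A_isqrt, B_inv = _rcca_factors(X, Y, lambda_x, lambda_y)
    Sxy = X.T @ Y / (n - 1)
    wx, wy, r = _rcca_core(X, Y, Sxy, A_isqrt, B_inv, sign_anchor)
    return RCCAResult(wx=wx, wy=wy, r=r, lambda_x=lambda_x, lambda_y=lambda_y)


def select_lambda_loo(X: np.ndarray, Y: np.ndarray,
                      grid=DEFAULT_LAMBDA_GRID,
                      tie_rule: str = "one_se") -> tuple[float, float]:
    """Leave-one-out selection of the (λx, λy) pair.

    For every grid pair: fit on n−1 subjects, project the held-out subject
    with the fold's weights, and score the pair by the Pearson correlation
    of the n held-out score pairs.

    ``tie_rule`` decides among statistically indistinguishable scores:
    ``"one_se"`` (default) returns the largest-penalty pair whose held-out
    correlation lies within one standard error of the best score — the
    usual cross-validation parsimony rule, appropriate here because at
    small n the held-out correlation rarely separates the penalties beyond
    its own noise; ``"argmax"`` returns the literal maximizer (exact ties
    toward larger penalties).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty lambda grid")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = len(X)
    pairs = sorted(((lx, ly) for lx in grid for ly in grid),
                   key=lambda t: (t[0] + t[1], t[0]))
    best, best_score = pairs[0], -np.inf
    scores: dict[tuple[float, float], float] = {}
    mask = np.ones(n, dtype=bool)
    for lx, ly in pairs:
        # reference orientation: the full-data solution at this penalty pair;
        # each fold's weight pair is globally sign-aligned to it so the
        # held-out score cloud is not scrambled by arbitrary per-fold flips
        ref = fit_rcca(X - X.mean(axis=0), Y - Y.mean(axis=0), lx, ly)
        u = np.empty(n)
        w = np.empty(n)
        ok = True
        for i in range(n):
            mask[i] = False
            Xi, Yi = X[mask], Y[mask]
            # center within the training fold so held-out projections are comparable
            xm, ym = Xi.mean(axis=0), Yi.mean(axis=0)
            try:
                res = fit_rcca(Xi - xm, Yi - ym, lx, ly)
            except ValueError:
                ok = False
                mask[i] = True
                break
            flip = -1.0 if res.wx @ ref.wx < 0 else 1.0
            u[i] = flip * ((X[i] - xm) @ res.wx)
            w[i] = flip * ((Y[i] - ym) @ res.wy)
            mask[i] = True
        if not ok:
            continue
        score = np.corrcoef(u, w)[0, 1]
        if np.isnan(score):
            continue
        scores[(lx, ly)] = score
        # pairs iterate in increasing total penalty, so ">=" breaks ties
        # toward the more regularized pair
        if score >= best_score:
            best, best_score = (lx, ly), score
    if tie_rule == "one_se" and scores:
        se = (1.0 - min(abs(best_score), 1.0) ** 2) / math.sqrt(max(n - 3, 1))
        eligible = [pair for pair, sc in scores.items() if sc >= best_score - se]
        best = max(eligible, key=lambda t: (t[0] + t[1], t[0]))
    elif tie_rule != "argmax" and tie_rule != "one_se":
        raise ValueError("tie_rule must be 'one_se' or 'argmax'")
    return best


def permutation_test(X: np.ndarray, Y: np.ndarray, lambda_x: float, lambda_y: float,
                     n_perm: int = 1000, seed: int | None = None,
                     sign_anchor: int | None = None,
                     reselect_lambda: bool = False,
                     grid=DEFAULT_LAMBDA_GRID) -> RCCAResult:
    """Permutation inference on the first canonical correlation.

    Rows of X are shuffled ``n_perm`` times (Y untouched) and r is recomputed
    with the fixed (λx, λy); perm_p = (1 + #{r_perm >= r_obs})/(n_perm + 1).
    Set ``reselect_lambda`` to rerun the LOO selection inside every
    permutation (slower; same inference logic).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = len(X)
    obs = fit_rcca(X, Y, lambda_x, lambda_y, sign_anchor=sign_anchor)
    rng = np.random.default_rng(seed)
    A_isqrt, B_inv = _rcca_factors(X, Y, lambda_x, lambda_y)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Xp = X[perm]
        if reselect_lambda:
            lx, ly = select_lambda_loo(Xp, Y, grid)
            r_perm = fit_rcca(Xp, Y, lx, ly).r
        else:
            Sxy = Xp.T @ Y / (n - 1)
            _, _, r_perm = _rcca_core(Xp, Y, Sxy, A_isqrt, B_inv, None)
        if r_perm >= obs.r:
            count += 1
    perm_p = (1 + count) / (n_perm + 1)
    return RCCAResult(
        wx=obs.wx, wy=obs.wy, r=obs.r, lambda_x=lambda_x, lambda_y=lambda_y,
        perm_p=perm_p, n_perm=n_perm, seed=seed,
        lambda_reselected_per_perm=reselect_lambda,
    )


def pool_and_correlate(X: np.ndarray, Y: np.ndarray, wx: np.ndarray) -> PooledAssociation:
    """Pooled Pearson follow-up informed by the canonical weight signs.

    pooled_us_i = mean_j sign(wx_j) X_ij; pooled_sway_i = mean_c Y_ic;
    returns their Pearson r with a two-sided p.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    signs = np.sign(np.asarray(wx, dtype=float))
    signs[signs == 0] = 1.0
    pooled_us = (X * signs).mean(axis=1)
    pooled_sway = Y.mean(axis=1)
    if pooled_us.std() == 0 or pooled_sway.std() == 0:
        raise ValueError("pooled score has zero variance")
    r, p = stats.pearsonr(pooled_us, pooled_sway)
    return PooledAssociation(pooled_us=pooled_us, pooled_sway=pooled_sway,
                             pearson_r=float(r), p=float(p))


def run_cca_analysis(us_block: np.ndarray, sway_block: np.ndarray, ages: np.ndarray,
                     cfg: PreprocConfig = PreprocConfig(),
                     grid=DEFAULT_LAMBDA_GRID, n_perm: int = 1000,
                     seed: int | None = None, us_names: list[str] | None = None,
                     sign_anchor_name: str = "MT") -> tuple[RCCAResult, PooledAssociation]:
    """End-to-end group analysis: preprocess both blocks, select λ by LOO,
    permutation-test the canonical r, and compute the pooled correlation."""
    us_names = us_names or ["EI", "MT", "ASM", "IDM", "Entropy"]
    anchor = us_names.index(sign_anchor_name) if sign_anchor_name in us_names else None
    Xp = preprocess(us_block, ages, cfg, names=us_names)
    Yp = preprocess(sway_block, ages, cfg)
    lx, ly = select_lambda_loo(Xp, Yp, grid)
    result = permutation_test(Xp, Yp, lx, ly, n_perm=n_perm, seed=seed, sign_anchor=anchor)
    pooled = pool_and_correlate(Xp, Yp, result.wx)
    return result, pooled
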