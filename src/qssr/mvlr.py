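"""Exhaustive subset multivariate linear regression with LOO cross-validation.

The modeling strategy for small ligand sets (n ~ 22): enumerate every
descriptor subset up to a feature cap, fit ordinary least squares on z-scored
features (scaling learned from the training rows only), and score each model
on the training rows, a held-out test split, and leave-one-out
cross-validation over the training rows.  The leaderboard is ranked by a
configurable, logged policy; the default prefers test-set R^2, breaking ties
by LOO MAE, then parsimony, then lexicographic subset order so results are
reproducible under candidate reordering.

Leave-one-out uses the exact refit definition: drop one training row, refit
(re-standardizing on the remaining rows), predict the held-out row.  Because
OLS predictions are invariant to affine rescaling of the features, the
hat-matrix identity e_i / (1 - h_ii) reproduces the refit predictions
exactly; ``loo_cv(..., method="hat")`` uses it so the exhaustive sweep stays
fast, and the equality is asserted in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .table import DescriptorTable, resolve_alias

__all__ = [
    "ModelSpec",
    "ModelEvaluation",
    "EvalMetrics",
    "RankDeficientError",
    "SearchResult",
    "fit_ols",
    "evaluate",
    "loo_cv",
    "exhaustive_search",
    "n_subsets",
    "random_split",
    "leaderboard_frame",
]

logger = logging.getLogger(__name__)


class RankDeficientError(ValueError):
    """The design matrix is rank-deficient; message names the features."""


@dataclass(frozen=True)
class ModelSpec:
    """A fitted linear model on a named feature subset.

    Coefficients are on the standardized scale (per unit of feature standard
    deviation, learned from the training rows), so their magnitudes are
    directly comparable across features; raw-scale coefficients are derived.
    """

    features: tuple[str, ...]
    coefficients: np.ndarray  # standardized scale
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray

    def __post_init__(self) -> None:
        if len(self.features) < 1:
            raise ValueError("a model needs at least one feature")
        if np.any(self.feature_sds <= 0):
            raise ValueError("feature standard deviations must be positive")

    @property
    def coefficients_raw(self) -> np.ndarray:
        return self.coefficients / self.feature_sds

    @property
    def intercept_raw(self) -> float:
        return float(self.intercept - np.sum(self.coefficients * self.feature_means / self.feature_sds))

    def predict(self, x_raw: np.ndarray) -> np.ndarray:
        z = (np.asarray(x_raw, dtype=float) - self.feature_means) / self.feature_sds
        return self.intercept + z @ self.coefficients


@dataclass(frozen=True)
class EvalMetrics:
    r2: float | None  # None when the evaluated response has zero variance
    mae: float
    n: int

    @property
    def r2_defined(self) -> bool:
        return self.r2 is not None


@dataclass(frozen=True)
class ModelEvaluation:
    r2_train: float | None
    mae_train: float
    r2_test: float | None
    mae_test: float | None
    mae_loo: float
    n_train: int
    n_test: int


def _design(table: DescriptorTable, features: Sequence[str], rows: np.ndarray):
    X = table.matrix(features, rows)
    y = table.column("response", rows)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in features/response for the fit rows")
    return X, y


def _check_rank(Z: np.ndarray, features: Sequence[str]) -> None:
    """Raise RankDeficientError naming the collinear features, if any."""
    A = np.column_stack([np.ones(len(Z)), Z])
    rank = np.linalg.matrix_rank(A)
    if rank == A.shape[1]:
        return
    # pivoted QR on the centered features points at the dependent columns
    _, R, piv = scipy.linalg.qr(Z - Z.mean(axis=0), pivoting=True, mode="economic")
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Z.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
    dependent = [features[piv[i]] for i in range(len(features)) if i >= rank - 1 or diag[min(i, len(diag) - 1)] <= tol]
    raise RankDeficientError(
        f"rank-deficient design for features {tuple(features)}; "
        f"collinear/constant candidates: {sorted(set(dependent))}"
    )


def fit_ols(table: DescriptorTable, features: Sequence[str], train_rows: np.ndarray) -> ModelSpec:
    """Ordinary least squares on z-scored features over the training rows.

    Scaling (mean, sd) is captured from the training rows only, so held-out
    rows can never leak into the standardization.  A rank-deficient design is
    an error that names the offending features -- never a silent
    pseudo-inverse.
    """
    features = tuple(resolve_alias(f, table.df.columns) for f in features)
    X, y = _design(table, features, train_rows)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n_train > n_features + 1; got n={n}, p={p}")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    zero = [features[j] for j in range(p) if sds[j] == 0]
    if zero:
        raise RankDeficientError(f"constant feature(s) within the training rows: {zero}")
    Z = (X - means) / sds
    _check_rank(Z, features)
    A = np.column_stack([np.ones(n), Z])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return ModelSpec(
        features=features,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        feature_means=means,
        feature_sds=sds,
    )


def evaluate(model: ModelSpec, table: DescriptorTable, rows: np.ndarray) -> EvalMetrics:
    """R^2 and MAE of a fitted model on the given rows.

    R^2 = 1 - SS_res/SS_tot with SS_tot about the evaluated rows' own mean.
    If the evaluated response has zero variance, R^2 is undefined and
    reported as None (flagged, never a silent NaN).
    """
    X, y = _design(table, model.features, rows)
    pred = model.predict(X)
    resid = y - pred
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return EvalMetrics(r2=None, mae=mae, n=len(y))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return EvalMetrics(r2=r2, mae=mae, n=len(y))


def loo_cv(
    table: DescriptorTable,
    features: Sequence[str],
    train_rows: np.ndarray,
    method: str = "refit",
) -> float:
    """Leave-one-out MAE over the training rows.

    ``method="refit"`` is the definition: for each training row, refit on the
    remaining rows (re-standardizing each time) and predict the held-out row.
    ``method="hat"`` evaluates the mathematically identical closed form
    e_i / (1 - h_ii) from a single fit; both agree to ~1e-12 on
    well-conditioned data.
    """
    features = tuple(resolve_alias(f, table.df.columns) for f in features)
    train_rows = np.asarray(train_rows)
    n, p = len(train_rows), len(features)
    if n < p + 3:
        raise ValueError(f"need n_train >= n_features + 3 for LOO; got n={n}, p={p}")
    if method == "refit":
        errors = []
        for i in range(n):
            keep = np.delete(train_rows, i)
            try:
                model = fit_ols(table, features, keep)
            except RankDeficientError as exc:
                raise RankDeficientError(
                    f"LOO refit without row {train_rows[i]} is rank-deficient: {exc}"
                ) from None
            x_out = table.matrix(features, train_rows[i : i + 1])
            y_out = table.column("response", train_rows[i : i + 1])
            errors.append(abs(float(y_out[0] - model.predict(x_out)[0])))
        return float(np.mean(errors))
    if method == "hat":
        X, y = _design(table, features, train_rows)
        A = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        # h_ii via the thin-QR factor: rows of Q give leverage directly
        Q, _ = np.linalg.qr(A)
        h = np.einsum("ij,ij->i", Q, Q)
        denom = 1.0 - h
        if np.any(denom <= 1e-12):
            bad = train_rows[denom <= 1e-12].tolist()
            raise RankDeficientError(
                f"leverage ~1 for rows {bad}: LOO refit would be rank-deficient"
            )
        return float(np.mean(np.abs(resid / denom)))
    raise ValueError(f"unknown LOO method {method!r}")


def n_subsets(n_candidates: int, max_features: int) -> int:
    """Number of feature subsets of size 1..max_features out of p candidates."""
    return sum(comb(n_candidates, k) for k in range(1, min(max_features, n_candidates) + 1))


@dataclass(frozen=True)
class SearchResult:
    model: ModelSpec
    evaluation: ModelEvaluation


# ranking policies: name -> sort key (ascending); None metrics sort last
def _key_r2_test(r: SearchResult):
    ev = r.evaluation
    r2t = ev.r2_test if ev.r2_test is not None else -np.inf
    return (-r2t, ev.mae_loo, len(r.model.features), r.model.features)


def _key_mae_loo(r: SearchResult):
    ev = r.evaluation
    r2t = ev.r2_test if ev.r2_test is not None else -np.inf
    return (ev.mae_loo, -r2t, len(r.model.features), r.model.features)


def _key_r2_train(r: SearchResult):
    ev = r.evaluation
    r2 = ev.r2_train if ev.r2_train is not None else -np.inf
    return (-r2, ev.mae_loo, len(r.model.features), r.model.features)


RANKING_POLICIES: dict[str, Callable[[SearchResult], tuple]] = {
    "r2_test": _key_r2_test,
    "mae_loo": _key_mae_loo,
    "r2_train": _key_r2_train,
}


def exhaustive_search(
    table: DescriptorTable,
    candidates: Sequence[str] | None = None,
    max_features: int = 6,
    ranking: str = "r2_test",
    train_rows: np.ndarray | None = None,
    test_rows: np.ndarray | None = None,
    max_models: int = 500_000,
    loo_method: str = "hat",
    progress_every: int = 0,
) -> tuple[list[SearchResult], list[tuple[tuple[str, ...], str]]]:
    """Fit and score every feature subset of size 1..``max_features``.

    Returns ``(ranked_results, skipped)`` where ``skipped`` lists subsets that
    could not be fitted (constant/collinear features within the training
    rows) with the reason -- the sweep completes rather than aborting.
    The split comes from the table's ``split`` column unless explicit row
    indices are given.  The candidate list defaults (deterministically,
    sorted) to every descriptor column, so reordering candidates cannot
    change the leaderboard.
    """
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    if ranking not in RANKING_POLICIES:
        raise ValueError(f"unknown ranking policy {ranking!r}; options: {sorted(RANKING_POLICIES)}")
    if candidates is None:
        candidates = table.descriptor_names
    candidates = sorted(resolve_alias(c, table.df.columns) for c in candidates)
    if train_rows is None or test_rows is None:
        train_rows, test_rows = table.split_indices()
    train_rows = np.asarray(train_rows)
    test_rows = np.asarray(test_rows)
    needs_test = ranking == "r2_test"
    if needs_test and len(test_rows) == 0:
        raise ValueError("ranking policy 'r2_test' requires a non-empty test split")

    total = n_subsets(len(candidates), max_features)
    if total > max_models:
        raise ValueError(
            f"{total} subsets exceed the enumeration guard ({max_models}); "
            "raise max_models explicitly to proceed"
        )
    logger.info(
        "exhaustive search: %d candidates, cap %d -> %d subsets (ranking=%s)",
        len(candidates), max_features, total, ranking,
    )

    results: list[SearchResult] = []
    skipped: list[tuple[tuple[str, ...], str]] = []
    done = 0
    for k in range(1, min(max_features, len(candidates)) + 1):
        for subset in combinations(candidates, k):
            done += 1
            if progress_every and done % progress_every == 0:
                logger.info("  fitted %d / %d subsets", done, total)
            try:
                model = fit_ols(table, subset, train_rows)
                ev_train = evaluate(model, table, train_rows)
                if len(test_rows):
                    ev_test = evaluate(model, table, test_rows)
                    r2_test, mae_test, n_test = ev_test.r2, ev_test.mae, ev_test.n
                else:
                    r2_test, mae_test, n_test = None, None, 0
                mae_loo = loo_cv(table, subset, train_rows, method=loo_method)
            except (RankDeficientError, ValueError) as exc:
                skipped.append((subset, str(exc)))
                logger.debug("skipping %s: %s", subset, exc)
                continue
            results.append(
                SearchResult(
                    model=model,
                    evaluation=ModelEvaluation(
                        r2_train=ev_train.r2,
                        mae_train=ev_train.mae,
                        r2_test=r2_test,
                        mae_test=mae_test,
                        mae_loo=mae_loo,
                        n_train=len(train_rows),
                        n_test=n_test,
                    ),
                )
            )
    results.sort(key=RANKING_POLICIES[ranking])
    return results, skipped


def random_split(n: int, test_fraction: float = 0.2, seed: int | None = None) -> np.ndarray:
    """Seeded random train/test tags (array of 'train'/'test' of length n)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_test = max(1, round(n * test_fraction))
    tags = np.array(["train"] * n, dtype=object)
    tags[rng.choice(n, size=n_test, replace=False)] = "test"
    return tags


def leaderboard_frame(results: Sequence[SearchResult]) -> pd.DataFrame:
    """Serializable leaderboard: one row per model, ranked order preserved."""
    rows = []
    for rank, r in enumerate(results, start=1):
        ev = r.evaluation
        rows.append(
            {
                "rank": rank,
                "n_features": len(r.model.features),
                "features": "+".join(r.model.features),
                "r2_train": ev.r2_train,
                "mae_train": ev.mae_train,
                "r2_test": ev.r2_test,
                "mae_test": ev.mae_test,
                "mae_loo": ev.mae_loo,
                "n_train": ev.n_train,
                "n_test": ev.n_test,
                "coefficients_std": ";".join(f"{c:.6g}" for c in r.model.coefficients),
                "intercept": r.model.intercept,
            }
        )
    return pd.DataFrame(rows)
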