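"""Rereading-effect and predictive models for word-level gaze measures.

Three analysis stages live here:

1. :func:`lmm_session_test` — a linear mixed model with session as the
   single fixed effect and a random intercept for word (nested within
   sonnet), testing first-vs-last rereading effects on an aggregated
   word-level measure.
2. :func:`repeated_kfold` — k-fold cross-validation (default 10-fold)
   repeated many times (default 100) with reshuffled folds, comparing a
   small single-hidden-layer tanh network against ordinary least squares.
   Held-out R^2 uses the test fold's own mean in the SST term.
3. :func:`total_effect_importance` — variance-based total-effect feature
   importance (FI) on a fitted model, estimated by a row-resampling
   Jansen estimator; FI > 0.1 is flagged as "important".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "LmmResult",
    "CVConfig",
    "NNSpec",
    "FitSummary",
    "ImportanceResult",
    "lmm_session_test",
    "fit_neural_net",
    "fit_least_squares",
    "repeated_kfold",
    "total_effect_importance",
    "importance_report",
    "correlation_table",
    "ADEQUACY_THRESHOLD",
    "IMPORTANCE_THRESHOLD",
]

ADEQUACY_THRESHOLD = 0.30   # satisfactory mean held-out R^2
IMPORTANCE_THRESHOLD = 0.1  # FI above this counts as important


# ---------------------------------------------------------------------------
# Linear mixed model: rereading effect
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LmmResult:
    """Session fixed effect from the word-level mixed model."""

    estimate_first_minus_last: float
    se: float
    tvalue: float
    p: float
    var_word: float      # random-intercept variance (word within sonnet)
    var_resid: float
    n_obs: int
    converged: bool

    def to_dict(self) -> dict:
        return asdict(self)


def lmm_session_test(long_table: pd.DataFrame, response: str) -> LmmResult:
    """REML fit of ``response ~ session`` with a word random intercept.

    ``long_table`` holds one row per word per session (the join of
    aggregated measures and features). Session is coded first=0, last=1;
    the reported estimate is the first-minus-last contrast, so a positive
    value means the measure decreased on rereading. Words are identified
    by (sonnet_id, line_no, word_no), which realizes nesting within
    sonnet. Rows with a missing response (never-fixated words) are
    dropped, mirroring skips-as-missing.
    """
    import statsmodels.api as sm

    df = long_table.dropna(subset=[response]).copy()
    if df.empty:
        raise ValueError(f"no complete rows for response {response!r}")
    df["session_code"] = (df["session"] == "last").astype(float)
    if df["session_code"].nunique() < 2:
        raise ValueError("need both sessions in the long table")
    df["word_uid"] = (
        df["sonnet_id"].astype(str)
        + ":" + df["line_no"].astype(str)
        + ":" + df["word_no"].astype(str)
    )
    if df.groupby("sonnet_id")["word_uid"].nunique().size < 2:
        logger.warning("single grouping unit; nested random effect is degenerate")

    exog = sm.add_constant(df[["session_code"]])
    model = sm.MixedLM(df[response].to_numpy(), exog, groups=df["word_uid"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    if not np.all(np.isfinite(fit.params)) or not np.isfinite(fit.scale):
        raise RuntimeError(f"mixed model did not converge: {fit.summary()}")
    if not fit.converged:
        # boundary fits (zero group variance) are usable; flag, don't fail
        logger.warning("mixed model hit a boundary; estimates retained")
    beta = float(fit.params["session_code"])   # last - first
    se = float(fit.bse["session_code"])
    return LmmResult(
        estimate_first_minus_last=-beta,
        se=se,
        tvalue=float(fit.tvalues["session_code"]),
        p=float(fit.pvalues["session_code"]),
        var_word=float(np.asarray(fit.cov_re).ravel()[0]),
        var_resid=float(fit.scale),
        n_obs=len(df),
        converged=bool(fit.converged),
    )


# ---------------------------------------------------------------------------
# Model families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NNSpec:
    """Single-hidden-layer tanh network with an L2 weight penalty.

    ``restarts`` random initializations are fitted per call and the one
    with the lowest penalized training loss is kept; given the same seed
    the result is bit-identical.
    """

    hidden_units: int = 3
    weight_decay: float = 0.02
    restarts: int = 5
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


class _TanhNet:
    """Fitted 1-hidden-layer tanh regressor (linear output)."""

    def __init__(self, W1, b1, w2, b2, loss):
        self.W1, self.b1, self.w2, self.b2 = W1, b1, w2, b2
        self.loss_ = loss

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.tanh(X @ self.W1 + self.b1) @ self.w2 + self.b2


def _nn_loss_grad(theta, X, y, lam, p, h):
    n = len(y)
    i = 0
    W1 = theta[i : i + p * h].reshape(p, h); i += p * h
    b1 = theta[i : i + h]; i += h
    w2 = theta[i : i + h]; i += h
    b2 = theta[i]
    A = np.tanh(X @ W1 + b1)
    r = A @ w2 + b2 - y
    # penalty on the mean-loss scale: loss = 0.5*mean(r^2) + lam*||theta||^2,
    # so lam is sample-size free (lam=0.01 ~ sklearn alpha of 2*n*0.01)
    penalty = lam * (np.sum(W1 ** 2) + np.sum(b1 ** 2) + np.sum(w2 ** 2) + b2 ** 2)
    loss = 0.5 * np.mean(r ** 2) + penalty
    gf = r / n
    gw2 = A.T @ gf + 2 * lam * w2
    gb2 = np.sum(gf) + 2 * lam * b2
    gZ = np.outer(gf, w2) * (1 - A ** 2)
    gW1 = X.T @ gZ + 2 * lam * W1
    gb1 = gZ.sum(axis=0) + 2 * lam * b1
    return loss, np.concatenate([gW1.ravel(), gb1, gw2, [gb2]])


def fit_neural_net(X, y, spec: NNSpec = NNSpec()) -> _TanhNet:
    """Fit the tanh network by L-BFGS, best of ``spec.restarts`` starts."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-d and aligned with y")
    p, h = X.shape[1], spec.hidden_units
    best = None
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.restarts):
        theta0 = rng.normal(0.0, 0.5, size=p * h + 2 * h + 1)
        res = minimize(
            _nn_loss_grad,
            theta0,
            args=(X, y, spec.weight_decay, p, h),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": spec.max_iter},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError("non-finite training loss in neural net fit")
        if best is None or res.fun < best.fun:
            best = res
    i = 0
    th = best.x
    W1 = th[i : i + p * h].reshape(p, h); i += p * h
    b1 = th[i : i + h]; i += h
    w2 = th[i : i + h]; i += h
    b2 = th[i]
    return _TanhNet(W1, b1, w2, float(b2), float(best.fun))


class _LinearModel:
    def __init__(self, coef, intercept):
        self.coef_, self.intercept_ = coef, intercept

    def predict(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def fit_least_squares(X, y) -> _LinearModel:
    """Ordinary least squares with intercept (standard linear family)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return _LinearModel(beta[1:], float(beta[0]))


def _r2(y_true, y_pred) -> float:
    """R^2 with SST about y_true's own mean (fold-local for test folds)."""
    y_true = np.asarray(y_true, dtype=float)
    sst = np.sum((y_true - y_true.mean()) ** 2)
    if sst == 0:
        raise ValueError("constant response; R^2 undefined")
    return 1.0 - np.sum((y_true - np.asarray(y_pred)) ** 2) / sst


# ---------------------------------------------------------------------------
# Repeated k-fold cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVConfig:
    """Repeated k-fold setup. Fold assignment reshuffles every repetition."""

    k: int = 10
    reps: int = 100
    seed: int = 0
    family: str = "neural_net"  # or "least_squares"
    nn: NNSpec = field(default_factory=NNSpec)

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.family not in ("neural_net", "least_squares"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class FitSummary:
    """Mean/SD of train and test R^2 over all k x reps folds."""

    family: str
    mean_test_r2: float
    sd_test_r2: float
    mean_train_r2: float
    sd_train_r2: float
    k: int
    reps: int
    n: int
    adequate: bool  # mean test R^2 above the satisfactory-fit criterion

    def to_dict(self) -> dict:
        return asdict(self)


def repeated_kfold(X, y, cfg: CVConfig = CVConfig()) -> FitSummary:
    """Repeated k-fold CV of one model family on a complete predictor table.

    For every repetition the rows are re-partitioned into ``cfg.k`` folds
    by a seeded RNG; each fold serves once as the held-out test set for a
    model fitted on the remaining folds. Test R^2 is computed against the
    held-out fold's own mean. The summary averages all k x reps fold
    scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("X and y must be complete (no missing values)")
    n = len(y)
    if n < cfg.k:
        raise ValueError(f"need at least k={cfg.k} rows, got {n}")
    if n // cfg.k < 2:
        raise ValueError("folds would hold fewer than 2 rows")

    test_scores: list[float] = []
    train_scores: list[float] = []
    # independent per-rep substreams so reps are order-insensitive
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.reps)
    for rep, ss in enumerate(seeds):
        fold_rng, fit_rng = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
        kf = KFold(n_splits=cfg.k, shuffle=True, random_state=fold_rng)
        for fold_i, (tr, te) in enumerate(kf.split(X)):
            if cfg.family == "neural_net":
                spec = NNSpec(
                    hidden_units=cfg.nn.hidden_units,
                    weight_decay=cfg.nn.weight_decay,
                    restarts=cfg.nn.restarts,
                    max_iter=cfg.nn.max_iter,
                    seed=fit_rng + fold_i,
                )
                model = fit_neural_net(X[tr], y[tr], spec)
            else:
                model = fit_least_squares(X[tr], y[tr])
            train_scores.append(_r2(y[tr], model.predict(X[tr])))
            test_scores.append(_r2(y[te], model.predict(X[te])))

    mean_test = float(np.mean(test_scores))
    return FitSummary(
        family=cfg.family,
        mean_test_r2=mean_test,
        sd_test_r2=float(np.std(test_scores, ddof=1)),
        mean_train_r2=float(np.mean(train_scores)),
        sd_train_r2=float(np.std(train_scores, ddof=1)),
        k=cfg.k,
        reps=cfg.reps,
        n=n,
        adequate=mean_test > ADEQUACY_THRESHOLD,
    )


# ---------------------------------------------------------------------------
# Total-effect feature importance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImportanceResult:
    """Total-effect FI per predictor, on a 0-to-1 scale."""

    predictors: tuple[str, ...]
    fi: tuple[float, ...]
    se: tuple[float, ...]

    def important(self) -> tuple[bool, ...]:
        return tuple(v > IMPORTANCE_THRESHOLD for v in self.fi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "fi": self.fi,
                "se": self.se,
                "important": self.important(),
            }
        )


def total_effect_importance(
    model,
    X,
    n_mc: int = 5000,
    seed: int = 0,
    n_redraws: int = 10,
    predictors: list[str] | None = None,
) -> ImportanceResult:
    """Variance-based total-effect index of each predictor of a fitted model.

    A Jansen-type estimator on resampled rows of the observed predictor
    table: two bootstrap row samples A and B of size ``n_mc`` are drawn
    from X; for predictor j, A_B(j) replaces column j of A with column j
    of B, and

        T_j = mean((f(A) - f(A_B(j)))^2) / (2 * Var(f over A u B)),

    clipped to [0, 1]. Resampling whole rows preserves the empirical
    joint distribution of the (correlated) predictors in the base
    samples. The estimate and its Monte-Carlo SE come from ``n_redraws``
    independent re-draws.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = predictors or [f"x{j}" for j in range(Xa.shape[1])]
    if Xa.ndim != 2:
        raise ValueError("X must be 2-d")
    n, p = Xa.shape
    if n_redraws < 2:
        raise ValueError("need at least 2 re-draws for a Monte-Carlo SE")

    rng = np.random.default_rng(seed)
    draws = np.empty((n_redraws, p))
    for r in range(n_redraws):
        ia = rng.integers(0, n, size=n_mc)
        ib = rng.integers(0, n, size=n_mc)
        A, B = Xa[ia], Xa[ib]
        fA = np.asarray(model.predict(A), dtype=float)
        fB = np.asarray(model.predict(B), dtype=float)
        var = np.var(np.concatenate([fA, fB]))
        if var < 1e-12:
            raise ValueError("model output variance ~ 0; importance undefined")
        for j in range(p):
            AB = A.copy()
            AB[:, j] = B[:, j]
            fAB = np.asarray(model.predict(AB), dtype=float)
            draws[r, j] = np.mean((fA - fAB) ** 2) / (2.0 * var)
    fi = np.clip(draws.mean(axis=0), 0.0, 1.0)
    se = draws.std(axis=0, ddof=1) / np.sqrt(n_redraws)
    return ImportanceResult(tuple(names), tuple(map(float, fi)), tuple(map(float, se)))


def importance_report(result: ImportanceResult) -> pd.DataFrame:
    """FI table ranked descending, flagged at the strict > 0.1 cutoff."""
    return (
        result.to_frame()
        .sort_values("fi", ascending=False, ignore_index=True)
    )


def correlation_table(columns: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix with unit diagonal.

    Complete cases only; a constant column yields missing entries with a
    warning rather than an error.
    """
    df = columns.dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete rows")
    for col in df.columns:
        if df[col].nunique() == 1:
            logger.warning("constant column %r: correlations undefined", col)
    return df.corr(method="pearson")
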