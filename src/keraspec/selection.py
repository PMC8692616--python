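"""Importance-guided recursive descriptor selection under RF and PLSR.

For one physical property the workflow is:

1. evaluate the current descriptor set by repeated k-fold cross-validation
   (default 100 repeats of 10-fold CV), pooling held-out predictions per
   repeat into RMSE and R^2 and averaging per-descriptor importance over
   every fold of every repeat;
2. rank descriptors by averaged importance and keep the top 90%;
3. repeat until two descriptors remain; the step with the highest mean R^2
   is the selected ("best") descriptor set;
4. intersect the top-20 descriptors of the RF and PLSR best steps into a
   consensus list.

Importance is held-out permutation importance (increase in held-out MSE
when one column is shuffled) for random forests — impurity importance is
available by flag — and a variance-explained-weighted sum of squared
loading weights for PLSR.  Standardization statistics are fitted on
training folds only by default; ``global_standardize=True`` reproduces the
simpler whole-matrix standardization.
"""

from __future__ import annotations

import builtins
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "ModelSpec", "CVResult", "SelectionStep", "SelectionTrace",
    "ConsensusResult", "repeated_cv_evaluate", "recursive_select",
    "best_set", "consensus_topk", "rf_permutation_importance",
    "plsr_importance",
]


@dataclass(frozen=True)
class ModelSpec:
    """Learner configuration for one CV series.

    ``algo`` is ``rf`` (random forest, ``n_trees`` trees, mtry =
    ``max_features``) or ``plsr`` (partial least squares; the component
    count minimizes PRESS in an inner 10-fold CV, capped at
    ``max_components``).  Descriptors are standardized and the property
    mean-centered inside each training fold.
    """

    algo: str = "rf"
    n_trees: int = 1000
    max_features: float | str = 1.0 / 3.0
    importance: str = "permutation"        # rf: permutation | impurity
    max_components: int = 20
    inner_cv_folds: int = 10
    standardize_x: bool = True
    center_y: bool = True
    global_standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algo not in ("rf", "plsr"):
            raise ValueError("algo must be 'rf' or 'plsr'")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.importance not in ("permutation", "impurity"):
            raise ValueError("unknown importance type")


@dataclass
class CVResult:
    """Pooled held-out accuracy (mean +- sd over repeats) and averaged
    per-descriptor importance."""

    rmse_mean: float
    rmse_sd: float
    r2_mean: float
    r2_sd: float
    importance_mean: pd.Series
    n_repeats: int
    k: int
    repeat_metrics: pd.DataFrame = field(repr=False, default=None)
    predictions: list = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.rmse_mean < 0 or self.rmse_sd < 0 or self.r2_sd < 0:
            raise ValueError("negative error statistic")


@dataclass(frozen=True)
class SelectionStep:
    descriptor_ids: tuple[str, ...]
    result: CVResult


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    property: str = ""
    algo: str = ""
    retention: float = 0.9

    # ``property`` the field shadows ``property`` the builtin in this class
    # body, hence the explicit builtins.property calls below.
    def best_index(self) -> int:
        """Step with the highest mean R^2; ties go to the smaller set."""
        best, best_r2 = 0, -math.inf
        for i, step in enumerate(self.steps):
            if step.result.r2_mean >= best_r2:
                best, best_r2 = i, step.result.r2_mean
        return best

    def sizes(self) -> list[int]:
        return [len(s.descriptor_ids) for s in self.steps]

    best_index = builtins.property(best_index)
    sizes = builtins.property(sizes)


@dataclass(frozen=True)
class ConsensusResult:
    property: str
    rf_top: tuple[str, ...]
    plsr_top: tuple[str, ...]

    @property
    def common(self) -> frozenset:
        return frozenset(self.rf_top) & frozenset(self.plsr_top)


# ---------------------------------------------------------------------------
# schedules and helpers
# ---------------------------------------------------------------------------

def retention_schedule(p: int, retention: float = 0.9,
                       floor: int = 2) -> list[int]:
    """Descriptor-count sequence: next = min(ceil(retention*p), p-1),
    stopping once the next count would fall below ``floor``."""
    if p < floor:
        raise ValueError(f"need at least {floor} descriptors")
    sizes = [p]
    while True:
        nxt = min(sizes[-1] - 1, math.ceil(retention * sizes[-1]))
        if nxt < floor:
            return sizes
        sizes.append(nxt)


def _rank_descriptors(importance: pd.Series) -> list[str]:
    """Importance descending, ties broken by id (lexicographic)."""
    frame = importance.rename("imp").reset_index()
    frame.columns = ["id", "imp"]
    frame = frame.sort_values(["imp", "id"], ascending=[False, True])
    return frame["id"].tolist()


def rf_permutation_importance(model, X_heldout: np.ndarray,
                              y_heldout: np.ndarray,
                              rng: np.random.Generator) -> np.ndarray:
    """Per-descriptor increase in held-out MSE under column permutation.

    All permuted copies are stacked into a single predict call, which keeps
    the cost of scoring ~900 descriptors on a small held-out fold low.
    """
    m, p = X_heldout.shape
    base = model.predict(X_heldout)
    base_mse = float(np.mean((y_heldout - base) ** 2))
    stacked = np.repeat(X_heldout[None, :, :], p, axis=0)
    for j in range(p):
        stacked[j, :, j] = X_heldout[rng.permutation(m), j]
    preds = model.predict(stacked.reshape(p * m, p)).reshape(p, m)
    mses = np.mean((preds - y_heldout[None, :]) ** 2, axis=1)
    return mses - base_mse


# -- PLSR internals --------------------------------------------------------

def _pls_coef_path(pls: PLSRegression, a_max: int) -> np.ndarray:
    """Regression-coefficient paths B_a for a = 1..a_max (centered scale)."""
    W = pls.x_weights_[:, :a_max]
    P = pls.x_loadings_[:, :a_max]
    Q = pls.y_loadings_[0, :a_max]
    p = W.shape[0]
    coefs = np.empty((p, a_max))
    for a in range(1, a_max + 1):
        R = W[:, :a] @ np.linalg.pinv(P[:, :a].T @ W[:, :a])
        coefs[:, a - 1] = R @ Q[:a]
    return coefs


def _fit_pls(Xc: np.ndarray, yc: np.ndarray, a_max: int) -> PLSRegression:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")     # benign deflation warnings
        pls = PLSRegression(n_components=a_max, scale=False)
        pls.fit(Xc, yc)
    return pls


def _select_components(Xc: np.ndarray, yc: np.ndarray, a_cap: int,
                       inner_k: int, rng: np.random.Generator) -> int:
    """Component count minimizing PRESS in an inner k-fold CV."""
    n = Xc.shape[0]
    inner_k = min(inner_k, n)
    if inner_k < 2 or a_cap < 2:
        return max(1, a_cap)
    perm = rng.permutation(n)
    folds = np.array_split(perm, inner_k)
    press = np.zeros(a_cap)
    counted = np.zeros(a_cap, dtype=bool)
    for fold in folds:
        tr = np.setdiff1d(perm, fold, assume_unique=True)
        a_fold = min(a_cap, len(tr) - 1, Xc.shape[1])
        if a_fold < 1:
            continue
        xm, ym = Xc[tr].mean(axis=0), yc[tr].mean()
        pls = _fit_pls(Xc[tr] - xm, yc[tr] - ym, a_fold)
        coefs = _pls_coef_path(pls, a_fold)
        preds = (Xc[fold] - xm) @ coefs + ym
        press[:a_fold] += np.sum((preds - yc[fold, None]) ** 2, axis=0)
        counted[:a_fold] = True
    if not counted.any():
        return 1
    press[~counted] = np.inf
    return int(np.argmin(press)) + 1


def plsr_importance(pls: PLSRegression, n_components: int) -> np.ndarray:
    """Variance-explained-weighted squared loading weights.

    importance_j = sum_a w_ja^2 * SSY_a / sum_a SSY_a, with SSY_a the y
    variance captured by component a (q_a^2 ||t_a||^2).
    """
    W = pls.x_weights_[:, :n_components]
    T = pls.x_scores_[:, :n_components]
    Q = pls.y_loadings_[0, :n_components]
    ssy = Q ** 2 * np.sum(T ** 2, axis=0)
    total = ssy.sum()
    if total <= 0:
        return np.zeros(W.shape[0])
    return (W ** 2) @ (ssy / total)


# ---------------------------------------------------------------------------
# repeated cross-validation
# ---------------------------------------------------------------------------

def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"d{j + 1}" for j in range(X.shape[1])]


def repeated_cv_evaluate(spec: ModelSpec, X, y, k: int = 10,
                         repeats: int = 100,
                         keep_predictions: bool = False) -> CVResult:
    """Repeated k-fold CV with per-fit importance averaging.

    Each repeat draws a fresh random k-partition (seeded from
    ``spec.seed``); RMSE and R^2 are computed on the pooled held-out
    predictions of that repeat and averaged over repeats.
    """
    Xm, ids = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if y.shape != (n,):
        raise ValueError("y must align with the rows of X")
    if n < k:
        raise ValueError(f"cannot form {k} folds from {n} samples")
    if np.std(y) == 0:
        raise ValueError("constant response: R^2 undefined")
    if spec.global_standardize and spec.standardize_x:
        sd = Xm.std(axis=0, ddof=0)
        Xg = (Xm - Xm.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    else:
        Xg = Xm
    ss = np.random.SeedSequence(spec.seed)
    repeat_rngs = [np.random.default_rng(s) for s in ss.spawn(repeats)]
    importance_sum = np.zeros(p)
    n_fits = 0
    metrics = []
    prediction_log = [] if keep_predictions else None
    for rng in repeat_rngs:
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        y_pred = np.empty(n)
        for fold in folds:
            tr = np.setdiff1d(perm, fold, assume_unique=True)
            if spec.global_standardize or not spec.standardize_x:
                Xtr, Xte = Xg[tr], Xg[fold]
            else:
                mu = Xm[tr].mean(axis=0)
                sd = Xm[tr].std(axis=0, ddof=0)
                sd = np.where(sd > 0, sd, 1.0)
                Xtr, Xte = (Xm[tr] - mu) / sd, (Xm[fold] - mu) / sd
            # wide-range transformed descriptors (e.g. exponentials of
            # widths) can put a held-out point at an astronomical z-score
            # relative to the training fold; winsorize so neither the
            # forests (single precision) nor the PLS coefficient paths are
            # destabilized.  Ordinary standardized data is far inside the
            # bound.
            if spec.standardize_x:
                Xtr = np.clip(Xtr, -20.0, 20.0)
                Xte = np.clip(Xte, -20.0, 20.0)
            else:
                Xtr = np.clip(Xtr, -1e12, 1e12)
                Xte = np.clip(Xte, -1e12, 1e12)
            ym = y[tr].mean() if spec.center_y else 0.0
            ytr = y[tr] - ym
            if spec.algo == "rf":
                model = RandomForestRegressor(
                    n_estimators=spec.n_trees,
                    max_features=spec.max_features,
                    min_samples_leaf=5,
                    random_state=int(rng.integers(2 ** 31)))
                model.fit(Xtr, ytr)
                y_pred[fold] = model.predict(Xte) + ym
                if spec.importance == "impurity":
                    importance_sum += model.feature_importances_
                else:
                    importance_sum += rf_permutation_importance(
                        model, Xte, y[fold] - ym, rng)
            else:
                a_cap = min(spec.max_components, len(tr) - 2, p)
                a_cap = max(1, a_cap)
                a_star = _select_components(Xtr, ytr, a_cap,
                                            spec.inner_cv_folds, rng)
                pls = _fit_pls(Xtr, ytr, a_star)
                coef = _pls_coef_path(pls, a_star)[:, -1]
                y_pred[fold] = Xte @ coef + ym
                importance_sum += plsr_importance(pls, a_star)
            n_fits += 1
        sse = float(np.sum((y - y_pred) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        metrics.append({"rmse": math.sqrt(sse / n), "r2": 1.0 - sse / sst})
        if keep_predictions:
            prediction_log.append(pd.DataFrame(
                {"y_true": y, "y_pred": y_pred.copy()}))
    frame = pd.DataFrame(metrics)
    return CVResult(
        rmse_mean=float(frame["rmse"].mean()),
        rmse_sd=float(frame["rmse"].std(ddof=1)) if repeats > 1 else 0.0,
        r2_mean=float(frame["r2"].mean()),
        r2_sd=float(frame["r2"].std(ddof=1)) if repeats > 1 else 0.0,
        importance_mean=pd.Series(importance_sum / n_fits, index=ids),
        n_repeats=repeats, k=k, repeat_metrics=frame,
        predictions=prediction_log)


# ---------------------------------------------------------------------------
# recursive elimination
# ---------------------------------------------------------------------------

def recursive_select(spec: ModelSpec, X, y, retention: float = 0.9,
                     k: int = 10, repeats: int = 100, floor: int = 2,
                     property_name: str = "") -> SelectionTrace:
    """Stepwise elimination keeping the top ``retention`` fraction by
    averaged importance at each step (nested descriptor sets)."""
    if isinstance(X, pd.DataFrame):
        frame = X
    else:
        Xm, ids = _as_matrix(X)
        frame = pd.DataFrame(Xm, columns=ids)
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 descriptors")
    steps: list[SelectionStep] = []
    current = list(frame.columns)
    step_idx = 0
    while True:
        eval_spec = replace(spec, seed=int(np.random.SeedSequence(
            [spec.seed, step_idx]).generate_state(1)[0] % (2 ** 31)))
        result = repeated_cv_evaluate(eval_spec, frame[current], y,
                                      k=k, repeats=repeats)
        steps.append(SelectionStep(tuple(current), result))
        p = len(current)
        nxt = min(p - 1, math.ceil(retention * p))
        if nxt < floor:
            break
        ranked = _rank_descriptors(result.importance_mean)
        current = ranked[:nxt]
        step_idx += 1
    return SelectionTrace(steps=steps, property=property_name,
                          algo=spec.algo, retention=retention)


def best_set(trace: SelectionTrace) -> tuple[tuple[str, ...], CVResult]:
    """Descriptor set and CV metrics of the highest-R^2 step."""
    if not trace.steps:
        raise ValueError("empty trace")
    step = trace.steps[trace.best_index]
    return step.descriptor_ids, step.result


def consensus_topk(trace_rf: SelectionTrace, trace_plsr: SelectionTrace,
                   k: int = 20) -> ConsensusResult:
    """Top-k by importance at each algorithm's best step, intersected."""
    if trace_rf.property != trace_plsr.property:
        raise ValueError("traces are for different properties")
    tops = []
    for trace in (trace_rf, trace_plsr):
        _, result = best_set(trace)
        ranked = _rank_descriptors(result.importance_mean)
        if len(ranked) < k:
            warnings.warn(f"best step has only {len(ranked)} descriptors; "
                          "clipping k")
        tops.append(tuple(ranked[:k]))
    return ConsensusResult(property=trace_rf.property,
                           rf_top=tops[0], plsr_top=tops[1])
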