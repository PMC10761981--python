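"""Context decoding from bout-locked coherence changes.

Feature rows are "average bouts": one row per session x stimulus holding the
per-pair mean bout coherence change, with explicit missingness where a pair
was never recorded for a mouse.  The pipeline is

1. drop mice with fewer than 40 recorded pairs,
2. per-mouse normalization (subtract, per pair, the unweighted average of
   the per-stimulus means),
3. iterative regression imputation of missing pairs (20 iterations of
   randomized per-column least-squares, MICE-style),
4. leave-one-mouse-out random forests (80 trees) with class-balanced
   training folds, repeated 100 times per mouse,
5. a random-classifier null (uniform labels; 83 averaged matrices per
   mouse) and per-cell Mann-Whitney tests with FDR correction.

Labelings: ``stimulus_2class`` (social vs. object within SP),
``context_3class`` (SP / EsP / SxP), ``stimulus_6class`` (task:stimulus).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier

from .screen import bh_fdr

ROW_INDEX = ["subject", "task", "session", "stimulus"]


@dataclass
class ConfusionSummary:
    """Class-by-class prediction percentages (columns = ground truth)."""

    classes: list[str]
    matrix: pd.DataFrame  # K x K, percent of truth-j rows predicted i
    per_mouse: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.matrix.to_numpy()), index=self.classes)


def build_feature_table(bout_coherence: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long-format bout coherence table into the decoder's feature
    table: one row per (subject, task, session, stimulus), one column per
    region pair; missing pairs stay NaN."""
    df = bout_coherence.copy()
    needed = set(ROW_INDEX + ["pair", "value"])
    if not needed <= set(df.columns):
        raise ValueError(f"bout table missing column(s) {sorted(needed - set(df.columns))}")
    ft = df.groupby(ROW_INDEX + ["pair"])["value"].mean().unstack("pair")
    # rows whose session produced no feature at all (no valid bouts) are dropped
    all_nan = ft.isna().all(axis=1)
    if all_nan.any():
        warnings.warn(f"dropping {int(all_nan.sum())} all-missing rows (no valid bouts)")
        ft = ft[~all_nan]
    return ft


def stimulus_labels(ft: pd.DataFrame) -> pd.Series:
    idx = ft.index.to_frame(index=False)
    return pd.Series(
        (idx["task"] + ":" + idx["stimulus"]).to_numpy(), index=ft.index
    )


def exclude_sparse_mice(ft: pd.DataFrame, min_pairs: int = 40) -> pd.DataFrame:
    """Drop mice with fewer than ``min_pairs`` recorded (ever-observed) pairs."""
    keep = []
    for mouse, grp in ft.groupby(level="subject"):
        n_rec = int(grp.notna().any(axis=0).sum())
        if n_rec >= min_pairs:
            keep.append(mouse)
        else:
            warnings.warn(f"mouse {mouse}: only {n_rec} recorded pairs; excluded")
    return ft[ft.index.get_level_values("subject").isin(keep)]


def normalize_per_mouse(ft: pd.DataFrame) -> pd.DataFrame:
    """Per mouse and pair, subtract the unweighted average of the
    per-stimulus means (so no stimulus dominates the centering)."""
    out = ft.copy()
    stim = stimulus_labels(ft)
    for mouse, grp in ft.groupby(level="subject"):
        per_stim_means = grp.groupby(stim.loc[grp.index]).mean()
        center = per_stim_means.mean(axis=0)
        out.loc[grp.index] = grp - center
    return out


class IterativeRegressionImputer(BaseEstimator, TransformerMixin):
    """Iterative randomized-regression imputation of missing feature columns.

    Missing entries of each column are initialized with the column's
    observed mean, then refined for ``n_iterations`` rounds: in a freshly
    randomized column order, each column is regressed (ordinary least
    squares with intercept, minimum-norm on rank deficiency) on a random
    predictor subset of the other columns of size
    ``min(floor(n_rows / 2) - 1, n_cols - 1)``, and its originally-missing
    entries are overwritten with the fit's predictions.  Observed entries
    are never altered.
    """

    def __init__(self, n_iterations: int = 20, random_state: int | None = 0):
        self.n_iterations = n_iterations
        self.random_state = random_state

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        df = isinstance(X, pd.DataFrame)
        arr = np.asarray(X, dtype=float).copy()
        n_rows, n_cols = arr.shape
        missing = np.isnan(arr)
        if missing.all(axis=0).any():
            raise ValueError("a column has no observed values; cannot impute")
        if not missing.any():
            return X.copy() if df else arr
        rng = np.random.default_rng(self.random_state)
        col_means = np.nanmean(arr, axis=0)
        for c in range(n_cols):
            arr[missing[:, c], c] = col_means[c]
        n_pred = min(n_rows // 2 - 1, n_cols - 1)
        n_pred = max(n_pred, 1)
        for _ in range(self.n_iterations):
            order = rng.permutation(n_cols)
            for c in order:
                if not missing[:, c].any():
                    continue
                others = np.delete(np.arange(n_cols), c)
                preds = rng.choice(others, size=n_pred, replace=False)
                design = np.column_stack([np.ones(n_rows), arr[:, preds]])
                coef, *_ = np.linalg.lstsq(design, arr[:, c], rcond=None)
                fitted = design @ coef
                arr[missing[:, c], c] = fitted[missing[:, c]]
        if df:
            return pd.DataFrame(arr, index=X.index, columns=X.columns)
        return arr


def impute(ft: pd.DataFrame, n_iterations: int = 20, seed: int | None = 0) -> pd.DataFrame:
    """Functional wrapper over :class:`IterativeRegressionImputer`."""
    return IterativeRegressionImputer(n_iterations, seed).fit_transform(ft)


def _labels_for(ft: pd.DataFrame, label: str) -> tuple[pd.DataFrame, np.ndarray]:
    idx = ft.index.to_frame(index=False)
    if label == "context_3class":
        return ft, idx["task"].to_numpy()
    if label == "stimulus_6class":
        return ft, (idx["task"] + ":" + idx["stimulus"]).to_numpy()
    if label == "stimulus_2class":
        keep = (idx["task"] == "SP").to_numpy()
        return ft[keep], idx.loc[keep, "stimulus"].to_numpy()
    raise ValueError(f"unknown label kind {label!r}")


def _balance(rng: np.random.Generator, y: np.ndarray) -> np.ndarray:
    """Indices of a class-balanced random down-sample."""
    classes, counts = np.unique(y, return_counts=True)
    m = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        keep.append(rng.choice(idx, size=m, replace=False))
    return np.sort(np.concatenate(keep))


def _percent_matrix(counts: np.ndarray) -> np.ndarray:
    """Column-normalized percentages; all-empty truth columns become NaN."""
    totals = counts.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(totals > 0, 100.0 * counts / totals, np.nan)


def crossval_confusion(
    ft: pd.DataFrame,
    label: str = "context_3class",
    n_trees: int = 80,
    n_repeats: int = 100,
    seed: int = 0,
) -> ConfusionSummary:
    """Leave-one-mouse-out random-forest confusion matrices.

    For each held-out mouse and repeat, the training fold (all other mice)
    is class-balanced by random down-sampling, an 80-tree random forest is
    trained, and the mouse's rows are predicted.  The per-mouse matrix
    averages the repeats; the overall matrix aggregates raw counts over all
    mouse-repeats.  A class missing from a training fold is an error.
    """
    X_df, y = _labels_for(ft, label)
    if X_df.isna().any().any():
        raise ValueError("feature table must be imputed (no NaNs) before decoding")
    classes = sorted(np.unique(y))
    cls_idx = {c: k for k, c in enumerate(classes)}
    K = len(classes)
    mice = X_df.index.get_level_values("subject").to_numpy()
    X = X_df.to_numpy()
    rng = np.random.default_rng(seed)
    per_mouse: dict[str, pd.DataFrame] = {}
    total_counts = np.zeros((K, K))
    for mouse in sorted(set(mice)):
        test = mice == mouse
        train = ~test
        y_tr_all, y_te = y[train], y[test]
        missing_cls = set(classes) - set(y_tr_all)
        if missing_cls:
            raise ValueError(f"fold holding out {mouse}: class(es) {missing_cls} "
                             "absent from training data")
        counts = np.zeros((K, K))
        for _ in range(n_repeats):
            bal = _balance(rng, y_tr_all)
            rf = RandomForestClassifier(
                n_estimators=n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(X[train][bal], y_tr_all[bal])
            pred = rf.predict(X[test])
            for pr, tr in zip(pred, y_te):
                counts[cls_idx[pr], cls_idx[tr]] += 1
        per_mouse[mouse] = pd.DataFrame(_percent_matrix(counts), index=classes, columns=classes)
        total_counts += counts
    overall = pd.DataFrame(_percent_matrix(total_counts), index=classes, columns=classes)
    return ConfusionSummary(classes, overall, per_mouse)


def random_null_confusion(
    ft: pd.DataFrame,
    label: str = "context_3class",
    n_matrices: int = 83,
    inner_repeats: int = 100,
    seed: int = 0,
) -> dict[str, list[pd.DataFrame]]:
    """Random-classifier null: same folds, predictions drawn uniformly over
    classes; ``n_matrices`` averaged matrices per mouse, each over
    ``inner_repeats`` inner repeats."""
    X_df, y = _labels_for(ft, label)
    classes = sorted(np.unique(y))
    cls_idx = {c: k for k, c in enumerate(classes)}
    K = len(classes)
    mice = X_df.index.get_level_values("subject").to_numpy()
    rng = np.random.default_rng(seed)
    out: dict[str, list[pd.DataFrame]] = {}
    for mouse in sorted(set(mice)):
        y_te = y[mice == mouse]
        truth_cols = np.array([cls_idx[t] for t in y_te])
        mats = []
        for _ in range(n_matrices):
            counts = np.zeros((K, K))
            draws = rng.integers(0, K, size=(inner_repeats, len(y_te)))
            for rep in range(inner_repeats):
                np.add.at(counts, (draws[rep], truth_cols), 1)
            mats.append(pd.DataFrame(_percent_matrix(counts), index=classes, columns=classes))
        out[mouse] = mats
    return out


def cell_significance(
    real: ConfusionSummary,
    null: dict[str, list[pd.DataFrame]],
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Per-cell Mann-Whitney U of the per-mouse real percentages against all
    per-mouse null percentages, FDR-corrected across cells.

    Mice with no ground-truth rows of class j (NaN column j) are dropped
    from column-j cells; cells with < 2 contributing mice are untestable.
    """
    classes = real.classes
    rows = []
    for j, truth in enumerate(classes):
        contributing = [
            m for m, mat in real.per_mouse.items()
            if np.isfinite(mat.to_numpy()[:, j]).all()
        ]
        for i, pred in enumerate(classes):
            real_vals = np.array(
                [real.per_mouse[m].to_numpy()[i, j] for m in contributing]
            )
            null_vals = np.concatenate(
                [[mat.to_numpy()[i, j] for mat in null[m]] for m in contributing]
            ) if contributing else np.array([])
            if len(real_vals) < 2:
                rows.append(dict(predicted=pred, truth=truth, n_mice=len(real_vals),
                                 real_mean=np.nan, null_mean=np.nan,
                                 U=np.nan, p=np.nan, testable=False))
                continue
            U, p = stats.mannwhitneyu(real_vals, null_vals, alternative="two-sided")
            rows.append(dict(predicted=pred, truth=truth, n_mice=len(real_vals),
                             real_mean=float(real_vals.mean()),
                             null_mean=float(null_vals.mean()),
                             U=float(U), p=float(p), testable=True))
    df = pd.DataFrame(rows)
    testable = df["testable"].to_numpy()
    df["p_adj"] = np.nan
    df["significant"] = False
    if testable.any():
        rej, adj = bh_fdr(df.loc[testable, "p"].to_numpy(), fdr_q)
        df.loc[testable, "p_adj"] = adj
        df.loc[testable, "significant"] = rej
    return df


def decode_pipeline(
    bout_coherence: pd.DataFrame,
    label: str = "context_3class",
    min_pairs: int = 40,
    n_trees: int = 80,
    n_repeats: int = 100,
    n_null_matrices: int = 83,
    null_inner_repeats: int = 100,
    impute_iterations: int = 20,
    seed: int = 0,
) -> dict:
    """Full decoding pipeline from a long-format bout coherence table."""
    ss = np.random.SeedSequence(seed)
    s_imp, s_cv, s_null = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3))
    ft = build_feature_table(bout_coherence)
    ft = exclude_sparse_mice(ft, min_pairs)
    ft = normalize_per_mouse(ft)
    ft_imp = impute(ft, impute_iterations, s_imp)
    real = crossval_confusion(ft_imp, label, n_trees, n_repeats, s_cv)
    null = random_null_confusion(ft_imp, label, n_null_matrices, null_inner_repeats, s_null)
    cells = cell_significance(real, null)
    return dict(features=ft, features_imputed=ft_imp, confusion=real,
                null=null, cells=cells)
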