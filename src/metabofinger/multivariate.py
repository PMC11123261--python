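"""PCA diagnostics, PLS-DA with VIP and permutation validation, and a
random-forest classifier with out-of-bag evaluation.

PLS-DA is fitted by the NIPALS algorithm on a single centered +/-1 dummy
response (for a binary response NIPALS extracts each component in closed
form). Model quality is summarized by R^2 = 1 - RSS/TSS on the fitted data
and by Q^2 = 1 - PRESS/TSS accumulated over stratified 7-fold
cross-validation, with the component count chosen to maximize Q^2.
Significance is assessed by y-scrambling: the full cross-validated pipeline
is re-run under n label permutations and empirical p-values are reported as
(1 + #{permuted >= observed}) / (n + 1).

Per-feature influence is the variable importance in projection,

    VIP_j = sqrt( p * sum_a w_ja^2 SSY_a / sum_a SSY_a ),

normalized so the mean squared VIP over features is 1. The random forest is
bagged CART trees with sqrt(p) candidate features per split; it reports the
out-of-bag AUC and out-of-bag permutation importance (mean decrease in
accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .core import RunConfig, substream, substream_int


class ClassBalanceError(ValueError):
    """Both classes must be present (and non-constant y)."""


def _encode_y(y) -> tuple[np.ndarray, np.ndarray]:
    """Map arbitrary binary labels to centered -1/+1 coding."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ClassBalanceError(f"need exactly 2 classes, got {list(classes)}")
    return np.where(y == classes[1], 1.0, -1.0), classes


def pca(X, n_components: int = 2) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA scores, loadings and explained variance of a samples x features matrix."""
    if isinstance(X, pd.DataFrame):
        index, columns, mat = X.index, X.columns, X.to_numpy(float)
    else:
        mat = np.asarray(X, float)
        index = pd.RangeIndex(mat.shape[0])
        columns = pd.RangeIndex(mat.shape[1])
    rank = min(mat.shape[0] - 1, mat.shape[1])
    k = min(n_components, rank)
    model = PCA(n_components=k)
    scores = model.fit_transform(mat)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=index, columns=comp_names),
        pd.DataFrame(model.components_.T, index=columns, columns=comp_names),
        model.explained_variance_,
    )


@dataclass
class PlsModel:
    """Fitted PLS-DA (PLS1) model with per-feature VIP."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # p x A
    scores: np.ndarray  # n x A
    loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    ssy: np.ndarray  # per-component explained y sum of squares
    vip: np.ndarray
    r2: float
    q2: float | None = None
    classes: np.ndarray | None = None
    feature_names: list | None = None

    @property
    def coefficients(self) -> np.ndarray:
        W, P, q = self.weights, self.loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X) -> np.ndarray:
        mat = np.asarray(X, float)
        return (mat - self.x_mean) @ self.coefficients + self.y_mean

    def vip_series(self) -> pd.Series:
        idx = self.feature_names if self.feature_names is not None else range(len(self.vip))
        return pd.Series(self.vip, index=idx, name="vip")


def plsda_fit(X, y, n_components: int = 2) -> PlsModel:
    """Fit a PLS-DA model by NIPALS on a centered +/-1 response."""
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    mat = np.asarray(X, float)
    yy, classes = _encode_y(y)
    n, p = mat.shape
    max_a = max(1, min(n - 1, p))
    if n_components > max_a:
        n_components = max_a
    x_mean = mat.mean(axis=0)
    Xc = mat - x_mean
    y_mean = yy.mean()
    yc = yy - y_mean
    tss = float(yc @ yc)

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    ssy = np.zeros(n_components)
    Xr, yr = Xc.copy(), yc.copy()
    a_used = 0
    for a in range(n_components):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = Xr @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pa = Xr.T @ t / tt
        qa = float(yr @ t) / tt
        Xr = Xr - np.outer(t, pa)
        yr = yr - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pa, qa
        ssy[a] = qa**2 * tt
        a_used += 1
    W, T, P, q, ssy = W[:, :a_used], T[:, :a_used], P[:, :a_used], q[:a_used], ssy[:a_used]
    rss = float(yr @ yr)
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")

    denom = ssy.sum()
    if denom > 0:
        vip = np.sqrt(p * (W**2 @ ssy) / denom)
    else:
        vip = np.ones(p)
    return PlsModel(
        n_components=a_used,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        scores=T,
        loadings=P,
        y_loadings=q,
        ssy=ssy,
        vip=vip,
        r2=r2,
        classes=classes,
        feature_names=feature_names,
    )


def _fold_coefficients(Xc: np.ndarray, yc: np.ndarray, a_max: int) -> list[np.ndarray]:
    """Regression coefficient vectors for 1..a_max components (NIPALS)."""
    n, p = Xc.shape
    a_max = max(1, min(a_max, n - 1, p))
    W = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    q = np.zeros(a_max)
    Xr, yr = Xc.copy(), yc.copy()
    coeffs = []
    used = 0
    for a in range(a_max):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = Xr @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pa = Xr.T @ t / tt
        qa = float(yr @ t) / tt
        Xr -= np.outer(t, pa)
        yr = yr - qa * t
        W[:, a], P[:, a], q[a] = w, pa, qa
        used = a + 1
        Wa, Pa, qa_vec = W[:, :used], P[:, :used], q[:used]
        coeffs.append(Wa @ np.linalg.solve(Pa.T @ Wa, qa_vec))
    return coeffs


def plsda_cv(
    X,
    y,
    folds: int = 7,
    a_max: int = 5,
    seed: int = 0,
    max_attempts: int = 100,
    n_components: int | None = None,
    rule: str = "improvement",
    improvement_threshold: float = 0.01,
) -> tuple[int, float]:
    """Cross-validated Q^2 and component-count choice for PLS-DA.

    Q^2(A) = 1 - PRESS(A)/TSS with PRESS accumulated over held-out
    stratified folds (seeded; a draw in which some training split lacks a
    class is re-drawn, error after ``max_attempts``). With
    ``n_components=None`` the count is chosen by the parsimony rule
    ``rule="improvement"``: components are added only while Q^2 improves by
    at least ``improvement_threshold`` (when samples are far fewer than
    features, additional components inflate the fitted R^2 toward exactly 1
    without predictive gain, which would degenerate permutation p-values);
    ``rule="max_q2"`` instead picks the Q^2 maximum. With an explicit
    ``n_components`` the Q^2 at that count is returned.
    """
    mat = np.asarray(X, float)
    yy, _ = _encode_y(y)
    min_class = int(np.unique(yy, return_counts=True)[1].min())
    folds = max(2, min(folds, min_class))
    tss = float(np.sum((yy - yy.mean()) ** 2))
    rng = substream(seed, "cv_folds")
    for attempt in range(max_attempts):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            splits = list(skf.split(mat, yy))
        except ValueError as exc:
            raise ClassBalanceError(str(exc)) from exc
        if all(len(np.unique(yy[tr])) == 2 for tr, _ in splits):
            break
    else:
        raise ClassBalanceError("could not draw folds with both classes in training")

    a_cap = max(1, min(a_max, min(len(tr) for tr, _ in splits) - 1, mat.shape[1]))
    if n_components is not None:
        a_cap = max(1, min(n_components, a_cap))
    press = np.zeros(a_cap)
    counts = np.zeros(a_cap, dtype=int)
    for tr, te in splits:
        x_mean = mat[tr].mean(axis=0)
        y_mean = yy[tr].mean()
        coeffs = _fold_coefficients(mat[tr] - x_mean, yy[tr] - y_mean, a_cap)
        Xte = mat[te] - x_mean
        for a, b in enumerate(coeffs):
            pred = Xte @ b + y_mean
            press[a] += float(np.sum((yy[te] - pred) ** 2))
            counts[a] += 1
    valid = counts == len(splits)
    q2 = np.where(valid, 1.0 - press / tss, -np.inf)
    if n_components is not None:
        a = min(n_components, a_cap)
        return a, float(q2[a - 1])
    if rule == "max_q2":
        best = int(np.argmax(q2))
        return best + 1, float(q2[best])
    best = 0
    while best + 1 < a_cap and q2[best + 1] - q2[best] >= improvement_threshold:
        best += 1
    return best + 1, float(q2[best])


def permutation_test(
    X,
    y,
    n_permutations: int = 1000,
    folds: int = 7,
    a_max: int = 5,
    seed: int = 0,
    statistic: str = "pvalue",
    rule: str = "improvement",
    improvement_threshold: float = 0.01,
) -> dict:
    """Y-scrambling validation of the cross-validated PLS-DA pipeline.

    The observed model's component count is chosen by cross-validation;
    each permutation re-runs the cross-validated fit with the model
    dimensionality held at that observed count (the convention of
    established PLS validation tools), yielding null R^2 and Q^2 values.
    Returns observed R^2 / Q^2 plus ``r2_perm`` and ``q2_perm``. With
    ``statistic="pvalue"`` (default) these are empirical p-values
    (1 + #{perm >= obs}) / (n + 1); with ``"mean"`` they are the mean
    permuted statistics.
    """
    if n_permutations <= 0:
        raise ValueError("n_permutations must be positive")
    mat = np.asarray(X, float)
    yy = np.asarray(y)
    a_obs, q2_obs = plsda_cv(
        mat, yy, folds, a_max, seed, rule=rule,
        improvement_threshold=improvement_threshold,
    )
    r2_obs = plsda_fit(mat, yy, a_obs).r2

    rng = substream(seed, "permutations")
    r2_null = np.empty(n_permutations)
    q2_null = np.empty(n_permutations)
    for i in range(n_permutations):
        yp = rng.permutation(yy)
        try:
            _, q2_p = plsda_cv(mat, yp, folds, a_max, seed + i + 1,
                               n_components=a_obs)
            r2_p = plsda_fit(mat, yp, a_obs).r2
        except ClassBalanceError:
            q2_p, r2_p = -np.inf, 0.0
        r2_null[i] = r2_p
        q2_null[i] = q2_p
    if statistic == "pvalue":
        r2_perm = (1 + np.sum(r2_null >= r2_obs)) / (n_permutations + 1)
        q2_perm = (1 + np.sum(q2_null >= q2_obs)) / (n_permutations + 1)
    else:
        r2_perm = float(np.mean(r2_null))
        q2_perm = float(np.mean(q2_null[np.isfinite(q2_null)]))
    return {
        "r2": r2_obs,
        "q2": q2_obs,
        "n_components": a_obs,
        "r2_perm": float(r2_perm),
        "q2_perm": float(q2_perm),
        "n_permutations": n_permutations,
    }


def rf_classify(
    X, y, n_trees: int = 500, seed: int = 0
) -> tuple[float, pd.Series]:
    """Random-forest classification with OOB AUC and OOB permutation MDA.

    Bagged CART trees with sqrt(p) candidate features per split. The OOB
    AUC scores each sample by the mean class-1 probability over the trees
    that did not see it. MDA_j averages, over all trees, the drop in that
    tree's OOB accuracy when feature j is permuted among its OOB samples
    (zero for trees that never split on j).
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    mat = np.asarray(X, float)
    yy, classes = _encode_y(y)
    y01 = (yy > 0).astype(int)
    n, p = mat.shape
    forest = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features="sqrt"),
        n_estimators=n_trees,
        bootstrap=True,
        random_state=substream_int(seed, "rf"),
        n_jobs=1,
    )
    forest.fit(mat, y01)

    prob_sum = np.zeros(n)
    prob_cnt = np.zeros(n)
    mda_sum = np.zeros(p)
    rng = substream(seed, "rf_mda")
    for tree, in_bag in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), np.unique(in_bag))
        if oob.size == 0:
            continue
        X_oob = mat[oob]
        proba = tree.predict_proba(X_oob)
        pos_col = int(np.where(tree.classes_ == 1)[0][0]) if 1 in tree.classes_ else None
        if pos_col is not None:
            prob_sum[oob] += proba[:, pos_col]
        prob_cnt[oob] += 1
        pred = tree.predict(X_oob)
        acc = float(np.mean(pred == y01[oob]))
        used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
        for j in used:
            Xp = X_oob.copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            acc_p = float(np.mean(tree.predict(Xp) == y01[oob]))
            mda_sum[j] += acc - acc_p
    if np.any(prob_cnt == 0):
        covered = prob_cnt > 0
    else:
        covered = np.ones(n, bool)
    oob_score = np.where(prob_cnt > 0, prob_sum / np.maximum(prob_cnt, 1), 0.5)
    auc = float(roc_auc_score(y01[covered], oob_score[covered]))
    mda = mda_sum / n_trees
    idx = feature_names if feature_names is not None else range(p)
    return auc, pd.Series(mda, index=idx, name="mda")


def multivariate_select(
    model: PlsModel, mda: pd.Series, config: RunConfig | None = None
) -> list:
    """Union of VIP-threshold and top-k-MDA selections.

    selected = {features with VIP >= vip_cutoff} U {k features with the
    largest mean decrease in accuracy}; both knobs are config keys.
    """
    cfg = config or RunConfig()
    vip = model.vip_series()
    chosen = set(vip.index[vip >= cfg.vip_cutoff])
    if cfg.mda_top_k > 0 and len(mda):
        top = mda.sort_values(ascending=False, kind="stable").index[: cfg.mda_top_k]
        chosen |= set(top)
    return [f for f in vip.index if f in chosen]


@dataclass
class ModelEvaluation:
    """Model-quality surface: R^2, Q^2, permutation p-values, OOB AUC, MDA."""

    r2: float
    q2: float
    r2_perm: float
    q2_perm: float
    n_permutations: int
    n_components: int
    oob_auc: float
    mda: pd.Series = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "R2": self.r2,
            "Q2": self.q2,
            "R2_PERM": self.r2_perm,
            "Q2_PERM": self.q2_perm,
            "n_permutations": self.n_permutations,
            "n_components": self.n_components,
            "AUC": self.oob_auc,
        }


def evaluate_models(
    X, y, config: RunConfig | None = None
) -> tuple[ModelEvaluation, PlsModel]:
    """Fit and validate the PLS-DA and RF models on one pretreated matrix."""
    cfg = config or RunConfig()
    perm = permutation_test(
        X, y,
        n_permutations=cfg.n_permutations,
        folds=cfg.cv_folds,
        a_max=cfg.max_components,
        seed=cfg.seed,
        statistic=cfg.permutation_statistic,
        rule=cfg.component_rule,
        improvement_threshold=cfg.q2_improvement_threshold,
    )
    model = plsda_fit(X, y, perm["n_components"])
    model.q2 = perm["q2"]
    auc, mda = rf_classify(X, y, n_trees=cfg.rf_trees, seed=cfg.seed)
    ev = ModelEvaluation(
        r2=perm["r2"],
        q2=perm["q2"],
        r2_perm=perm["r2_perm"],
        q2_perm=perm["q2_perm"],
        n_permutations=perm["n_permutations"],
        n_components=perm["n_components"],
        oob_auc=auc,
        mda=mda,
    )
    return ev, model
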