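"""Downstream evaluation on the learned sample factor matrix H.

Three analyses, all consuming H columns as per-sample representations:

* **Classification** — repeated random 80/20 splits; within each training
  split, k-fold cross-validation over a (K, α, β) grid scores every
  configuration by mean validation AUC with an L2-regularized logistic
  classifier; the winner is refit on the full training split and evaluated
  on the held-out samples by AUC and MCC.
* **Survival** — Cox proportional hazards with an elastic-net penalty
  (mixing η fixed, shrinkage ξ chosen by cross-validation); the prognostic
  index PI = λᵀH_test splits test samples at the median into high-/low-risk
  groups, compared by Kaplan–Meier curves and the log-rank test.
* **Subtyping** — hierarchical clustering of the sample-by-sample absolute
  Pearson correlation matrix of H, with an annotated clustermap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import matthews_corrcoef, roc_auc_score
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .data_model import ClinicalTable, MultiOmicsDataset
from .factorization import FactorModel, Hyperparameters, fit, transform
from .network import BlockInteractionNetwork

logger = logging.getLogger("xintnmf")

__all__ = [
    "GridSpec",
    "SurvivalConfig",
    "EvaluationResult",
    "mcc",
    "auc",
    "run_classification",
    "cox_elasticnet_pi",
    "km_logrank",
    "subtype_clustermap",
]


@dataclass
class GridSpec:
    """Hyperparameter grid and split schedule for the classification harness.

    Defaults are the standard tuning grid: K over five latent sizes, α over
    ten orders of magnitude including 0 (the no-network ablation), β applied
    uniformly across layers, 100 random 80/20 splits with 5-fold inner CV.
    """

    K_values: Sequence[int] = (10, 25, 50, 100, 200)
    alpha_values: Sequence[float] = (0, 1e-4, 1e-3, 1e-2, 0.1, 1, 10, 100, 1000, 10000)
    beta_values: Sequence[float] = (1, 0.1, 0.01, 10, 100)
    n_splits: int = 100
    test_fraction: float = 0.2
    cv_folds: int = 5
    seed: int = 0
    max_iter: int = 300  # solver iterations per harness fit

    def points(self) -> list[tuple[int, float, float]]:
        """Grid order fixes tie-breaking: K outermost, then α, then β."""
        return list(product(self.K_values, self.alpha_values, self.beta_values))


@dataclass
class SurvivalConfig:
    eta: float = 0.5  # elastic-net mixing, fixed
    xi_grid: Sequence[float] | None = None  # None -> auto path from the data
    cv_folds: int = 5
    n_xi: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.eta <= 1:
            raise ValueError("eta must lie in [0, 1]")


@dataclass
class EvaluationResult:
    auc_per_split: list[float] = field(default_factory=list)
    mcc_per_split: list[float] = field(default_factory=list)
    chosen: list[tuple[int, float, float]] = field(default_factory=list)
    skipped_splits: int = 0

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_per_split)) if self.auc_per_split else float("nan")

    @property
    def mean_mcc(self) -> float:
        return float(np.mean(self.mcc_per_split)) if self.mcc_per_split else float("nan")

    @property
    def modal_choice(self) -> tuple[int, float, float] | None:
        """Most frequently selected grid point (first in grid order on ties);
        the configuration to reuse for additional downstream analyses."""
        if not self.chosen:
            return None
        counts: dict[tuple, int] = {}
        for c in self.chosen:
            counts[c] = counts.get(c, 0) + 1
        best = max(counts.values())
        for c in self.chosen:  # insertion follows split order; tie -> earliest seen
            if counts[c] == best:
                return c
        return None


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def mcc(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(matthews_corrcoef(labels, predictions))


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based ROC AUC (Mann–Whitney normalization, ties averaged)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if labels.size == 0:
        raise ValueError("empty input")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# classification harness
# ---------------------------------------------------------------------------

def _classifier_scores(
    H_train: np.ndarray, y_train: np.ndarray, H_eval: np.ndarray
) -> np.ndarray:
    """L2-regularized logistic model on standardized H columns -> decision scores."""
    scaler = StandardScaler()
    Z = scaler.fit_transform(H_train.T)
    clf = LogisticRegression(C=1.0, max_iter=1000)
    clf.fit(Z, y_train)
    return clf.decision_function(scaler.transform(H_eval.T))


def _fit_score(
    dataset: MultiOmicsDataset,
    network: BlockInteractionNetwork | None,
    y: np.ndarray,
    train_idx: np.ndarray,
    eval_idx: np.ndarray,
    point: tuple[int, float, float],
    max_iter: int,
    seed: int,
) -> tuple[np.ndarray, FactorModel]:
    """Fit on the training samples, project the eval samples, return scores."""
    K, alpha, beta = point
    hp = Hyperparameters(K=K, alpha=alpha, beta=beta, max_iter=max_iter, seed=seed)
    train_ds = dataset.select_samples(train_idx)
    model = fit(train_ds, network if alpha > 0 else None, hp)
    H_eval = transform(model, dataset.select_samples(eval_idx), seed=seed)
    scores = _classifier_scores(model.H, y[train_idx], H_eval)
    return scores, model


def run_classification(
    dataset: MultiOmicsDataset,
    network: BlockInteractionNetwork | None,
    clinical: ClinicalTable,
    grid: GridSpec,
) -> EvaluationResult:
    """Repeated-split grid-search evaluation of the latent representation.

    Samples without a label are excluded.  Splits whose training portion
    lacks one of the classes are skipped with a warning.  Grid ties are
    broken by grid order (first maximal mean inner-CV AUC wins).
    """
    y_all = clinical.aligned_labels(dataset.sample_ids)
    labeled = np.flatnonzero(~np.isnan(y_all))
    if labeled.size == 0:
        raise ValueError("no labeled samples")
    data = dataset.select_samples(labeled)
    y = y_all[labeled].astype(int)
    n = len(labeled)
    n_test = max(1, int(round(grid.test_fraction * n)))
    points = grid.points()
    rng = np.random.default_rng(grid.seed)
    result = EvaluationResult()

    for s in range(grid.n_splits):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            warnings.warn(f"split {s}: a class is absent; split skipped", stacklevel=2)
            result.skipped_splits += 1
            continue
        split_seed = int(rng.integers(0, 2**31 - 1))

        if len(points) == 1:
            best_point = points[0]
        else:
            best_point, best_score = None, -np.inf
            kf = KFold(n_splits=grid.cv_folds, shuffle=True, random_state=split_seed)
            folds = list(kf.split(train_idx))
            for point in points:
                fold_aucs = []
                for tr, va in folds:
                    tr_idx, va_idx = train_idx[tr], train_idx[va]
                    if len(np.unique(y[tr_idx])) < 2 or len(np.unique(y[va_idx])) < 2:
                        continue
                    scores, _ = _fit_score(
                        data, network, y, tr_idx, va_idx, point, grid.max_iter, split_seed
                    )
                    fold_aucs.append(auc(y[va_idx], scores))
                if fold_aucs and np.mean(fold_aucs) > best_score:
                    best_score = float(np.mean(fold_aucs))
                    best_point = point
            if best_point is None:
                warnings.warn(f"split {s}: no valid inner fold; split skipped", stacklevel=2)
                result.skipped_splits += 1
                continue

        scores, _ = _fit_score(
            data, network, y, train_idx, test_idx, best_point, grid.max_iter, split_seed
        )
        result.auc_per_split.append(auc(y[test_idx], scores))
        result.mcc_per_split.append(mcc(y[test_idx], (scores > 0).astype(int)))
        result.chosen.append(best_point)
    return result


# ---------------------------------------------------------------------------
# survival analysis
# ---------------------------------------------------------------------------

def cox_elasticnet_pi(
    H_train: np.ndarray,
    survival_train: tuple[np.ndarray, np.ndarray],
    H_test: np.ndarray,
    config: SurvivalConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Penalized Cox fit on H columns -> (PI, risk_groups, coefficients).

    The elastic-net Cox model (mixing η fixed, shrinkage ξ chosen by k-fold
    cross-validated concordance over a data-driven path) yields coefficients
    λ; the prognostic index PI = λᵀH_test is split at its median into
    high-risk (1) and low-risk (0) groups, ties assigned to low risk.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    config = config or SurvivalConfig()
    times, events = survival_train
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if events.sum() == 0:
        raise ValueError("no events in the training data")
    X = np.asarray(H_train, dtype=float).T  # samples x K
    y = Surv.from_arrays(event=events, time=times)

    # ξ path: either supplied or the data-driven path of the path solver
    l1r = max(config.eta, 1e-6)  # path solver requires a strictly positive L1 part
    if config.xi_grid is not None:
        alphas = np.sort(np.asarray(config.xi_grid, dtype=float))[::-1]
    else:
        probe = CoxnetSurvivalAnalysis(l1_ratio=l1r, n_alphas=config.n_xi, alpha_min_ratio=0.01)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probe.fit(X, y)
        alphas = probe.alphas_

    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    fold_scores = np.zeros((config.cv_folds, len(alphas)))
    valid = np.ones(len(alphas), dtype=bool)
    for f, (tr, va) in enumerate(kf.split(X)):
        if events[tr].sum() == 0 or events[va].sum() == 0:
            continue
        est = CoxnetSurvivalAnalysis(l1_ratio=l1r, alphas=alphas, fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[tr], y[tr])
        from sksurv.metrics import concordance_index_censored

        for j, a in enumerate(alphas):
            try:
                risk = est.predict(X[va], alpha=a)
                fold_scores[f, j] = concordance_index_censored(events[va], times[va], risk)[0]
            except Exception:
                valid[j] = False
    mean_scores = fold_scores.mean(axis=0)
    mean_scores[~valid] = -np.inf
    best_alpha = float(alphas[int(np.argmax(mean_scores))])

    final = CoxnetSurvivalAnalysis(l1_ratio=l1r, alphas=[best_alpha], fit_baseline_model=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    lam = final.coef_.ravel()

    pi = lam @ np.asarray(H_test, dtype=float)
    if np.allclose(pi, pi[0] if pi.size else 0.0):
        warnings.warn("constant prognostic index: no risk split possible", stacklevel=2)
        groups = np.zeros(pi.shape, dtype=int)
    else:
        groups = (pi > np.median(pi)).astype(int)  # ties at the median -> low risk
    return pi, groups, lam


def km_logrank(
    times: np.ndarray,
    events: np.ndarray,
    groups: np.ndarray,
) -> tuple[dict[int, pd.DataFrame], float, float]:
    """Kaplan–Meier curves per group and the two-sample log-rank test.

    Returns ({group: survival curve DataFrame}, chi-square statistic on 1 df,
    p-value).  With no events anywhere the statistic is 0 and p = 1.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {len(uniq)}")
    curves = {}
    for g in uniq:
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        curves[int(g)] = kmf.survival_function_
    if events.sum() == 0:
        return curves, 0.0, 1.0
    m0, m1 = groups == uniq[0], groups == uniq[1]
    res = logrank_test(times[m0], times[m1], event_observed_A=events[m0], event_observed_B=events[m1])
    return curves, float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# subtype analysis
# ---------------------------------------------------------------------------

def subtype_clustermap(
    H: np.ndarray,
    subtype_labels: Sequence | None = None,
    n_clusters: int = 2,
    linkage_method: str = "ward",
    render: bool = False,
):
    """Hierarchical clustering of the sample |PCC| matrix of H.

    Returns (corr, leaf_order, flat_clusters, figure); the figure is rendered
    (seaborn clustermap with a label annotation bar) only when requested.
    Constant H columns get all-zero correlations with a warning.
    """
    H = np.asarray(H, dtype=float)
    if H.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = H.std(axis=0)
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(H).max(axis=0))
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant factor columns: correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.abs(np.corrcoef(H.T))
    corr[~np.isfinite(corr)] = 0.0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)

    Z = sch.linkage(corr, method=linkage_method, metric="euclidean")
    leaf_order = sch.leaves_list(Z)
    flat = sch.fcluster(Z, t=n_clusters, criterion="maxclust")

    fig = None
    if render:
        import matplotlib
        matplotlib.use("Agg")
        import seaborn as sns

        row_colors = None
        if subtype_labels is not None:
            palette = sns.color_palette("husl", len(set(subtype_labels)))
            lut = {lab: palette[i] for i, lab in enumerate(dict.fromkeys(subtype_labels))}
            row_colors = [lut[lab] for lab in subtype_labels]
        g = sns.clustermap(
            pd.DataFrame(corr),
            row_linkage=Z,
            col_linkage=Z,
            row_colors=row_colors,
            col_colors=row_colors,
            cmap="viridis",
        )
        fig = g.fig
    return corr, leaf_order, flat, fig


# ---------------------------------------------------------------------------
# permutation calibration helper
# ---------------------------------------------------------------------------

def logrank_permutation_pvalues(
    times: np.ndarray,
    events: np.ndarray,
    groups: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Log-rank p-values under random permutations of the group labels —
    a null-calibration check for the survival machinery."""
    rng = np.random.default_rng(seed)
    groups = np.asarray(groups)
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        out[i] = km_logrank(times, events, rng.permutation(groups))[2]
    return out
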