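"""Network-regularized joint NMF solver for multi-omics integration.

The model factorizes D non-negative omics layers X(d) (m_d x N) into
omic-specific factor matrices W(d) (m_d x K) and one shared sample factor
matrix H (K x N), minimizing

    f = 1/2 Σ_d ||X(d) − W(d)H||_F²                 (reconstruction)
      + α/2 · Tr(W̄ᵀ L W̄)                           (network regularization)
      + Σ_d β_d ||W(d)||₁                            (feature-factor sparsity)
      + Σ_i γ_i ||H·,i||₁                            (sample-factor sparsity)

where W̄ stacks the W(d) along the feature axis and L is the normalized
Laplacian of the block feature-interaction network.  The Laplacian term pulls
the factor rows of interacting features — within one omics layer or across
layers (e.g. a miRNA and its target mRNAs) — toward each other, injecting
prior regulatory structure into the latent space.

Optimization alternates
  * a multiplicative update of all W(d) (derived from the KKT conditions by
    splitting L = I − Ã into its diagonal part, which lands in the
    denominator, and the elementwise non-negative Ã part, which lands in the
    numerator — the standard graph-regularized-NMF construction, so the
    update preserves non-negativity and never increases f), and
  * an exact per-sample non-negative Lasso solve for each column of H by
    cyclic coordinate descent with soft-thresholding.

W(d) is initialized by NNDSVD; H by the non-negative Lasso solve with the
per-sample penalties γ_i chosen once by k-fold cross-validation over an L1
path and frozen for the remainder of the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import MultiOmicsDataset
from .network import BlockInteractionNetwork, laplacian_quadratic

__all__ = [
    "Hyperparameters",
    "FactorModel",
    "objective",
    "init_W",
    "init_H",
    "update_W",
    "update_H",
    "fit",
    "transform",
]

_EPS_DENOM = 1e-10  # multiplicative-update denominator guard
_DESCENT_SLACK = 1e-9  # absolute tolerance on objective monotonicity


@dataclass
class Hyperparameters:
    """Model hyperparameters.

    K        latent dimension; must satisfy K <= min(m_d, N) for every layer
             (NNDSVD feasibility).
    alpha    network regularization weight, >= 0.  0 disables the network
             term entirely (ablation mode; the Laplacian is never touched).
    beta     per-layer L1 weight on W(d); a scalar is broadcast to all layers.
    gamma    per-sample L1 weight on H columns.  None means "select by CV at
             initialization"; a scalar or vector fixes the values.
    tol      absolute objective-change convergence threshold; None means
             1e-5 x f_0 (proportional to the initial objective).
    """

    K: int
    alpha: float = 0.0
    beta: float | Sequence[float] = 0.0
    gamma: float | Sequence[float] | None = None
    max_iter: int = 2000
    tol: float | None = None
    seed: int = 0
    gamma_cv_folds: int = 3
    gamma_path_size: int = 10

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        if self.alpha < 0 or not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite and >= 0")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if self.tol is not None and self.tol <= 0:
            raise ValueError("tol must be > 0")

    def beta_per_layer(self, D: int) -> np.ndarray:
        b = np.broadcast_to(np.asarray(self.beta, dtype=float), (D,)).copy()
        if np.any(b < 0):
            raise ValueError("beta must be >= 0")
        return b

    def gamma_per_sample(self, N: int) -> np.ndarray | None:
        if self.gamma is None:
            return None
        g = np.broadcast_to(np.asarray(self.gamma, dtype=float), (N,)).copy()
        if np.any(g < 0):
            raise ValueError("gamma must be >= 0")
        return g


@dataclass
class FactorModel:
    """Fitted factors plus diagnostics."""

    W: list[np.ndarray]  # D matrices, m_d x K
    H: np.ndarray  # K x N
    layer_ids: list[str]
    feature_ids: list[list[str]]
    sample_ids: list[str]
    hp: Hyperparameters
    gamma: np.ndarray  # per-sample L1 weights actually used (frozen)
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def K(self) -> int:
        return self.H.shape[0]

    @property
    def Wbar(self) -> np.ndarray:
        """Stacked M x K view of the omic-specific factors."""
        return np.vstack(self.W)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def objective(
    dataset: MultiOmicsDataset,
    network: BlockInteractionNetwork | None,
    W: list[np.ndarray],
    H: np.ndarray,
    hp: Hyperparameters,
    gamma: np.ndarray | None = None,
) -> tuple[float, dict[str, float]]:
    """Evaluate f and its four-term breakdown.

    With alpha == 0 the network term is exactly 0 and ``network`` may be
    None — it is never accessed.
    """
    beta = hp.beta_per_layer(dataset.D)
    if gamma is None:
        gamma = hp.gamma_per_sample(dataset.n_samples)
        if gamma is None:
            gamma = np.zeros(dataset.n_samples)

    recon = 0.0
    for layer, Wd in zip(dataset.layers, W):
        resid = layer.values - Wd @ H
        recon += 0.5 * float((resid * resid).sum())

    if hp.alpha > 0:
        if network is None:
            raise ValueError("alpha > 0 requires an interaction network")
        net = 0.5 * hp.alpha * laplacian_quadratic(network, np.vstack(W))
    else:
        net = 0.0

    w_l1 = float(sum(b * np.abs(Wd).sum() for b, Wd in zip(beta, W)))
    h_l1 = float((gamma * np.abs(H).sum(axis=0)).sum())

    total = recon + net + w_l1 + h_l1
    terms = {
        "reconstruction": recon,
        "network": net,
        "w_sparsity": w_l1,
        "h_sparsity": h_l1,
    }
    if not np.isfinite(total):
        bad = {k: v for k, v in terms.items() if not np.isfinite(v)}
        raise FloatingPointError(f"non-finite objective; offending terms: {bad}")
    return total, terms


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _nndsvd(X: np.ndarray, K: int) -> np.ndarray:
    """Non-negative Double SVD initializer (left factor only).

    Splits each of the leading K singular triplets into its non-negative
    part, keeping whichever signed half carries more mass — the deterministic
    standard initializer for NMF.
    """
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    m = X.shape[0]
    W = np.zeros((m, K))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    for j in range(1, K):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_un = np.linalg.norm(up), np.linalg.norm(un)
        n_vp, n_vn = np.linalg.norm(vp), np.linalg.norm(vn)
        term_p, term_n = n_up * n_vp, n_un * n_vn
        if term_p >= term_n:
            if n_up > 0:
                W[:, j] = np.sqrt(S[j] * term_p) / n_up * up
        else:
            if n_un > 0:
                W[:, j] = np.sqrt(S[j] * term_n) / n_un * un
    return W


def init_W(dataset: MultiOmicsDataset, K: int, seed: int = 0) -> list[np.ndarray]:
    """NNDSVD initialization of each W(d); exact zeros nudged to a small
    positive epsilon so multiplicative updates are not absorbed at 0."""
    W = []
    for layer in dataset.layers:
        bound = min(layer.n_features, layer.n_samples)
        if K > bound:
            raise ValueError(
                f"K={K} exceeds min(m_d, N)={bound} for layer {layer.layer_id!r}"
            )
        Wd = _nndsvd(layer.values, K)
        eps = 1e-6 * layer.values.mean()
        if eps == 0:
            eps = 1e-6
        Wd[Wd == 0] = eps
        W.append(Wd)
    return W


# ---------------------------------------------------------------------------
# non-negative Lasso core (shared by init_H, update_H, transform)
# ---------------------------------------------------------------------------

def _nn_lasso_columns(
    G: np.ndarray,
    C: np.ndarray,
    gamma: np.ndarray,
    H0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 1000,
) -> np.ndarray:
    """Solve min_{h>=0} 1/2 hᵀGh − cᵀh + γ||h||₁ for every column jointly.

    G = W̄ᵀW̄ (K x K), C = W̄ᵀX̄ (K x N), γ per column.  Cyclic coordinate
    descent with non-negative soft-thresholding, vectorized across columns;
    this is the exact solution of each per-sample subproblem.  Coordinates
    whose design column has zero norm are skipped (coefficient 0).
    """
    K, N = C.shape
    H = np.zeros((K, N)) if H0 is None else H0.copy()
    diag = np.diag(G).copy()
    active = diag > 0
    for _ in range(max_sweeps):
        delta = 0.0
        GH = G @ H
        for k in range(K):
            if not active[k]:
                H[k] = 0.0
                continue
            num = C[k] - GH[k] + diag[k] * H[k] - gamma
            new = np.maximum(0.0, num) / diag[k]
            step = new - H[k]
            m = np.abs(step).max(initial=0.0)
            if m > 0:
                GH += np.outer(G[:, k], step)
                H[k] = new
                delta = max(delta, m)
        if delta < tol:
            break
    return H


def _gamma_path_cv(
    Wbar: np.ndarray,
    Xbar: np.ndarray,
    n_folds: int,
    path_size: int,
    seed: int,
) -> np.ndarray:
    """Per-sample L1 penalty selection by k-fold CV over a log-spaced path.

    Observations are the M stacked feature rows; for each candidate penalty
    (a fraction of the per-sample null threshold γ_max,i = max_k w̄_kᵀx̄_i)
    the non-negative Lasso is solved on the training rows and scored by
    validation squared error, vectorized over all samples at once.
    """
    M, N = Xbar.shape
    gmax = np.maximum((Wbar.T @ Xbar).max(axis=0), 0.0)  # per-sample null threshold
    mult = np.logspace(0, -3, path_size)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(M)
    folds = np.array_split(perm, n_folds)

    err = np.zeros((path_size, N))
    for f in range(n_folds):
        val = folds[f]
        train = np.concatenate([folds[g] for g in range(n_folds) if g != f])
        Wt, Wv = Wbar[train], Wbar[val]
        Xt, Xv = Xbar[train], Xbar[val]
        G = Wt.T @ Wt
        C = Wt.T @ Xt
        scale = len(train) / M  # keep the penalty per-observation consistent
        H = None
        for j, mj in enumerate(mult):  # warm-start down the path
            H = _nn_lasso_columns(G, C, mj * gmax * scale, H0=H)
            R = Xv - Wv @ H
            err[j] += (R * R).sum(axis=0)

    best = err.argmin(axis=0)  # ties -> strongest penalty (path is decreasing)
    gamma = mult[best] * gmax
    gamma[gmax <= 0] = 0.0
    return gamma


def init_H(
    dataset: MultiOmicsDataset,
    W: list[np.ndarray],
    gamma_mode: str | float | Sequence[float] = "cv",
    seed: int = 0,
    cv_folds: int = 3,
    path_size: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Initialize H given W by per-sample non-negative Lasso (returns H, γ).

    ``gamma_mode`` "cv" selects each γ_i by k-fold cross-validation over an
    L1 path; a scalar/vector fixes the penalties directly.  γ values are
    frozen for the remainder of the fit.
    """
    Wbar = np.vstack(W)
    Xbar = dataset.stacked()
    N = Xbar.shape[1]

    if isinstance(gamma_mode, str):
        if gamma_mode != "cv":
            raise ValueError(f"unknown gamma_mode {gamma_mode!r}")
        gamma = _gamma_path_cv(Wbar, Xbar, cv_folds, path_size, seed)
    else:
        gamma = np.broadcast_to(np.asarray(gamma_mode, dtype=float), (N,)).copy()

    dead = Xbar.max(axis=0) <= 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} all-zero sample columns: gamma set to 0, "
            "factor column set to 0",
            stacklevel=2,
        )
        gamma[dead] = 0.0

    G = Wbar.T @ Wbar
    C = Wbar.T @ Xbar
    H = _nn_lasso_columns(G, C, gamma)
    H[:, dead] = 0.0
    return H, gamma


# ---------------------------------------------------------------------------
# alternating updates
# ---------------------------------------------------------------------------

def update_W(
    dataset: MultiOmicsDataset,
    network: BlockInteractionNetwork | None,
    W: list[np.ndarray],
    H: np.ndarray,
    hp: Hyperparameters,
) -> list[np.ndarray]:
    """One multiplicative pass over all layers (H fixed):

        W(p) <- W(p) ⊙ [X(p)Hᵀ + α(ÃW̄)_p] ⊘ [W(p)HHᵀ + αW(p) + β_p + ε]

    Non-negativity is preserved because Ã >= 0 elementwise; the update is the
    stacked graph-regularized-NMF multiplicative rule and never increases f.
    """
    beta = hp.beta_per_layer(dataset.D)
    HHt = H @ H.T
    if hp.alpha > 0:
        if network is None:
            raise ValueError("alpha > 0 requires an interaction network")
        AtW = network.normalized @ np.vstack(W)
    out = []
    off = 0
    for layer, Wd, b in zip(dataset.layers, W, beta):
        numer = layer.values @ H.T
        denom = Wd @ HHt + b + _EPS_DENOM
        if hp.alpha > 0:
            numer = numer + hp.alpha * AtW[off : off + Wd.shape[0]]
            denom = denom + hp.alpha * Wd
        Wd_new = Wd * (numer / denom)
        if not np.all(np.isfinite(Wd_new)):
            raise FloatingPointError(
                f"non-finite entries in W update for layer {layer.layer_id!r}"
            )
        out.append(Wd_new)
        off += Wd.shape[0]
    return out


def update_H(
    dataset: MultiOmicsDataset,
    W: list[np.ndarray],
    H: np.ndarray,
    gamma: np.ndarray,
    inner_tol: float = 1e-6,
    max_sweeps: int = 1000,
) -> np.ndarray:
    """Exact non-negative Lasso solve of every H column with W̄ frozen."""
    Wbar = np.vstack(W)
    G = Wbar.T @ Wbar
    C = Wbar.T @ dataset.stacked()
    return _nn_lasso_columns(G, C, gamma, H0=H, tol=inner_tol, max_sweeps=max_sweeps)


def fit(
    dataset: MultiOmicsDataset,
    network: BlockInteractionNetwork | None,
    hp: Hyperparameters,
) -> FactorModel:
    """Full alternating fit: NNDSVD W init, Lasso-CV H init, then alternate
    multiplicative W updates and exact H solves until the absolute change in
    the objective drops below ``tol`` or ``max_iter`` is reached.

    Raises if the objective ever increases beyond the numerical slack — that
    is a solver-bug signal, not a data condition.
    """
    W = init_W(dataset, hp.K, seed=hp.seed)
    gamma_fixed = hp.gamma_per_sample(dataset.n_samples)
    H, gamma = init_H(
        dataset,
        W,
        gamma_mode="cv" if gamma_fixed is None else gamma_fixed,
        seed=hp.seed,
        cv_folds=hp.gamma_cv_folds,
        path_size=hp.gamma_path_size,
    )

    f0, _ = objective(dataset, network, W, H, hp, gamma=gamma)
    trace = [f0]
    tol = hp.tol if hp.tol is not None else 1e-5 * f0
    converged = False
    n_iter = 0
    for t in range(hp.max_iter):
        W = update_W(dataset, network, W, H, hp)
        H = update_H(dataset, W, H, gamma)
        f, _ = objective(dataset, network, W, H, hp, gamma=gamma)
        if not np.isfinite(f):
            raise FloatingPointError(f"non-finite objective at iteration {t + 1}")
        if f > trace[-1] + _DESCENT_SLACK:
            raise RuntimeError(
                f"objective increased at iteration {t + 1}: "
                f"{trace[-1]:.12g} -> {f:.12g}"
            )
        trace.append(f)
        n_iter = t + 1
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    return FactorModel(
        W=W,
        H=H,
        layer_ids=dataset.layer_ids,
        feature_ids=[list(l.feature_ids) for l in dataset.layers],
        sample_ids=list(dataset.sample_ids),
        hp=hp,
        gamma=gamma,
        objective_trace=trace,
        converged=converged,
        n_iter=n_iter,
    )


def transform(
    model: FactorModel,
    new_data: MultiOmicsDataset,
    gamma_mode: str | float | Sequence[float] = "cv",
    seed: int = 0,
) -> np.ndarray:
    """Project new samples into the latent space with W̄ frozen.

    Each test column solves the same per-sample non-negative Lasso problem as
    in training, with its penalty chosen by the same CV procedure (or fixed
    via ``gamma_mode``).  The feature space must match the fitted model.
    """
    if new_data.layer_ids != model.layer_ids:
        raise ValueError(
            f"layer mismatch: model {model.layer_ids}, data {new_data.layer_ids}"
        )
    for layer, fids in zip(new_data.layers, model.feature_ids):
        if list(layer.feature_ids) != fids:
            missing = sorted(set(fids) - set(layer.feature_ids))[:10]
            raise ValueError(
                f"feature mismatch in layer {layer.layer_id!r}; "
                f"missing (first 10): {missing}"
            )
    H_test, _ = init_H(
        new_data,
        model.W,
        gamma_mode=gamma_mode,
        seed=seed,
        cv_folds=model.hp.gamma_cv_folds,
        path_size=model.hp.gamma_path_size,
    )
    return H_test
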