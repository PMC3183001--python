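"""Unsupervised decompositions of reduced imaging MS datasets.

Six methods share one output contract: a :class:`ComponentSet` holding
*component images* (per-pixel scores, rendered on the grid downstream) and
*component spectra* (per-feature loadings).

========  ===========================================================
pca       orthogonal variance-maximizing factors (mean-centered)
nnmf      additive non-negative factors, multiplicative updates
maf       maximum autocorrelation factors: generalized eigenproblem on
          the covariance of one-pixel shift differences
kmeans    hard partition by squared Euclidean distance
fcm       fuzzy c-means soft partition (fuzziness m = 1.25)
plsa      probabilistic latent semantic analysis aspect model (EM)
========  ===========================================================

PCA, MAF, k-means and fuzzy c-means receive mean-centered data; NNMF and
PLSA require non-negative input and are run without centering.  PCA and MAF
scores are sign-indefinite; each such component is stored with the sign that
makes the skewness of its score image non-negative, a deterministic
canonical form (matching downstream may still flip per-template).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.stats import skew
from sklearn.cluster import KMeans, kmeans_plusplus
from sklearn.decomposition import PCA

from .msidata import ReducedDataset

SIGN_INDEFINITE = {"pca", "maf"}
DEFAULT_AGREEMENT_METHODS = ("pca", "nnmf", "maf", "fcm", "plsa")
ALL_METHODS = ("pca", "nnmf", "maf", "kmeans", "fcm", "plsa")


@dataclass
class FactorizeConfig:
    n_components: int = 8
    nnmf_iterations: int = 100
    nnmf_restarts: int = 3
    plsa_max_iterations: int = 500
    plsa_rel_tol: float = 1e-5
    fcm_fuzziness: float = 1.25
    fcm_max_iterations: int = 300
    fcm_tol: float = 1e-6
    kmeans_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.fcm_fuzziness <= 1:
            raise ValueError("fcm fuzziness m must be > 1")
        if self.plsa_rel_tol <= 0 or self.fcm_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class ComponentSet:
    method: str
    scores: np.ndarray     # (n_pixels, K) component images, unfolded
    loadings: np.ndarray   # (K, n_features) component spectra
    sign_definite: bool
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.scores.shape[1] != self.loadings.shape[0]:
            raise ValueError("scores / loadings component counts differ")

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def validate(self) -> None:
        """Check the per-method invariants of the output contract."""
        if not (np.all(np.isfinite(self.scores))
                and np.all(np.isfinite(self.loadings))):
            raise ValueError(f"{self.method}: non-finite output")
        if self.method in ("nnmf", "plsa", "fcm", "kmeans"):
            if np.any(self.scores < -1e-12):
                raise ValueError(f"{self.method}: negative scores")
        if self.method == "fcm":
            if np.max(np.abs(self.scores.sum(axis=1) - 1.0)) > 1e-9:
                raise ValueError("fcm memberships must sum to 1 per pixel")
        if self.method == "plsa":
            if np.max(np.abs(self.scores.sum(axis=0) - 1.0)) > 1e-9:
                raise ValueError("plsa p(pixel|z) must sum to 1 per topic")
            if np.max(np.abs(self.loadings.sum(axis=1) - 1.0)) > 1e-9:
                raise ValueError("plsa p(feature|z) must sum to 1 per topic")


def _orient_nonneg_skew(scores: np.ndarray, loadings: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Canonical sign for sign-indefinite components: non-negative skewness
    of the score image (localized structure sticks out positively)."""
    scores = scores.copy()
    loadings = loadings.copy()
    for j in range(scores.shape[1]):
        if skew(scores[:, j]) < 0:
            scores[:, j] *= -1
            loadings[j] *= -1
    return scores, loadings


def _centered(data: ReducedDataset) -> np.ndarray:
    return data.matrix - data.matrix.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def run_pca(data: ReducedDataset, config: FactorizeConfig) -> ComponentSet:
    """Principal component analysis of the mean-centered matrix.

    Components are ordered by descending explained variance; loadings are
    orthonormal.  If more components are requested than the matrix rank the
    set is truncated with a warning.
    """
    X = data.matrix
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0, keepdims=True)))
    k = config.n_components
    if k > rank:
        warnings.warn(f"pca: requested {k} components but rank is {rank}; "
                      "truncating", stacklevel=2)
        k = rank
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    scores, loadings = _orient_nonneg_skew(scores, model.components_)
    return ComponentSet(
        method="pca", scores=scores, loadings=loadings, sign_definite=False,
        diagnostics={"explained_variance": model.explained_variance_.tolist(),
                     "mean": model.mean_.tolist()})


# ---------------------------------------------------------------------------
# NNMF (Lee & Seung multiplicative updates)
# ---------------------------------------------------------------------------

def _nnmf_once(X: np.ndarray, k: int, iterations: int,
               rng: np.random.Generator,
               extend_tol: float = 1e-6, max_extra: int = 900
               ) -> tuple[np.ndarray, np.ndarray, list[float]]:
    n, f = X.shape
    eps = 1e-12
    scale = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
    W = rng.random((n, k)) * scale
    H = rng.random((k, f)) * scale
    objective: list[float] = []

    def obj() -> float:
        return float(np.linalg.norm(X - W @ H) ** 2)

    objective.append(obj())
    it = 0
    while True:
        H *= (W.T @ X) / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ (H @ H.T) + eps)
        objective.append(obj())
        it += 1
        if it >= iterations:
            rel = abs(objective[-2] - objective[-1]) / max(objective[-2], eps)
            # extend past the nominal iteration budget until converged
            if rel < extend_tol or it >= iterations + max_extra:
                break
    return W, H, objective


def run_nnmf(data: ReducedDataset, config: FactorizeConfig) -> ComponentSet:
    """Non-negative matrix factorization minimizing squared Frobenius error.

    Multiplicative updates (which never increase the objective) from
    non-negative random starts; the best of ``nnmf_restarts`` runs is kept.
    Runs for ``nnmf_iterations`` and is extended until the relative objective
    change drops below 1e-6 if not yet converged.
    """
    X = data.matrix
    if np.any(X < 0):
        raise ValueError("nnmf requires non-negative input")
    k = min(config.n_components, min(X.shape))
    best = None
    for r in range(config.nnmf_restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed % 2**31, 11, r]))
        W, H, objective = _nnmf_once(X, k, config.nnmf_iterations, rng)
        if best is None or objective[-1] < best[2][-1]:
            best = (W, H, objective)
    W, H, objective = best

    # scale-invariance: unit-max loading rows, energy-ordered components
    hmax = np.maximum(H.max(axis=1), 1e-300)
    W = W * hmax
    H = H / hmax[:, None]
    energy = (W ** 2).sum(axis=0)
    order = np.argsort(energy)[::-1]
    return ComponentSet(method="nnmf", scores=W[:, order], loadings=H[order],
                        sign_definite=True,
                        diagnostics={"objective": objective})


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def shift_pairs(data: ReducedDataset) -> np.ndarray:
    """Index pairs of horizontally / vertically adjacent pixels.

    Pairs spanning a merge gutter or different source datasets are excluded,
    so shift differences never mix tissues.
    """
    index = {tuple(p): i for i, p in enumerate(data.pixels)}
    source = [prov.source_id for prov in data.provenance]
    pairs = []
    for (x, y), i in index.items():
        for dx, dy in ((1, 0), (0, 1)):
            j = index.get((x + dx, y + dy))
            if j is not None and source[i] == source[j]:
                pairs.append((i, j))
    return np.array(pairs, dtype=int)


def run_maf(data: ReducedDataset, config: FactorizeConfig) -> ComponentSet:
    """Maximum autocorrelation factorization.

    Let D be the pooled one-pixel horizontal+vertical difference vectors of
    the mean-centered data X.  MAF solves the generalized eigenproblem
    cov(D) w = lambda cov(X) w and orders components by ascending lambda,
    i.e. descending spatial autocorrelation 1 - lambda/2: the first factor
    is the linear combination of features that varies most smoothly over the
    tissue.
    """
    Xc = _centered(data)
    pairs = shift_pairs(data)
    if len(pairs) == 0:
        raise ValueError("maf: no adjacent pixel pairs available")
    D = Xc[pairs[:, 0]] - Xc[pairs[:, 1]]
    S_delta = (D.T @ D) / len(D)
    S = (Xc.T @ Xc) / len(Xc)

    F = S.shape[0]
    try:
        np.linalg.cholesky(S + 0.0)
    except np.linalg.LinAlgError:
        ridge = 1e-9 * np.trace(S) / F
        warnings.warn(f"maf: singular covariance; ridge-regularizing with "
                      f"epsilon {ridge:.3e}", stacklevel=2)
        S = S + ridge * np.eye(F)
    lam, W = scipy.linalg.eigh(S_delta, S)
    k = min(config.n_components, F)
    W = W[:, :k]           # ascending lambda = descending autocorrelation
    scores = Xc @ W
    scores, loadings = _orient_nonneg_skew(scores, W.T)
    return ComponentSet(method="maf", scores=scores, loadings=loadings,
                        sign_definite=False,
                        diagnostics={
                            "eigenvalues": lam[:k].tolist(),
                            "autocorrelation": (1 - lam[:k] / 2).tolist(),
                            "n_pairs": int(len(pairs))})


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

def run_kmeans(data: ReducedDataset, config: FactorizeConfig,
               n_classes: int | None = None) -> ComponentSet:
    """Hard k-means partition of the mean-centered spectra.

    Scores are one-hot class indicators; loadings are class centroid spectra
    (on the original, uncentered scale).  Classes are ordered by size.
    """
    n_classes = n_classes or config.n_components
    if n_classes > data.n_pixels:
        raise ValueError("more classes than pixels")
    Xc = _centered(data)
    model = KMeans(n_clusters=n_classes, init="k-means++",
                   n_init=config.kmeans_restarts,
                   random_state=config.seed % 2**31)
    labels = model.fit_predict(Xc)
    sizes = np.bincount(labels, minlength=n_classes)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(n_classes, dtype=int)
    relabel[order] = np.arange(n_classes)
    labels = relabel[labels]
    scores = np.eye(n_classes)[labels]
    loadings = np.array([
        data.matrix[labels == c].mean(axis=0) if np.any(labels == c)
        else np.zeros(data.n_features)
        for c in range(n_classes)])
    return ComponentSet(method="kmeans", scores=scores, loadings=loadings,
                        sign_definite=True,
                        diagnostics={"inertia": float(model.inertia_),
                                     "sizes": sizes[order].tolist()})


# ---------------------------------------------------------------------------
# fuzzy c-means
# ---------------------------------------------------------------------------

def run_fcm(data: ReducedDataset, config: FactorizeConfig,
            n_classes: int | None = None) -> ComponentSet:
    """Fuzzy c-means with fuzziness exponent m (default 1.25).

    Alternating updates of memberships u and centroids c:
        u_ic  proportional to  d(x_i, c)^(-2/(m-1))
        c     = sum_i u_ic^m x_i / sum_i u_ic^m
    until the largest membership change is below ``fcm_tol`` or the iteration
    cap is reached.  Scores are the membership maps (rows sum to 1); loadings
    are the fuzzy centroids on the original scale.
    """
    n_classes = n_classes or config.n_components
    if n_classes > data.n_pixels:
        raise ValueError("more classes than pixels")
    Xc = _centered(data)
    m = config.fcm_fuzziness
    power = 2.0 / (m - 1.0)

    for attempt in range(2):
        seed = (config.seed + 1013904223 * attempt) % 2**31
        centers, _ = kmeans_plusplus(Xc, n_clusters=n_classes,
                                     random_state=seed)
        if attempt == 1:
            # nudge a re-seed away from exact duplicates
            rng = np.random.default_rng(seed)
            centers = centers + 1e-8 * rng.standard_normal(centers.shape)
        dup = any(np.allclose(centers[a], centers[b])
                  for a in range(n_classes) for b in range(a + 1, n_classes))
        if not dup:
            break
    else:
        raise ValueError("fcm: coincident duplicate centroids after re-seed")

    U = np.full((len(Xc), n_classes), 1.0 / n_classes)
    trace = []
    for _ in range(config.fcm_max_iterations):
        d2 = ((Xc[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        has_zero = zero.any(axis=1)
        # u_ic proportional to d2^(-power/2); computed as a row-wise softmax
        # of -(power/2) log d2 for overflow safety
        with np.errstate(divide="ignore"):
            logu = -(power / 2.0) * np.log(np.maximum(d2, 1e-300))
        logu -= logu.max(axis=1, keepdims=True)
        U_new = np.exp(logu)
        U_new /= U_new.sum(axis=1, keepdims=True)
        # a pixel sitting exactly on a centroid belongs to it entirely
        if has_zero.any():
            U_new[has_zero] = zero[has_zero] / zero[has_zero].sum(
                axis=1, keepdims=True)
        Um = U_new ** m
        centers = (Um.T @ Xc) / np.maximum(Um.sum(axis=0)[:, None], 1e-300)
        delta = float(np.max(np.abs(U_new - U)))
        trace.append(delta)
        U = U_new
        if delta < config.fcm_tol:
            break

    order = np.argsort(-U.sum(axis=0), kind="stable")
    U = U[:, order]
    Um = U ** m
    loadings = (Um.T @ data.matrix) / np.maximum(
        Um.sum(axis=0)[:, None], 1e-300)
    return ComponentSet(method="fcm", scores=U, loadings=loadings,
                        sign_definite=True,
                        diagnostics={"membership_delta": trace})


# ---------------------------------------------------------------------------
# PLSA
# ---------------------------------------------------------------------------

def run_plsa(data: ReducedDataset, config: FactorizeConfig) -> ComponentSet:
    """EM for the aspect model p(d, w) = sum_z p(z) p(d|z) p(w|z).

    Pixels play the role of documents d, features of words w, with the
    intensity matrix as (fractional) counts.  EM stops when the relative
    log-likelihood change falls below ``plsa_rel_tol`` or after
    ``plsa_max_iterations``.  Scores are p(d|z) (columns sum to 1), loadings
    p(w|z) (rows sum to 1); topics are ordered by descending p(z).
    """
    X = data.matrix
    if np.any(X < 0):
        raise ValueError("plsa requires non-negative input")
    total = X.sum()
    if total <= 0:
        raise ValueError("plsa: all-zero matrix")
    n, f = X.shape
    k = min(config.n_components, min(n, f))
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed % 2**31, 17]))
    eps = 1e-300

    Pz = np.full(k, 1.0 / k)
    Pd_z = rng.random((n, k)) + 0.1
    Pd_z /= Pd_z.sum(axis=0, keepdims=True)
    Pw_z = rng.random((k, f)) + 0.1
    Pw_z /= Pw_z.sum(axis=1, keepdims=True)

    loglik: list[float] = []
    for _ in range(config.plsa_max_iterations):
        joint = np.einsum("z,dz,zw->dw", Pz, Pd_z, Pw_z)  # p(d, w)
        ll = float(np.sum(X * np.log(joint + eps)))
        loglik.append(ll)
        nz = np.zeros(k)
        new_Pd = np.zeros_like(Pd_z)
        new_Pw = np.zeros_like(Pw_z)
        ratio = X / (joint + eps)
        for z in range(k):
            # T = n(d,w) p(z|d,w), accumulated without the full 3-d tensor
            T = ratio * (Pz[z] * np.outer(Pd_z[:, z], Pw_z[z]))
            nz[z] = T.sum()
            new_Pd[:, z] = T.sum(axis=1)
            new_Pw[z] = T.sum(axis=0)
        Pz = nz / total
        Pd_z = new_Pd / np.maximum(new_Pd.sum(axis=0, keepdims=True), eps)
        Pw_z = new_Pw / np.maximum(new_Pw.sum(axis=1, keepdims=True), eps)
        if len(loglik) >= 2:
            rel = abs(loglik[-1] - loglik[-2]) / max(abs(loglik[-2]), eps)
            if rel < config.plsa_rel_tol:
                break

    order = np.argsort(-Pz, kind="stable")
    return ComponentSet(method="plsa", scores=Pd_z[:, order],
                        loadings=Pw_z[order], sign_definite=True,
                        diagnostics={"log_likelihood": loglik,
                                     "p_z": Pz[order].tolist()})


# ---------------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------------

_RUNNERS = {
    "pca": run_pca,
    "nnmf": run_nnmf,
    "maf": run_maf,
    "kmeans": run_kmeans,
    "fcm": run_fcm,
    "plsa": run_plsa,
}


def run_method(method: str, data: ReducedDataset,
               config: FactorizeConfig) -> ComponentSet:
    if method not in _RUNNERS:
        raise ValueError(f"unknown method '{method}' "
                         f"(choose from {sorted(_RUNNERS)})")
    result = _RUNNERS[method](data, config)
    result.validate()
    return result


def run_methods(methods, data: ReducedDataset,
                config: FactorizeConfig) -> dict[str, ComponentSet]:
    return {m: run_method(m, data, config) for m in methods}
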