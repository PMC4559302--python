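"""Gaussian finite-mixture models fit by EM, scored and selected by BIC.

The model is the classical finite mixture f(y) = Σ_k π_k φ(y; μ_k, Σ_k) with
Gaussian components. Fitting alternates an E-step (posterior membership
probabilities, the "responsibilities" p̂_nk) and an M-step
(responsibility-weighted maximum-likelihood updates of π, μ, Σ under a
constrained covariance family), until the relative log-likelihood improvement
falls below tolerance. Model choice — the number of clusters K and the
covariance family — maximizes BIC = 2ℓ̂ − p log N, where p is the number of
free parameters; on this orientation larger BIC is better.

Six covariance families are supported (mclust-style nesting): spherical or
diagonal or full, each either shared across components ("equal") or
per-component ("varying").

The public surface follows the Model/Results convention:

>>> model = GaussianMixture(data, k=3, covariance_type="full-varying")
>>> res = model.fit(seed=0)
>>> res.bic, res.predict(data)

plus functional building blocks (`e_step`, `m_step`, `log_likelihood`,
`fit_em`, `bic`, `select_model`) for users who want the raw algorithm steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2

from . import _emcore
from .data import (
    DegenerateComponentError,
    FeatureMatrix,
    FitFailureError,
    as_feature_matrix,
)

#: Supported covariance families, ordered simplest to most complex. This
#: order is also the tie-break order in model selection.
COVARIANCE_TYPES = (
    "spherical-equal",
    "spherical-varying",
    "diagonal-equal",
    "diagonal-varying",
    "full-equal",
    "full-varying",
)

_COV_PARAM_COUNT = {
    "spherical-equal": lambda k, d: 1,
    "spherical-varying": lambda k, d: k,
    "diagonal-equal": lambda k, d: d,
    "diagonal-varying": lambda k, d: k * d,
    "full-equal": lambda k, d: d * (d + 1) // 2,
    "full-varying": lambda k, d: k * d * (d + 1) // 2,
}


def n_parameters(k: int, d: int, covariance_type: str) -> int:
    """Free-parameter count: (k−1) weights + k·d means + covariance terms."""
    if covariance_type not in _COV_PARAM_COUNT:
        raise ValueError(f"unknown covariance type: {covariance_type!r}")
    return (k - 1) + k * d + _COV_PARAM_COUNT[covariance_type](k, d)


def bic(loglik: float, n_params: int, n_obs: int) -> float:
    """BIC = 2ℓ̂ − p·log N; larger is better on this orientation."""
    return 2.0 * loglik - n_params * np.log(n_obs)


def _component_log_pdf(X: np.ndarray, means: np.ndarray, covs: np.ndarray):
    """Log N(x; μ_k, Σ_k) for all n, k at once. Returns (N, K)."""
    k, d = means.shape
    try:
        L = np.linalg.cholesky(covs)  # (k, d, d)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"non-positive-definite covariance in component log-density: {exc}"
        )
    diff = X[None, :, :] - means[:, None, :]          # (k, n, d)
    z = np.linalg.solve(L, np.swapaxes(diff, 1, 2))   # (k, d, n)
    maha = np.einsum("kdn,kdn->kn", z, z)
    logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
    logpdf = -0.5 * (d * np.log(2 * np.pi) + logdet[:, None] + maha)
    return logpdf.T


@dataclass
class GaussianMixtureResults:
    """A fitted Gaussian mixture: parameter estimates, fit diagnostics, BIC.

    Covariances are always materialized as full (k, d, d) matrices regardless
    of the fitted family; `n_params` counts the family's free parameters.
    Labels and responsibilities for new data come from :meth:`predict` /
    :meth:`responsibilities`; cluster labels are 1-based.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    covariance_type: str
    loglik: float
    n_params: int
    n_obs: int
    bic: float
    converged: bool
    n_iter: int
    loglik_history: np.ndarray = field(repr=False, default=None)
    floored: bool = False
    variable_names: list[str] | None = None

    def __post_init__(self):
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("mixture weights must be nonnegative")

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def responsibilities(self, data) -> np.ndarray:
        """Posterior membership probabilities P(k | y_n), one row per unit."""
        return e_step(data, self)

    def predict(self, data) -> np.ndarray:
        """Hard assignments: argmax posterior, 1-based, lowest index on ties."""
        return np.argmax(self.responsibilities(data), axis=1) + 1

    def summary(self) -> str:
        lines = [
            "Gaussian mixture fit",
            "=" * 60,
            f"components (K):     {self.k}",
            f"covariance family:  {self.covariance_type}",
            f"observations:       {self.n_obs}",
            f"free parameters:    {self.n_params}",
            f"log-likelihood:     {self.loglik:.4f}",
            f"BIC (2l - p logN):  {self.bic:.4f}",
            f"converged:          {self.converged} ({self.n_iter} iterations)",
        ]
        names = self.variable_names or [f"x{j}" for j in range(self.d)]
        head = "cluster   weight  " + "  ".join(f"{n:>12s}" for n in names)
        lines += ["", "Component means", head]
        for j in range(self.k):
            row = "  ".join(f"{m:12.4f}" for m in self.means[j])
            lines.append(f"{j + 1:7d}  {self.weights[j]:7.4f}  {row}")
        return "\n".join(lines)


def e_step(data, model: GaussianMixtureResults) -> np.ndarray:
    """Posterior responsibilities p̂_nk ∝ π_k φ(y_n; μ_k, Σ_k).

    Computed in log space and normalized per row; rows sum to 1.
    """
    fm = as_feature_matrix(data)
    if fm.n_vars != model.means.shape[1]:
        raise ValueError(
            f"data has {fm.n_vars} variables but model expects {model.means.shape[1]}"
        )
    resp, _ = _e_step_arrays(fm.values, model.weights, model.means, model.covariances)
    return resp


def _e_step_arrays(X, weights, means, covs):
    """Responsibilities and total log-likelihood in one pass.

    The row normalization is an inlined log-sum-exp (max-subtract), which is
    both the stability trick and markedly faster than the generic routine on
    these small row widths.
    """
    with np.errstate(divide="ignore"):  # zero weights are legal
        logw = np.log(weights)
    logdens = logw[None, :] + _component_log_pdf(X, means, covs)
    top = logdens.max(axis=1)
    resp = np.exp(logdens - top[:, None])
    tot = resp.sum(axis=1)
    norm = top + np.log(tot)
    if not np.all(np.isfinite(norm)):
        raise FloatingPointError("non-finite mixture density in E-step")
    resp /= tot[:, None]
    return resp, float(norm.sum())


def m_step(data, resp: np.ndarray, covariance_type: str = "full-varying",
           var_floor: float = 0.0):
    """Responsibility-weighted ML updates of (weights, means, covariances).

    Maximizes Σ_n p̂_nk log f(y_n | θ_k) per component under the covariance
    family constraint. `var_floor` is an absolute eigenvalue/variance floor
    applied to the covariance estimates; hitting it is reported via the
    returned `floored` flag.

    Returns
    -------
    (weights, means, covariances, floored)
    """
    fm = as_feature_matrix(data)
    X = fm.values
    resp = np.asarray(resp, dtype=float)
    n = X.shape[0]
    if resp.shape[0] != n:
        raise ValueError("responsibility rows must match data rows")
    if np.any(np.abs(resp.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("responsibility rows must sum to 1")
    if n <= resp.shape[1]:
        raise ValueError("need more observations than components")
    return _m_step_arrays(X, resp, covariance_type, var_floor)


def _m_step_arrays(X, resp, covariance_type, var_floor):
    """M-step on bare arrays, without per-call validation (hot path)."""
    n, d = X.shape
    k = resp.shape[1]
    nk = resp.sum(axis=0)
    if nk.min() < 1e-8:
        dead = int(np.argmin(nk))
        raise DegenerateComponentError(
            f"component {dead + 1} has vanishing responsibility mass ({nk.min():.3g})"
        )
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    diff = X[None, :, :] - means[:, None, :]  # (k, n, d)

    floored = False
    if covariance_type.startswith("full"):
        W = np.einsum("nk,knd,kne->kde", resp, diff, diff)
        if covariance_type == "full-equal":
            S = W.sum(axis=0) / n
            covs = np.broadcast_to(S, (k, d, d)).copy()
        else:
            covs = W / nk[:, None, None]
        covs = (covs + np.swapaxes(covs, 1, 2)) / 2.0
        if var_floor > 0:
            vals = np.linalg.eigvalsh(covs)
            if vals.min() < var_floor:
                floored = True
                vals, vecs = np.linalg.eigh(covs)
                vals = np.maximum(vals, var_floor)
                covs = np.einsum("kij,kj,klj->kil", vecs, vals, vecs)
                covs = (covs + np.swapaxes(covs, 1, 2)) / 2.0
        elif np.linalg.eigvalsh(covs).min() <= 0:
            raise DegenerateComponentError("singular covariance estimate")
    else:
        dW = np.einsum("nk,knd->kd", resp, diff ** 2)
        if covariance_type == "diagonal-varying":
            var = dW / nk[:, None]
        elif covariance_type == "diagonal-equal":
            var = np.broadcast_to(dW.sum(axis=0) / n, (k, d)).copy()
        elif covariance_type == "spherical-varying":
            var = np.broadcast_to((dW.sum(axis=1) / (nk * d))[:, None], (k, d)).copy()
        elif covariance_type == "spherical-equal":
            var = np.full((k, d), dW.sum() / (n * d))
        else:
            raise ValueError(f"unknown covariance type: {covariance_type!r}")
        if var_floor > 0:
            if var.min() < var_floor:
                floored = True
                var = np.maximum(var, var_floor)
        elif var.min() <= 0:
            raise DegenerateComponentError("singular covariance estimate")
        covs = np.zeros((k, d, d))
        covs[:, np.arange(d), np.arange(d)] = var
    return weights, means, covs, floored


def log_likelihood(data, model: GaussianMixtureResults) -> float:
    """Observed-data log-likelihood Σ_n log Σ_k π_k φ(y_n; μ_k, Σ_k)."""
    fm = as_feature_matrix(data)
    if fm.n_vars != model.means.shape[1]:
        raise ValueError("data/model dimension mismatch")
    _, ll = _e_step_arrays(fm.values, model.weights, model.means, model.covariances)
    return ll


def _initial_responsibilities(X, k, method, rng):
    n = X.shape[0]
    if method == "kmeans":
        seed = int(rng.integers(0, 2 ** 31 - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # kmeans2 warns on empty clusters
            _, labels = kmeans2(X, k, minit="++", seed=seed)
        if len(np.unique(labels)) < k:
            return _initial_responsibilities(X, k, "random", rng)
        resp = np.zeros((n, k))
        resp[np.arange(n), labels] = 1.0
        return resp
    # random: soft memberships from uniform draws (every component gets mass)
    resp = rng.uniform(0.1, 1.0, size=(n, k))
    return resp / resp.sum(axis=1, keepdims=True)


_COV_KIND = {
    "spherical-equal": (_emcore.SPHERICAL, True),
    "spherical-varying": (_emcore.SPHERICAL, False),
    "diagonal-equal": (_emcore.DIAGONAL, True),
    "diagonal-varying": (_emcore.DIAGONAL, False),
    "full-equal": (_emcore.FULL, True),
    "full-varying": (_emcore.FULL, False),
}


def _em_loop(X, resp0, covariance_type, tol, max_iter, var_floor):
    if _emcore.HAVE_NUMBA:
        kind, equal = _COV_KIND[covariance_type]
        status, weights, means, covs, ll_hist, converged, n_iter, floored = \
            _emcore._em_core(np.ascontiguousarray(X),
                             np.ascontiguousarray(resp0), kind, equal,
                             tol, max_iter, var_floor)
        if status == 1:
            raise DegenerateComponentError(
                "component with vanishing responsibility mass")
        if status == 2:
            raise DegenerateComponentError(
                "singular covariance / non-finite density during EM")
        return (weights, means, covs, ll_hist[-1], ll_hist, converged,
                n_iter, floored)
    return _em_loop_numpy(X, resp0, covariance_type, tol, max_iter, var_floor)


def _em_loop_numpy(X, resp0, covariance_type, tol, max_iter, var_floor):
    weights, means, covs, floored = _m_step_arrays(
        X, resp0, covariance_type, var_floor)
    ll_hist = []
    prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        resp, ll = _e_step_arrays(X, weights, means, covs)
        ll_hist.append(ll)
        if ll - prev < tol * max(1.0, abs(ll)):
            converged = True
            break
        prev = ll
        # `floored` reports the final parameters, not transient iterations
        weights, means, covs, floored = _m_step_arrays(
            X, resp, covariance_type, var_floor)
    return weights, means, covs, ll_hist[-1], np.array(ll_hist), converged, it, floored


def fit_em(data, k: int, covariance_type: str = "full-varying",
           init: str = "kmeans", n_starts: int = 2, tol: float = 1e-8,
           max_iter: int = 500, seed=None, var_floor_frac: float = 1e-6,
           warn_unstandardized: bool = True) -> GaussianMixtureResults:
    """Fit a K-component Gaussian mixture by EM with multiple restarts.

    Parameters
    ----------
    data : FeatureMatrix, DataFrame or ndarray
        Observations. A warning is issued when the FeatureMatrix is not
        flagged standardized, since BIC comparisons across variables assume a
        common scale.
    k : int
        Number of components (K ≥ 1).
    covariance_type : str
        One of :data:`COVARIANCE_TYPES`.
    init : {"kmeans", "random"}
        First start; remaining `n_starts − 1` restarts use random soft
        responsibilities. The best converged log-likelihood wins.
    tol : float
        Relative log-likelihood improvement threshold for convergence.
    var_floor_frac : float
        Covariance eigenvalue floor as a fraction of the mean data variance;
        fits that hit the floor are flagged `floored`.
    """
    fm = as_feature_matrix(data)
    if warn_unstandardized and isinstance(data, FeatureMatrix) \
            and not fm.standardized:
        warnings.warn("fitting on non-standardized data", stacklevel=2)
    X = fm.values
    n, d = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k:
        raise ValueError("need more observations than components")
    if covariance_type not in COVARIANCE_TYPES:
        raise ValueError(f"unknown covariance type: {covariance_type!r}")
    rng = np.random.default_rng(seed)
    var_floor = var_floor_frac * float(X.var(axis=0).mean())

    methods = [init] + ["random"] * (n_starts - 1)
    best = None
    failures = []
    for m in methods:
        resp0 = _initial_responsibilities(X, k, m, rng)
        try:
            out = _em_loop(X, resp0, covariance_type, tol, max_iter, var_floor)
        except (DegenerateComponentError, FloatingPointError,
                np.linalg.LinAlgError) as exc:
            failures.append(f"{m} start: {exc}")
            continue
        if best is None or out[3] > best[3]:
            best = out
    if best is None:
        raise FitFailureError(
            f"all {len(methods)} EM initializations failed for K={k}, "
            f"{covariance_type}", diagnostics=failures)

    weights, means, covs, ll, ll_hist, converged, n_iter, floored = best
    p = n_parameters(k, d, covariance_type)
    return GaussianMixtureResults(
        k=k, weights=weights, means=means, covariances=covs,
        covariance_type=covariance_type, loglik=ll, n_params=p, n_obs=n,
        bic=bic(ll, p, n), converged=converged, n_iter=n_iter,
        loglik_history=ll_hist, floored=floored,
        variable_names=fm.variable_names,
    )


class GaussianMixture:
    """Model object for a K-component Gaussian mixture on a feature matrix.

    Thin statsmodels-style wrapper: construction binds the data and model
    structure, :meth:`fit` runs EM and returns a
    :class:`GaussianMixtureResults`.
    """

    def __init__(self, data, k: int, covariance_type: str = "full-varying"):
        self.data = as_feature_matrix(data)
        self.k = int(k)
        self.covariance_type = covariance_type

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, variables: list[str], k: int,
                       covariance_type: str = "full-varying",
                       standardize_data: bool = True) -> "GaussianMixture":
        from .indices import standardize
        fm = standardize(df, variables) if standardize_data else FeatureMatrix(
            df[variables].to_numpy(float), list(variables))
        return cls(fm, k, covariance_type)

    def fit(self, **kwargs) -> GaussianMixtureResults:
        return fit_em(self.data, self.k, self.covariance_type, **kwargs)


@dataclass
class ClusteringSolution:
    """The BIC-selected mixture plus responsibilities, labels, and the grid.

    `bic_table` is a (K × covariance-family) DataFrame of BIC values for every
    candidate evaluated (NaN where the fit failed); the selected model's cell
    is the maximum over the retained (non-degenerate) entries.
    """

    model: GaussianMixtureResults
    responsibilities: np.ndarray
    labels: np.ndarray
    bic_table: pd.DataFrame

    @property
    def k(self) -> int:
        return self.model.k

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def summary(self) -> str:
        sizes = ", ".join(str(s) for s in self.cluster_sizes())
        lines = [
            self.model.summary(),
            "",
            f"cluster sizes:      {sizes}",
            "",
            "BIC table (larger is better; NaN = failed fit)",
            self.bic_table.round(2).to_string(),
        ]
        return "\n".join(lines)


def select_model(data, k_range=range(1, 10),
                 covariance_types=COVARIANCE_TYPES, init: str = "kmeans",
                 n_starts: int = 2, tol: float = 1e-8, max_iter: int = 500,
                 seed=None, exclude_floored: bool = True) -> ClusteringSolution:
    """Fit every (K, covariance family) cell and keep the best-BIC model.

    Ties break toward smaller K, then the simpler family (the order of
    :data:`COVARIANCE_TYPES`). Fits that hit the covariance floor are
    excluded from selection by default (their BIC still appears in the table);
    if every cell is floored or failed, a FitFailureError carries the per-cell
    diagnostics.
    """
    fm = as_feature_matrix(data)
    if isinstance(data, FeatureMatrix) and not fm.standardized:
        warnings.warn("model selection on non-standardized data", stacklevel=2)
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("k_range must be nonempty")
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    # in one dimension the families collapse pairwise to {equal, varying}:
    # fit each distinct model once and mirror its score across synonyms
    synonyms: dict[str, str] = {}
    fit_types = list(covariance_types)
    if fm.n_vars == 1:
        canon = {"equal": None, "varying": None}
        fit_types = []
        for cov in covariance_types:
            kind = cov.split("-")[1]
            if canon[kind] is None:
                canon[kind] = cov
                fit_types.append(cov)
            else:
                synonyms[cov] = canon[kind]
    children = ss.spawn(len(k_range) * len(fit_types))

    fits: dict[tuple[int, str], GaussianMixtureResults] = {}
    diagnostics = {}
    table = pd.DataFrame(np.nan, index=k_range, columns=list(covariance_types))
    table.index.name = "K"
    idx = 0
    for k in k_range:
        for cov in fit_types:
            child_seed = children[idx]
            idx += 1
            try:
                res = fit_em(fm, k, cov, init=init, n_starts=n_starts, tol=tol,
                             max_iter=max_iter, seed=child_seed,
                             warn_unstandardized=False)
            except (FitFailureError, ValueError) as exc:
                diagnostics[(k, cov)] = str(exc)
                continue
            table.loc[k, cov] = res.bic
            if exclude_floored and res.floored:
                diagnostics[(k, cov)] = "covariance floor reached (degenerate)"
                continue
            fits[(k, cov)] = res
    for cov, canon_cov in synonyms.items():
        table[cov] = table[canon_cov]
    if not fits:
        raise FitFailureError("every (K, covariance) cell failed or was degenerate",
                              diagnostics=diagnostics)

    best_key = None
    for k in k_range:  # ordered: smaller K, then simpler family, wins ties
        for cov in covariance_types:
            if (k, cov) not in fits:
                continue
            if best_key is None or fits[(k, cov)].bic > fits[best_key].bic:
                best_key = (k, cov)
    best = fits[best_key]
    resp = e_step(fm, best)
    labels = np.argmax(resp, axis=1) + 1
    return ClusteringSolution(model=best, responsibilities=resp, labels=labels,
                              bic_table=table)
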