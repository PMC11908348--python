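"""Latent unknown clustering with integrated data (LUCID), unsupervised,
fitted in parallel across omics layers.

Model (one layer). Each subject i carries an exposure design row
``E_i`` (intercept + log2 exposure by default) and a standardized omics
vector ``Z_i`` (length P). A latent cluster ``X_i`` in {0..K-1} follows a
multinomial-logistic prior with reference cluster 0,

    P(X_i = k | E_i) = softmax_k(beta_k . E_i),     beta_0 = 0,

and the omics vector is Gaussian given the cluster,

    Z_i | X_i = k  ~  N(mu_k, Sigma),

with Sigma diagonal, shared across clusters by default (optionally
cluster-specific diagonal). The observed-data log-likelihood

    sum_i log sum_k P(X_i=k|E_i; beta) N(Z_i; mu_k, Sigma)

is maximized by EM: the E-step computes responsibilities (the per-subject
inclusion probabilities, IPs), the M-step updates mu and Sigma in closed
form and beta by Newton steps on the responsibility-weighted multinomial
logistic objective. Multiple restarts guard against local optima; the
model with the best final log-likelihood wins.

"In parallel" integration: one latent cluster variable per layer, no
cross-layer correlation, so the joint likelihood factorizes and the
multi-layer fit equals independent per-layer fits; :class:`LucidParallel`
enforces the shared exposure design and subject alignment.

Cluster labels are arbitrary up to permutation; :func:`align_clusters`
fixes a convention (ascending exposure-implied cluster propensity by
default) so that reported betas and profiles are comparable across runs.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "LucidLayer",
    "LucidParallel",
    "fit_lucid_layer",
    "fit_lucid_parallel",
    "select_k_bic",
    "align_clusters",
]

_EMPTY_CLUSTER_MASS = 1e-6


def _as_design(E) -> np.ndarray:
    """Exposure design with a leading intercept column."""
    E = np.asarray(E, float)
    if E.ndim == 1:
        E = E[:, None]
    if not np.allclose(E[:, 0], 1.0):
        E = np.column_stack([np.ones(len(E)), E])
    return E


def _weighted_multinomial_newton(
    X: np.ndarray,
    R: np.ndarray,
    beta0: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> np.ndarray:
    """Maximize sum_ik R_ik log softmax_k(beta_k . X_i) over beta (ref 0).

    Damped Newton with step halving; warm start from ``beta0``. X is
    (n, d) including the intercept, R is (n, K) with rows summing to 1,
    beta is (K-1, d).
    """
    n, d = X.shape
    K = R.shape[1]
    beta = beta0.copy()

    def objective(b: np.ndarray) -> tuple[float, np.ndarray]:
        logits = np.hstack([np.zeros((n, 1)), X @ b.T])
        lse = logsumexp(logits, axis=1)
        logp = logits - lse[:, None]
        q = float(np.sum(R * logp))
        return q, np.exp(logp)

    q, p = objective(beta)
    for _ in range(max_iter):
        grad = np.empty((K - 1, d))
        for k in range(1, K):
            grad[k - 1] = X.T @ (R[:, k] - p[:, k])
        g = grad.ravel()
        if np.max(np.abs(g)) < 1e-9:
            break
        H = np.zeros(((K - 1) * d, (K - 1) * d))
        for k in range(1, K):
            for l in range(k, K):
                w = p[:, k] * ((k == l) - p[:, l])
                blk = -(X.T * w) @ X
                H[(k - 1) * d : k * d, (l - 1) * d : l * d] = blk
                if l != k:
                    H[(l - 1) * d : l * d, (k - 1) * d : k * d] = blk.T
        try:
            step = np.linalg.solve(H - 1e-10 * np.eye(H.shape[0]), -g)
        except np.linalg.LinAlgError:
            step = -np.linalg.lstsq(H, g, rcond=None)[0]
        step = step.reshape(K - 1, d)
        # step halving: never decrease the M-step objective
        t = 1.0
        for _ in range(30):
            q_new, p_new = objective(beta + t * step)
            if q_new >= q - 1e-12:
                break
            t *= 0.5
        else:
            break
        if q_new - q < tol * (abs(q) + 1.0):
            beta = beta + t * step
            q, p = q_new, p_new
            break
        beta = beta + t * step
        q, p = q_new, p_new
    return beta


class LucidLayer(BaseEstimator):
    """Unsupervised LUCID for a single omics layer.

    Parameters
    ----------
    n_clusters : int
        Number of latent clusters K (K=1 degenerates to a single
        Gaussian with no exposure model).
    covariance : {"shared-diagonal", "diagonal"}
        Diagonal Sigma shared across clusters (default) or
        cluster-specific diagonal.
    tol : float
        Relative log-likelihood change declaring convergence.
    n_restarts : int
        Restart 0 initializes from a first-principal-component quantile
        split (deterministic, subject-order invariant); restart 1 from
        k-means; further restarts from random responsibilities.
    var_floor : float
        Lower bound on feature variances, guarding degenerate spikes.

    Attributes (after ``fit``)
    --------------------------
    beta_ : (K-1, 1+d) exposure-to-cluster log-odds, reference cluster 0
    mu_ : (K, P) cluster-specific feature means
    sigma2_ : (P,) or (K, P) feature variances
    responsibilities_ : (n, K) inclusion probabilities (IPs)
    loglik_trace_ : per-iteration observed-data log-likelihood
    bic_ : -2 loglik + n_params log(n)
    """

    def __init__(
        self,
        n_clusters: int = 2,
        covariance: str = "shared-diagonal",
        max_iter: int = 1000,
        tol: float = 1e-6,
        n_restarts: int = 3,
        var_floor: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.covariance = covariance
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.var_floor = var_floor
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, Z, E):
        """Fit by EM. ``Z`` is the (n, P) standardized omics matrix (array
        or DataFrame); ``E`` the exposure design (vector of log2 exposure,
        or (n, d) matrix; an intercept column is prepended if absent)."""
        K = int(self.n_clusters)
        if K < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.tol <= 0 or self.n_restarts < 1:
            raise ValueError("tol must be > 0 and n_restarts >= 1")
        if self.covariance not in ("shared-diagonal", "diagonal"):
            raise ValueError(f"unknown covariance structure {self.covariance!r}")
        self.feature_names_ = (
            list(Z.columns) if isinstance(Z, pd.DataFrame) else None
        )
        Z = np.asarray(Z, float)
        Ed = _as_design(E)
        n, P = Z.shape
        if len(Ed) != n:
            raise ValueError("Z and E have different numbers of subjects")
        if n <= K:
            raise ValueError(f"need n > K, got n={n}, K={K}")
        if not np.isfinite(Z).all() or not np.isfinite(Ed).all():
            raise ValueError("missing or non-finite values are not supported")

        if K == 1:
            self._fit_single_gaussian(Z, Ed)
            return self

        rng = np.random.default_rng(self.random_state)
        best = None
        plan = ["pc1", "kmeans"][: min(2, self.n_restarts)]
        plan += ["random"] * (self.n_restarts - len(plan))
        extra_draws = 3  # budget for redraws after a collapsed cluster
        i = 0
        while i < len(plan):
            kind = plan[i]
            i += 1
            R0 = self._initial_responsibilities(Z, K, kind, rng)
            result = self._run_em(Z, Ed, R0)
            if result is None:  # empty cluster: redraw a random init
                logger.debug("%s init collapsed a cluster; redrawing", kind)
                if extra_draws > 0:
                    plan.append("random")
                    extra_draws -= 1
                continue
            if best is None or result["loglik"] > best["loglik"]:
                best = result
        if best is None:
            raise RuntimeError(
                "all EM restarts collapsed a cluster; try fewer clusters"
            )
        self._store(best, n, P, Ed.shape[1])
        return self

    # ------------------------------------------------------------------
    def _initial_responsibilities(
        self, Z: np.ndarray, K: int, kind: str, rng: np.random.Generator
    ) -> np.ndarray:
        n = len(Z)
        if kind == "pc1":
            labels = _pc1_quantile_split(Z, K)
        elif kind == "kmeans":
            km = KMeans(
                n_clusters=K,
                n_init=4,
                random_state=(
                    self.random_state if self.random_state is not None else 0
                ),
            )
            labels = km.fit_predict(Z)
        else:
            return rng.dirichlet(np.ones(K), size=n)
        R = np.full((n, K), 1e-3 / max(K - 1, 1))
        R[np.arange(n), labels] = 1.0 - 1e-3
        return R

    def _run_em(self, Z: np.ndarray, Ed: np.ndarray, R: np.ndarray) -> dict | None:
        n, P = Z.shape
        K = R.shape[1]
        d = Ed.shape[1]
        beta = np.zeros((K - 1, d))
        trace: list[float] = []
        prev_ll = -np.inf
        converged = False
        mu, sigma2 = self._mstep_gaussian(Z, R)
        beta = _weighted_multinomial_newton(Ed, R, beta)
        for it in range(self.max_iter):
            R, ll = self._estep(Z, Ed, beta, mu, sigma2)
            trace.append(ll)
            mass = R.sum(axis=0)
            if mass.min() < _EMPTY_CLUSTER_MASS:
                return None
            mu, sigma2 = self._mstep_gaussian(Z, R)
            beta = _weighted_multinomial_newton(Ed, R, beta)
            if np.isfinite(prev_ll) and abs(ll - prev_ll) < self.tol * (abs(prev_ll) + 1.0):
                converged = True
                break
            prev_ll = ll
        # final E-step so responsibilities match the returned parameters
        R, ll = self._estep(Z, Ed, beta, mu, sigma2)
        trace.append(ll)
        return {
            "beta": beta,
            "mu": mu,
            "sigma2": sigma2,
            "resp": R,
            "loglik": ll,
            "trace": np.asarray(trace),
            "converged": converged,
            "n_iter": len(trace) - 1,
        }

    def _estep(
        self,
        Z: np.ndarray,
        Ed: np.ndarray,
        beta: np.ndarray,
        mu: np.ndarray,
        sigma2: np.ndarray,
    ) -> tuple[np.ndarray, float]:
        n = len(Z)
        K = mu.shape[0]
        logits = np.hstack([np.zeros((n, 1)), Ed @ beta.T])
        log_prior = logits - logsumexp(logits, axis=1)[:, None]
        log_like = np.empty((n, K))
        for k in range(K):
            s2 = sigma2[k] if sigma2.ndim == 2 else sigma2
            diff = Z - mu[k]
            log_like[:, k] = -0.5 * (
                np.sum(np.log(2.0 * np.pi * s2)) + np.sum(diff**2 / s2, axis=1)
            )
        joint = log_prior + log_like
        norm = logsumexp(joint, axis=1)
        R = np.exp(joint - norm[:, None])
        return R, float(norm.sum())

    def _mstep_gaussian(self, Z: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n, P = Z.shape
        K = R.shape[1]
        Nk = R.sum(axis=0)
        mu = (R.T @ Z) / Nk[:, None]
        if self.covariance == "shared-diagonal":
            s2 = np.zeros(P)
            for k in range(K):
                diff = Z - mu[k]
                s2 += R[:, k] @ diff**2
            sigma2 = np.maximum(s2 / n, self.var_floor)
            if np.any(s2 / n < self.var_floor):
                warnings.warn("variance floored at var_floor", stacklevel=2)
        else:
            sigma2 = np.empty((K, P))
            for k in range(K):
                diff = Z - mu[k]
                sigma2[k] = np.maximum((R[:, k] @ diff**2) / Nk[k], self.var_floor)
        return mu, sigma2

    def _fit_single_gaussian(self, Z: np.ndarray, Ed: np.ndarray) -> None:
        n, P = Z.shape
        mu = Z.mean(axis=0, keepdims=True)
        s2 = np.maximum(((Z - mu) ** 2).mean(axis=0), self.var_floor)
        sigma2 = s2 if self.covariance == "shared-diagonal" else s2[None, :]
        ll = float(
            -0.5 * n * np.sum(np.log(2.0 * np.pi * s2))
            - 0.5 * np.sum((Z - mu) ** 2 / s2)
        )
        self._store(
            {
                "beta": np.zeros((0, Ed.shape[1])),
                "mu": mu,
                "sigma2": sigma2,
                "resp": np.ones((n, 1)),
                "loglik": ll,
                "trace": np.array([ll]),
                "converged": True,
                "n_iter": 0,
            },
            n,
            P,
            Ed.shape[1],
        )

    def _store(self, res: dict, n: int, P: int, d: int) -> None:
        K = int(self.n_clusters)
        self.beta_ = res["beta"]
        self.mu_ = res["mu"]
        self.sigma2_ = res["sigma2"]
        self.responsibilities_ = res["resp"]
        self.loglik_ = res["loglik"]
        self.loglik_trace_ = res["trace"]
        self.converged_ = bool(res["converged"])
        self.n_iter_ = int(res["n_iter"])
        n_var = P if self.sigma2_.ndim == 1 else K * P
        self.n_parameters_ = (K - 1) * d + K * P + n_var
        self.bic_ = float(-2.0 * self.loglik_ + self.n_parameters_ * np.log(n))
        self.n_features_in_ = P
        if not self.converged_:
            logger.warning("EM did not converge within max_iter=%d", self.max_iter)

    # ------------------------------------------------------------------
    @property
    def ip_(self) -> np.ndarray:
        """Inclusion probabilities, an alias for ``responsibilities_``."""
        return self.responsibilities_

    def predict_proba(self, Z, E) -> np.ndarray:
        Z = np.asarray(Z, float)
        R, _ = self._estep(Z, _as_design(E), self.beta_, self.mu_, self.sigma2_)
        return R

    def predict(self, Z, E) -> np.ndarray:
        return self.predict_proba(Z, E).argmax(axis=1)

    def score(self, Z, E) -> float:
        """Observed-data log-likelihood of new data under the fit."""
        Z = np.asarray(Z, float)
        _, ll = self._estep(Z, _as_design(E), self.beta_, self.mu_, self.sigma2_)
        return ll

    def to_dict(self) -> dict:
        return {
            "n_clusters": int(self.n_clusters),
            "covariance": self.covariance,
            "beta": self.beta_.tolist(),
            "mu": self.mu_.tolist(),
            "sigma2": self.sigma2_.tolist(),
            "loglik": self.loglik_,
            "loglik_trace": np.asarray(self.loglik_trace_).tolist(),
            "bic": self.bic_,
            "converged": self.converged_,
            "n_iter": self.n_iter_,
            "feature_names": self.feature_names_,
        }


def _pc1_quantile_split(Z: np.ndarray, K: int) -> np.ndarray:
    """Hard split at K-quantiles of the first principal component.

    Deterministic and invariant to subject order; the component sign is
    fixed by making its largest-magnitude loading positive.
    """
    Zc = Z - Z.mean(axis=0)
    _, _, vt = np.linalg.svd(Zc, full_matrices=False)
    v = vt[0]
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        v = -v
    score = Zc @ v
    cuts = np.quantile(score, np.linspace(0, 1, K + 1)[1:-1])
    return np.searchsorted(np.unique(cuts), score, side="left").clip(0, K - 1)


# ----------------------------------------------------------------------
class LucidParallel(BaseEstimator):
    """LUCID in parallel: one independent latent cluster variable per
    omics layer, sharing the exposure design and the subject order.

    The unsupervised likelihood factorizes across layers, so the joint
    fit is exactly the collection of per-layer fits; this wrapper
    enforces subject alignment and applies the same ``random_state`` to
    every layer.
    """

    def __init__(
        self,
        n_clusters: int | Mapping[str, int] = 2,
        covariance: str = "shared-diagonal",
        max_iter: int = 1000,
        tol: float = 1e-6,
        n_restarts: int = 3,
        var_floor: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.covariance = covariance
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.var_floor = var_floor
        self.random_state = random_state

    def _k_for(self, layer: str) -> int:
        if isinstance(self.n_clusters, Mapping):
            return int(self.n_clusters[layer])
        return int(self.n_clusters)

    def fit(self, layers: Mapping[str, "pd.DataFrame | np.ndarray"], E):
        index = None
        for name, Z in layers.items():
            if isinstance(Z, pd.DataFrame):
                if index is None:
                    index = Z.index
                elif not index.equals(Z.index):
                    raise ValueError(
                        f"subject mismatch between layers: {name!r} differs"
                    )
        n = {name: len(Z) for name, Z in layers.items()}
        if len(set(n.values())) > 1:
            raise ValueError(f"layers have different subject counts: {n}")
        self.layer_models_: dict[str, LucidLayer] = {}
        for name, Z in layers.items():
            m = LucidLayer(
                n_clusters=self._k_for(name),
                covariance=self.covariance,
                max_iter=self.max_iter,
                tol=self.tol,
                n_restarts=self.n_restarts,
                var_floor=self.var_floor,
                random_state=self.random_state,
            )
            self.layer_models_[name] = m.fit(Z, E)
        self.loglik_ = float(sum(m.loglik_ for m in self.layer_models_.values()))
        self.bic_ = float(sum(m.bic_ for m in self.layer_models_.values()))
        return self

    def predict_proba(self, layers, E) -> dict[str, np.ndarray]:
        return {
            name: self.layer_models_[name].predict_proba(Z, E)
            for name, Z in layers.items()
        }

    @property
    def ip_(self) -> dict[str, np.ndarray]:
        return {name: m.ip_ for name, m in self.layer_models_.items()}


# ----------------------------------------------------------------------
def fit_lucid_layer(Z, E, n_clusters: int = 2, **kwargs) -> LucidLayer:
    """Functional wrapper over :class:`LucidLayer`."""
    return LucidLayer(n_clusters=n_clusters, **kwargs).fit(Z, E)


def fit_lucid_parallel(layers, E, n_clusters=2, **kwargs) -> LucidParallel:
    """Functional wrapper over :class:`LucidParallel`."""
    return LucidParallel(n_clusters=n_clusters, **kwargs).fit(layers, E)


def select_k_bic(
    Z,
    E,
    k_grid: Sequence[int] = (1, 2, 3, 4),
    **kwargs,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of clusters by BIC over ``k_grid``.

    Returns the argmin-BIC K (ties toward smaller K) and the K-by-BIC
    table; fits that fail (e.g. every restart collapses) are recorded with
    BIC = +inf.
    """
    if len(k_grid) == 0:
        raise ValueError("k_grid must be non-empty")
    rows = []
    fits: dict[int, LucidLayer] = {}
    for k in sorted(k_grid):
        try:
            m = LucidLayer(n_clusters=k, **kwargs).fit(Z, E)
            fits[k] = m
            rows.append({"k": k, "bic": m.bic_, "loglik": m.loglik_, "converged": m.converged_})
        except (RuntimeError, ValueError) as e:
            logger.warning("K=%d fit failed: %s", k, e)
            rows.append({"k": k, "bic": np.inf, "loglik": np.nan, "converged": False})
    table = pd.DataFrame(rows)
    if not np.isfinite(table["bic"]).any():
        raise RuntimeError("all fits failed across the K grid")
    chosen = int(table.loc[table["bic"].idxmin(), "k"])  # idxmin: first min, small K
    return chosen, table


# ----------------------------------------------------------------------
def align_clusters(
    model: LucidLayer,
    rule: str = "exposure",
    anchor: str | int | None = None,
    outcome: np.ndarray | None = None,
    E=None,
) -> LucidLayer:
    """Return a copy of ``model`` with clusters permuted to a fixed order.

    Rules
    -----
    ``exposure``
        Ascending mean exposure-implied cluster propensity (cluster 0 is
        the cluster least favoured as exposure increases); requires ``E``.
    ``anchor``
        Ascending cluster mean of the designated anchor feature.
    ``outcome``
        Descending mean outcome within MAP cluster (cluster 0 = highest
        outcome rate); requires ``outcome``.
    """
    K = model.mu_.shape[0]
    if K == 1:
        return model
    if rule == "exposure":
        if E is None:
            raise ValueError("rule 'exposure' requires the exposure design E")
        Ed = _as_design(E)
        logits = np.hstack([np.zeros((len(Ed), 1)), Ed @ model.beta_.T])
        prop = logits.mean(axis=0)
        order = np.argsort(prop, kind="stable")
    elif rule == "anchor":
        if anchor is None:
            raise ValueError("rule 'anchor' requires an anchor feature")
        if isinstance(anchor, str):
            if model.feature_names_ is None or anchor not in model.feature_names_:
                raise KeyError(f"anchor feature {anchor!r} not in fit")
            j = model.feature_names_.index(anchor)
        else:
            j = int(anchor)
        order = np.argsort(model.mu_[:, j], kind="stable")
    elif rule == "outcome":
        if outcome is None:
            raise ValueError("rule 'outcome' requires an outcome vector")
        lab = model.responsibilities_.argmax(axis=1)
        y = np.asarray(outcome, float)
        rates = np.array(
            [y[lab == k].mean() if np.any(lab == k) else -np.inf for k in range(K)]
        )
        order = np.argsort(-rates, kind="stable")
    else:
        raise ValueError(f"unknown alignment rule {rule!r}")
    return _permute(model, np.asarray(order))


def _permute(model: LucidLayer, order: np.ndarray) -> LucidLayer:
    import copy

    K = model.mu_.shape[0]
    out = copy.deepcopy(model)
    out.mu_ = model.mu_[order]
    out.responsibilities_ = model.responsibilities_[:, order]
    if model.sigma2_.ndim == 2:
        out.sigma2_ = model.sigma2_[order]
    # re-express beta with the new cluster 0 as reference:
    # logits_k = beta_k . E (beta_ref = 0); subtract the new reference row
    full = np.vstack([np.zeros((1, model.beta_.shape[1])), model.beta_])
    full = full[order]
    out.beta_ = full[1:] - full[0]
    return out
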