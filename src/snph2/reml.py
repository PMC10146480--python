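"""Restricted maximum likelihood for GRM variance components.

Fits the linear mixed model

    y = X b + g_1 + ... + g_K + e,   g_k ~ N(0, A_k sigma2_k),  e ~ N(0, I sigma2_e)

by average-information REML with initial EM steps (the scheme GCTA uses),
maximizing

    lR = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    V = Sum_k sigma2_k A_k + sigma2_e I,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

A binary phenotype is analysed as 0/1 on the observed scale; the resulting
``h2_observed = Sum sigma2_k / (Sum sigma2_k + sigma2_e)`` is converted to
the liability scale downstream. Two numerically equivalent backends exist: a
dense one for arbitrary GRM lists, and a spectral one for a single GRM that
rotates the model into the kernel's eigenbasis (reducing the rank-deficient
complement exactly to p+1 pseudo-observations), so repeated fits and large-n
single-component fits cost O(n) per iteration after one decomposition.

The sklearn-style front end is :class:`GREML`; :func:`reml_fit` is the
functional wrapper.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .relatedness import Grm, compute_grm
from .simulate import GenotypeMatrix

__all__ = ["RemlFit", "GREML", "reml_fit", "pcs_from_grm", "h2_partition", "design_matrix"]

logger = logging.getLogger(__name__)


@dataclass
class RemlFit:
    """Variance-component estimates and REML diagnostics for one fit."""

    sigma2_g: np.ndarray
    sigma2_e: float
    h2_observed: float
    se_h2: float
    se_components: np.ndarray
    loglik: float
    loglik_null: float
    p_lrt: float
    n_iter: int
    converged: bool
    n: int
    n_components: int
    var_phenotypic: float
    messages: list[str] = field(default_factory=list)

    @property
    def lrt(self) -> float:
        return max(0.0, 2.0 * (self.loglik - self.loglik_null))

    def to_hsq(self) -> str:
        """GCTA-style .hsq text report (Source / Variance / SE table)."""
        lines = ["Source\tVariance\tSE"]
        vp = float(np.sum(self.sigma2_g) + self.sigma2_e)
        for k, (v, s) in enumerate(zip(self.sigma2_g, self.se_components[:-1]), start=1):
            lines.append(f"V(G{k})\t{v:.6f}\t{s:.6f}")
        lines.append(f"V(e)\t{self.sigma2_e:.6f}\t{self.se_components[-1]:.6f}")
        lines.append(f"Vp\t{vp:.6f}\t-")
        lines.append(f"V(G)/Vp\t{self.h2_observed:.6f}\t{self.se_h2:.6f}")
        lines.append(f"logL\t{self.loglik:.4f}")
        lines.append(f"logL0\t{self.loglik_null:.4f}")
        lines.append(f"LRT\t{self.lrt:.4f}")
        lines.append(f"df\t{self.n_components}")
        lines.append(f"Pval\t{self.p_lrt:.4e}")
        lines.append(f"n\t{self.n}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# backends: each exposes stats(theta) -> (loglik, yPApy, trPA, score, AI)
# with component order (g_1, ..., g_K, e).


class _DenseKernel:
    def __init__(self, y: np.ndarray, X: np.ndarray, A_list: list[np.ndarray]):
        self.y, self.X = y, X
        self.A = A_list
        self.n, self.p = X.shape

    def stats(self, theta: np.ndarray):
        K = len(self.A)
        V = theta[-1] * np.eye(self.n)
        for k in range(K):
            V += theta[k] * self.A[k]
        try:
            c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
        Vi = linalg.cho_solve((c, low), np.eye(self.n), check_finite=False)
        ViX = Vi @ self.X
        C = self.X.T @ ViX
        sign, logdetC = np.linalg.slogdet(C)
        if sign <= 0:
            return None
        Cinv = np.linalg.inv(C)
        P = Vi - ViX @ Cinv @ ViX.T
        u = P @ self.y
        yPy = float(self.y @ u)
        ll = -0.5 * (logdetV + logdetC + yPy)

        mats = self.A + [np.eye(self.n)]
        trPA = np.array([float(np.sum(P * M)) for M in mats])
        Au = [M @ u for M in mats]
        yPApy = np.array([float(u @ a) for a in Au])
        score = -0.5 * (trPA - yPApy)
        PAu = [P @ a for a in Au]
        AI = 0.5 * np.array([[float(Au[i] @ PAu[j]) for j in range(K + 1)] for i in range(K + 1)])
        return ll, yPApy, trPA, score, AI


class _SpectralKernel:
    """Single-GRM model rotated into the kernel eigenbasis.

    The GRM's non-null eigendirections carry rotated data (d_i, y_i, x_i);
    the null-space interaction with the data is captured exactly by p+1
    pseudo-observations whose Gram matrix equals the complement Gram of
    [y X], and the remaining n - r - (p+1) pure-noise dimensions enter the
    log-determinant and trace terms analytically.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, grm: Grm):
        n, p = X.shape
        d, U = grm.spectrum()
        r = d.size
        yt, Xt = U.T @ y, U.T @ X
        if r < n:
            W = np.column_stack([y, X])
            Wt = np.column_stack([yt, Xt])
            B = W.T @ W - Wt.T @ Wt
            B = 0.5 * (B + B.T)
            w, Vb = np.linalg.eigh(B)
            w = np.clip(w, 0.0, None)
            k = min(p + 1, n - r)
            order = np.argsort(w)[::-1][:k]
            Mrows = (Vb[:, order] * np.sqrt(w[order])).T  # (k, p+1), M'M ~= B
            d = np.concatenate([d, np.zeros(k)])
            yt = np.concatenate([yt, Mrows[:, 0]])
            Xt = np.vstack([Xt, Mrows[:, 1:]])
            self.n_phantom = n - r - k
        else:
            self.n_phantom = 0
        self.d, self.yt, self.Xt = d, yt, Xt
        self.n, self.p = n, p

    def stats(self, theta: np.ndarray):
        sg, se = float(theta[0]), float(theta[1])
        v = sg * self.d + se
        if np.any(v <= 0) or se <= 0:
            return None
        logdetV = float(np.sum(np.log(v))) + self.n_phantom * np.log(se)
        Xv = self.Xt / v[:, None]
        C = self.Xt.T @ Xv
        sign, logdetC = np.linalg.slogdet(C)
        if sign <= 0:
            return None
        Cinv = np.linalg.inv(C)
        Xvy = self.Xt.T @ (self.yt / v)
        b = Cinv @ Xvy
        u = (self.yt - self.Xt @ b) / v
        yPy = float(self.yt @ u)  # y'Py = y'V^-1(y - Xb) with REML projection
        ll = -0.5 * (logdetV + logdetC + yPy)

        def trPA(dvec, phantom):
            t1 = float(np.sum(dvec / v)) + phantom
            XdX = self.Xt.T @ (self.Xt * (dvec / v**2)[:, None])
            return t1 - float(np.sum(Cinv * XdX))

        tr = np.array([trPA(self.d, 0.0), trPA(np.ones_like(v), self.n_phantom / se)])

        def Pdot(t):
            return (t - self.Xt @ (Cinv @ (self.Xt.T @ (t / v)))) / v

        # quadratic forms y'P A P y with u = Py reduce to u'A u
        w = self.d * u
        yPApy = np.array([float(w @ u), float(u @ u)])
        score = -0.5 * (tr - yPApy)
        Pw, Pu = Pdot(w), Pdot(u)
        AI = 0.5 * np.array(
            [[float(w @ Pw), float(w @ Pu)], [float(w @ Pu), float(u @ Pu)]]
        )
        return ll, yPApy, tr, score, AI


# ---------------------------------------------------------------------------


def _null_loglik(y: np.ndarray, X: np.ndarray) -> float:
    """Closed-form restricted log-likelihood of the no-genetic-variance model."""
    n, p = X.shape
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ b) ** 2))
    s2 = rss / (n - p)
    sign, logdetXX = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * np.log(s2) + logdetXX + (n - p))


def _reml_loop(kernel, theta0, n, constrain, max_iter, tol, em_steps, messages):
    theta = theta0.copy()
    vp = float(np.sum(theta0))
    floor = 1e-8 * vp
    out = kernel.stats(theta)
    if out is None:
        raise linalg.LinAlgError("initial covariance matrix is not positive definite")
    ll = out[0]
    converged = False
    n_iter = 0
    ai_singular = False
    for it in range(1, max_iter + 1):
        n_iter = it
        ll_prev = ll
        _, yPApy, trPA, score, AI = out
        if it <= em_steps:
            theta_new = theta + theta**2 * (yPApy - trPA) / n
        else:
            # active set: components pinned at the floor whose score points
            # further down are frozen, so the AI step stays an ascent direction
            active = ~((theta <= floor * (1 + 1e-6)) & (score < 0)) if constrain else np.ones_like(theta, bool)
            active[-1] = True
            AIa = AI[np.ix_(active, active)]
            cond = np.linalg.cond(AIa)
            if not np.isfinite(cond) or cond > 1e10:
                if not ai_singular:
                    messages.append(
                        "average-information matrix is near-singular; "
                        "variance components may not be jointly identifiable"
                    )
                    ai_singular = True
                delta_a = np.linalg.lstsq(AIa, score[active], rcond=None)[0]
            else:
                delta_a = np.linalg.solve(AIa, score[active])
            delta = np.zeros_like(theta)
            delta[active] = delta_a
            step = 1.0
            theta_new = theta + delta
            for _ in range(12):
                cand = theta + step * delta
                if constrain:
                    cand = np.maximum(cand, floor)
                trial = kernel.stats(cand)
                if trial is not None and trial[0] >= ll_prev - 1e-10:
                    theta_new = cand
                    break
                step *= 0.5
            else:
                theta_new = theta + theta**2 * (yPApy - trPA) / n  # EM fallback
        if constrain:
            theta_new = np.maximum(theta_new, floor)
        else:
            theta_new = np.where(theta_new <= 0, np.maximum(theta_new, -vp * 10), theta_new)
            theta_new[-1] = max(theta_new[-1], floor)  # residual must stay positive
        out_new = kernel.stats(theta_new)
        if out_new is None:
            theta_new = np.maximum(theta + theta**2 * (yPApy - trPA) / n, floor)
            out_new = kernel.stats(theta_new)
            if out_new is None:
                messages.append("covariance became indefinite; stopping early")
                break
        theta, out, ll = theta_new, out_new, out_new[0]
        if it > em_steps and abs(ll - ll_prev) < tol:
            converged = True
            break
    return theta, out, n_iter, converged, ai_singular


def reml_fit(
    y: np.ndarray,
    X: np.ndarray | None,
    grms: Grm | list[Grm],
    constrain: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
    em_steps: int = 3,
) -> RemlFit:
    """AI-REML fit of one or several GRM variance components.

    Parameters
    ----------
    y : phenotype vector (0/1 disease status analysed on the observed scale,
        or any quantitative trait).
    X : fixed-effect design matrix including an intercept column; ``None``
        for intercept only.
    grms : a single :class:`Grm` or a list (one variance component each).
    constrain : clamp components to a small positive floor (default); with
        ``False`` components may go negative (residual stays positive).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != n:
        raise ValueError(f"design matrix shape {X.shape} does not match n={n}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear covariates)")
    grm_list = [grms] if isinstance(grms, Grm) else list(grms)
    if not grm_list:
        raise ValueError("at least one GRM is required")
    for g in grm_list:
        if g.n_samples != n:
            raise ValueError(f"GRM dimension {g.n_samples} does not match n={n}")
    K = len(grm_list)
    n_res = n - X.shape[1]
    if n_res <= K:
        raise ValueError("too few residual degrees of freedom for the number of components")

    vp = float(np.var(y, ddof=1))
    theta0 = np.full(K + 1, vp / (K + 1))
    messages: list[str] = []
    if K == 1:
        kernel = _SpectralKernel(y, X, grm_list[0])
    else:
        kernel = _DenseKernel(y, X, [g.values for g in grm_list])
    theta, out, n_iter, converged, ai_singular = _reml_loop(
        kernel, theta0, n, constrain, max_iter, tol, em_steps, messages
    )
    if not converged:
        messages.append(f"REML did not converge within {max_iter} iterations")
        logger.warning("REML did not converge within %d iterations", max_iter)

    ll, _, _, _, AI = out
    ll0 = _null_loglik(y, X)
    lrt = max(0.0, 2.0 * (ll - ll0))
    # boundary-corrected null: 0.5 chi2_0 + 0.5 chi2_1 for one component;
    # conservative chi2_K for multi-component fits (documented approximation)
    p_lrt = 0.5 * chi2.sf(lrt, 1) if K == 1 else chi2.sf(lrt, K)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(AI)
    if np.any(np.diag(cov) < 0):
        cov = np.linalg.pinv(AI)
    se_comp = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    S, E = float(np.sum(theta[:-1])), float(theta[-1])
    T = S + E
    grad = np.empty(K + 1)
    grad[:K] = E / T**2
    grad[K] = -S / T**2
    se_h2 = float(np.sqrt(max(0.0, grad @ cov @ grad)))
    h2 = S / T

    return RemlFit(
        sigma2_g=theta[:-1].copy(),
        sigma2_e=E,
        h2_observed=h2,
        se_h2=se_h2,
        se_components=se_comp,
        loglik=ll,
        loglik_null=ll0,
        p_lrt=float(p_lrt),
        n_iter=n_iter,
        converged=converged,
        n=n,
        n_components=K,
        var_phenotypic=T,
        messages=messages,
    )


def restricted_loglik(y: np.ndarray, X: np.ndarray, grms, theta: np.ndarray) -> float:
    """Dense evaluation of the restricted log-likelihood at fixed components.

    ``theta = (sigma2_g1, ..., sigma2_gK, sigma2_e)``. Used for grid-search
    cross-checks of the iterative fit; shares no code with the AI-REML path
    beyond the model definition.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    grm_list = [grms] if isinstance(grms, Grm) else list(grms)
    n = y.size
    V = theta[-1] * np.eye(n)
    for k, g in enumerate(grm_list):
        V += theta[k] * g.values
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    C = X.T @ Vi @ X
    signC, logdetC = np.linalg.slogdet(C)
    if signC <= 0:
        return -np.inf
    P = Vi - Vi @ X @ np.linalg.inv(C) @ X.T @ Vi
    return -0.5 * (logdetV + logdetC + float(y @ P @ y))


def pcs_from_grm(grm: Grm, k: int) -> np.ndarray:
    """Top-k unit-norm eigenvectors of the GRM as ancestry covariates.

    Sign convention: the loading of largest magnitude is positive, so the
    output is deterministic.
    """
    if k < 0 or k >= grm.n_samples:
        raise ValueError(f"k must satisfy 0 <= k < N; got {k}")
    if k == 0:
        return np.empty((grm.n_samples, 0))
    d, U = grm.spectrum()
    if k > d.size:
        raise ValueError(f"GRM has only {d.size} non-null eigendirections; cannot take {k} PCs")
    pcs = U[:, :k].copy()
    for j in range(k):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


def h2_partition(fit: RemlFit) -> dict:
    """Per-component share of genetic and phenotypic variance from a multi-GRM fit."""
    total_g = float(np.sum(fit.sigma2_g))
    if total_g <= 0:
        return {
            "share_of_genetic": np.full(fit.n_components, np.nan),
            "share_of_phenotypic": np.zeros(fit.n_components),
            "total_h2_observed": fit.h2_observed,
        }
    return {
        "share_of_genetic": fit.sigma2_g / total_g,
        "share_of_phenotypic": fit.sigma2_g / fit.var_phenotypic,
        "total_h2_observed": fit.h2_observed,
    }


def design_matrix(n: int, *covariates) -> np.ndarray:
    """Intercept plus the given covariate columns (each length n)."""
    cols = [np.ones(n)]
    for c in covariates:
        c = np.asarray(c, dtype=float)
        cols.append(c.reshape(n, -1))
    return np.column_stack(cols)


class GREML(BaseEstimator):
    """Genome-based REML heritability estimator with a scikit-learn interface.

    Parameters
    ----------
    kernel : 'grm' builds the relatedness kernel from dosages passed to
        :meth:`fit`; 'precomputed' expects a :class:`Grm` or list of Grm.
    n_pcs : number of GRM principal components appended to the fixed effects
        (population-structure adjustment).
    constrain, max_iter, tol, em_steps : REML optimizer controls.

    Attributes (after :meth:`fit`)
    ------------------------------
    sigma2_g_, sigma2_e_, h2_observed_, se_h2_, loglik_, loglik_null_,
    p_lrt_, n_iter_, converged_, fit_ (the full :class:`RemlFit`).
    """

    def __init__(
        self,
        kernel: str = "grm",
        n_pcs: int = 0,
        constrain: bool = True,
        max_iter: int = 100,
        tol: float = 1e-6,
        em_steps: int = 3,
    ):
        self.kernel = kernel
        self.n_pcs = n_pcs
        self.constrain = constrain
        self.max_iter = max_iter
        self.tol = tol
        self.em_steps = em_steps

    def fit(self, X, y, covariates=None):
        """Fit variance components.

        ``X`` is an (n, m) dosage array or :class:`GenotypeMatrix` when
        ``kernel='grm'``, else a Grm or list of Grm. ``covariates`` is an
        optional (n, c) array appended after the intercept (and PCs).
        """
        if self.kernel not in ("grm", "precomputed"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        y = np.asarray(y, dtype=float).ravel()
        if self.kernel == "precomputed":
            grms = X if isinstance(X, (list, tuple)) else [X]
            grms = list(grms)
            pc_source = grms[0]
        else:
            if isinstance(X, GenotypeMatrix):
                G = X
            else:
                X = np.asarray(X)
                import pandas as pd

                meta = pd.DataFrame(
                    {
                        "chrom": 1,
                        "snp_id": [f"snp{j}" for j in range(X.shape[1])],
                        "pos_bp": np.arange(1, X.shape[1] + 1),
                        "a1": "A",
                        "a2": "G",
                        "allele_freq": np.asarray(X, dtype=float).mean(axis=0) / 2.0,
                    }
                )
                G = GenotypeMatrix(X, meta, [f"id{i}" for i in range(X.shape[0])])
            grms = [compute_grm(G)]
            pc_source = grms[0]
        cols = []
        if self.n_pcs:
            cols.append(pcs_from_grm(pc_source, self.n_pcs))
        if covariates is not None:
            cols.append(np.asarray(covariates, dtype=float).reshape(y.size, -1))
        design = design_matrix(y.size, *cols)
        fit = reml_fit(
            y,
            design,
            grms,
            constrain=self.constrain,
            max_iter=self.max_iter,
            tol=self.tol,
            em_steps=self.em_steps,
        )
        self.fit_ = fit
        self.sigma2_g_ = fit.sigma2_g
        self.sigma2_e_ = fit.sigma2_e
        self.h2_observed_ = fit.h2_observed
        self.se_h2_ = fit.se_h2
        self.loglik_ = fit.loglik
        self.loglik_null_ = fit.loglik_null
        self.p_lrt_ = fit.p_lrt
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        return self
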