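"""Genomic cline model: prediction, weighted least-squares fit, interpretation.

The cline function relates locus-specific ancestry theta to the genome-wide
hybrid index h:

    theta(h) = h + 2 (h - h^2) (alpha + beta (2 h - 1))

alpha shifts the cline center (biased introgression toward one parental
genome) and beta steepens it (divergent selection); theta(0) = 0 and
theta(1) = 1 for any (alpha, beta), and alpha = beta = 0 gives the neutral
identity theta = h.  The model is linear in (alpha, beta) given h, so the
damped Gauss-Newton fit converges to the closed-form weighted linear
solution; both are exposed and agree to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ClineFit", "cline_predict", "fit_cline", "fit_cline_closed_form",
           "interpret_cline"]

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class ClineFit:
    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    ci_alpha: tuple[float, float]
    ci_beta: tuple[float, float]
    residuals: np.ndarray
    n: int
    converged: bool
    n_iter: int
    weights: np.ndarray


def cline_predict(h: np.ndarray | float, alpha: float, beta: float,
                  clamp: bool = False) -> np.ndarray | float:
    """Predicted block ancestry theta at hybrid index h.

    Values are reported unclamped by default; ``clamp`` restricts the
    output to [0, 1] for display.  h outside [0, 1] raises.
    """
    h_arr = np.asarray(h, dtype=float)
    if np.any((h_arr < 0) | (h_arr > 1)):
        raise ValueError("hybrid index h must lie in [0, 1]")
    theta = h_arr + 2.0 * (h_arr - h_arr**2) * (alpha + beta * (2.0 * h_arr - 1.0))
    if clamp:
        theta = np.clip(theta, 0.0, 1.0)
    return float(theta) if np.isscalar(h) else theta


def _design(h: np.ndarray) -> np.ndarray:
    """Jacobian of theta w.r.t. (alpha, beta): columns 2(h-h^2), 2(h-h^2)(2h-1)."""
    g = 2.0 * (h - h**2)
    return np.column_stack([g, g * (2.0 * h - 1.0)])


def _check_inputs(theta: np.ndarray, h: np.ndarray, weights, cluster=None
                  ) -> tuple[np.ndarray, ...]:
    theta = np.asarray(theta, dtype=float)
    h = np.asarray(h, dtype=float)
    ok = np.isfinite(theta) & np.isfinite(h)
    theta, h = theta[ok], h[ok]
    w = np.ones_like(h) if weights is None else np.asarray(weights, dtype=float)[ok]
    cl = None if cluster is None else np.asarray(cluster)[ok]
    if h.size < 10:
        raise ValueError(f"need >= 10 individuals with defined theta and h, got {h.size}")
    if h.max() - h.min() < 0.3:
        raise ValueError("degenerate hybrid-index spread: max(h) - min(h) < 0.3")
    return theta, h, w, cl


def _finalize(theta: np.ndarray, h: np.ndarray, w: np.ndarray,
              ab: np.ndarray, converged: bool, n_iter: int,
              cluster: np.ndarray | None = None) -> ClineFit:
    J = _design(h)
    resid = theta - cline_predict(h, *ab)
    n = h.size
    bread = np.linalg.inv(J.T @ (w[:, None] * J))
    if cluster is None:
        dof = max(n - 2, 1)
        sigma2 = float(np.sum(w * resid**2) / dof)
        cov = sigma2 * bread
        # the model is linear in (alpha, beta), so the t reference is exact
        # under iid Gaussian errors
        crit = float(stats.t.ppf(0.975, df=dof))
    else:
        # cluster-robust sandwich: individuals within a sampling site share
        # drift of the linked block, so their residuals are correlated
        labels = np.unique(cluster)
        G = labels.size
        meat = np.zeros((2, 2))
        for lab in labels:
            m = cluster == lab
            g = J[m].T @ (w[m] * resid[m])
            meat += np.outer(g, g)
        cov = bread @ meat @ bread * (G / max(G - 1, 1))
        crit = Z95
    se = np.sqrt(np.diag(cov))
    return ClineFit(
        alpha=float(ab[0]), beta=float(ab[1]),
        se_alpha=float(se[0]), se_beta=float(se[1]),
        ci_alpha=(float(ab[0] - crit * se[0]), float(ab[0] + crit * se[0])),
        ci_beta=(float(ab[1] - crit * se[1]), float(ab[1] + crit * se[1])),
        residuals=resid, n=n, converged=converged, n_iter=n_iter, weights=w,
    )


def fit_cline_closed_form(theta: np.ndarray, h: np.ndarray,
                          weights: np.ndarray | None = None,
                          cluster: np.ndarray | None = None) -> ClineFit:
    """Closed-form weighted regression of (theta - h) on the two cline predictors."""
    theta, h, w, cl = _check_inputs(theta, h, weights, cluster)
    J = _design(h)
    A = J.T @ (w[:, None] * J)
    b = J.T @ (w * (theta - h))
    ab = np.linalg.solve(A, b)
    return _finalize(theta, h, w, ab, converged=True, n_iter=0, cluster=cl)


def fit_cline(theta: np.ndarray, h: np.ndarray, weights: np.ndarray | None = None,
              max_iter: int = 200, tol: float = 1e-12,
              cluster: np.ndarray | None = None) -> ClineFit:
    """Damped Gauss-Newton weighted least squares from the neutral start (0, 0).

    Standard errors come from the Jacobian at the optimum
    (cov = sigma^2 (J' W J)^-1); 95% CIs are normal-approximation.  With
    ``cluster`` labels (e.g. sampling site), a cluster-robust sandwich
    covariance replaces the iid one and CIs use a t reference with
    n_clusters - 2 df.  Raises on non-convergence with the iteration trace.
    """
    theta, h, w, cl = _check_inputs(theta, h, weights, cluster)
    ab = np.zeros(2)
    J = _design(h)
    trace = []
    converged = False
    it = 0
    sse = float(np.sum(w * (theta - cline_predict(h, *ab))**2))
    for it in range(1, max_iter + 1):
        resid = theta - cline_predict(h, *ab)
        A = J.T @ (w[:, None] * J)
        g = J.T @ (w * resid)
        step = np.linalg.solve(A, g)
        lam = 1.0
        while lam > 1e-8:
            cand = ab + lam * step
            sse_new = float(np.sum(w * (theta - cline_predict(h, *cand))**2))
            if sse_new <= sse + 1e-15:
                break
            lam /= 2.0
        ab = ab + lam * step
        trace.append((it, float(ab[0]), float(ab[1]), sse_new))
        if np.max(np.abs(lam * step)) < tol or abs(sse - sse_new) < tol * (1 + sse):
            converged = True
            sse = sse_new
            break
        sse = sse_new
    if not converged:
        raise RuntimeError(f"cline fit did not converge in {max_iter} iterations; trace={trace[-5:]}")
    return _finalize(theta, h, w, ab, converged=True, n_iter=it, cluster=cl)


def interpret_cline(fit: ClineFit) -> list[str]:
    """Classify a fitted cline by which CIs exclude zero.

    "divergent selection" iff the beta CI is strictly above 0;
    "A-biased introgression" / "B-biased introgression" iff the alpha CI is
    strictly below / above 0; "neutral-compatible" iff both CIs cover 0.
    CIs touching zero do not count as exclusion.
    """
    labels = []
    if fit.ci_beta[0] > 0:
        labels.append("divergent selection")
    if fit.ci_alpha[1] < 0:
        labels.append("A-biased introgression")
    elif fit.ci_alpha[0] > 0:
        labels.append("B-biased introgression")
    if not labels:
        labels.append("neutral-compatible")
    return labels
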