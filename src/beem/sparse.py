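"""Sparse gradient-matching regression.

The interaction structure of microbial communities is assumed sparse: each
species is directly affected by only a few others. The M-step regressions are
therefore solved with an L1 path estimator: a lasso coordinate-descent path
(scikit-learn) generates candidate supports, the extended Bayesian
information criterion (EBIC, gamma = 0.5) selects one, and ordinary least
squares on the selected support gives the final, de-biased coefficients
(relaxed lasso). This keeps the estimator fully deterministic while retaining
the selection behaviour of a Bayesian lasso with sparsity-favouring defaults.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from sklearn.linear_model import lasso_path


def _log_binom(p: int, k: int) -> float:
    return float(gammaln(p + 1) - gammaln(k + 1) - gammaln(p - k + 1))


def _ols(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ coef
    return coef, float(resid @ resid)


def fit_ols(Z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Plain least squares with intercept; returns (intercept, coef, rss)."""
    n = Z.shape[0]
    D = np.column_stack([np.ones(n), Z])
    coef, rss = _ols(D, y)
    return float(coef[0]), coef[1:], rss


def fit_sparse(
    Z: np.ndarray,
    y: np.ndarray,
    gamma: float = 0.5,
    n_alphas: int = 50,
    eps: float = 1e-3,
) -> tuple[float, np.ndarray, float]:
    """Relaxed lasso with EBIC model selection.

    Parameters
    ----------
    Z : (n, p) design matrix (no intercept column; an unpenalized intercept
        is always included).
    y : (n,) response.
    gamma : EBIC sparsity weight in [0, 1]; 0.5 is the standard choice for
        p comparable to n.

    Returns
    -------
    (intercept, coef, rss) with ``coef`` exactly zero off the selected
    support and OLS-refit values on it.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Z.shape
    if n <= p + 1:
        raise ValueError(
            f"rank-deficient design: {n} usable points for {p + 1} parameters"
        )
    sd = Z.std(axis=0)
    active_cols = sd > 0
    Zs = np.zeros_like(Z)
    Zs[:, active_cols] = (Z[:, active_cols] - Z[:, active_cols].mean(axis=0)) / sd[active_cols]
    yc = y - y.mean()

    _, coefs, _ = lasso_path(Zs, yc, alphas=n_alphas, eps=eps)

    # candidate supports along the path (deduplicated), scored by EBIC with
    # an OLS refit so that shrinkage does not distort the criterion. The RSS
    # is floored relative to the response scale so that an exactly-fitting
    # model does not send the log-likelihood term to -inf and erase the
    # complexity penalty (the floor decides ties among perfect fits in
    # favour of the most parsimonious support).
    rss_floor = n * 1e-20 * max(float(np.var(y)), 1e-300)
    seen: set[tuple[int, ...]] = set()
    best = (np.inf, ())  # (ebic, support)
    supports = [tuple(np.flatnonzero(coefs[:, k] != 0)) for k in range(coefs.shape[1])]
    supports.append(())  # always consider the empty model
    for supp in supports:
        if supp in seen or len(supp) >= n - 1:
            continue
        seen.add(supp)
        cols = list(supp)
        D = np.column_stack([np.ones(n)] + ([Z[:, cols]] if cols else []))
        _, rss = _ols(D, y)
        rss = max(rss, rss_floor)
        k = len(cols)
        ebic = n * np.log(rss / n) + k * np.log(n) + 2.0 * gamma * _log_binom(p, k)
        if ebic < best[0]:
            best = (ebic, supp)

    cols = list(best[1])
    D = np.column_stack([np.ones(n)] + ([Z[:, cols]] if cols else []))
    full_coef, rss = _ols(D, y)
    coef = np.zeros(p)
    coef[cols] = full_coef[1:]
    return float(full_coef[0]), coef, rss
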