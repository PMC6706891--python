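"""From reference-relative EM estimates back to gLV parameters and networks.

The EM works in the transformed coordinates ``b_ij = beta_ij - beta_rj``.
Because interaction matrices are sparse, most entries of each column of
``beta`` are zero, so the median of column ``j`` of ``b`` estimates
``-beta_rj``; adding it back recovers all rows. Growth rates are not sparse
and are recovered by solving the original gLV equations point-wise with the
estimated biomass and ``beta``, taking the median of the positive per-time
estimates for robustness. Confidence in each interaction is a Z-score-like
ratio of the estimate to its column's spread.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .em import EMResult
from .preprocess import PreprocessedData, robust_gradient
from .sparse import fit_ols, fit_sparse

logger = logging.getLogger("beem")


def recover_beta(b: np.ndarray, r: int) -> np.ndarray:
    """Recover the full (p, p) interaction matrix from (p-1, p) ``b``.

    Per column ``j``: ``beta_rj = -median_i b_ij`` (sparsity makes the median
    of each column of ``beta`` zero), then ``beta_ij = b_ij + beta_rj``.
    """
    n_alr, p = b.shape
    if n_alr != p - 1:
        raise ValueError(f"b must be (p-1, p); got {b.shape}")
    beta_r = -np.median(b, axis=0)
    beta = np.empty((p, p))
    rows = [i for i in range(p) if i != r]
    beta[rows, :] = b + beta_r[None, :]
    beta[r, :] = beta_r
    return beta


def confidence_scores(beta_hat: np.ndarray) -> np.ndarray:
    """Z-score-like confidence ``s_ij = |beta_ij / sigma_j|``.

    ``sigma_j`` is the standard deviation of column ``j`` over its
    off-diagonal entries; self-interactions are systematically large and
    would inflate it. An all-constant column gets scores 0 with a warning.
    """
    p = beta_hat.shape[0]
    if p < 3:
        raise ValueError("confidence scores require at least 3 species")
    off = ~np.eye(p, dtype=bool)
    s = np.zeros_like(beta_hat)
    for j in range(p):
        sigma = beta_hat[off[:, j], j].std(ddof=1)
        if sigma == 0:
            logger.warning("confidence_scores: column %d has zero spread; scores set to 0", j)
            continue
        s[:, j] = np.abs(beta_hat[:, j]) / sigma
    return s


def recover_growth_rates(
    pre: PreprocessedData,
    m: np.ndarray,
    beta: np.ndarray,
    tau: float = 5.0,
) -> np.ndarray:
    """Per-species growth rates from the original gLV equations.

    With absolute abundance ``x_i = m_t x~_i``, the model gives
    ``mu_i = d ln x_i/dt - sum_j beta_ij m_t x~_jt``; the log-derivative is
    split as ``d ln m/dt + d ln x~_i/dt`` with each part estimated by the
    robust spline smoother per replicate. The final estimate per species is
    the median of the strictly positive per-time values over retained
    (non-equilibrium) time points; a species with no positive estimate is
    reported as NaN with a warning.
    """
    p = beta.shape[0]
    mu_samples: list[list[float]] = [[] for _ in range(p)]
    for rep, idx in enumerate(pre.rep_slices()):
        t = pre.time_flat[idx]
        if t.size < 2:
            continue
        Xz = pre.Xz[rep]
        m_rep = m[idx]
        dlnm, _ = robust_gradient(np.log(m_rep), t, tau=tau)
        keep_t = pre.gradients.eq_keep[rep]
        interaction = beta @ (m_rep[None, :] * Xz)  # (p, T)
        for i in range(p):
            dlnx, out = robust_gradient(np.log(Xz[i]), t, tau=tau)
            est = dlnm + dlnx - interaction[i]
            ok = keep_t & ~out
            mu_samples[i].extend(est[ok][est[ok] > 0].tolist())
    mu = np.full(p, np.nan)
    for i in range(p):
        if mu_samples[i]:
            mu[i] = float(np.median(mu_samples[i]))
        else:
            logger.warning("no positive growth-rate estimate for species %d", i)
    return mu


def params_from_em(
    pre: PreprocessedData, result: EMResult, sparse: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Final (mu, beta) from an EM run.

    ``sparse=True`` (default): median-column recovery of ``beta`` from ``b``
    plus gLV-based growth rates. ``sparse=False``: re-fit the gLV system
    directly by ordinary least squares on abundances scaled by the estimated
    biomass, with no shrinkage and no median-column step.
    """
    if sparse:
        beta = recover_beta(result.b_hat, result.reference_index)
        mu = recover_growth_rates(pre, result.m_hat, beta)
        return mu, beta
    m_by_rep = [result.m_hat[idx] for idx in pre.rep_slices()]
    return fit_glv_direct(pre, m_by_rep, sparse_mode="ols")


def fit_glv_direct(
    pre: PreprocessedData,
    m_by_rep: list[np.ndarray],
    sparse_mode: str = "ebic",
    tau: float = 5.0,
    robust_filters: bool = False,
    equilibrium_exclusion: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient matching in absolute-abundance space with known biomass.

    For given per-sample scaling factors, regress ``d ln x_i/dt`` (spline
    estimate on the scaled series) on ``[1, x_1 .. x_p]`` per species:
    intercepts are ``mu_i``, coefficients are rows of ``beta``. This is the
    estimator shared by all fixed-scaling benchmark conditions (noise-free
    biomass, raw relative abundance, noisy qPCR, CSS), so condition
    differences isolate the quality of the scaling factors.

    The equilibrium-time-point exclusion and the MAD/LOESS outlier layers
    are refinements of the EM method itself and default to off here: this
    is the plain gradient-matching baseline, fitted to every sample. Set
    ``robust_filters=True`` for data with genuine spikes, and
    ``equilibrium_exclusion=True`` to drop near-static samples whose
    gradients are noise-dominated.
    """
    from .preprocess import detrend_gradient_outliers  # local to avoid cycle noise

    p = pre.X_flat.shape[0]
    rows_grad, rows_x, rows_valid = [], [], []
    for rep, idx in enumerate(pre.rep_slices()):
        t = pre.time_flat[idx]
        Xz = pre.Xz[rep]
        x_abs = m_by_rep[rep][None, :] * Xz  # (p, T)
        if equilibrium_exclusion:
            keep_t = pre.gradients.eq_keep[rep]
        else:
            keep_t = np.ones(t.shape, dtype=bool)
        G = np.empty_like(x_abs)
        V = np.ones(x_abs.shape, dtype=bool)
        for i in range(p):
            if robust_filters:
                grad, out1 = robust_gradient(np.log(x_abs[i]), t, tau=tau)
                out2 = detrend_gradient_outliers(grad, t, tau=tau)
            else:
                grad, _ = robust_gradient(np.log(x_abs[i]), t, tau=np.inf)
                out1 = out2 = np.zeros(t.shape, dtype=bool)
            G[i] = grad
            V[i] = ~(out1 | out2) & keep_t
        rows_grad.append(G)
        rows_x.append(x_abs)
        rows_valid.append(V)
    Gf = np.concatenate(rows_grad, axis=1)
    Xf = np.concatenate(rows_x, axis=1)
    Vf = np.concatenate(rows_valid, axis=1)

    fit = fit_sparse if sparse_mode == "ebic" else fit_ols
    mu = np.empty(p)
    beta = np.empty((p, p))
    for i in range(p):
        mask = Vf[i]
        mu[i], beta[i], _ = fit(Xf.T[mask], Gf[i, mask])
    return mu, beta


def export_network(
    beta: np.ndarray,
    scores: np.ndarray,
    mean_abundance: np.ndarray,
    species_ids: list[str],
    threshold: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directed interaction edge list ``j -> i`` for off-diagonal entries
    with confidence above ``threshold``, plus a node table.

    Edge columns: source, target, sign (+1/-1), strength ``|beta_ij|``,
    confidence ``s_ij``. An empty network is allowed.
    """
    p = beta.shape[0]
    edges = []
    for i in range(p):
        for j in range(p):
            if i == j or scores[i, j] <= threshold or beta[i, j] == 0:
                continue
            edges.append(
                {
                    "source": species_ids[j],
                    "target": species_ids[i],
                    "sign": int(np.sign(beta[i, j])),
                    "strength": float(np.abs(beta[i, j])),
                    "confidence": float(scores[i, j]),
                }
            )
    edge_df = pd.DataFrame(edges, columns=["source", "target", "sign", "strength", "confidence"])
    node_df = pd.DataFrame(
        {"species_id": species_ids, "mean_relative_abundance": mean_abundance}
    )
    return edge_df, node_df


def consensus_edges(
    score_stack: list[np.ndarray],
    threshold: float = 1.0,
    min_fraction: float = 0.5,
    keep_if_large: bool = True,
) -> np.ndarray:
    """Edge stability across repeated runs (e.g. different seeds).

    Default keeps edges whose confidence exceeds ``threshold`` in at least
    ``min_fraction`` of the runs. ``keep_if_large=False`` applies the
    inverted literal rule (keep edges at or below the threshold in a majority
    of runs), exposed for completeness.
    """
    stack = np.stack(score_stack)
    if keep_if_large:
        frac = (stack > threshold).mean(axis=0)
        return frac >= min_fraction
    frac = (stack <= threshold).mean(axis=0)
    return frac > min_fraction
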