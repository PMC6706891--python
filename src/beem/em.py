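"""The biomass/parameter EM loop.

Relative abundances determine gLV dynamics only jointly with the unknown
per-sample total biomass ``m_t``. Writing the ALR-gradient model

    Y_it = a_i + m_t * sum_j b_ij * X~_jt + eps,   eps ~ Normal(0, sigma^2),

the two blocks of unknowns are conditionally linear in each other, so the
algorithm alternates:

* E-step - given (a, b), each sample's biomass is the slope of the
  no-intercept regression of ``U_ti = Y_it - a_i`` on
  ``V_ti = sum_j b_ij X~_jt`` over species ``i != r``, after removing
  boxplot outliers (deviation from the median beyond 1.5x IQR in U or V)
  and sign-discordant pairs (which would force a negative biomass).
* M-step - given ``m``, each species' (a_i, b_i.) comes from sparse
  gradient matching of ``Y_i.`` on the scaled abundances ``m_t X~_jt``.

Biomass is initialized from cumulative-sum-scaling factors; between
iterations, outlier biomass values are replaced by smoothing-spline
interpolation per replicate. Convergence is declared when the E-step mean
squared error, smoothed by a moving median of window 3, changes by less than
a tolerance (0.1% by default) for 3 consecutive iterations. Final estimates
are element-wise medians over all post-burn-in iterations whose MSE lies
within 5% of the minimum. The biomass scale is a gauge freedom - only the
products ``m_t * b_ij`` are identified - so reported biomass is normalized
to median one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import PreprocessedData, _sequential_spline_outliers
from .sparse import fit_ols, fit_sparse

logger = logging.getLogger("beem")


@dataclass
class TransformedParameters:
    """Reference-relative parameters the EM alternates over:
    ``a_i = mu_i - mu_r`` and ``b_ij = beta_ij - beta_rj`` for ``i != r``."""

    a: np.ndarray  # (p-1,)
    b: np.ndarray  # (p-1, p)
    reference_index: int
    sigma2: float

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("non-finite transformed parameters")


@dataclass
class BiomassSeries:
    """Per-sample biomass scaling factors; positive, identified only up to a
    global multiplicative constant (median-1 convention on output)."""

    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if np.any(self.m <= 0):
            raise ValueError("biomass factors must be positive")

    def normalized(self) -> np.ndarray:
        return self.m / np.median(self.m)


@dataclass
class EMConfig:
    max_iter: int = 100
    tol: float = 1e-3  # relative change of smoothed MSE, "0.1%"
    burn_in: int = 30
    mse_band: float = 0.05  # qualifying iterations: MSE within 5% of minimum
    sparse_mode: str = "ebic"  # "ebic" (sparse) or "ols" (non-sparse)
    tau: float = 5.0  # biomass-repair MAD threshold
    poor_fit_mse: float = 1e-5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_iter < 5:
            raise ValueError("max_iter must be at least 5")
        if self.sparse_mode not in ("ebic", "ols"):
            raise ValueError(f"unknown sparse_mode {self.sparse_mode!r}")


@dataclass
class EMTrace:
    biomass: list[np.ndarray] = field(default_factory=list)
    params: list[TransformedParameters] = field(default_factory=list)
    mse: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def iterations_run(self) -> int:
        return len(self.mse)


@dataclass
class EMResult:
    trace: EMTrace
    a_hat: np.ndarray
    b_hat: np.ndarray
    m_hat: np.ndarray  # median-1 normalized
    reference_index: int
    warnings: list[str]


# ---------------------------------------------------------------------------


def e_step(
    Y: np.ndarray,
    X: np.ndarray,
    params: TransformedParameters,
    valid: np.ndarray | None = None,
    m_prev: np.ndarray | None = None,
    min_pairs: int = 3,
) -> tuple[BiomassSeries, float]:
    """Per-sample biomass as the slope of U on V (no intercept).

    Outliers in U or V (beyond 1.5x IQR from the median) and sign-discordant
    pairs are removed before the fit. Samples with fewer than ``min_pairs``
    surviving pairs inherit the previous sample's estimate (or the previous
    iteration's value via ``m_prev``).

    Returns the biomass series and the mean squared residual over the pairs
    used for fitting.
    """
    n_alr, N = Y.shape
    if n_alr + 1 <= 6:
        logger.warning(
            "accurate estimation of biomass through this regression requires a "
            "sufficient number of data points (number of species > 6); got %d",
            n_alr + 1,
        )
    if valid is None:
        valid = np.ones(Y.shape, dtype=bool)
    U = Y - params.a[:, None]
    V = params.b @ X
    m = np.empty(N)
    sq_sum, n_pairs = 0.0, 0
    n_carried = 0
    for t in range(N):
        ok = valid[:, t].copy()
        if ok.sum() >= min_pairs:
            u, v = U[ok, t], V[ok, t]
            keep = np.ones(u.size, dtype=bool)
            for w in (u, v):
                iqr = np.subtract(*np.percentile(w, [75, 25]))
                if iqr > 0:
                    keep &= np.abs(w - np.median(w)) <= 1.5 * iqr
            keep &= u * v > 0
            u, v = u[keep], v[keep]
        else:
            u = np.empty(0)
        if u.size < min_pairs:
            n_carried += 1
            if t > 0:
                m[t] = m[t - 1]
            elif m_prev is not None:
                m[t] = m_prev[t]
            else:
                m[t] = 1.0
            continue
        m[t] = float(u @ v / (v @ v))
        resid = u - m[t] * v
        sq_sum += float(resid @ resid)
        n_pairs += u.size
    if n_pairs == 0:
        raise ValueError("no time point had enough surviving (U, V) pairs")
    if n_carried:
        logger.warning("E-step: %d sample(s) carried forward from previous estimate", n_carried)
    return BiomassSeries(m=m), sq_sum / n_pairs


def m_step(
    Y: np.ndarray,
    X: np.ndarray,
    m: np.ndarray,
    valid: np.ndarray | None = None,
    reference_index: int = 0,
    sparse_mode: str = "ebic",
) -> TransformedParameters:
    """Gradient matching: per species, regress ALR gradients on the scaled
    abundances ``m_t X~_jt`` (plus intercept) with a sparse penalty on the
    interaction coefficients."""
    n_alr, N = Y.shape
    p = X.shape[0]
    if valid is None:
        valid = np.ones(Y.shape, dtype=bool)
    scaled = (m[None, :] * X).T  # (N, p)
    a = np.empty(n_alr)
    b = np.empty((n_alr, p))
    rss_total, n_total = 0.0, 0
    bad: list[int] = []
    for i in range(n_alr):
        mask = valid[i]
        n_pts = int(mask.sum())
        if n_pts <= p + 1:
            bad.append(i)
            continue
        fit = fit_sparse if sparse_mode == "ebic" else fit_ols
        a[i], b[i], rss = fit(scaled[mask], Y[i, mask])
        rss_total += rss
        n_total += n_pts
    if bad:
        raise ValueError(
            f"rank-deficient design after filtering for species rows {bad}: "
            f"need more than {p + 1} usable points each"
        )
    return TransformedParameters(
        a=a, b=b, reference_index=reference_index, sigma2=rss_total / max(n_total, 1)
    )


def repair_biomass(
    m: np.ndarray,
    rep_slices: list[np.ndarray],
    times: np.ndarray,
    tau: float = 5.0,
) -> np.ndarray:
    """Replace outlier biomass values with spline-interpolated ones.

    Per replicate, on the log scale (biomass is positive and roughly
    log-normal): the sequential spline outlier rule flags robust-z
    outliers; the GCV spline fitted to the survivors supplies replacements.
    """
    out = m.copy()
    for idx in rep_slices:
        if idx.size < 6:
            continue
        t = times[idx]
        lm = np.log(m[idx])
        flags, spline = _sequential_spline_outliers(t, lm, tau)
        if np.any(flags):
            out[idx[flags]] = np.exp(spline(t[flags]))
    return out


def _smoothed_mse(mse: list[float]) -> list[float]:
    """Moving median with window 3 (shorter at the left edge)."""
    return [float(np.median(mse[max(0, i - 2): i + 1])) for i in range(len(mse))]


def run_em(pre: PreprocessedData, config: EMConfig | None = None) -> EMResult:
    """Full EM: CSS initialization, alternation, convergence detection and
    median aggregation over qualifying iterations."""
    config = config or EMConfig()
    warnings_out: list[str] = []
    p = pre.X_flat.shape[0]
    n_params_per_species = p + 1
    usable = int(pre.valid_flat[0].sum()) if pre.valid_flat.shape[0] else 0
    if usable <= n_params_per_species:
        msg = (
            f"insufficient data: {usable} usable points per species for "
            f"{n_params_per_species} parameters"
        )
        logger.warning(msg)
        warnings_out.append(msg)
    if p <= 6:
        msg = (
            "accurate estimation of biomass through this regression requires "
            f"a sufficient number of data points (number of species > 6); got {p}"
        )
        warnings_out.append(msg)

    rep_slices = pre.rep_slices()
    m = pre.css.copy()
    trace = EMTrace()
    smooth_hist: list[float] = []
    n_stable = 0
    for _ in range(config.max_iter):
        params = m_step(
            pre.Y_flat, pre.X_flat, m,
            valid=pre.valid_flat,
            reference_index=pre.reference_index,
            sparse_mode=config.sparse_mode,
        )
        biomass, mse = e_step(
            pre.Y_flat, pre.X_flat, params, valid=pre.evalid_flat, m_prev=m
        )
        m = repair_biomass(biomass.m, rep_slices, pre.time_flat, tau=config.tau)
        # fix the multiplicative gauge before storing: only m_t * b_ij is
        # identified, and element-wise medians across iterations are only
        # meaningful if every iteration uses the same gauge
        gauge = float(np.median(m))
        trace.params.append(
            TransformedParameters(
                a=params.a, b=params.b * gauge,
                reference_index=params.reference_index, sigma2=params.sigma2,
            )
        )
        trace.biomass.append(m / gauge)
        trace.mse.append(mse)
        smooth_hist = _smoothed_mse(trace.mse)
        if len(smooth_hist) >= 2 and smooth_hist[-2] > 0:
            rel = abs(smooth_hist[-1] - smooth_hist[-2]) / smooth_hist[-2]
            n_stable = n_stable + 1 if rel < config.tol else 0
        if n_stable >= 3:
            trace.converged = True
            break

    if not trace.converged:
        msg = f"EM did not converge within {config.max_iter} iterations"
        logger.warning(msg)
        warnings_out.append(msg)

    n_iter = trace.iterations_run
    burn = config.burn_in if n_iter > config.burn_in else n_iter // 2
    idx = np.arange(burn, n_iter)
    mse_post = np.asarray(trace.mse)[idx]
    qual = idx[mse_post <= (1.0 + config.mse_band) * mse_post.min()]
    a_hat = np.median(np.stack([trace.params[i].a for i in qual]), axis=0)
    b_hat = np.median(np.stack([trace.params[i].b for i in qual]), axis=0)
    m_hat = np.median(np.stack([trace.biomass[i] for i in qual]), axis=0)

    norm_mse = trace.mse[int(qual[-1])] / float(np.median(m_hat)) ** 2
    if norm_mse > config.poor_fit_mse:
        msg = f"poor fit to the data: biomass-normalized MSE {norm_mse:.3g} > {config.poor_fit_mse:g}"
        logger.warning(msg)
        warnings_out.append(msg)

    return EMResult(
        trace=trace,
        a_hat=a_hat,
        b_hat=b_hat,
        m_hat=m_hat / np.median(m_hat),
        reference_index=pre.reference_index,
        warnings=warnings_out,
    )
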