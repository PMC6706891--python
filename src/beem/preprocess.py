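"""From count tables to regression-ready gradients.

Sequencing yields per-sample proportions (relative abundances), which destroy
the absolute scale of the community. The additive log-ratio (ALR) transform
``y_i(t) = ln(x~_i(t) / x~_r(t))`` against a reference species ``r`` removes
the shared biomass term from the log-derivative equations, leaving

    dy_i/dt = a_i + m(t) * sum_j b_ij * x~_j(t),   i != r,

with ``a_i = mu_i - mu_r`` and ``b_ij = beta_ij - beta_rj``. This module
computes the left-hand side: it closes counts to proportions, picks the
reference (lowest coefficient of variation by default), estimates ``dy_i/dt``
by robust two-pass spline smoothing, masks outliers in both the abundances and
the estimated gradients, and drops near-equilibrium time points whose
gradients are dominated by noise. It also computes cumulative-sum-scaling
(CSS) factors used to initialize the biomass EM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.stats import median_abs_deviation
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger("beem")

#: cap on the fraction of points the sequential outlier-deletion pass may
#: remove from one series; protects against cascades on structured series.
MAX_OUTLIER_FRACTION = 0.2

DEFAULT_TAU = 5.0
DEFAULT_LOESS_SPAN = 0.75
DEFAULT_EQ_FRACTION = 0.8
DEFAULT_EQ_CHANGE = 0.05


# ---------------------------------------------------------------------------
# containers


@dataclass
class RelativeAbundanceSet:
    """Per-replicate relative-abundance matrices with their time grids.

    ``X`` columns sum to one; raw zeros are preserved here and only replaced
    by a pseudo-fraction at log-transform time (see :meth:`zero_replaced`).
    """

    X: list[np.ndarray]  # per replicate (p, T), columns sum to 1
    times: list[np.ndarray]
    species_ids: list[str]
    sample_ids: list[list[str]] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return self.X[0].shape[0]

    @property
    def n_replicates(self) -> int:
        return len(self.X)

    def min_positive(self) -> float:
        vals = [x[x > 0].min() for x in self.X if np.any(x > 0)]
        return float(min(vals))

    def zero_replaced(self) -> list[np.ndarray]:
        """Zeros replaced by half the smallest positive relative abundance
        in the dataset, columns renormalized; safe input for logs."""
        delta = 0.5 * self.min_positive()
        out = []
        for x in self.X:
            xz = np.where(x > 0, x, delta)
            out.append(xz / xz.sum(axis=0, keepdims=True))
        return out


@dataclass
class GradientTable:
    """Spline-estimated ALR gradients with validity masks.

    ``Y[rep]`` has one row per non-reference species, ordered as in
    ``alr_species``; ``valid[rep]`` marks the (species, time) points that
    survive the abundance- and gradient-outlier filters. The equilibrium
    filter is kept separately in ``eq_keep``: near-static samples are
    excluded from the gradient-matching (parameter) regressions, whose
    signal lives in the time derivatives, but not from the per-sample
    biomass regression, whose signal is the spread across species.
    """

    Y: list[np.ndarray]  # per replicate (p-1, T)
    valid: list[np.ndarray]  # per replicate (p-1, T) bool, outlier filters only
    reference_index: int
    alr_species: list[int]  # original indices of the p-1 non-reference rows
    eq_keep: list[np.ndarray]  # per replicate (T,) bool, equilibrium filter


@dataclass
class PreprocessedData:
    """Everything the EM engine consumes, in both per-replicate and
    flattened-sample layouts."""

    abundances: RelativeAbundanceSet
    Xz: list[np.ndarray]  # zero-replaced, renormalized (p, T)
    gradients: GradientTable
    css: np.ndarray  # per flattened sample, median-1 CSS factors (or ones)

    # flattened over replicates, N = total samples
    X_flat: np.ndarray  # (p, N)
    Y_flat: np.ndarray  # (p-1, N)
    valid_flat: np.ndarray  # (p-1, N) bool, outlier + equilibrium (M-step)
    evalid_flat: np.ndarray  # (p-1, N) bool, outlier filters only (E-step)
    rep_index: np.ndarray  # (N,) int
    time_flat: np.ndarray  # (N,)

    @property
    def reference_index(self) -> int:
        return self.gradients.reference_index

    @property
    def n_samples(self) -> int:
        return self.X_flat.shape[1]

    def rep_slices(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.rep_index == r) for r in range(len(self.Xz))]


# ---------------------------------------------------------------------------
# basic transforms


def relative_abundance(
    counts: list[np.ndarray],
    times: list[np.ndarray],
    species_ids: list[str] | None = None,
    sample_ids: list[list[str]] | None = None,
) -> RelativeAbundanceSet:
    """Close per-replicate count matrices to proportions."""
    X = []
    for c in counts:
        c = np.asarray(c, dtype=float)
        colsum = c.sum(axis=0)
        if np.any(colsum <= 0):
            raise ValueError("all-zero sample column in counts")
        X.append(c / colsum)
    p = X[0].shape[0]
    if species_ids is None:
        species_ids = [f"sp{i + 1}" for i in range(p)]
    return RelativeAbundanceSet(
        X=X,
        times=[np.asarray(t, dtype=float) for t in times],
        species_ids=list(species_ids),
        sample_ids=sample_ids or [],
    )


def filter_low_abundance(
    ra: RelativeAbundanceSet, min_mean_abundance: float = 1e-3
) -> RelativeAbundanceSet:
    """Drop species whose mean relative abundance across all samples is below
    ``min_mean_abundance`` (default 0.1%), then re-close the composition."""
    pooled = np.concatenate([x for x in ra.X], axis=1)
    keep = pooled.mean(axis=1) >= min_mean_abundance
    if not np.any(keep):
        raise ValueError("no species pass the abundance filter")
    X = [x[keep] / x[keep].sum(axis=0, keepdims=True) for x in ra.X]
    ids = [s for s, k in zip(ra.species_ids, keep) if k]
    return RelativeAbundanceSet(X=X, times=ra.times, species_ids=ids, sample_ids=ra.sample_ids)


def css_factors(counts: list[np.ndarray], quantile: float = 0.5) -> np.ndarray:
    """Cumulative-sum-scaling factors for the flattened samples.

    Per sample, the factor is the sum of counts at or below the ``quantile``
    of that sample's positive-count distribution, normalized to median one
    across samples. A sample with a single positive species falls back to its
    total count (with a warning). Used only to initialize the biomass.
    """
    factors = []
    for c in counts:
        c = np.asarray(c, dtype=float)
        for k in range(c.shape[1]):
            col = c[:, k]
            pos = col[col > 0]
            if pos.size == 0:
                raise ValueError("all-zero sample column in counts")
            if pos.size == 1:
                logger.warning("CSS: sample with a single positive species; using total sum")
                factors.append(col.sum())
                continue
            q = np.quantile(pos, quantile)
            factors.append(col[col <= q].sum())
    f = np.asarray(factors, dtype=float)
    med = np.median(f)
    if med <= 0:
        raise ValueError("degenerate CSS factors (median <= 0)")
    return f / med


def choose_reference(ra: RelativeAbundanceSet, override: int | None = None) -> int:
    """Reference species for the ALR transform: lowest pooled CV of relative
    abundance across all samples; ties broken by species order.

    Species with zero abundance in any sample are deprioritized (their log
    ratios would hinge entirely on the pseudo-fraction); if every species has
    a zero somewhere, the overall lowest-CV species is used with a warning.
    """
    if override is not None:
        return int(override)
    pooled = np.concatenate(ra.X, axis=1)
    mean = pooled.mean(axis=1)
    sd = pooled.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.inf)
    order = np.argsort(cv, kind="stable")
    never_zero = np.all(pooled > 0, axis=1)
    for idx in order:
        if never_zero[idx]:
            return int(idx)
    logger.warning(
        "every species has a zero count in some sample; reference %s has zeros",
        ra.species_ids[int(order[0])],
    )
    return int(order[0])


def alr_transform(Xz: np.ndarray, r: int) -> np.ndarray:
    """ALR transform ``y_i = ln(x~_i / x~_r)`` for all species ``i != r``.

    ``Xz`` must be strictly positive (zero-replaced).
    """
    if np.any(Xz <= 0):
        raise ValueError("alr_transform requires strictly positive abundances "
                         "(apply zero replacement first)")
    logx = np.log(Xz)
    rows = [i for i in range(Xz.shape[0]) if i != r]
    return logx[rows] - logx[r]


def alr_inverse(y: np.ndarray, r: int) -> np.ndarray:
    """Inverse ALR: softmax over the rows of ``y`` augmented with a zero row
    at the reference position."""
    p = y.shape[0] + 1
    full = np.zeros((p, y.shape[1]))
    rows = [i for i in range(p) if i != r]
    full[rows] = y
    e = np.exp(full - full.max(axis=0, keepdims=True))
    return e / e.sum(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# robust spline gradients


def _mad_outliers(e: np.ndarray, tau: float) -> np.ndarray:
    """Robust-z flags: ``(e - median(e)) / MAD(e) > tau``.

    MAD uses the normal-consistency scale (as R's ``mad``). A constant
    residual series (MAD = 0) flags nothing: no point can be an outlier of a
    constant series.
    """
    mad = median_abs_deviation(e, scale="normal")
    if mad == 0:
        return np.zeros(e.shape, dtype=bool)
    return (e - np.median(e)) / mad > tau


def _gcv_spline(t: np.ndarray, y: np.ndarray):
    """Cross-validated cubic smoothing spline (generalized cross-validation)."""
    return make_smoothing_spline(t, y, lam=None)


def _quintic_cv_spline(t: np.ndarray, y: np.ndarray, n_penalties: int = 15, folds: int = 5):
    """Order-5 smoothing spline with penalty chosen by k-fold cross-validation
    over a log-spaced grid.

    gLV time series combine a fast transient with a long plateau; a quintic
    spline tracks the transient's curvature, and choosing the smoothing
    level by held-out prediction error keeps it from chasing sequencing
    noise. Falls back to the cubic GCV spline when the series is too short
    for quintic fits.
    """
    import warnings as _warnings

    from scipy.interpolate import BSpline, splrep

    n = t.size
    if n < 9:
        return _gcv_spline(t, y)
    resid = y - np.polyval(np.polyfit(t, y, 1), t)
    s_hi = max(3.0 * float(resid @ resid), 1e-6)
    grid = np.logspace(np.log10(s_hi), -8, n_penalties)
    idx = np.arange(n)
    best = (np.inf, s_hi)
    with _warnings.catch_warnings():
        # FITPACK warns when a small smoothing target cannot be matched
        # exactly; the CV criterion already discards poorly converged fits
        _warnings.filterwarnings(
            "ignore", message="The maximal number of iterations", category=RuntimeWarning
        )
        for s in grid:
            err = 0.0
            for f in range(folds):
                test = idx[f::folds]
                test = test[(test > 0) & (test < n - 1)]  # endpoints anchor the fit
                if test.size == 0:
                    continue
                train = np.setdiff1d(idx, test)
                try:
                    tck = splrep(t[train], y[train], k=5, s=s * train.size / n)
                except Exception:
                    err = np.inf
                    break
                err += float(np.sum((BSpline(*tck)(t[test]) - y[test]) ** 2))
            if err < best[0]:
                best = (err, s)
        try:
            return BSpline(*splrep(t, y, k=5, s=best[1]))
        except Exception:
            return _gcv_spline(t, y)


def _sequential_spline_outliers(
    t: np.ndarray, y: np.ndarray, tau: float
) -> tuple[np.ndarray, object]:
    """Flag outliers by sequential deletion against a GCV smoothing spline.

    Repeatedly fit the cross-validated spline to the surviving points,
    compute robust z-scores of the absolute residuals,
    ``(e - median e) / MAD e``, and delete the single worst point while it
    exceeds ``tau``. gLV abundance series are smooth but have a fast early
    transient, so a rigid global trend would mistake the transient itself
    for outliers; scoring against the flexible cross-validated fit flags
    only points the data around them cannot explain. Deletion is capped at
    ``MAX_OUTLIER_FRACTION`` of the series.

    Returns (flag mask, spline fitted to the survivors).
    """
    n = t.size
    keep = np.ones(n, dtype=bool)
    max_drop = max(1, int(MAX_OUTLIER_FRACTION * n))
    spline = _quintic_cv_spline(t, y)
    for _ in range(max_drop):
        e = np.abs(y[keep] - spline(t[keep]))
        mad = median_abs_deviation(e, scale="normal")
        if mad == 0:
            break
        z = (e - np.median(e)) / mad
        worst = int(np.argmax(z))
        if z[worst] <= tau:
            break
        idx = np.flatnonzero(keep)[worst]
        keep[idx] = False
        if keep.sum() < 5:
            keep[idx] = True
            break
        spline = _quintic_cv_spline(t[keep], y[keep])
    return ~keep, spline


def robust_gradient(
    y: np.ndarray, times: np.ndarray, tau: float = DEFAULT_TAU
) -> tuple[np.ndarray, np.ndarray]:
    """Robust spline estimate of ``dy/dt`` at every observation time.

    Outliers are flagged by robust z-scores of absolute spline residuals,
    ``(e_t - median e) / MAD e > tau``, using sequential deletion against
    the cross-validated smoothing spline (see
    :func:`_sequential_spline_outliers`); the final GCV spline is fitted to
    the survivors and its analytic derivative is evaluated at all original
    times.

    Returns
    -------
    grad : (T,) derivative estimates at every original time point.
    outlier : (T,) bool, flagged points (to be excluded from downstream
        regressions).

    Series with fewer than 6 points fall back to finite differences with a
    warning.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 6:
        logger.warning("robust_gradient: only %d points; using finite differences", t.size)
        return np.gradient(y, t), np.zeros(t.shape, dtype=bool)

    outlier, spline = _sequential_spline_outliers(t, y, tau)
    return spline.derivative()(t), outlier


def detrend_gradient_outliers(
    Y_row: np.ndarray,
    times: np.ndarray,
    tau: float = DEFAULT_TAU,
    span: float = DEFAULT_LOESS_SPAN,
) -> np.ndarray:
    """Flag outliers in an estimated-gradient time series.

    A robust LOESS smoother (iterated bisquare reweighting, so spikes do not
    drag the local fit) de-trends the series; residuals are then subjected
    to the robust-z MAD rule used for abundance outliers. Gradient series
    are strongly heteroscedastic - variability is naturally larger during
    the fast transient than at the plateau - so residuals are first
    studentized by a local scale estimate (robust LOESS of the absolute
    residuals, floored at a fraction of the median scale); a global MAD on
    raw residuals would flag the transient itself. Returns a bool mask of
    flagged points (possibly empty); a constant series flags nothing.
    """
    t = np.asarray(times, dtype=float)
    Y_row = np.asarray(Y_row, dtype=float)
    if t.size < 6:
        return np.zeros(t.shape, dtype=bool)
    fit = lowess(Y_row, t, frac=span, it=3, return_sorted=False)
    e = np.abs(Y_row - fit)
    # degenerate: residuals at numerical noise level
    if np.max(e) < 1e-9 * max(1.0, float(np.ptp(Y_row))):
        return np.zeros(t.shape, dtype=bool)
    scale = lowess(e, t, frac=span, it=3, return_sorted=False)
    scale = np.maximum(scale, 0.3 * np.median(e))
    if np.all(scale <= 0):
        return np.zeros(t.shape, dtype=bool)
    flags = _mad_outliers(e / np.maximum(scale, 1e-300), tau)
    # a gradient artefact worth masking is large on the scale of the series
    # itself; this keeps smoother boundary misfit on noiseless series from
    # registering as outliers
    series_scale = median_abs_deviation(Y_row, scale="normal")
    return flags & (e > 0.3 * series_scale)


def equilibrium_filter(
    X: np.ndarray,
    eq_fraction: float = DEFAULT_EQ_FRACTION,
    eq_change: float = DEFAULT_EQ_CHANGE,
) -> np.ndarray:
    """Keep-mask over time points of one replicate; near-equilibrium samples
    are dropped.

    A time point is dropped when more than ``eq_fraction`` (default 80%) of
    the detected species changed by less than ``eq_change`` (default 5%) in
    relative abundance since the previous time point (forward differences;
    the first point is always kept). Relative change is ``|dx| / x_prev``; a
    species absent at the previous time point counts as changed if it is now
    present, and is not counted at all if absent at both.
    """
    p, T = X.shape
    keep = np.ones(T, dtype=bool)
    for k in range(1, T):
        prev, cur = X[:, k - 1], X[:, k]
        detected = (prev > 0) | (cur > 0)
        n_det = detected.sum()
        if n_det == 0:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(cur - prev) / prev
        changed_from_zero = (prev == 0) & (cur > 0)
        small = (rel < eq_change) & ~changed_from_zero & detected
        if small.sum() > eq_fraction * n_det:
            keep[k] = False
    return keep


# ---------------------------------------------------------------------------
# full pipeline


def compute_gradients(
    ra: RelativeAbundanceSet,
    reference: int | None = None,
    tau: float = DEFAULT_TAU,
    loess_span: float = DEFAULT_LOESS_SPAN,
    eq_fraction: float = DEFAULT_EQ_FRACTION,
    eq_change: float = DEFAULT_EQ_CHANGE,
) -> GradientTable:
    """ALR-transform each replicate and estimate gradients with all filters.

    Splines are fitted per species per replicate (replicates start from
    independent states, so a shared spline would be meaningless). The valid
    mask combines the abundance-outlier flags, the gradient-outlier flags and
    the equilibrium filter.
    """
    r = choose_reference(ra, reference)
    p = ra.n_species
    alr_species = [i for i in range(p) if i != r]
    Xz_list = ra.zero_replaced()
    Y_list, valid_list, eq_list = [], [], []
    for Xz, X_raw, t in zip(Xz_list, ra.X, ra.times):
        y = alr_transform(Xz, r)
        Y = np.empty_like(y)
        valid = np.ones(y.shape, dtype=bool)
        for i in range(y.shape[0]):
            grad, out1 = robust_gradient(y[i], t, tau=tau)
            out2 = detrend_gradient_outliers(grad, t, tau=tau, span=loess_span)
            Y[i] = grad
            valid[i] = ~(out1 | out2)
        eq_keep = equilibrium_filter(X_raw, eq_fraction, eq_change)
        if not np.any(eq_keep[1:]) and X_raw.shape[1] > 1:
            logger.warning("replicate appears to be at equilibrium throughout")
        Y_list.append(Y)
        valid_list.append(valid)
        eq_list.append(eq_keep)
    if not any(np.any(v & e[np.newaxis, :]) for v, e in zip(valid_list, eq_list)):
        raise ValueError("system at equilibrium; gLVM not identifiable")
    return GradientTable(
        Y=Y_list, valid=valid_list, reference_index=r, alr_species=alr_species, eq_keep=eq_list
    )


def preprocess(
    counts: list[np.ndarray] | None,
    times: list[np.ndarray],
    species_ids: list[str] | None = None,
    abundances: list[np.ndarray] | None = None,
    reference: int | None = None,
    min_mean_abundance: float = 0.0,
    tau: float = DEFAULT_TAU,
    loess_span: float = DEFAULT_LOESS_SPAN,
    eq_fraction: float = DEFAULT_EQ_FRACTION,
    eq_change: float = DEFAULT_EQ_CHANGE,
) -> PreprocessedData:
    """End-to-end preprocessing from counts (or proportions) to
    :class:`PreprocessedData` ready for the EM engine.

    Either ``counts`` (per-replicate integer matrices, used also for the CSS
    initialization factors) or ``abundances`` (proportion matrices; CSS
    factors default to one) must be given.
    """
    if counts is not None:
        ra = relative_abundance(counts, times, species_ids)
        css = css_factors(counts)
    elif abundances is not None:
        ra = relative_abundance(abundances, times, species_ids)
        css = np.ones(sum(x.shape[1] for x in ra.X))
    else:
        raise ValueError("provide counts or abundances")
    if min_mean_abundance > 0:
        ra = filter_low_abundance(ra, min_mean_abundance)
    grads = compute_gradients(
        ra, reference, tau=tau, loess_span=loess_span,
        eq_fraction=eq_fraction, eq_change=eq_change,
    )
    Xz = ra.zero_replaced()
    X_flat = np.concatenate(Xz, axis=1)
    Y_flat = np.concatenate(grads.Y, axis=1)
    evalid_flat = np.concatenate(grads.valid, axis=1)
    eq_flat = np.concatenate(grads.eq_keep)
    valid_flat = evalid_flat & eq_flat[np.newaxis, :]
    rep_index = np.concatenate(
        [np.full(x.shape[1], r_i, dtype=int) for r_i, x in enumerate(Xz)]
    )
    time_flat = np.concatenate(ra.times)
    return PreprocessedData(
        abundances=ra,
        Xz=Xz,
        gradients=grads,
        css=css,
        X_flat=X_flat,
        Y_flat=Y_flat,
        valid_flat=valid_flat,
        evalid_flat=evalid_flat,
        rep_index=rep_index,
        time_flat=time_flat,
    )
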