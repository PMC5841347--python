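"""Spatial statistics: weights, Moran's I, OLS and SAR spatial-error models.

Assemblage-level responses (mean egg elongation per nest type, proportion of
dome-nesting species) are regressed on VPD, LAI and their interaction.
Because neighbouring cells share species and climate, OLS residuals are
usually spatially autocorrelated; Moran's I correlograms diagnose this and
a simultaneous autoregressive (SAR) *error* model corrects it:

    y = X beta + u,   u = lambda W u + eps,   eps ~ N(0, sigma^2 I)

fitted by maximum likelihood with the log-Jacobian log|I - lambda W| taken
from the eigenvalues of W (computed once per weights matrix).  Model fit is
summarised with Nagelkerke's pseudo-R^2 against a non-spatial
intercept-only null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# spatial weights
# ---------------------------------------------------------------------------

class WeightsError(ValueError):
    pass


@dataclass
class SpatialWeights:
    """Distance-band neighbour weights for a set of cell centroids.

    Neighbours are pairs with Euclidean centroid distance <= threshold
    (inclusive), no self-neighbours.  ``style='binary'`` gives weight 1 per
    pair; ``'row_standardised'`` scales each non-empty row to sum 1.
    """

    n: int
    neighbors: list  # per-cell int arrays
    weights: list    # per-cell float arrays
    style: str
    threshold: float
    _dense: np.ndarray | None = field(default=None, repr=False)
    _eigs: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_centroids(cls, centroids, threshold: float = 200_000.0,
                       style: str = "row_standardised") -> "SpatialWeights":
        pts = np.asarray(centroids, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise WeightsError("need at least 2 cells with (x, y) centroids")
        if not np.all(np.isfinite(pts)):
            raise WeightsError("non-finite centroid coordinates")
        if style not in ("binary", "row_standardised"):
            raise WeightsError(f"unknown coding scheme {style!r}")
        n = pts.shape[0]
        dist = squareform(pdist(pts))
        adj = (dist <= threshold) & ~np.eye(n, dtype=bool)
        degrees = adj.sum(axis=1)
        n_isolated = int(np.count_nonzero(degrees == 0))
        if n_isolated == n:
            raise WeightsError("no spatial structure: all cells isolated")
        if n_isolated:
            logger.info("%d isolated cell(s) (no neighbour within %.0f m)",
                        n_isolated, threshold)
        neighbors, wts = [], []
        for i in range(n):
            idx = np.flatnonzero(adj[i])
            neighbors.append(idx)
            if style == "binary" or idx.size == 0:
                wts.append(np.ones(idx.size))
            else:
                wts.append(np.full(idx.size, 1.0 / idx.size))
        return cls(n, neighbors, wts, style, float(threshold))

    # -- derived quantities ------------------------------------------------

    def dense(self) -> np.ndarray:
        if self._dense is None:
            W = np.zeros((self.n, self.n))
            for i, (idx, w) in enumerate(zip(self.neighbors, self.weights)):
                W[i, idx] = w
            self._dense = W
        return self._dense

    @property
    def degrees(self) -> np.ndarray:
        return np.array([idx.size for idx in self.neighbors])

    @property
    def n_isolated(self) -> int:
        return int(np.count_nonzero(self.degrees == 0))

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of W used for the SAR log-Jacobian.

        Binary weights are symmetric; for row-standardised weights (no empty
        rows) the spectrum equals that of the similar symmetric matrix
        D^{-1/2} B D^{-1/2}, which is what is diagonalised.
        """
        if self._eigs is None:
            if self.style == "binary":
                self._eigs = np.linalg.eigvalsh(self.dense())
            else:
                d = self.degrees.astype(float)
                if np.any(d == 0):
                    raise WeightsError(
                        "row-standardised eigenvalues undefined with isolated "
                        "cells; subset to non-isolated cells first"
                    )
                B = (self.dense() > 0).astype(float)
                s = 1.0 / np.sqrt(d)
                self._eigs = np.linalg.eigvalsh(B * np.outer(s, s))
        return self._eigs

    def s0_s1_s2(self):
        W = self.dense()
        s0 = W.sum()
        s1 = 0.5 * ((W + W.T) ** 2).sum()
        rows = W.sum(axis=1)
        cols = W.sum(axis=0)
        s2 = ((rows + cols) ** 2).sum()
        return float(s0), float(s1), float(s2)

    def subset(self, idx) -> "SpatialWeights":
        """Weights restricted to a subset of cells (rebuilt, re-standardised)."""
        idx = np.asarray(idx)
        lookup = -np.ones(self.n, dtype=int)
        lookup[idx] = np.arange(idx.size)
        W = self.dense()[np.ix_(idx, idx)]
        neighbors, wts = [], []
        for i in range(idx.size):
            nz = np.flatnonzero(W[i] > 0)
            neighbors.append(nz)
            if self.style == "binary" or nz.size == 0:
                wts.append(np.ones(nz.size))
            else:
                wts.append(np.full(nz.size, 1.0 / nz.size))
        return SpatialWeights(idx.size, neighbors, wts, self.style, self.threshold)

    def nonisolated_subset(self):
        """(weights, index) for the cells that have at least one neighbour."""
        keep = np.flatnonzero(self.degrees > 0)
        if keep.size == self.n:
            return self, np.arange(self.n)
        return self.subset(keep), keep

    def to_triplets(self):
        """Sparse (i, j, w) triplet rows for export/cross-checking."""
        rows = []
        for i, (idx, w) in enumerate(zip(self.neighbors, self.weights)):
            rows.extend((i, int(j), float(wij)) for j, wij in zip(idx, w))
        return rows


def build_weights(centroids, threshold: float = 200_000.0,
                  style: str = "row_standardised") -> SpatialWeights:
    """Distance-band spatial weights from projected centroids (metres)."""
    return SpatialWeights.from_centroids(centroids, threshold, style)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    i_stat: float
    expected: float
    variance: float
    z: float
    p_value: float
    distance_class: tuple | None = None
    n_pairs: int | None = None


def morans_i(values, weights: SpatialWeights, permutations: int = 0,
             seed: int | None = None) -> MoranResult:
    """Moran's I with the analytic normality-null variance.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centred
    values.  ``permutations > 0`` adds a seeded permutation p-value in place
    of the analytic two-sided normal p.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n != weights.n:
        raise ValueError("values length does not match weights")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("zero variance: Moran's I undefined for constant values")
    W = weights.dense()
    s0, s1, s2 = weights.s0_s1_s2()
    if s0 == 0.0:
        raise ValueError("weights sum to zero")
    i_stat = float(n / s0 * (z @ W @ z) / denom)
    e_i = -1.0 / (n - 1)
    var = (n * n * s1 - n * s2 + 3.0 * s0 * s0) / (s0 * s0 * (n * n - 1)) - e_i**2
    zscore = (i_stat - e_i) / np.sqrt(var) if var > 0 else np.nan
    if permutations > 0:
        rng = np.random.default_rng(seed)
        sims = np.empty(permutations)
        for k in range(permutations):
            zp = rng.permutation(z)
            sims[k] = n / s0 * (zp @ W @ zp) / denom
        n_extreme = np.count_nonzero(np.abs(sims - e_i) >= abs(i_stat - e_i))
        p = (n_extreme + 1) / (permutations + 1)
    else:
        p = 2.0 * stats.norm.sf(abs(zscore)) if np.isfinite(zscore) else np.nan
    return MoranResult(i_stat, e_i, float(var), float(zscore), float(p))


def correlogram(values, centroids, n_classes: int = 20,
                class_width: float = 100_000.0) -> list[MoranResult]:
    """Moran's I per half-open distance band [k*w, (k+1)*w), binary weights.

    Bands with no pairs are reported with NaN statistics (missing).
    """
    x = np.asarray(values, dtype=float)
    pts = np.asarray(centroids, dtype=float)
    n = x.size
    dist = squareform(pdist(pts))
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("zero variance: correlogram undefined for constant values")
    out = []
    for k in range(n_classes):
        lo, hi = k * class_width, (k + 1) * class_width
        adj = (dist >= lo) & (dist < hi) & ~np.eye(n, dtype=bool)
        band = (float(lo), float(hi))
        n_pairs = int(adj.sum() // 2)
        if n_pairs == 0:
            out.append(MoranResult(np.nan, -1.0 / (n - 1), np.nan, np.nan,
                                   np.nan, band, 0))
            continue
        W = adj.astype(float)
        s0 = W.sum()
        s1 = 0.5 * ((W + W.T) ** 2).sum()
        s2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
        i_stat = float(n / s0 * (z @ W @ z) / denom)
        e_i = -1.0 / (n - 1)
        var = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - e_i**2
        zs = (i_stat - e_i) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(zs))
        out.append(MoranResult(i_stat, e_i, float(var), float(zs), float(p),
                               band, n_pairs))
    return out


# ---------------------------------------------------------------------------
# regression models
# ---------------------------------------------------------------------------

DESIGN_NAMES = ("intercept", "vpd", "lai", "vpd:lai")


def build_design(vpd, lai, interaction: bool = True):
    """Design matrix [1, vpd, lai, vpd*lai] and its column names."""
    vpd = np.asarray(vpd, dtype=float)
    lai = np.asarray(lai, dtype=float)
    cols = [np.ones_like(vpd), vpd, lai]
    names = ["intercept", "vpd", "lai"]
    if interaction:
        cols.append(vpd * lai)
        names.append("vpd:lai")
    return np.column_stack(cols), names


@dataclass
class OLSFit:
    beta: np.ndarray
    names: list
    sigma2: float       # ML estimate RSS/n
    log_lik: float
    r2: float
    residuals: np.ndarray
    se: np.ndarray
    p_values: np.ndarray


def _check_rank(X: np.ndarray, names):
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify the offending columns via QR pivoting on correlations
        _, Rq = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1]) if abs(Rq[i, i]) < 1e-10]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or names}")


def ols_fit(y, X, names=None) -> OLSFit:
    """Ordinary least squares with Gaussian log-likelihood and residuals."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    if y.size <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    _check_rank(X, names)
    res = sm.OLS(y, X).fit()
    return OLSFit(
        beta=res.params.copy(),
        names=list(names),
        sigma2=float(res.ssr / y.size),
        log_lik=float(res.llf),
        r2=float(res.rsquared),
        residuals=res.resid.copy(),
        se=res.bse.copy(),
        p_values=res.pvalues.copy(),
    )


@dataclass
class SARFit:
    lam: float
    beta: np.ndarray
    names: list
    sigma2: float
    log_lik: float
    log_lik_null: float
    pseudo_r2: float
    #: 'nagelkerke', or 'cox_snell' when the Nagelkerke rescaling is
    #: undefined (positive null log-likelihood, possible for continuous
    #: responses with tiny variance)
    pseudo_r2_kind: str
    lam_bounds: tuple
    residuals: np.ndarray    # u = y - X beta
    innovations: np.ndarray  # (I - lam W) u, spatially filtered
    se: np.ndarray
    converged: bool = True
    boundary: bool = False


def _sar_grams(y, X, W):
    """Cross-product matrices making the profile likelihood O(k^3) per lambda."""
    Z = np.column_stack([X, y])
    WZ = W @ Z
    return Z.T @ Z, Z.T @ WZ, WZ.T @ WZ


def _sar_profile_loglik(lam, grams, eigs, n, k):
    C0, C1, C2 = grams
    M = C0 - lam * (C1 + C1.T) + lam * lam * C2
    Mxx, mxy, myy = M[:k, :k], M[:k, k], M[k, k]
    beta = np.linalg.solve(Mxx, mxy)
    rss = myy - mxy @ beta
    if rss <= 0:
        return -np.inf, beta, 0.0
    sigma2 = rss / n
    logdet = float(np.sum(np.log(1.0 - lam * eigs)))
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet
    return float(ll), beta, float(sigma2)


def intercept_only_loglik(y) -> float:
    """Gaussian ML log-likelihood of the non-spatial intercept-only model."""
    y = np.asarray(y, dtype=float)
    s2 = float(np.mean((y - y.mean()) ** 2))
    if s2 == 0.0:
        raise ValueError("zero-variance response")
    return -0.5 * y.size * (np.log(2.0 * np.pi * s2) + 1.0)


def sar_error_fit(y, X, weights: SpatialWeights, names=None,
                  boundary_tol: float = 1e-4,
                  fixed_lambda: float | None = None) -> SARFit:
    """Maximum-likelihood SAR spatial-error fit via the profile likelihood.

    For each candidate lambda the GLS coefficients and error variance have
    closed forms, so only lambda is searched (bounded scalar optimisation
    inside the stability interval given by the reciprocal extreme
    eigenvalues of W).  The log-Jacobian uses the eigenvalues of W computed
    once.  Rows without neighbours are not allowed — subset the cells first.

    ``fixed_lambda`` skips the search and evaluates the profile at the given
    value (0 recovers OLS exactly).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    if n < 10:
        raise ValueError("SAR fit needs at least 10 observations")
    if weights.n != n:
        raise ValueError("weights dimension does not match data")
    if weights.n_isolated:
        raise WeightsError(
            "SAR fit requires every cell to have a neighbour; use "
            "SpatialWeights.nonisolated_subset() first"
        )
    _check_rank(X, names)
    eigs = weights.eigenvalues()
    w_min, w_max = float(eigs.min()), float(eigs.max())
    if w_max <= 0 or w_min >= 0:  # pragma: no cover - needs a pathological graph
        raise WeightsError("weights spectrum does not bracket zero")
    lo, hi = 1.0 / w_min, 1.0 / w_max
    margin = 1e-8 * (hi - lo)
    W = weights.dense()
    grams = _sar_grams(y, X, W)

    def neg_ll(lam):
        return -_sar_profile_loglik(lam, grams, eigs, n, k)[0]

    if fixed_lambda is None:
        opt = optimize.minimize_scalar(
            neg_ll, bounds=(lo + margin, hi - margin), method="bounded",
            options={"xatol": 1e-9},
        )
        lam = float(opt.x)
        converged = bool(opt.success)
    else:
        if not lo < fixed_lambda < hi:
            raise ValueError("fixed_lambda outside the stability interval")
        lam = float(fixed_lambda)
        converged = True
    ll, beta, sigma2 = _sar_profile_loglik(lam, grams, eigs, n, k)
    boundary = min(lam - lo, hi - lam) < boundary_tol * (hi - lo)
    if boundary:
        warnings.warn("SAR lambda at the edge of its stability interval "
                      "(boundary solution)", stacklevel=2)
    u = y - X @ beta
    innov = u - lam * (W @ u)
    XA = X - lam * (W @ X)
    cov = sigma2 * np.linalg.inv(XA.T @ XA)
    ll_null = intercept_only_loglik(y)
    try:
        pr2 = nagelkerke_r2(ll, ll_null, n)
        pr2_kind = "nagelkerke"
    except ValueError:
        # rescaling undefined; report the likelihood-ratio (Cox-Snell) R^2,
        # which for a Gaussian ML fit equals a classical R^2 and stays in [0,1)
        pr2 = float(np.clip(1.0 - np.exp(-(2.0 / n) * (ll - ll_null)),
                            0.0, 1.0 - 1e-15))
        pr2_kind = "cox_snell"
    return SARFit(
        lam=lam, beta=beta, names=list(names), sigma2=sigma2, log_lik=ll,
        log_lik_null=ll_null, pseudo_r2=pr2, pseudo_r2_kind=pr2_kind,
        lam_bounds=(lo, hi),
        residuals=u, innovations=innov, se=np.sqrt(np.diag(cov)),
        converged=converged, boundary=boundary,
    )


def nagelkerke_r2(log_lik_model: float, log_lik_null: float, n: int) -> float:
    """Nagelkerke's rescaled likelihood-ratio pseudo-R^2 in [0, 1).

    Cox-Snell R^2 = 1 - exp(-(2/n)(llM - ll0)), divided by its maximum
    attainable value 1 - exp((2/n) ll0).
    """
    if log_lik_model < log_lik_null - 1e-8:
        raise ValueError("model log-likelihood below the null's")
    r2_cs = 1.0 - np.exp(-(2.0 / n) * (log_lik_model - log_lik_null))
    divisor = 1.0 - np.exp((2.0 / n) * log_lik_null)
    if divisor <= 0:
        raise ValueError(
            "Nagelkerke divisor non-positive (null log-likelihood >= 0); "
            "the rescaling is undefined for this likelihood"
        )
    return float(np.clip(r2_cs / divisor, 0.0, 1.0 - 1e-15))


def predict_percentile_curves(fit, vpd_grid, lai_values: dict | None = None,
                              lai_data=None):
    """Trend predictions X beta over a VPD grid at fixed LAI values.

    ``lai_values`` maps labels to LAI levels; by default the 5th percentile,
    mean and 95th percentile of ``lai_data`` are used.  The spatial error
    component is excluded — these are mean-response curves.
    Returns a list of (label, lai, vpd_array, predicted_array).
    """
    if lai_values is None:
        if lai_data is None:
            raise ValueError("provide lai_values or lai_data")
        lai_data = np.asarray(lai_data, dtype=float)
        lai_values = {
            "p05": float(np.quantile(lai_data, 0.05)),
            "mean": float(lai_data.mean()),
            "p95": float(np.quantile(lai_data, 0.95)),
        }
    vpd_grid = np.asarray(vpd_grid, dtype=float)
    names = list(fit.names)
    if "vpd:lai" not in names:
        raise ValueError("fitted model lacks the vpd:lai interaction term")
    beta = {nm: b for nm, b in zip(names, fit.beta)}
    curves = []
    for label, lai in lai_values.items():
        pred = (beta["intercept"] + beta["vpd"] * vpd_grid + beta["lai"] * lai
                + beta["vpd:lai"] * vpd_grid * lai)
        curves.append((label, float(lai), vpd_grid.copy(), pred))
    return curves
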