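"""EM fit of the two-component nearest-neighbour distance mixture.

The observed-data density of a distance d from survey year y is

    L_y(d) = (1 - pi) * g_y(d) + pi * f(d, sigma)

with g_y the empirical density of random-point nearest-neighbour distances
(the uniform anthropogenic component) and f a half-Gaussian (the natural
component). The E-step computes per-record natural-origin probabilities

    W_i = pi * f(d_i, sigma) / L_{y_i}(d_i)

and the M-step updates pi = sum(W_i)/n and sigma = sqrt(sum(W_i d_i^2) /
sum(W_i)); iteration stops when neither pi nor sigma moves by more than the
tolerance (1e-5 by default). Records are labelled natural when W_i >= 0.5.

`OriginClassifier` wraps the whole chain (nearest-neighbour distances,
yearly g densities, EM, thresholding) as a scikit-learn style transductive
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .density import estimate_g_all, half_normal_pdf
from .neighbors import nn_distances
from .series import ANTHROPOGENIC, NATURAL, OccurrenceSeries

__all__ = ["EMResult", "em_fit", "classify", "OriginClassifier"]


@dataclass
class EMResult:
    """Converged mixture fit.

    pi : probability that a record is of natural origin
    sigma : half-Gaussian scale (km)
    W : per-record natural-origin probability, aligned with the fitted
        distances
    log_likelihood : observed-data log-likelihood per iteration
        (non-decreasing)
    """

    pi: float
    sigma: float
    W: np.ndarray
    n_iter: int
    converged: bool
    log_likelihood: np.ndarray = field(repr=False, default=None)


def _m_step(W, d):
    """Mixture weight and half-Gaussian scale updates."""
    W = np.asarray(W, dtype=float)
    d = np.asarray(d, dtype=float)
    pi = W.mean()
    sw = W.sum()
    if sw == 0:
        raise ValueError("sum of W is zero; sigma update undefined")
    sigma = float(np.sqrt((W * d**2).sum() / sw))
    return float(pi), sigma


def em_fit(d, years, g_by_year, pi0=0.5, sigma0=None, tol=1e-5, max_iter=1000):
    """Fit the mixture by EM.

    Parameters
    ----------
    d : array of usable nearest-neighbour distances (km)
    years : year label per distance; each must have an entry in `g_by_year`
    g_by_year : mapping year -> EmpiricalNNDensity
    pi0, sigma0 : initial values (sigma0 defaults to the RMS of d)
    tol : convergence tolerance on both pi and sigma
    max_iter : iteration cap; non-convergence is flagged, not raised

    Returns
    -------
    EMResult
    """
    d = np.asarray(d, dtype=float)
    years = np.asarray(years, dtype=int)
    if d.size < 2:
        raise ValueError("EM needs at least two usable distances")
    if np.any(~np.isfinite(d)):
        raise ValueError("non-finite distances in the EM sample")

    g_vals = np.empty_like(d)
    for y in np.unique(years):
        if y not in g_by_year:
            raise ValueError(f"no g density for year {y}")
        sel = years == y
        g_vals[sel] = g_by_year[y](d[sel])

    if sigma0 is None:
        sigma0 = float(np.sqrt(np.mean(d**2)))
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive (are all distances zero?)")

    pi, sigma = float(pi0), float(sigma0)
    W = np.full_like(d, pi)
    lls = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        f_vals = half_normal_pdf(d, sigma)
        denom = np.maximum((1.0 - pi) * g_vals + pi * f_vals, 1e-300)
        W = pi * f_vals / denom
        lls.append(float(np.log(denom).sum()))
        pi_new, sigma_new = _m_step(W, d)
        if sigma_new <= 0:
            raise ValueError("sigma collapsed to zero during EM")
        done = abs(pi_new - pi) <= tol and abs(sigma_new - sigma) <= tol
        pi, sigma = pi_new, sigma_new
        if done:
            converged = True
            break
    return EMResult(
        pi=pi,
        sigma=sigma,
        W=W,
        n_iter=n_iter,
        converged=converged,
        log_likelihood=np.asarray(lls),
    )


def classify(result, threshold=0.5):
    """Origin labels from natural-origin probabilities: natural when
    W_i >= threshold (a tie at the threshold counts as natural)."""
    W = np.asarray(result.W if isinstance(result, EMResult) else result, dtype=float)
    return np.where(W >= threshold, NATURAL, ANTHROPOGENIC).astype(object)


class OriginClassifier(BaseEstimator):
    """Transductive origin classifier for invasion occurrence records.

    Fits the EM mixture of corrected nearest-neighbour distances and labels
    each record natural or anthropogenic. Like a clustering estimator it
    labels the records it is fitted on (`labels_` / `fit_predict`).

    Parameters
    ----------
    window : SpatialWindow, required unless X is an OccurrenceSeries
    n_mc : Monte-Carlo replicates per yearly g density
    pi0 : initial natural-origin probability
    tol : EM convergence tolerance on pi and sigma
    threshold : natural-origin probability threshold for labelling
    max_iter : EM iteration cap
    g_window : optional sub-window for the random points of g (e.g. one
        island when the species never occurs on the other)
    random_state : seed for the Monte-Carlo draws

    Attributes
    ----------
    pi_, sigma_ : fitted mixture parameters
    W_ : per-record natural-origin probability (NaN for records excluded
        from the EM sample)
    labels_ : per-record origin labels; the excluded earliest record is the
        introduction itself and is labelled natural
    distances_ : the NNDistanceSet used
    """

    def __init__(
        self,
        window=None,
        n_mc=10000,
        pi0=0.5,
        tol=1e-5,
        threshold=0.5,
        max_iter=1000,
        g_window=None,
        random_state=None,
    ):
        self.window = window
        self.n_mc = n_mc
        self.pi0 = pi0
        self.tol = tol
        self.threshold = threshold
        self.max_iter = max_iter
        self.g_window = g_window
        self.random_state = random_state

    def _as_series(self, X):
        if isinstance(X, OccurrenceSeries):
            return X
        if self.window is None:
            raise ValueError("window must be set when X is not an OccurrenceSeries")
        return OccurrenceSeries(
            X if hasattr(X, "columns") else
            {"x": np.asarray(X)[:, 0], "y": np.asarray(X)[:, 1],
             "year": np.asarray(X)[:, 2]},
            self.window,
        )

    def fit(self, X, y=None):
        series = self._as_series(X)
        ndist = nn_distances(series)
        rng = np.random.default_rng(self.random_state)
        g = estimate_g_all(series, n_mc=self.n_mc, rng=rng, window=self.g_window)
        usable = ndist.usable
        result = em_fit(
            ndist.d[usable],
            ndist.years[usable],
            g,
            pi0=self.pi0,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        n = len(series)
        W = np.full(n, np.nan)
        W[usable] = result.W
        labels = np.full(n, NATURAL, dtype=object)
        labels[usable] = classify(result, self.threshold)
        self.series_ = series
        self.distances_ = ndist
        self.result_ = result
        self.pi_ = result.pi
        self.sigma_ = result.sigma
        self.W_ = W
        self.labels_ = labels
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    @property
    def anthropogenic_fraction_(self):
        """Fraction of records labelled anthropogenic."""
        return float(np.mean(self.labels_ == ANTHROPOGENIC))
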