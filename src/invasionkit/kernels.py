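"""The exponential-power dispersal kernel and the cluster analysis that
motivates fixing its shape.

The one-dimensional kernel is

    f(x) = C / (2 * alpha * Gamma(1/C)) * exp(-|x / alpha|^C)

with distance parameter alpha (km) and shape parameter C; C=1 is the
Laplace (negative-exponential) kernel and C=2 the Gaussian, while C<1 gives
fat tails. Dispersal distances are |x| truncated at a maximum distance dmax
by rejection, which preserves the relative shape on [0, dmax].

`cluster_kernels` reproduces the design analysis: single-generation point
sets for a grid of (alpha, C) combinations are compared by the sum of
squared differences of their Ripley K-curves, the dissimilarity matrix is
embedded by classical multidimensional scaling, and K-means across a range
of k locates a small number of mutually indistinguishable kernel groups —
the justification for estimating alpha only, with C fixed at 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gennorm
from sklearn.cluster import KMeans

from .ripley import KCurve, k_function
from .window import SpatialWindow

__all__ = [
    "KernelSpec",
    "epk_pdf",
    "sample_distance",
    "cluster_kernels",
    "detect_elbow",
    "KernelClusterResult",
]


@dataclass(frozen=True)
class KernelSpec:
    """Exponential-power dispersal kernel parameters.

    alpha : distance parameter (km), > 0
    C : shape parameter, > 0 (1 = Laplace, 2 = Gaussian)
    dmax : maximum dispersal distance (km), > 0
    """

    alpha: float
    C: float = 2.0
    dmax: float = 30.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.dmax <= 0:
            raise ValueError("dmax must be positive")


def epk_pdf(x, spec):
    """Exponential-power density on the real line.

    `spec` may be a KernelSpec or an (alpha, C) pair. The density equals
    scipy's generalized-normal family with beta=C and scale=alpha.
    """
    if not isinstance(spec, KernelSpec):
        alpha, C = spec
        spec = KernelSpec(alpha=alpha, C=C, dmax=1.0)
    return gennorm.pdf(np.asarray(x, dtype=float), spec.C, scale=spec.alpha)


def sample_distance(spec, rng=None, size=None):
    """Draw dispersal distances |x| with x exponential-power distributed,
    truncated at dmax by rejection.

    Returns a scalar when `size` is None, else an array of that size.
    Raises after bounded retries when the acceptance rate is ~0
    (dmax << alpha).
    """
    rng = np.random.default_rng(rng)
    n = 1 if size is None else int(size)
    out = np.empty(n, dtype=float)
    got = 0
    for _ in range(200):
        m = max(2 * (n - got), 64)
        draw = np.abs(gennorm.rvs(spec.C, scale=spec.alpha, size=m, random_state=rng))
        keep = draw[draw <= spec.dmax]
        k = min(keep.size, n - got)
        out[got : got + k] = keep[:k]
        got += k
        if got == n:
            return float(out[0]) if size is None else out
    raise RuntimeError(
        f"truncated kernel sampling failed: acceptance rate ~0 for "
        f"alpha={spec.alpha}, dmax={spec.dmax}"
    )


def detect_elbow(ks, wss):
    """Elbow of a within-group-sum-of-squares curve: the k with the largest
    second difference (the sharpest bend). A piecewise-linear curve with a
    single breakpoint returns that breakpoint exactly."""
    ks = np.asarray(ks)
    wss = np.asarray(wss, dtype=float)
    if ks.size < 3:
        raise ValueError("elbow detection needs at least three k values")
    d2 = wss[:-2] - 2.0 * wss[1:-1] + wss[2:]
    return int(ks[1:-1][int(np.argmax(d2))])


@dataclass
class KernelClusterResult:
    """K-means grouping of (alpha, C) kernel combinations.

    grid : list of (alpha, C) pairs, one per single-generation dataset
    dissimilarity : symmetric matrix of K-curve sum-of-squared-differences
    wss_by_k : within-group sum of squares per candidate k
    elbow_k : chosen number of clusters
    assignment : cluster id per grid cell at the elbow k
    """

    grid: list
    dissimilarity: np.ndarray
    embedding: np.ndarray = field(repr=False)
    wss_by_k: dict
    elbow_k: int
    assignment: np.ndarray

    def alpha_centroids(self):
        """Mean alpha of each cluster, sorted ascending."""
        alphas = np.array([a for a, _ in self.grid])
        cents = [alphas[self.assignment == c].mean() for c in np.unique(self.assignment)]
        return np.sort(cents)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "alpha": [a for a, _ in self.grid],
                "C": [c for _, c in self.grid],
                "cluster": self.assignment,
            }
        )


def _single_generation(spec, n_points, rng):
    """Points dispersed from a common source at the origin."""
    d = sample_distance(spec, rng, size=n_points)
    theta = rng.uniform(0.0, 2.0 * np.pi, n_points)
    return np.column_stack([d * np.cos(theta), d * np.sin(theta)])


def _classical_mds(D, n_dims):
    """Classical MDS of a squared-distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = min(n_dims, int((vals > 1e-9).sum()))
    return vecs[:, :keep] * np.sqrt(np.maximum(vals[:keep], 0.0))


def cluster_kernels(
    alphas=None,
    Cs=None,
    dmax=10.0,
    n_points=300,
    k_range=range(1, 11),
    rng=None,
    radii=None,
    n_embed=10,
    n_restarts=25,
):
    """Group (alpha, C) kernel combinations by the spatial similarity of the
    single-generation point sets they produce.

    Defaults follow the design analysis: alpha from 1 to 7 in steps of 0.2,
    C from 0.25 to 2.5 in steps of 0.25, maximum dispersal distance 10. Each
    combination generates one dataset of `n_points` points dispersed from a
    common source; K-curves are computed in a disc window of radius dmax
    around the source and compared pairwise by sum of squared differences.
    """
    rng = np.random.default_rng(rng)
    if alphas is None:
        alphas = np.round(np.arange(1.0, 7.0 + 1e-9, 0.2), 10)
    if Cs is None:
        Cs = np.round(np.arange(0.25, 2.5 + 1e-9, 0.25), 10)
    alphas = np.asarray(alphas, dtype=float)
    Cs = np.asarray(Cs, dtype=float)
    if alphas.size == 0 or Cs.size == 0:
        raise ValueError("parameter grids must be non-empty")
    if radii is None:
        # single-generation patterns differ most well below dmax: at large
        # radii every K-curve saturates and the comparison loses power, so
        # the default grid spans a quarter of the maximum dispersal distance
        radii = np.linspace(0.0, dmax / 4.0, 11)

    window = SpatialWindow.disc((0.0, 0.0), dmax)
    grid = [(float(a), float(c)) for a in alphas for c in Cs]
    curves = np.empty((len(grid), len(radii)), dtype=float)
    for i, (a, c) in enumerate(grid):
        pts = _single_generation(KernelSpec(alpha=a, C=c, dmax=dmax), n_points, rng)
        curves[i] = k_function(pts, window, radii).K

    diff = curves[:, None, :] - curves[None, :, :]
    D = np.einsum("ijk,ijk->ij", diff, diff)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)

    emb = _classical_mds(D, n_embed)
    seed = int(rng.integers(2**31))
    wss = {}
    labels_by_k = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(emb)
        wss[int(k)] = float(km.inertia_)
        labels_by_k[int(k)] = km.labels_
    ks = sorted(wss)
    elbow = detect_elbow(ks, [wss[k] for k in ks])
    return KernelClusterResult(
        grid=grid,
        dissimilarity=D,
        embedding=emb,
        wss_by_k=wss,
        elbow_k=elbow,
        assignment=labels_by_k[elbow],
    )
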