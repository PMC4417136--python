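"""Community-matrix preprocessing, Bray-Curtis distances and NMDS ordination.

The ordination is non-metric multidimensional scaling in the classical
Kruskal formulation: configuration distances are fitted to the dissimilarity
ranks by monotone (isotonic) regression, and the configuration is updated by
SMACOF majorization until Kruskal stress-1,

    stress = sqrt( sum (dhat_ij - d_ij)^2 / sum d_ij^2 ),

stops changing.  Multiple starts are used (one start is the principal
coordinates configuration, the rest are random Gaussian clouds) and the best
solution is kept.  Because an NMDS solution is only defined up to rotation,
translation, reflection and scale, the returned scores are centred, scaled to
unit root-mean-square, rotated to their principal axes and sign-pinned, so
identical seeds give identical output arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.optimize import isotonic_regression as _pava
from skbio import DistanceMatrix

from .io import InputError, OtuTable

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "average_subsamples",
    "bray_curtis",
    "choose_k",
    "filter_rare",
    "nmds",
    "ordination_fit",
    "stress_profile",
]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def average_subsamples(table: OtuTable) -> OtuTable:
    """Cell-wise arithmetic mean of each sample's subsample rows.

    Returns a table with one row per sample (the subsample id is the sample
    id itself), in the original sample order.
    """
    means = table.values.groupby(level="sample_id", sort=False).mean()
    means = means.loc[table.sample_ids]
    idx = pd.MultiIndex.from_arrays([means.index, means.index],
                                    names=["sample_id", "subsample_id"])
    out = means.copy()
    out.index = idx
    return OtuTable(out)


def filter_rare(table: OtuTable, threshold: float) -> OtuTable:
    """Drop OTUs present in no more than ``threshold`` of subsample rows.

    Presence means abundance strictly greater than zero, assessed at the
    subsample level (before averaging).  An OTU is retained iff its presence
    fraction is strictly greater than ``threshold``, so with the default 0.07
    an OTU seen in 11 of 168 subsamples (6.5 %) is removed and one seen in 12
    (7.1 %) is kept.
    """
    if not 0 <= threshold <= 1:
        raise InputError("threshold must lie in [0, 1]")
    presence = (table.values.to_numpy() > 0).mean(axis=0)
    keep = presence > threshold
    if not keep.any():
        raise InputError(
            f"rare-taxon filter at threshold {threshold} removed every OTU"
        )
    return OtuTable(table.values.loc[:, keep])


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    ``D_ij = 1 - 2 * sum_k min(x_ik, x_jk) / (sum_k x_ik + sum_k x_jk)``.
    Requires one row per sample (average subsamples first).
    """
    if table.n_subsamples != table.n_samples:
        raise InputError("bray_curtis needs one row per sample; average subsamples first")
    x = table.matrix()
    zero = x.sum(axis=1) == 0
    if zero.any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(zero)]
        raise InputError(f"all-zero sample row(s) make Bray-Curtis undefined: {bad}")
    d = pdist(x, metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=[str(s) for s in table.sample_ids])


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    """A k-axis NMDS solution.

    ``scores`` is an n x k array, centred, unit-RMS, principal-axis aligned;
    ``stress`` is Kruskal stress-1 of the best start.
    """

    labels: list
    scores: np.ndarray
    k: int
    stress: float
    n_starts: int
    converged: bool
    best_start: int

    def axis(self, i: int) -> np.ndarray:
        """1-based ordination axis."""
        return self.scores[:, i - 1]

    def distances(self) -> np.ndarray:
        """Condensed Euclidean distances between sample scores."""
        return pdist(self.scores)


def _disparities(
    dis: np.ndarray,
    d: np.ndarray,
    fixed_perm: np.ndarray | None,
) -> np.ndarray:
    """Monotone (PAVA) fit of configuration distances to dissimilarity order.

    Ties in the dissimilarities are handled by Kruskal's primary approach:
    within a tie block the pairs are ordered by their current configuration
    distance, so tied dissimilarities may receive unequal fitted values.
    When the dissimilarities are tie-free the sort order never changes and
    ``fixed_perm`` (precomputed once) is used directly.
    """
    perm = np.lexsort((d, dis)) if fixed_perm is None else fixed_perm
    dhat = np.empty_like(d)
    dhat[perm] = _pava(d[perm]).x
    return dhat


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(d * d))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def _guttman_update(x: np.ndarray, d: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, dhat / d, 0.0)
    b = -squareform(ratio)
    np.fill_diagonal(b, -b.sum(axis=1))
    return b @ x / n


def _align(scores: np.ndarray) -> np.ndarray:
    """Centre, unit-RMS scale, rotate to principal axes, pin signs."""
    x = scores - scores.mean(axis=0)
    rms = np.sqrt((x**2).sum() / x.shape[0])
    if rms > 0:
        x = x / rms
    # principal axes via SVD; stress-1 is invariant to this similarity
    # transform because the isotonic fit rescales with the distances.
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for j in range(x.shape[1]):
        if x[np.argmax(np.abs(x[:, j])), j] < 0:
            x[:, j] = -x[:, j]
    return x


def nmds(
    D: DistanceMatrix,
    k: int,
    n_starts: int = 20,
    seed: int | np.random.SeedSequence | list = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> Ordination:
    """Non-metric MDS of a distance matrix into ``k`` dimensions.

    Start 0 is the PCoA configuration of ``D``; the remaining ``n_starts - 1``
    starts are standard-Gaussian clouds.  Each start is polished by
    alternating isotonic fits and SMACOF majorization steps until the
    relative stress change drops below ``tol`` (or ``max_iter`` iterations);
    the lowest-stress solution is returned.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    if n_starts < 1:
        raise InputError("n_starts must be >= 1")
    dmat = np.asarray(D.data, dtype=float)
    n = dmat.shape[0]
    if n < 3:
        raise InputError("need at least 3 samples to ordinate")
    dis = squareform(dmat, checks=False)
    # with tie-free dissimilarities the isotonic sort order is constant
    fixed_perm = None
    if np.unique(dis).size == dis.size:
        fixed_perm = np.argsort(dis, kind="stable")

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    from .eigen import pcoa  # local import to avoid a cycle at module load

    evs = pcoa(D)
    init = np.zeros((n, k))
    m = min(k, evs.vectors.shape[1])
    if m:
        init[:, :m] = evs.vectors.to_numpy()[:, :m]
    if m < k:
        init[:, m:] = 1e-3 * rng.standard_normal((n, k - m))
    starts.append(init)
    for _ in range(n_starts - 1):
        starts.append(rng.standard_normal((n, k)))

    best = None
    for idx, x in enumerate(starts):
        x = np.array(x, dtype=float)
        d = pdist(x)
        if not d.any():
            x = x + 1e-8
            d = pdist(x)
        dhat = _disparities(dis, d, fixed_perm)
        stress = _stress1(d, dhat)
        converged = False
        for _ in range(max_iter):
            x = _guttman_update(x, d, dhat)
            d = pdist(x)
            dhat = _disparities(dis, d, fixed_perm)
            new = _stress1(d, dhat)
            done = abs(stress - new) < tol * max(stress, 1e-12)
            stress = new
            if done:
                converged = True
                break
        if best is None or stress < best[0]:
            best = (stress, x, converged, idx)

    stress, x, converged, idx = best
    return Ordination(
        labels=list(D.ids),
        scores=_align(x),
        k=k,
        stress=float(stress),
        n_starts=n_starts,
        converged=bool(converged),
        best_start=int(idx),
    )


def stress_profile(
    D: DistanceMatrix,
    k_max: int,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
) -> tuple[list[tuple[int, float]], dict[int, Ordination]]:
    """NMDS stress for k = 1 .. k_max, plus the fitted ordinations.

    Each dimensionality gets its own deterministic seed stream derived from
    ``seed`` so profiles are reproducible and individual k values can be
    refitted in isolation.
    """
    if k_max < 2:
        raise InputError("k_max must be >= 2")
    profile = []
    fits = {}
    for k in range(1, k_max + 1):
        ordn = nmds(D, k, n_starts=n_starts, seed=[seed, k], max_iter=max_iter)
        profile.append((k, ordn.stress))
        fits[k] = ordn
    return profile, fits


def choose_k(profile: list[tuple[int, float]], ceiling: float = 0.20) -> int:
    """Smallest dimensionality whose stress falls below ``ceiling``."""
    for k, stress in sorted(profile):
        if stress < ceiling:
            return k
    raise InputError(
        f"no dimensionality reaches stress < {ceiling}; profile = "
        + ", ".join(f"k={k}: {s:.3f}" for k, s in sorted(profile))
    )


# ---------------------------------------------------------------------------
# post hoc ordination fit (matrix regression with permutation inference)
# ---------------------------------------------------------------------------


def ordination_fit(
    ordination: Ordination,
    D_community: DistanceMatrix,
    n_permutations: int = 1000,
    seed: int | list = 0,
) -> tuple[float, float]:
    """How much community structure the ordination represents.

    Unfolds the lower triangles of (a) Euclidean distances between ordination
    scores and (b) the community dissimilarity matrix, regresses (b) on (a)
    by OLS, and reports the R-squared (a fraction in [0, 1]; multiply by 100
    for the percentage) together with a permutation p-value obtained by
    simultaneously shuffling the rows and columns of the response matrix.

    This is the two-matrix case of Mantel-style matrix regression; the
    permutation scheme (relabelling the samples of the response matrix) is
    what makes the test exact under exchangeability.
    """
    if n_permutations < 1:
        raise InputError("n_permutations must be >= 1")
    if list(ordination.labels) != list(D_community.ids):
        raise InputError("ordination and community matrix labels differ")
    x = ordination.distances()
    ymat = np.asarray(D_community.data, dtype=float)
    y = squareform(ymat, checks=False)

    def _r2(yv: np.ndarray) -> float:
        c = np.corrcoef(x, yv)[0, 1]
        return float(c * c)

    r2_obs = _r2(y)
    rng = np.random.default_rng(seed)
    n = ymat.shape[0]
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = squareform(ymat[np.ix_(perm, perm)], checks=False)
        if _r2(yp) >= r2_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return r2_obs, float(p)
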