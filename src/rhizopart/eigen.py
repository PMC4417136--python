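"""Eigenvector predictors from phylogenetic and spatial distance matrices.

Phylogenetic eigenvector regression (PVR) and spatial eigenvector filtering
share one primitive: principal coordinates analysis of a distance matrix.
The matrix is Gower double-centred, ``G = -1/2 C (D o D) C`` with
``C = I - 11'/n``, and eigendecomposed; eigenvectors belonging to positive
eigenvalues, scaled by the square root of their eigenvalue, are coordinates
that reproduce the (Euclidean part of the) input distances.  Leading axes of
the patristic distance matrix summarise deep-versus-shallow phylogenetic
structure; leading axes of the geographic distance matrix are broad spatial
gradients.  Negative eigenvalues (legal for non-Euclidean input such as
patristic distances) are reported but their axes are discarded, following
common PVR practice; no Lingoes/Cailliez correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .community import DistanceMatrix
from .io import InputError, Phylogeny, SampleFrame

__all__ = [
    "EigenvectorSet",
    "patristic_distances",
    "pcoa",
    "phylo_eigenvectors",
    "scree_break",
    "spatial_eigenvectors",
    "write_eigenvectors",
]


@dataclass
class EigenvectorSet:
    """Eigenvectors of a decomposed distance matrix.

    ``vectors`` is a labels x m DataFrame whose columns (``EV1``, ``EV2``,
    ...) are ordered by descending eigenvalue and scaled by sqrt(eigenvalue);
    ``eigenvalues`` holds the full descending spectrum, including any
    negative values whose axes were discarded.  ``broadcast`` marks a set
    whose species-level rows were expanded to sample level (such a set is
    only column-orthogonal under balanced replication, so the orthogonality
    check is skipped for it).
    """

    source: str  # "phylogenetic" | "spatial"
    vectors: pd.DataFrame
    eigenvalues: np.ndarray
    broadcast: bool = False

    def __post_init__(self):
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-10 * max(1.0, np.abs(ev).max())):
            raise InputError("eigenvalues must be sorted in descending order")
        self.eigenvalues = ev
        if not self.broadcast and self.vectors.shape[1] > 1:
            v = self.vectors.to_numpy()
            gram = v.T @ v
            off = gram - np.diag(np.diag(gram))
            if np.abs(off).max() > 1e-8 * max(1.0, np.abs(gram).max()):
                raise InputError("eigenvector columns are not orthogonal")

    @property
    def labels(self) -> list:
        return list(self.vectors.index)

    @property
    def n_axes(self) -> int:
        return self.vectors.shape[1]

    def take(self, m: int) -> "EigenvectorSet":
        """First ``m`` axes."""
        if m > self.n_axes:
            raise InputError(f"requested {m} axes but only {self.n_axes} available")
        return EigenvectorSet(
            source=self.source,
            vectors=self.vectors.iloc[:, :m],
            eigenvalues=self.eigenvalues,
            broadcast=self.broadcast,
        )

    def expand_to_samples(self, species_of_sample: pd.Series) -> "EigenvectorSet":
        """Broadcast species-level rows to one row per sample."""
        missing = sorted(set(species_of_sample) - set(self.vectors.index))
        if missing:
            raise InputError(f"species absent from eigenvector set: {missing}")
        rows = self.vectors.loc[species_of_sample.to_numpy()]
        rows.index = species_of_sample.index
        return EigenvectorSet(
            source=self.source,
            vectors=rows,
            eigenvalues=self.eigenvalues,
            broadcast=True,
        )


def write_eigenvectors(evs: EigenvectorSet, path) -> None:
    """Write an eigenvector table as TSV with the spectrum in a comment block."""
    with open(path, "w") as fh:
        fh.write(f"# source: {evs.source}\n")
        fh.write("# eigenvalues: "
                 + "\t".join(f"{v:.10g}" for v in evs.eigenvalues) + "\n")
        evs.vectors.to_csv(fh, sep="\t", index_label="label")


def pcoa(D: DistanceMatrix, eig_tol: float = 1e-9) -> EigenvectorSet:
    """Principal coordinates analysis by Gower double-centering.

    Eigenvectors with eigenvalue greater than ``eig_tol * max|eigenvalue|``
    are kept and scaled by sqrt(eigenvalue); the full spectrum (negative
    eigenvalues included) is reported in ``eigenvalues``.  Column signs are
    pinned so each axis's largest-magnitude element is positive.
    """
    d = np.asarray(D.data, dtype=float)
    n = d.shape[0]
    a = -0.5 * d * d
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    cutoff = eig_tol * max(1.0, np.abs(vals).max())
    pos = vals > cutoff
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    for j in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    frame = pd.DataFrame(
        coords,
        index=list(D.ids),
        columns=[f"EV{i + 1}" for i in range(coords.shape[1])],
    )
    source = "spatial"  # caller overrides for phylogenetic input
    return EigenvectorSet(source=source, vectors=frame, eigenvalues=vals)


def patristic_distances(phylogeny: Phylogeny) -> DistanceMatrix:
    """Sum of branch lengths along the tree path between every pair of tips."""
    dm = phylogeny.tree.tip_tip_distances()
    # reorder to the phylogeny's canonical tip order
    return DistanceMatrix(dm.filter(phylogeny.tip_names).data, ids=phylogeny.tip_names)


def phylo_eigenvectors(
    phylogeny: Phylogeny, frame: SampleFrame, n_screen: int = 7
) -> EigenvectorSet:
    """Sample-level phylogenetic eigenvector predictors (the PVR front end).

    Decomposes the species-level patristic distance matrix, keeps the first
    ``n_screen`` axes (the reference analysis screened the first seven after
    inspecting the eigenvalue scree), and broadcasts each species' eigenvector
    values to all of its samples, so every sample of a species carries
    identical predictor values.
    """
    if n_screen > phylogeny.n_tips - 1:
        raise InputError(
            f"n_screen={n_screen} exceeds n_tips-1={phylogeny.n_tips - 1}"
        )
    missing = sorted(set(frame.species) - set(phylogeny.tip_names))
    if missing:
        raise InputError(f"species in sample frame absent from tree: {missing}")
    decomp = pcoa(patristic_distances(phylogeny))
    decomp.source = "phylogenetic"
    if decomp.n_axes < n_screen:
        raise InputError(
            f"only {decomp.n_axes} positive axes available, n_screen={n_screen}"
        )
    return decomp.take(n_screen).expand_to_samples(frame.species)


def spatial_eigenvectors(frame: SampleFrame, n_keep: int = 2) -> EigenvectorSet:
    """Leading PCoA axes of the geographic distance matrix.

    For planar coordinates the Euclidean distance matrix is exactly
    embeddable, so the two leading axes span the same plane as the centred
    coordinates themselves; they are kept as the spatial predictors.
    """
    if n_keep < 1:
        raise InputError("n_keep must be >= 1")
    xy = frame.coordinates
    d = squareform(pdist(xy))
    decomp = pcoa(DistanceMatrix(d, ids=[str(s) for s in frame.sample_ids]))
    decomp.source = "spatial"
    if decomp.n_axes < n_keep:
        raise InputError(
            f"only {decomp.n_axes} positive spatial axes (need {n_keep}); "
            "are the sites collinear?"
        )
    kept = decomp.take(n_keep)
    kept.vectors.index = frame.data.index
    return kept


def scree_break(eigenvalues: np.ndarray) -> int:
    """Number of axes before the largest successive eigenvalue drop.

    Returns the index (1-based count of axes to keep) after the largest
    ratio ``lambda_i / lambda_{i+1}`` among positive eigenvalues; if all
    positive eigenvalues are equal the full count is returned.  Offered as an
    automated alternative to a fixed screening depth.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size < 2:
        raise InputError("need at least two eigenvalues")
    pos = ev[ev > 0]
    if pos.size == 0:
        raise InputError("no positive eigenvalues")
    if pos.size == 1:
        return 1
    ratios = pos[:-1] / pos[1:]
    if np.allclose(ratios, 1.0):
        return int(pos.size)
    return int(np.argmax(ratios) + 1)
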