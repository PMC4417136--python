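"""Synthetic rhizosphere study generator with known, tunable signal sources.

The generator emulates the reference sampling design — 7 plant genera x 2
congeneric species x 6 collection locations (84 soil samples) with 2 DNA
subsamples each — and injects four independently controllable sources of
community variation:

* **species identity**: per-OTU, per-species affinity offsets that carry no
  phylogenetic structure,
* **soil chemistry**: per-OTU loadings on the standardized chemistry table,
* **spatial location**: a smooth Gaussian random field per OTU,
* **plant phylogeny**: a Brownian-motion trait evolved on the plant tree, so
  congeners receive similar values.

Log-affinities are summed across channels, perturbed by sample- and
subsample-level noise, and pushed through a softmax to give compositional
peak-area profiles; peaks below a detection limit are zeroed and rows are
renormalized, which is what makes the rare-taxon filter meaningful.

By default the channels are residualized in-sample against the other
classes' design matrices (``orthogonal_channels=True``), so that switching
one weight on injects signal detectable by exactly one predictor class.
Without this projection a strong signal in any channel leaks into every
other class design through chance subspace overlap — an inherent feature of
observational designs, available here via ``orthogonal_channels=False`` for
studying confounded scenarios.  One exception is structural and no
projection can remove it: a phylogenetic trait is constant within species,
so the species factor always nests a phylogeny signal.

Chemistry marginals are calibrated to the reference site's printed summary
statistics (pH 6.07, range 5.01-8.03; organic matter mean 4.2 %; Na mean
91.8 ppm, range 12-390); the remaining assays use plausible agronomic values
for a coastal grassland.  All draws come from per-purpose seed streams fanned
out from one master seed, so changing one weight leaves every other draw
unchanged.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import CHEMISTRY_COLUMNS, InputError, OtuTable, Phylogeny, SampleFrame, read_newick

__all__ = [
    "ScenarioSpec",
    "SignalWeights",
    "simulate_chemistry",
    "simulate_community",
    "simulate_sites",
    "simulate_study",
    "simulate_tree",
]

# fixed stream ids: one per random purpose, so redrawing one component never
# perturbs another
_STREAM = {"tree": 11, "sites": 23, "chem": 37, "community": 53}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], int(seed), int(extra)])


@dataclass(frozen=True)
class SignalWeights:
    """Relative strength of each variation source, in log-affinity sd units.

    Each channel is standardized to unit variance before weighting, so the
    weights are directly comparable; ``noise_sd`` is unstructured per-sample
    noise and ``subsample_sd`` the extraction-replicate noise.  Defaults are
    calibrated so the default scenario reproduces the qualitative structure
    of the reference study: a four-axis ordination below the 0.20 stress
    ceiling, species identity the strongest class, chemistry next, then
    space, with phylogeny significant but weak.
    """

    w_species: float = 1.0
    w_chem: float = 0.9
    w_space: float = 1.0
    w_phylo: float = 0.7
    noise_sd: float = 0.65
    subsample_sd: float = 0.25

    def __post_init__(self):
        for name in ("w_species", "w_chem", "w_space", "w_phylo"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.noise_sd <= 0:
            raise InputError("noise_sd must be > 0")
        if self.subsample_sd < 0:
            raise InputError("subsample_sd must be >= 0")

    @classmethod
    def null(cls, noise_sd: float = 0.65, subsample_sd: float = 0.25) -> "SignalWeights":
        return cls(0.0, 0.0, 0.0, 0.0, noise_sd, subsample_sd)

    @classmethod
    def single(cls, channel: str, weight: float,
               noise_sd: float = 0.65, subsample_sd: float = 0.25) -> "SignalWeights":
        """All-zero weights except one named channel."""
        w = {"species": 0.0, "chem": 0.0, "space": 0.0, "phylo": 0.0}
        if channel not in w:
            raise InputError(f"unknown channel {channel!r}")
        w[channel] = weight
        return cls(w["species"], w["chem"], w["space"], w["phylo"],
                   noise_sd, subsample_sd)


@dataclass(frozen=True)
class ScenarioSpec:
    """A complete synthetic study design.

    The defaults mirror the reference design: 7 genera x 2 species x 6 sites
    = 84 samples, 2 subsamples each, sites at least 100 m apart within a
    5 km coastal terrace.
    """

    n_genera: int = 7
    species_per_genus: int = 2
    sites_per_species: int = 6
    subsamples_per_sample: int = 2
    n_otus: int = 150
    extent: float = 5000.0
    min_spacing: float = 100.0
    patch_sd: float | None = None  # default: extent / 2 (weak clustering)
    patch_rule: str = "random"  # or "phylogenetic"
    detection_limit: float = 0.002
    weights: SignalWeights = field(default_factory=SignalWeights)
    orthogonal_channels: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genera", "species_per_genus", "sites_per_species",
                     "subsamples_per_sample", "n_otus"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be >= 1")
        if self.n_genera < 2:
            raise InputError("need at least 2 genera to build a phylogeny")
        if self.min_spacing <= 0 or self.extent <= 0:
            raise InputError("extent and min_spacing must be positive")
        if self.patch_rule not in ("random", "phylogenetic"):
            raise InputError(f"unknown patch_rule {self.patch_rule!r}")
        if not 0 <= self.detection_limit < 1:
            raise InputError("detection_limit must lie in [0, 1)")

    @property
    def n_species(self) -> int:
        return self.n_genera * self.species_per_genus

    @property
    def n_samples(self) -> int:
        return self.n_species * self.sites_per_species

    def genus_names(self) -> list[str]:
        return [f"Genus{i + 1:02d}" for i in range(self.n_genera)]

    def species_names(self) -> list[str]:
        letters = string.ascii_lowercase
        if self.species_per_genus > len(letters):
            raise InputError("species_per_genus too large for naming scheme")
        return [
            f"{g}_{letters[j]}"
            for g in self.genus_names()
            for j in range(self.species_per_genus)
        ]


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------


def simulate_tree(spec: ScenarioSpec) -> Phylogeny:
    """Random ultrametric plant phylogeny for the scenario's species.

    Genus ancestors coalesce with a random (Kingman) topology; the tree is
    rescaled to unit height; each genus tip is then replaced by a clade of
    congeners splitting at a recent depth drawn uniformly from [0.05, 0.2]
    of tree height (capped below the genus's parent node, so a very shallow
    genus join cannot produce a negative branch).
    """
    rng = _rng(spec.seed, "tree")
    genera = spec.genus_names()
    # Kingman coalescent among genus lineages; nodes are either a genus name
    # (a leaf at height 0) or (height, left, right)
    lineages: list = list(genera)
    height = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        height += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        node = (height, a, b)
        lineages.append(node)
    root = lineages[0]
    root_h = root[0]

    letters = string.ascii_lowercase
    splits = {g: float(rng.uniform(0.05, 0.2)) for g in genera}

    def nw(node, parent_h: float) -> str:
        if isinstance(node, str):  # genus leaf -> clade of congeners
            if spec.species_per_genus == 1:
                return f"{node}_a:{parent_h:.10f}"
            s = min(splits[node], 0.9 * parent_h)
            tips = ",".join(
                f"{node}_{letters[j]}:{s:.10f}"
                for j in range(spec.species_per_genus)
            )
            return f"({tips}):{parent_h - s:.10f}"
        h, a, b = node
        # affine warp keeps genus divergences deeper than 0.25 of tree
        # height so every congener split in [0.05, 0.2] fits below them
        h = 0.25 + 0.75 * (h / root_h) if h < root_h else 1.0
        return f"({nw(a, h)},{nw(b, h)}):{parent_h - h:.10f}"

    _, a, b = root
    newick = f"({nw(a, 1.0)},{nw(b, 1.0)});"
    return read_newick(newick)


def tree_vcv(phylogeny: Phylogeny) -> pd.DataFrame:
    """Brownian-motion tip covariance: shared branch length from the root.

    ``V_ij = (depth_i + depth_j - d_ij) / 2`` where d is patristic distance.
    """
    from .eigen import patristic_distances

    d = patristic_distances(phylogeny)
    depths = phylogeny.depths().to_numpy()
    v = (depths[:, None] + depths[None, :] - np.asarray(d.data)) / 2.0
    return pd.DataFrame(v, index=phylogeny.tip_names, columns=phylogeny.tip_names)


# ---------------------------------------------------------------------------
# sites
# ---------------------------------------------------------------------------


def simulate_sites(spec: ScenarioSpec) -> SampleFrame:
    """Collection locations: a Gaussian patch per species inside the window.

    Every species gets ``sites_per_species`` points drawn about a
    species-specific patch centre; rejection sampling enforces the minimum
    within-species spacing and keeps points inside the square window.  Under
    ``patch_rule="phylogenetic"`` congeners share a genus-level patch centre
    (plus a small offset), making close relatives spatially close; under the
    default ``"random"`` rule centres are independent.
    """
    rng = _rng(spec.seed, "sites")
    patch_sd = spec.patch_sd if spec.patch_sd is not None else spec.extent / 2.0
    genera = spec.genus_names()
    centers: dict[str, np.ndarray] = {}
    genus_centers = {g: rng.uniform(0, spec.extent, size=2) for g in genera}
    lo, hi = 0.08 * spec.extent, 0.92 * spec.extent
    for sp_name in spec.species_names():
        genus = sp_name.rsplit("_", 1)[0]
        if spec.patch_rule == "phylogenetic":
            c = genus_centers[genus] + rng.normal(0, spec.extent / 10.0, size=2)
        else:
            c = rng.uniform(0, spec.extent, size=2)
        # keep patch centres inside the window so tight patches stay feasible
        centers[sp_name] = np.clip(c, lo, hi)

    rows = []
    for sp_name in spec.species_names():
        genus = sp_name.rsplit("_", 1)[0]
        pts: list[np.ndarray] = []
        rejections = 0
        while len(pts) < spec.sites_per_species:
            p = centers[sp_name] + rng.normal(0, patch_sd, size=2)
            ok = (0 <= p[0] <= spec.extent) and (0 <= p[1] <= spec.extent)
            if ok and pts:
                ok = min(np.hypot(*(p - q)) for q in pts) >= spec.min_spacing
            if ok:
                pts.append(p)
            else:
                rejections += 1
                if rejections > 10_000:
                    raise InputError(
                        "site placement failed after 10000 rejections; "
                        "increase the extent or reduce min_spacing"
                    )
        for k, p in enumerate(pts):
            rows.append(
                {
                    "sample_id": f"{sp_name}.{k + 1}",
                    "species": sp_name,
                    "genus": genus,
                    "x": p[0],
                    "y": p[1],
                }
            )
    data = pd.DataFrame(rows).set_index("sample_id")
    return SampleFrame(data)


# ---------------------------------------------------------------------------
# chemistry
# ---------------------------------------------------------------------------

# target marginals per assay: (mean, sd, low, high); pH, OM and Na follow the
# reference site's printed summaries, the rest are plausible agronomic values
_CHEM_MARGINALS = {
    "NO3_ppm": (8.0, 5.0, 0.5, 40.0),
    "P_olsen_ppm": (25.0, 12.0, 2.0, 80.0),
    "K_ppm": (180.0, 70.0, 40.0, 500.0),
    "K_meq": (0.46, 0.18, 0.10, 1.28),
    "Na_ppm": (91.8, 61.0, 12.0, 390.0),
    "Ca_meq": (6.5, 2.5, 1.0, 15.0),
    "Mg_meq": (3.0, 1.2, 0.5, 8.0),
    "CEC": (12.0, 4.0, 3.0, 30.0),
    "OM_pct": (4.2, 1.8, 0.6, 15.5),
    "pH": (6.07, 0.46, 5.01, 8.03),
}

# cross-assay structure: each standardized field is a mix of the base fields
# (rows: assay, cols: base field weights before renormalization); K in ppm
# and meq/100 g are near-duplicates, CEC tracks the major cations, OM loads
# weakly on CEC's driver
_CHEM_MIX = {
    "NO3_ppm": {"NO3_ppm": 1.0},
    "P_olsen_ppm": {"P_olsen_ppm": 1.0},
    "K_ppm": {"K_ppm": 1.0},
    "K_meq": {"K_ppm": 0.9, "K_meq": 0.436},
    "Na_ppm": {"Na_ppm": 1.0},
    "Ca_meq": {"Ca_meq": 1.0},
    "Mg_meq": {"Ca_meq": 0.5, "Mg_meq": 0.866},
    "CEC": {"Ca_meq": 0.55, "Mg_meq": 0.25, "K_ppm": 0.2, "Na_ppm": 0.15,
            "CEC": 0.75},
    "OM_pct": {"CEC": 0.4, "OM_pct": 0.917},
    "pH": {"pH": 1.0},
}


def _gaussian_field_chol(coords: np.ndarray, corr_range: float) -> np.ndarray:
    """Cholesky factor of an exponential-covariance field on the sites."""
    d = squareform(pdist(coords))
    cov = np.exp(-d / corr_range)
    return np.linalg.cholesky(cov + 1e-8 * np.eye(len(coords)))


def simulate_chemistry(
    frame: SampleFrame,
    spec: ScenarioSpec,
    nugget: float = 0.3,
    corr_range: float | None = None,
) -> SampleFrame:
    """Fill the ten chemistry assays with spatially autocorrelated fields.

    Each assay is a unit-variance mixture of exponential-covariance Gaussian
    fields (correlation range ``extent / 5`` unless overridden) plus an
    independent nugget (fraction ``nugget`` of the variance), affinely
    rescaled to the target marginal and clipped to its plausible range.  As
    the correlation range grows without bound the smooth component collapses
    to a site-wide constant and only the nugget varies between samples.
    """
    rng = _rng(spec.seed, "chem")
    coords = frame.coordinates
    if corr_range is None:
        corr_range = spec.extent / 5.0
    L = _gaussian_field_chol(coords, corr_range)
    n = len(frame)
    base = {}
    for name in CHEMISTRY_COLUMNS:
        f = L @ rng.standard_normal(n)
        z = rng.standard_normal(n)
        base[name] = np.sqrt(1 - nugget) * f + np.sqrt(nugget) * z
    chem = {}
    for name in CHEMISTRY_COLUMNS:
        mix = _CHEM_MIX[name]
        zfield = sum(w * base[src] for src, w in mix.items())
        zfield = zfield / np.sqrt(sum(w * w for w in mix.values()))
        mean, sd, low, high = _CHEM_MARGINALS[name]
        chem[name] = np.clip(mean + sd * zfield, low, high)
    chem_df = pd.DataFrame(chem, index=frame.data.index)
    return frame.with_chemistry(chem_df)


# ---------------------------------------------------------------------------
# community
# ---------------------------------------------------------------------------


def _residualize(channel: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Project the columns of ``channel`` off the span of ``nuisance``."""
    q, _ = np.linalg.qr(nuisance)
    return channel - q @ (q.T @ channel)


def _unit_scale(channel: np.ndarray) -> np.ndarray:
    sd = channel.std()
    return channel if sd == 0 else channel / sd


def simulate_community(
    frame: SampleFrame,
    phylogeny: Phylogeny,
    spec: ScenarioSpec,
    stream: int = 0,
) -> OtuTable:
    """Synthesize a TRFLP-style relative-abundance table.

    For OTU j in sample i the log-affinity is the weighted sum of the four
    standardized channels plus sample noise; subsample rows add replicate
    noise; a softmax turns affinities into compositions; peaks below the
    detection limit are zeroed and rows renormalized.  ``stream`` selects an
    independent community (e.g. 0 = bacterial, 1 = fungal) under the same
    master seed.
    """
    if not frame.has_chemistry:
        raise InputError("frame must carry chemistry before community simulation")
    missing = sorted(set(frame.species) - set(phylogeny.tip_names))
    if missing:
        raise InputError(f"species missing from tree: {missing}")
    rng = _rng(spec.seed, "community", extra=stream)
    w = spec.weights
    n = len(frame)
    J = spec.n_otus
    species = list(dict.fromkeys(frame.species))
    indicator = pd.get_dummies(frame.species, dtype=float)[species].to_numpy()

    # fixed nuisance designs used for channel orthogonalization
    from .eigen import phylo_eigenvectors, spatial_eigenvectors

    n_screen = min(7, phylogeny.n_tips - 1)
    E = phylo_eigenvectors(phylogeny, frame, n_screen).vectors.to_numpy()
    S = spatial_eigenvectors(frame, 2).vectors.to_numpy()
    Z = frame.chemistry_zscores().to_numpy()
    ones = np.ones((n, 1))

    # species channel: iid per-species offsets (no phylogenetic structure)
    A = rng.standard_normal((len(species), J))
    ch_species = indicator @ A
    # chemistry channel: iid loadings on the standardized assays
    B = rng.standard_normal((Z.shape[1], J))
    ch_chem = Z @ B / np.sqrt(Z.shape[1])
    # spatial channel: one broad Gaussian field per OTU
    Lsp = _gaussian_field_chol(frame.coordinates, spec.extent / 2.0)
    ch_space = Lsp @ rng.standard_normal((n, J))
    # phylogeny channel: Brownian trait per OTU, broadcast to samples
    V = tree_vcv(phylogeny).loc[species, species].to_numpy()
    Lph = np.linalg.cholesky(V + 1e-9 * np.eye(len(species)))
    ch_phylo = indicator @ (Lph @ rng.standard_normal((len(species), J)))
    # unstructured noise, drawn before any optional projection so that
    # toggling orthogonalization does not shift the noise stream
    eps = rng.standard_normal((n, J))
    baseline = rng.normal(0.0, 1.0, size=J)  # uneven OTU commonness
    sub_eps = rng.standard_normal((n * spec.subsamples_per_sample, J))

    if spec.orthogonal_channels:
        ch_species = _residualize(ch_species, np.hstack([ones, E, S, Z]))
        ch_chem = _residualize(ch_chem, np.hstack([indicator, S]))
        ch_space = _residualize(ch_space, np.hstack([indicator, Z]))
        ch_phylo = _residualize(ch_phylo, np.hstack([ones, S, Z]))
    else:
        ch_species = ch_species - ch_species.mean(axis=0)
        ch_chem = ch_chem - ch_chem.mean(axis=0)
        ch_space = ch_space - ch_space.mean(axis=0)
        ch_phylo = ch_phylo - ch_phylo.mean(axis=0)

    eta = (
        w.w_species * _unit_scale(ch_species)
        + w.w_chem * _unit_scale(ch_chem)
        + w.w_space * _unit_scale(ch_space)
        + w.w_phylo * _unit_scale(ch_phylo)
        + w.noise_sd * eps
        + baseline[None, :]
    )

    sub_labels = string.ascii_lowercase
    rows = []
    index = []
    r = 0
    for i, sid in enumerate(frame.sample_ids):
        for s in range(spec.subsamples_per_sample):
            row = eta[i] + w.subsample_sd * sub_eps[r]
            r += 1
            rows.append(row)
            index.append((sid, f"{sid}.{sub_labels[s % 26]}{s // 26 or ''}"))
    logits = np.asarray(rows)
    logits = logits - logits.max(axis=1, keepdims=True)
    abund = np.exp(logits)
    abund = abund / abund.sum(axis=1, keepdims=True)
    if spec.detection_limit > 0:
        # TRFLP peak detection: drop sub-threshold peaks, keep each row's
        # dominant peak unconditionally, renormalize
        keep = abund >= spec.detection_limit
        keep[np.arange(len(abund)), abund.argmax(axis=1)] = True
        abund = np.where(keep, abund, 0.0)
        abund = abund / abund.sum(axis=1, keepdims=True)

    values = pd.DataFrame(
        abund,
        index=pd.MultiIndex.from_tuples(index, names=["sample_id", "subsample_id"]),
        columns=[f"otu{j + 1:04d}" for j in range(J)],
    )
    return OtuTable(values)


def simulate_study(
    spec: ScenarioSpec,
    communities: dict[str, SignalWeights] | None = None,
) -> tuple[Phylogeny, SampleFrame, dict[str, OtuTable]]:
    """Generate a full study: tree, sites + chemistry, one or two communities.

    ``communities`` maps community names to their signal weights (defaults to
    ``{"bacterial": spec.weights, "fungal": spec.weights}``); the tree, site
    layout and chemistry are shared, mirroring a paired bacterial/fungal
    fingerprinting study of the same soils.
    """
    tree = simulate_tree(spec)
    frame = simulate_chemistry(simulate_sites(spec), spec)
    if communities is None:
        communities = {"bacterial": spec.weights, "fungal": spec.weights}
    tables = {}
    for idx, (name, weights) in enumerate(communities.items()):
        sub = replace(spec, weights=weights)
        tables[name] = simulate_community(frame, tree, sub, stream=idx)
    return tree, frame, tables
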