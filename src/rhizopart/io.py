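"""Readers, writers and container types for everything the pipeline touches.

The pipeline consumes four external artefacts:

* an OTU abundance table (TRFLP peak-area style; tab separated; one row per
  DNA subsample, with two subsamples per soil sample in the reference design),
* a sample metadata table (plant species, genus, GPS coordinates),
* a soil chemistry table (ten standard agronomic assays per sample),
* a rooted, time-calibrated plant phylogeny in Newick format.

All tables are TSV with a header row; missing values are rejected rather than
imputed.  GPS latitude/longitude are projected to planar metres with an
equirectangular projection about the mean latitude, which is accurate to well
under a metre over the few-kilometre extent of a single field site.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

__all__ = [
    "CHEMISTRY_COLUMNS",
    "EARTH_RADIUS_M",
    "InputError",
    "NewickError",
    "OtuTable",
    "Phylogeny",
    "RunConfig",
    "SampleFrame",
    "geographic_to_planar",
    "planar_to_geographic",
    "read_newick",
    "read_otu_table",
    "read_sample_frame",
    "write_newick",
    "write_otu_table",
    "write_sample_frame",
]

#: Spherical mean Earth radius used for the planar projection (metres).
EARTH_RADIUS_M = 6_371_000.0

#: The ten soil chemistry assays, in canonical column order.
CHEMISTRY_COLUMNS = [
    "NO3_ppm",
    "P_olsen_ppm",
    "K_ppm",
    "K_meq",
    "Na_ppm",
    "Ca_meq",
    "Mg_meq",
    "CEC",
    "OM_pct",
    "pH",
]

METADATA_COLUMNS = ["sample_id", "species", "genus", "lat", "lon"]


class InputError(ValueError):
    """Malformed or inconsistent external input."""


class NewickError(InputError):
    """Unparseable or invalid Newick tree."""


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------


class OtuTable:
    """Samples x OTUs non-negative abundance matrix with subsample rows.

    ``values`` is a DataFrame whose row index is a ``(sample_id,
    subsample_id)`` MultiIndex and whose columns are OTU identifiers (TRFLP
    fragment classes).  Every sample has at least one subsample; cells are
    finite and non-negative.
    """

    def __init__(self, values: pd.DataFrame):
        if not isinstance(values.index, pd.MultiIndex) or values.index.nlevels != 2:
            raise InputError("OtuTable rows must be indexed by (sample_id, subsample_id)")
        values = values.copy()
        values.index = values.index.set_names(["sample_id", "subsample_id"])
        if values.shape[0] == 0 or values.shape[1] == 0:
            raise InputError("OtuTable must have at least one row and one OTU")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise InputError(f"duplicate OTU id: {dup!r}")
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise InputError(f"duplicate (sample, subsample) pair: {dup!r}")
        arr = values.to_numpy(dtype=float)
        bad = ~np.isfinite(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InputError(
                f"non-finite abundance at subsample {values.index[i]!r}, OTU "
                f"{values.columns[j]!r}"
            )
        neg = arr < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise InputError(
                f"negative abundance {arr[i, j]} at subsample {values.index[i]!r}, "
                f"OTU {values.columns[j]!r}"
            )
        self.values = values.astype(float)

    # -- introspection ------------------------------------------------------

    @property
    def sample_ids(self) -> list:
        """Sample ids, in first-appearance order."""
        seen = dict.fromkeys(self.values.index.get_level_values("sample_id"))
        return list(seen)

    @property
    def otu_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_subsamples(self) -> int:
        return self.values.shape[0]

    @property
    def n_otus(self) -> int:
        return self.values.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<OtuTable: {self.n_samples} samples, {self.n_subsamples} subsamples, "
            f"{self.n_otus} OTUs>"
        )

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def read_otu_table(path: str | Path | IO) -> OtuTable:
    """Read a tab-separated OTU table.

    The file has a header row; the first two columns are ``sample_id`` and
    ``subsample_id``, the remaining columns are OTU identifiers.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise InputError("OTU table needs sample_id, subsample_id and >=1 OTU column")
    first_two = list(df.columns[:2])
    if first_two != ["sample_id", "subsample_id"]:
        raise InputError(
            f"first two columns must be sample_id, subsample_id (got {first_two})"
        )
    df = df.set_index(["sample_id", "subsample_id"])
    return OtuTable(df)


def write_otu_table(table: OtuTable, path: str | Path | IO) -> None:
    table.values.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample frame (metadata + chemistry)
# ---------------------------------------------------------------------------


class SampleFrame:
    """Per-sample predictors: species, genus, planar coordinates, chemistry.

    ``data`` is indexed by sample_id and carries ``species``, ``genus``,
    ``x``, ``y`` (planar metres) and, once chemistry has been attached, the
    ten columns of :data:`CHEMISTRY_COLUMNS`.  A frame without chemistry is
    legal (the synthetic generator builds coordinates first) but the analysis
    pipeline requires a complete frame.
    """

    def __init__(self, data: pd.DataFrame):
        required = ["species", "genus", "x", "y"]
        missing = [c for c in required if c not in data.columns]
        if missing:
            raise InputError(f"sample frame missing column(s): {missing}")
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise InputError(f"duplicate sample_id: {dup!r}")
        xy = data[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise InputError("non-finite coordinates in sample frame")
        self.has_chemistry = all(c in data.columns for c in CHEMISTRY_COLUMNS)
        if self.has_chemistry:
            chem = data[CHEMISTRY_COLUMNS].to_numpy(dtype=float)
            if not np.isfinite(chem).all():
                i, j = np.argwhere(~np.isfinite(chem))[0]
                raise InputError(
                    f"non-finite chemistry value: sample {data.index[i]!r}, "
                    f"column {CHEMISTRY_COLUMNS[j]!r}"
                )
            ph = data["pH"].to_numpy(dtype=float)
            if ((ph <= 0) | (ph >= 14)).any():
                raise InputError("pH outside (0, 14)")
        self.data = data.copy()
        self.data.index = self.data.index.set_names("sample_id")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def species(self) -> pd.Series:
        return self.data["species"]

    @property
    def genus(self) -> pd.Series:
        return self.data["genus"]

    @property
    def coordinates(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def chemistry(self) -> pd.DataFrame:
        if not self.has_chemistry:
            raise InputError("sample frame has no chemistry columns")
        return self.data[CHEMISTRY_COLUMNS].astype(float)

    def chemistry_zscores(self) -> pd.DataFrame:
        """Column-standardized chemistry (zero mean, unit sd)."""
        chem = self.chemistry()
        sd = chem.std(ddof=1)
        if (sd == 0).any():
            zero = list(sd.index[sd == 0])
            raise InputError(f"constant chemistry column(s): {zero}")
        return (chem - chem.mean()) / sd

    def with_chemistry(self, chem: pd.DataFrame) -> "SampleFrame":
        merged = self.data.drop(columns=CHEMISTRY_COLUMNS, errors="ignore").join(
            chem[CHEMISTRY_COLUMNS], how="left"
        )
        return SampleFrame(merged)

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        chem = "with" if self.has_chemistry else "without"
        return f"<SampleFrame: {len(self)} samples, {chem} chemistry>"


def geographic_to_planar(
    lat: np.ndarray, lon: np.ndarray, origin: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection of degrees to planar metres.

    ``x`` grows eastward, ``y`` northward, both relative to the (mean lat,
    mean lon) origin unless an explicit origin is given.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if origin is None:
        origin = (float(lat.mean()), float(lon.mean()))
    lat0, lon0 = origin
    y = EARTH_RADIUS_M * np.deg2rad(lat - lat0)
    x = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * np.deg2rad(lon - lon0)
    return x, y


def planar_to_geographic(
    x: np.ndarray, y: np.ndarray, origin: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`geographic_to_planar` about a fixed origin."""
    lat0, lon0 = origin
    lat = lat0 + np.rad2deg(np.asarray(y, dtype=float) / EARTH_RADIUS_M)
    lon = lon0 + np.rad2deg(
        np.asarray(x, dtype=float) / (EARTH_RADIUS_M * math.cos(math.radians(lat0)))
    )
    return lat, lon


def read_sample_frame(
    metadata_path: str | Path | IO, chemistry_path: str | Path | IO
) -> SampleFrame:
    """Join a metadata TSV and a chemistry TSV into a :class:`SampleFrame`.

    The metadata file has columns ``sample_id, species, genus, lat, lon``;
    the chemistry file is keyed by ``sample_id`` and must contain all ten
    assay columns.  Samples present in one file but not the other are an
    error.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise InputError(f"metadata missing column(s): {missing}")
    chem = pd.read_csv(chemistry_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in chem.columns:
        raise InputError("chemistry table missing column: ['sample_id']")
    missing = [c for c in CHEMISTRY_COLUMNS if c not in chem.columns]
    if missing:
        raise InputError(f"chemistry table missing column(s): {missing}")

    meta = meta.set_index("sample_id")
    chem = chem.set_index("sample_id")
    only_meta = sorted(set(meta.index) - set(chem.index))
    only_chem = sorted(set(chem.index) - set(meta.index))
    if only_meta or only_chem:
        raise InputError(
            "sample id mismatch between metadata and chemistry: "
            f"metadata-only={only_meta}, chemistry-only={only_chem}"
        )
    x, y = geographic_to_planar(meta["lat"].to_numpy(), meta["lon"].to_numpy())
    data = meta[["species", "genus"]].copy()
    data["x"] = x
    data["y"] = y
    data = data.join(chem[CHEMISTRY_COLUMNS])
    return SampleFrame(data)


def write_sample_frame(
    frame: SampleFrame,
    metadata_path: str | Path | IO,
    chemistry_path: str | Path | IO,
    origin: tuple[float, float] = (38.3157, -123.0686),
) -> None:
    """Write a frame back to a metadata TSV + chemistry TSV pair.

    Planar coordinates are converted to lat/lon about ``origin`` (defaults to
    a northern-California coastal reserve) so the files round-trip through
    :func:`read_sample_frame`.
    """
    xy = frame.coordinates
    # read_sample_frame re-centres about the mean coordinate, so centre first
    # to make write -> read the identity up to float error.
    x = xy[:, 0] - xy[:, 0].mean()
    y = xy[:, 1] - xy[:, 1].mean()
    lat, lon = planar_to_geographic(x, y, origin)
    meta = pd.DataFrame(
        {
            "sample_id": frame.sample_ids,
            "species": frame.species.to_numpy(),
            "genus": frame.genus.to_numpy(),
            "lat": lat,
            "lon": lon,
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False, float_format="%.10f")
    chem = frame.chemistry().reset_index()
    chem.to_csv(chemistry_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted plant phylogeny with branch lengths (time-calibrated).

    Thin wrapper around :class:`skbio.TreeNode` that enforces the invariants
    the downstream eigenvector decomposition needs: unique tip labels and
    non-negative branch lengths on every non-root node.
    """

    def __init__(self, tree: TreeNode):
        tips = [t.name for t in tree.tips()]
        if any(t is None for t in tips):
            raise NewickError("tree has unnamed tips")
        dupes = {t for t in tips if tips.count(t) > 1}
        if dupes:
            raise NewickError(f"duplicate tip label(s): {sorted(dupes)}")
        for node in tree.traverse(include_self=False):
            if node.length is None:
                raise NewickError(
                    f"missing branch length above node {node.name or '<internal>'}"
                )
            if node.length < 0:
                raise NewickError(f"negative branch length: {node.length}")
        if tree.length is None:
            tree.length = 0.0
        self.tree = tree
        self.tip_names = tips

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def depths(self) -> pd.Series:
        """Root-to-tip path length for every tip."""
        out = {}
        for tip in self.tree.tips():
            d = tip.length
            node = tip.parent
            while node is not None:
                d += node.length or 0.0
                node = node.parent
            out[tip.name] = d
        return pd.Series(out)[self.tip_names]

    def height(self) -> float:
        return float(self.depths().max())

    def is_ultrametric(self, rel_tol: float = 1e-9) -> bool:
        d = self.depths().to_numpy()
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1.0))

    def to_newick(self) -> str:
        import io as _io

        buf = _io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Phylogeny: {self.n_tips} tips, height {self.height():.4g}>"


def read_newick(source: str | Path | IO) -> Phylogeny:
    """Parse a single-tree Newick file (or literal string) with branch lengths."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        import io as _io

        handle: object = _io.StringIO(source)
    else:
        handle = source
    try:
        tree = TreeNode.read(handle, format="newick", convert_underscores=False)
    except Exception as exc:  # skbio raises NewickFormatError with position info
        raise NewickError(f"could not parse Newick input: {exc}") from exc
    return Phylogeny(tree)


def write_newick(phylogeny: Phylogeny, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(phylogeny.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Tunable settings of the analysis pipeline.

    Defaults are the reference study settings: rare OTUs are those present in
    <=7 % of subsamples; ordination uses 20 random starts and accepts the
    smallest dimensionality with stress below 0.20; matrix-regression
    inference uses 1000 permutations; the first seven phylogenetic and two
    spatial eigenvectors enter the linear-model stage, with eigenvector
    retention at P < 0.05.
    """

    rare_threshold: float = 0.07
    max_dimensions: int = 6
    stress_ceiling: float = 0.20
    n_starts: int = 20
    n_permutations: int = 1000
    n_phylo_screened: int = 7
    n_spatial: int = 2
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.rare_threshold <= 1:
            raise InputError("rare_threshold must lie in [0, 1]")
        for name in ("max_dimensions", "n_starts", "n_permutations",
                     "n_phylo_screened", "n_spatial"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise InputError(f"{name} must be a positive integer (got {v!r})")
        if not 0 < self.alpha < 1:
            raise InputError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)
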