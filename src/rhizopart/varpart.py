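"""Three-set variance partitioning of an ordination axis.

The explained variance of each axis is decomposed among plant phylogeny,
soil chemistry and spatial location by fitting the seven non-empty subset
models and combining their *adjusted* R-squared values by
inclusion-exclusion.  With ``A_S`` the adjusted R-squared of the model on
the union of the predictor sets in ``S``:

    unique(phylo)        a = A_pcs - A_cs
    unique(chem)         b = A_pcs - A_ps
    unique(space)        c = A_pcs - A_pc
    shared(phylo, chem)  d = A_pcs - a - b - A_s
    shared(chem, space)  e = A_pcs - b - c - A_p
    shared(phylo, space) f = A_pcs - a - c - A_c
    three-way            g = A_pcs - a - b - c - d - e - f
    residual                 = 1 - A_pcs

Adjusted R-squared is used because the three sets have unequal sizes; as a
consequence the shared fractions can be negative (a suppression signature),
and they are reported as such rather than clipped.  The eight fractions sum
to one by construction.  Species identity is not a partitioning set: at
species level it is perfectly collinear with the phylogenetic eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ModelError, fit_ols

__all__ = ["VariancePartition", "partition3", "partition_report"]

SET_NAMES = ("phylo", "chem", "space")


@dataclass
class VariancePartition:
    """Unique, shared and residual adjusted-R^2 fractions for one response."""

    response: str
    unique_phylo: float
    unique_chem: float
    unique_space: float
    shared_phylo_chem: float
    shared_chem_space: float
    shared_phylo_space: float
    shared_all: float
    residual: float
    subset_adj_r2: dict

    def fractions(self) -> pd.Series:
        return pd.Series(
            {
                "unique_phylo": self.unique_phylo,
                "unique_chem": self.unique_chem,
                "unique_space": self.unique_space,
                "shared_phylo_chem": self.shared_phylo_chem,
                "shared_chem_space": self.shared_chem_space,
                "shared_phylo_space": self.shared_phylo_space,
                "shared_all": self.shared_all,
                "residual": self.residual,
            },
            name=self.response,
        )

    def total(self) -> float:
        return float(self.fractions().sum())


def _adj_r2(y, X: pd.DataFrame, label: str) -> float:
    if X.shape[1] == 0:
        return 0.0
    try:
        return fit_ols(y, X).adj_r2
    except ModelError as exc:
        raise ModelError(f"subset model {label!r} failed: {exc}") from exc


def partition3(
    y: pd.Series | np.ndarray,
    X_phylo: pd.DataFrame,
    X_chem: pd.DataFrame,
    X_space: pd.DataFrame,
    response: str = "axis",
) -> VariancePartition:
    """Partition one axis's variance among phylogeny, chemistry and space.

    The predictor sets are the ones the modelling layer produced: the
    retained phylogenetic eigenvectors, the AIC-selected chemistry subset and
    the spatial eigenvectors.  Any set may be empty (its fractions are then
    zero by construction).
    """
    sets = {"phylo": X_phylo, "chem": X_chem, "space": X_space}
    for a in sets.values():
        for b in sets.values():
            if a is not b and set(a.columns) & set(b.columns):
                raise ModelError("partitioning sets share columns")

    def union(*names: str) -> pd.DataFrame:
        return pd.concat([sets[n] for n in names], axis=1)

    A = {}
    for combo in [("phylo",), ("chem",), ("space",),
                  ("phylo", "chem"), ("phylo", "space"), ("chem", "space"),
                  ("phylo", "chem", "space")]:
        A[combo] = _adj_r2(y, union(*combo), "+".join(combo))

    a_pcs = A[("phylo", "chem", "space")]
    a = a_pcs - A[("chem", "space")]
    b = a_pcs - A[("phylo", "space")]
    c = a_pcs - A[("phylo", "chem")]
    d = a_pcs - a - b - A[("space",)]
    e = a_pcs - b - c - A[("phylo",)]
    f = a_pcs - a - c - A[("chem",)]
    g = a_pcs - a - b - c - d - e - f
    residual = 1.0 - a_pcs
    part = VariancePartition(
        response=response,
        unique_phylo=a,
        unique_chem=b,
        unique_space=c,
        shared_phylo_chem=d,
        shared_chem_space=e,
        shared_phylo_space=f,
        shared_all=g,
        residual=residual,
        subset_adj_r2={"+".join(k): v for k, v in A.items()},
    )
    assert abs(part.total() - 1.0) < 1e-10
    return part


def partition_report(partitions: list[VariancePartition]) -> tuple[pd.DataFrame, str]:
    """Tabular + textual (Venn-style) summary of per-axis partitions."""
    if not partitions:
        raise ModelError("need at least one partition")
    table = pd.DataFrame([p.fractions() for p in partitions])
    table.index.name = "response"
    lines = []
    for p in partitions:
        lines.append(f"{p.response}: explained {1 - p.residual:.3f}")
        lines.append(
            f"  unique  phylo={p.unique_phylo:+.3f}  chem={p.unique_chem:+.3f}  "
            f"space={p.unique_space:+.3f}"
        )
        lines.append(
            f"  shared  phylo&chem={p.shared_phylo_chem:+.3f}  "
            f"chem&space={p.shared_chem_space:+.3f}  "
            f"phylo&space={p.shared_phylo_space:+.3f}  "
            f"all={p.shared_all:+.3f}"
        )
        neg = [k for k, v in p.fractions().items()
               if k.startswith("shared") and v < 0]
        if neg:
            lines.append(f"  note: negative shared fraction(s): {', '.join(neg)}")
    return table, "\n".join(lines)
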