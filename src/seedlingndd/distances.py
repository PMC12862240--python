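"""Species-by-species phylogenetic and functional distance matrices.

Phylogenetic distances are cophenetic (patristic) path lengths on the study
phylogeny.  Functional distances come from the nine standardized leaf traits,
either as cophenetic distances on a UPGMA trait dendrogram (default, matching
the trait-dendrogram workflow of neighborhood studies) or as raw pairwise
Euclidean distances; the wording of published workflows is ambiguous between
the two, so both are exposed and the pipeline manifest records which was
used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import pdist, squareform

from .dataio import Phylogeny
from .errors import InvalidArgumentError

FUNCTIONAL_METHODS = ("dendrogram-cophenetic", "euclidean")


@dataclass
class SpeciesDistances:
    """Paired distance matrices sharing one species order."""

    species: list[str]
    phylo: pd.DataFrame
    func: pd.DataFrame
    functional_method: str = "dendrogram-cophenetic"

    def __post_init__(self) -> None:
        for name, m in (("phylo", self.phylo), ("func", self.func)):
            if list(m.index) != self.species or list(m.columns) != self.species:
                raise InvalidArgumentError(f"{name} matrix is not indexed by the species order")
            a = m.to_numpy()
            if not np.allclose(a, a.T) or not np.allclose(np.diag(a), 0) or (a < -1e-12).any():
                raise InvalidArgumentError(f"{name} matrix must be symmetric, zero-diagonal, >= 0")


def cophenetic_phylo(tree: Phylogeny, species: list[str] | None = None) -> pd.DataFrame:
    """Patristic distance matrix; entry (a, b) sums branch lengths tip-to-tip."""
    return tree.cophenetic_matrix(species)


def standardize_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """z-score each trait to mean 0, sample SD 1 across species."""
    if traits.shape[0] < 2:
        raise InvalidArgumentError("standardize_traits needs >= 2 species")
    if traits.isna().any().any():
        col = traits.columns[traits.isna().any()][0]
        raise InvalidArgumentError(f"trait {col!r} has missing values")
    sd = traits.std(axis=0, ddof=1)
    constant = sd < 1e-12
    if constant.any():
        name = traits.columns[np.flatnonzero(constant.to_numpy())[0]]
        raise InvalidArgumentError(f"trait {name!r} is constant across species; cannot standardize")
    return (traits - traits.mean(axis=0)) / sd


def functional_distances(
    std_traits: pd.DataFrame, method: str = "dendrogram-cophenetic"
) -> pd.DataFrame:
    """Pairwise functional distances among species from standardized traits.

    ``dendrogram-cophenetic`` builds a UPGMA (average-linkage) dendrogram on
    Euclidean trait distances and returns its cophenetic matrix (ultrametric);
    ``euclidean`` returns the raw Euclidean matrix.  Species are sorted
    lexicographically before clustering so merge-order ties are deterministic.
    """
    if method not in FUNCTIONAL_METHODS:
        raise InvalidArgumentError(
            f"unknown functional distance method {method!r}; choose from {FUNCTIONAL_METHODS}"
        )
    std_traits = std_traits.sort_index()
    species = list(std_traits.index)
    X = std_traits.to_numpy(dtype=float)
    d = pdist(X, metric="euclidean")
    if method == "euclidean":
        mat = squareform(d)
    else:
        if len(species) == 2:
            mat = squareform(d)
        else:
            Z = average(d)
            mat = squareform(cophenet(Z))
    return pd.DataFrame(mat, index=species, columns=species)


def build_species_distances(
    tree: Phylogeny,
    traits: pd.DataFrame,
    species: list[str] | None = None,
    functional_method: str = "dendrogram-cophenetic",
    log_traits: list[str] | None = None,
) -> SpeciesDistances:
    """Assemble both matrices over a shared, lexicographically sorted order.

    ``log_traits`` optionally log-transforms the named traits (e.g. leaf area)
    before z-scoring; the default applies no transformation.
    """
    species = sorted(species) if species is not None else sorted(traits.index)
    missing = sorted(set(species) - set(traits.index))
    if missing:
        raise InvalidArgumentError(f"species missing from the trait table: {missing}")
    traits = traits.loc[species].copy()
    for col in log_traits or []:
        if col not in traits.columns:
            raise InvalidArgumentError(f"log_traits names unknown trait {col!r}")
        if (traits[col] <= 0).any():
            raise InvalidArgumentError(f"trait {col!r} has non-positive values; cannot log")
        traits[col] = np.log(traits[col])
    phylo = cophenetic_phylo(tree, species)
    func = functional_distances(standardize_traits(traits), functional_method).loc[species, species]
    return SpeciesDistances(
        species=species, phylo=phylo, func=func, functional_method=functional_method
    )


def write_distance_matrix(mat: pd.DataFrame, path) -> None:
    mat.rename_axis("species").to_csv(path)


def read_distance_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="species")
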