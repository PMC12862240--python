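"""Readers and writers for every external artifact of a study.

All tabular files are UTF-8 comma-separated with a header row and "." decimal
point, one file per table; the phylogeny is newick.  Coordinates are
plot-local metres with the origin at the southwest corner, and quadrat ids
encode the subplot grid position as ``rXXcYY`` (row = south-to-north index).
Every reader validates what its writer guarantees, so write-then-read is an
identity on valid data and malformed input fails loudly with the offending
row or column named.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .config import SOIL_VARIABLES, SEASONS
from .errors import DataFormatError, InvalidArgumentError

STEM_COLUMNS = ["stem_id", "species", "x", "y", "dbh_cm"]
CENSUS_COLUMNS = [
    "seedling_id",
    "species",
    "quadrat_id",
    "interval_id",
    "season",
    "year",
    "height_cm",
    "y",
]
RAINFALL_COLUMNS = ["year", "month", "rainfall_mm"]

#: Months belonging to each season; dry spans two calendar years and is
#: labelled by its starting year (November--April of the next year).
RAINY_MONTHS = (5, 6, 7, 8, 9, 10)
DRY_MONTHS_START_YEAR = (11, 12)
DRY_MONTHS_NEXT_YEAR = (1, 2, 3, 4)


# ---------------------------------------------------------------------------
# generic CSV plumbing
# ---------------------------------------------------------------------------

def _read_csv(path, required: list[str], numeric: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"{what} file {path} is empty") from None
    if df.shape[0] == 0 and df.shape[1] == 0:
        raise DataFormatError(f"{what} file {path} is empty")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"{what} file {path} is missing columns {missing}")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col].astype(str).str.strip() != "")
        bad |= df[col].astype(str).str.strip() == ""
        bad &= converted.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataFormatError(
                f"{what} file {path}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r} at data row {row}"
            )
        df[col] = converted
    return df


def _write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stem map
# ---------------------------------------------------------------------------

def validate_stem_map(df: pd.DataFrame, plot_size_m: tuple[float, float] | None = None) -> pd.DataFrame:
    missing = [c for c in STEM_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"stem map is missing columns {missing}")
    if df["stem_id"].duplicated().any():
        dup = df.loc[df["stem_id"].duplicated(), "stem_id"].iloc[0]
        raise DataFormatError(f"duplicate stem_id {dup!r} in stem map")
    small = df["dbh_cm"] < 1.0
    if small.any():
        row = int(np.flatnonzero(small.to_numpy())[0])
        raise DataFormatError(
            f"stem map row {row} (stem_id={df['stem_id'].iloc[row]!r}) has "
            f"dbh_cm={df['dbh_cm'].iloc[row]} < 1; only stems with DBH >= 1 cm are tagged"
        )
    if plot_size_m is not None:
        lx, ly = plot_size_m
        out = (df["x"] < 0) | (df["x"] > lx) | (df["y"] < 0) | (df["y"] > ly)
        if out.any():
            row = int(np.flatnonzero(out.to_numpy())[0])
            raise DataFormatError(f"stem map row {row} lies outside the {lx} x {ly} m plot")
    return df.reset_index(drop=True)


def read_stem_map(path, plot_size_m: tuple[float, float] | None = None) -> pd.DataFrame:
    df = _read_csv(path, STEM_COLUMNS, ["x", "y", "dbh_cm"], "stem map")
    return validate_stem_map(df[STEM_COLUMNS], plot_size_m)


def write_stem_map(df: pd.DataFrame, path) -> None:
    _write_csv(validate_stem_map(df)[STEM_COLUMNS], path)


# ---------------------------------------------------------------------------
# seedling censuses
# ---------------------------------------------------------------------------

def validate_censuses(
    df: pd.DataFrame,
    min_height_cm: float = 20.0,
    interval_order: list[str] | None = None,
) -> pd.DataFrame:
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"seedling census table is missing columns {missing}")
    if not df["y"].isin([0, 1]).all():
        row = int(np.flatnonzero(~df["y"].isin([0, 1]).to_numpy())[0])
        raise DataFormatError(f"census row {row}: survival outcome y must be 0 or 1")
    bad_season = ~df["season"].isin(SEASONS)
    if bad_season.any():
        row = int(np.flatnonzero(bad_season.to_numpy())[0])
        raise DataFormatError(
            f"census row {row}: season {df['season'].iloc[row]!r} not in {SEASONS}"
        )
    short = df["height_cm"] < min_height_cm
    if short.any():
        row = int(np.flatnonzero(short.to_numpy())[0])
        raise DataFormatError(
            f"census row {row}: height_cm={df['height_cm'].iloc[row]} below the "
            f"{min_height_cm} cm inclusion threshold"
        )
    if df.duplicated(["seedling_id", "interval_id"]).any():
        raise DataFormatError("duplicate (seedling_id, interval_id) record in census table")
    if interval_order is not None:
        rank = {iv: k for k, iv in enumerate(interval_order)}
        unknown = ~df["interval_id"].isin(rank)
        if unknown.any():
            raise DataFormatError(
                f"census interval {df.loc[unknown, 'interval_id'].iloc[0]!r} "
                "not in the declared interval order"
            )
        r = df["interval_id"].map(rank)
        dead_at = df.assign(_r=r).loc[df["y"] == 0].groupby("seedling_id")["_r"].min()
        later = df.assign(_r=r).merge(dead_at.rename("_dead"), on="seedling_id", how="left")
        ghost = later["_dead"].notna() & (later["_r"] > later["_dead"])
        if ghost.any():
            sid = later.loc[ghost, "seedling_id"].iloc[0]
            raise DataFormatError(
                f"seedling {sid!r} has a census record after the interval it died in"
            )
    return df.reset_index(drop=True)


def read_censuses(path, min_height_cm: float = 20.0) -> pd.DataFrame:
    df = _read_csv(path, CENSUS_COLUMNS, ["height_cm", "y"], "seedling census")
    df["y"] = df["y"].astype(int)
    df["year"] = df["year"].astype(int)
    return validate_censuses(df[CENSUS_COLUMNS], min_height_cm)


def write_censuses(df: pd.DataFrame, path, min_height_cm: float = 20.0) -> None:
    _write_csv(validate_censuses(df, min_height_cm)[CENSUS_COLUMNS], path)


# ---------------------------------------------------------------------------
# traits / soil / canopy / elevation
# ---------------------------------------------------------------------------

def read_traits(path) -> pd.DataFrame:
    df = _read_csv(path, ["species"], [], "trait table")
    trait_cols = [c for c in df.columns if c != "species"]
    if not trait_cols:
        raise DataFormatError(f"trait table {path} has no trait columns")
    for col in trait_cols:
        df[col] = pd.to_numeric(df[col], errors="raise")
    if df["species"].duplicated().any():
        raise DataFormatError("duplicate species in trait table")
    return df.set_index("species")


def write_traits(df: pd.DataFrame, path) -> None:
    _write_csv(df.reset_index() if df.index.name == "species" else df, path)


def read_soil(path) -> pd.DataFrame:
    df = _read_csv(path, ["quadrat_id"] + SOIL_VARIABLES, SOIL_VARIABLES, "soil table")
    if df["quadrat_id"].duplicated().any():
        raise DataFormatError("duplicate quadrat_id in soil table")
    return df.set_index("quadrat_id")


def write_soil(df: pd.DataFrame, path) -> None:
    _write_csv(df.reset_index() if df.index.name == "quadrat_id" else df, path)


def read_canopy(path) -> pd.Series:
    df = _read_csv(path, ["quadrat_id", "canopy_openness"], ["canopy_openness"], "canopy table")
    s = df.set_index("quadrat_id")["canopy_openness"]
    if ((s <= 0) | (s >= 1)).any():
        bad = s[(s <= 0) | (s >= 1)].index[0]
        raise DataFormatError(f"canopy openness for quadrat {bad!r} is not in (0, 1)")
    return s


def write_canopy(s: pd.Series, path) -> None:
    _write_csv(s.rename("canopy_openness").rename_axis("quadrat_id").reset_index(), path)


def read_corner_elevations(path) -> np.ndarray:
    """Corner-elevation grid as a (n_rows+1, n_cols+1) array, row 0 at the south."""
    df = _read_csv(path, ["row", "col", "elevation_m"], ["row", "col", "elevation_m"], "elevation grid")
    rows = df["row"].astype(int)
    cols = df["col"].astype(int)
    grid = np.full((rows.max() + 1, cols.max() + 1), np.nan)
    grid[rows, cols] = df["elevation_m"].to_numpy()
    if np.isnan(grid).any():
        r, c = np.argwhere(np.isnan(grid))[0]
        raise DataFormatError(f"elevation grid is missing the corner at row {r}, col {c}")
    return grid


def write_corner_elevations(grid: np.ndarray, path) -> None:
    rows, cols = np.indices(grid.shape)
    df = pd.DataFrame(
        {"row": rows.ravel(), "col": cols.ravel(), "elevation_m": grid.ravel()}
    )
    _write_csv(df, path)


# ---------------------------------------------------------------------------
# rainfall
# ---------------------------------------------------------------------------

def validate_rainfall(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RAINFALL_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"rainfall table is missing columns {missing}")
    if not df["month"].between(1, 12).all():
        raise DataFormatError("rainfall month must be in 1..12")
    if (df["rainfall_mm"] < 0).any():
        raise DataFormatError("rainfall_mm must be >= 0")
    if df.duplicated(["year", "month"]).any():
        dup = df.loc[df.duplicated(["year", "month"]), ["year", "month"]].iloc[0]
        raise DataFormatError(f"duplicate rainfall record for {int(dup['year'])}-{int(dup['month']):02d}")
    return df.reset_index(drop=True)


def read_rainfall(path) -> pd.DataFrame:
    df = _read_csv(path, RAINFALL_COLUMNS, ["year", "month", "rainfall_mm"], "rainfall table")
    df["year"] = df["year"].astype(int)
    df["month"] = df["month"].astype(int)
    return validate_rainfall(df)


def write_rainfall(df: pd.DataFrame, path) -> None:
    _write_csv(validate_rainfall(df)[RAINFALL_COLUMNS], path)


def aggregate_seasonal_rainfall(
    rainfall: pd.DataFrame, intervals: list[str] | None = None
) -> dict[str, float]:
    """Seasonal rainfall totals keyed by interval id (``"rainy-2021"`` etc.).

    The rainy total of year *y* sums May--October of *y*; the dry total of
    year *y* sums November--December of *y* plus January--April of *y*+1.
    With ``intervals=None`` every interval whose months are fully present is
    returned; an explicitly requested interval with missing months raises,
    naming them.
    """
    rainfall = validate_rainfall(rainfall)
    table = {(int(r.year), int(r.month)): float(r.rainfall_mm) for r in rainfall.itertuples()}

    def months_of(interval: str) -> list[tuple[int, int]]:
        try:
            season, year_s = interval.rsplit("-", 1)
            year = int(year_s)
        except ValueError:
            raise InvalidArgumentError(f"malformed interval id {interval!r}") from None
        if season == "rainy":
            return [(year, m) for m in RAINY_MONTHS]
        if season == "dry":
            return [(year, m) for m in DRY_MONTHS_START_YEAR] + [
                (year + 1, m) for m in DRY_MONTHS_NEXT_YEAR
            ]
        raise InvalidArgumentError(f"unknown season in interval id {interval!r}")

    if intervals is None:
        years = sorted({y for (y, _) in table})
        intervals = [f"{s}-{y}" for y in years for s in ("dry", "rainy")]
        intervals = [iv for iv in intervals if all(m in table for m in months_of(iv))]

    out: dict[str, float] = {}
    for interval in intervals:
        months = months_of(interval)
        absent = [f"{y}-{m:02d}" for (y, m) in months if (y, m) not in table]
        if absent:
            raise InvalidArgumentError(
                f"rainfall for interval {interval!r} is incomplete; missing months: {absent}"
            )
        out[interval] = float(sum(table[m] for m in months))
    return out


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

class Phylogeny:
    """Thin wrapper over a dendropy tree exposing tips and patristic distances."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                raise DataFormatError("newick tree has an edge without a branch length")
        self.tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        if len(self.tips) != len(set(self.tips)):
            raise DataFormatError("newick tree has duplicate tip labels")

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    def cophenetic_matrix(self, species: list[str] | None = None) -> pd.DataFrame:
        """Patristic (tip-to-tip path length) distances among tips."""
        species = list(species) if species is not None else self.tips
        missing = sorted(set(species) - set(self.tips))
        if missing:
            raise InvalidArgumentError(f"species missing from the phylogeny: {missing}")
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        n = len(species)
        mat = np.zeros((n, n))
        for i, a in enumerate(species):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[a], taxa[species[j]])
                mat[i, j] = mat[j, i] = d
        return pd.DataFrame(mat, index=species, columns=species)


def read_newick(source) -> Phylogeny:
    """Parse a newick file path or literal newick string."""
    text = source if str(source).strip().startswith("(") else Path(source).read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises assorted parse errors
        raise DataFormatError(f"cannot parse newick: {exc}") from exc
    return Phylogeny(tree)


def write_newick(newick_text: str, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(newick_text.strip() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# the assembled study
# ---------------------------------------------------------------------------

FILES = {
    "stems": "stems.csv",
    "censuses": "seedlings.csv",
    "traits": "traits.csv",
    "soil": "soil.csv",
    "canopy": "canopy.csv",
    "elevation": "elevation.csv",
    "rainfall": "rainfall.csv",
    "tree": "phylogeny.nwk",
    "config": "config.yml",
}


@dataclass
class Study:
    """Every input table of one study, cross-validated at assembly."""

    stems: pd.DataFrame
    censuses: pd.DataFrame
    traits: pd.DataFrame
    soil: pd.DataFrame
    canopy: pd.Series
    corner_elevations: np.ndarray
    rainfall: pd.DataFrame
    newick: str
    plot_size_m: tuple[float, float] = (200.0, 200.0)
    subplot_size_m: float = 20.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tree = read_newick(self.newick)
        seedling_sp = set(self.censuses["species"])
        missing_tree = sorted(seedling_sp - set(tree.tips))
        if missing_tree:
            raise DataFormatError(f"seedling species missing from the phylogeny: {missing_tree}")
        missing_traits = sorted(seedling_sp - set(self.traits.index))
        if missing_traits:
            raise DataFormatError(f"seedling species missing from the trait table: {missing_traits}")
        quads = set(self.censuses["quadrat_id"])
        missing_soil = sorted(quads - set(self.soil.index))
        if missing_soil:
            raise DataFormatError(f"quadrats missing from the soil table: {missing_soil}")
        missing_canopy = sorted(quads - set(self.canopy.index))
        if missing_canopy:
            raise DataFormatError(f"quadrats missing from the canopy table: {missing_canopy}")
        validate_stem_map(self.stems, self.plot_size_m)

    @property
    def interval_order(self) -> list[str]:
        seen: list[str] = []
        for iv in self.censuses["interval_id"]:
            if iv not in seen:
                seen.append(iv)
        return seen

    def seasonal_rainfall(self) -> dict[str, float]:
        return aggregate_seasonal_rainfall(self.rainfall, self.interval_order)


def write_study(study: Study, out_dir) -> dict[str, str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stem_map(study.stems, out / FILES["stems"])
    write_censuses(study.censuses, out / FILES["censuses"])
    write_traits(study.traits, out / FILES["traits"])
    write_soil(study.soil, out / FILES["soil"])
    write_canopy(study.canopy, out / FILES["canopy"])
    write_corner_elevations(study.corner_elevations, out / FILES["elevation"])
    write_rainfall(study.rainfall, out / FILES["rainfall"])
    write_newick(study.newick, out / FILES["tree"])
    return {k: str(out / v) for k, v in FILES.items()}


def read_study(
    in_dir, plot_size_m: tuple[float, float] = (200.0, 200.0), subplot_size_m: float = 20.0
) -> Study:
    d = Path(in_dir)
    for key in ("stems", "censuses", "traits", "soil", "canopy", "elevation", "rainfall", "tree"):
        if not (d / FILES[key]).exists():
            raise DataFormatError(f"study directory {d} is missing {FILES[key]}")
    return Study(
        stems=read_stem_map(d / FILES["stems"], plot_size_m),
        censuses=read_censuses(d / FILES["censuses"]),
        traits=read_traits(d / FILES["traits"]),
        soil=read_soil(d / FILES["soil"]),
        canopy=read_canopy(d / FILES["canopy"]),
        corner_elevations=read_corner_elevations(d / FILES["elevation"]),
        rainfall=read_rainfall(d / FILES["rainfall"]),
        newick=(d / FILES["tree"]).read_text().strip(),
        plot_size_m=plot_size_m,
        subplot_size_m=subplot_size_m,
    )


# ---------------------------------------------------------------------------
# quadrat geometry helpers
# ---------------------------------------------------------------------------

def quadrat_id(row: int, col: int) -> str:
    return f"r{row + 1:02d}c{col + 1:02d}"


def quadrat_grid_index(qid: str) -> tuple[int, int]:
    if len(qid) != 6 or qid[0] != "r" or qid[3] != "c":
        raise InvalidArgumentError(f"malformed quadrat id {qid!r} (expected rXXcYY)")
    return int(qid[1:3]) - 1, int(qid[4:6]) - 1


def quadrat_centers(
    plot_size_m: tuple[float, float], subplot_size_m: float, quadrat_size_m: float = 2.0
) -> pd.DataFrame:
    """Centre coordinates of each seedling quadrat.

    Quadrats sit in the top-right (northeast) corner of their subplot, so the
    centre lies half a quadrat in from the subplot's NE corner.
    """
    nx = int(round(plot_size_m[0] / subplot_size_m))
    ny = int(round(plot_size_m[1] / subplot_size_m))
    rows = []
    for r in range(ny):
        for c in range(nx):
            cx = (c + 1) * subplot_size_m - quadrat_size_m / 2
            cy = (r + 1) * subplot_size_m - quadrat_size_m / 2
            rows.append({"quadrat_id": quadrat_id(r, c), "row": r, "col": c, "cx": cx, "cy": cy})
    return pd.DataFrame(rows).set_index("quadrat_id")
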