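"""External validation against a locally supplied field-data deposit.

Field deposits rarely match our column layout exactly, so a thin alias map
(YAML: ``{table: {deposit_column: our_column}}``) adapts the files before the
standard validators run.  The loader returns an ordinary :class:`Study`;
``external_validate`` then runs the full pipeline on it and returns the
per-season coefficient and importance tables for side-by-side comparison
with published values.  Nothing is fetched over the network: the deposit
directory must exist locally.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .dataio import (
    FILES,
    Study,
    read_canopy,
    read_corner_elevations,
    read_rainfall,
    read_soil,
    read_stem_map,
    read_traits,
    validate_censuses,
    validate_stem_map,
)
from .errors import DataFormatError
from .pipeline import AnalysisOptions, analyze_study


def load_deposit(
    deposit_dir,
    aliases: dict | str | Path | None = None,
    plot_size_m: tuple[float, float] = (200.0, 200.0),
    subplot_size_m: float = 20.0,
    min_height_cm: float = 20.0,
) -> Study:
    """Read a deposit-layout directory into a Study, applying column aliases."""
    d = Path(deposit_dir)
    if not d.is_dir():
        raise DataFormatError(f"deposit directory {d} does not exist")
    if isinstance(aliases, (str, Path)):
        aliases = yaml.safe_load(Path(aliases).read_text())
    aliases = aliases or {}

    def load(table: str, fname: str) -> pd.DataFrame:
        df = pd.read_csv(d / fname)
        return df.rename(columns=aliases.get(table, {}))

    stems = validate_stem_map(load("stems", FILES["stems"]), plot_size_m)
    censuses = validate_censuses(load("censuses", FILES["censuses"]), min_height_cm)
    traits = load("traits", FILES["traits"]).set_index("species")
    soil = load("soil", FILES["soil"]).set_index("quadrat_id")
    return Study(
        stems=stems,
        censuses=censuses,
        traits=traits,
        soil=soil,
        canopy=read_canopy(d / FILES["canopy"]),
        corner_elevations=read_corner_elevations(d / FILES["elevation"]),
        rainfall=read_rainfall(d / FILES["rainfall"]),
        newick=(d / FILES["tree"]).read_text().strip(),
        plot_size_m=plot_size_m,
        subplot_size_m=subplot_size_m,
    )


def external_validate(
    deposit_dir, aliases=None, options: AnalysisOptions | None = None
) -> dict[str, pd.DataFrame]:
    """Run the seasonal analysis on a local deposit; return comparison tables."""
    study = load_deposit(deposit_dir, aliases)
    options = options or AnalysisOptions(do_radius_scan=False, do_dispersion=False)
    result = analyze_study(study, options)
    out = {}
    for season, fit in result.fits.items():
        out[f"coefficients_{season}"] = fit.coefficients
        if season in result.importance:
            out[f"importance_{season}"] = result.importance[season]
    return out
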