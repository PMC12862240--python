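"""End-to-end orchestration: simulate, analyze, recover, with manifests.

``analyze_study`` runs the full seasonal analysis on any :class:`Study`
(synthetic or read from disk): species distances, neighborhood metrics,
per-season community GLMMs, diagnostics, importance partitioning, the
optional radius scan, species-level random slopes for the significant
predictors, seasonal paired contrasts with FDR, and trade-off regressions.
All outputs are plain CSV/JSON under a run directory with a manifest (config
hash, seed, input checksums, decisions in effect) so a run can be re-created
exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PREDICTOR_GROUPS, PREDICTORS, SEASONS, SimulationConfig
from .dataio import Study, read_newick, write_study
from .distances import build_species_distances, write_distance_matrix
from .errors import InvalidArgumentError
from .habitat import topography_table
from .neighborhood import DEFAULT_D_MIN_M, DEFAULT_RADIUS_M, build_neighborhood_table
from .species import (
    SlopeModel,
    adjust_contrasts,
    fit_species_slopes,
    seasonal_paired_test,
    tradeoff_regression,
)
from .survival import (
    SurvivalFit,
    fit_survival_glmm,
    overdispersion_check,
    partition_importance,
    prepare_design,
    scan_radius,
)
from .synthetic import simulate_study, substream

log = logging.getLogger("seedlingndd")

#: Predictors classed as biotic crowding vs abiotic drivers for the
#: trade-off regressions (x = abiotic sensitivity, y = biotic sensitivity).
BIOTIC = ["s_con", "a_con", "s_totpd", "a_totpd", "s_totfd", "a_totfd"]
ABIOTIC = ["canopy", "rainfall"]


@dataclass
class AnalysisOptions:
    seasons: tuple[str, ...] = SEASONS
    functional_method: str = "dendrogram-cophenetic"
    radius_m: float = DEFAULT_RADIUS_M
    d_min_m: float = DEFAULT_D_MIN_M
    scan_radii: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    do_radius_scan: bool = True
    do_importance: bool = True
    importance_mode: str = "fixed-theta"
    per_predictor_importance: bool = False
    do_species_effects: bool = True
    slope_predictors: tuple[str, ...] | None = None   # None = significant ones
    do_dispersion: bool = True
    n_boot: int = 250
    alpha: float = 0.05
    year_as_fixed: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisOptions":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidArgumentError(f"unknown analysis options: {sorted(unknown)}")
        d = dict(d)
        for key in ("seasons", "scan_radii", "slope_predictors"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class AnalysisResult:
    fits: dict[str, SurvivalFit]
    importance: dict[str, pd.DataFrame]
    grouped_importance: dict[str, pd.Series]
    dispersion: dict[str, tuple[float, float]]
    slope_models: dict[tuple[str, str], SlopeModel]   # (season, predictor)
    contrasts: pd.DataFrame
    tradeoffs: pd.DataFrame
    radius_scan: dict[str, pd.DataFrame]
    selected_radius: dict[str, float]
    distances_method: str = "dendrogram-cophenetic"
    designs: dict = field(default_factory=dict)


def analyze_study(study: Study, options: AnalysisOptions | None = None) -> AnalysisResult:
    options = options or AnalysisOptions()
    tree = read_newick(study.newick)
    species = sorted(set(study.censuses["species"]) | set(study.stems["species"]))
    distances = build_species_distances(
        tree, study.traits, species=species, functional_method=options.functional_method
    )
    topo = topography_table(study.corner_elevations, side_m=study.subplot_size_m)
    rainfall = study.seasonal_rainfall()
    nbhd = build_neighborhood_table(
        study.censuses,
        study.stems,
        distances,
        plot_size_m=study.plot_size_m,
        subplot_size_m=study.subplot_size_m,
        radius_m=options.radius_m,
        d_min_m=options.d_min_m,
    )

    fits: dict[str, SurvivalFit] = {}
    designs = {}
    importance: dict[str, pd.DataFrame] = {}
    grouped: dict[str, pd.Series] = {}
    dispersion: dict[str, tuple[float, float]] = {}
    slope_models: dict[tuple[str, str], SlopeModel] = {}
    scan_tables: dict[str, pd.DataFrame] = {}
    selected_radius: dict[str, float] = {}

    for season in options.seasons:
        log.info("fitting %s-season community model", season)
        design = prepare_design(
            study.censuses, nbhd, topo, study.soil, study.canopy, rainfall, season
        )
        fit = fit_survival_glmm(design, year_as_fixed=options.year_as_fixed)
        designs[season] = design
        fits[season] = fit
        if options.do_importance:
            if options.per_predictor_importance:
                units = {c: [c] for c in design.X.columns}
                imp = partition_importance(fit, groups=units, mode=options.importance_mode)
                from .survival import grouped_importance as _gi

                grouped[season] = _gi(imp, PREDICTOR_GROUPS)
            else:
                imp = partition_importance(fit, mode=options.importance_mode)
                grouped[season] = imp.set_index("unit")["share_pct"]
            importance[season] = imp
            fit.importance = imp
        if options.do_dispersion:
            seed = int(substream(options.seed, f"dispersion-{season}").integers(2**31))
            dispersion[season] = overdispersion_check(fit, n_boot=options.n_boot, seed=seed)
            fit.dispersion = dispersion[season]
        if options.do_radius_scan:
            log.info("radius scan, %s season", season)
            scan_tables[season], selected_radius[season] = scan_radius(
                study, distances, season, radii=options.scan_radii, d_min_m=options.d_min_m
            )

    contrasts_rows: list = []
    tradeoff_rows: list = []
    if options.do_species_effects:
        if options.slope_predictors is not None:
            predictors = list(options.slope_predictors)
        else:
            sig: list[str] = []
            for fit in fits.values():
                sig.extend(fit.significant_predictors(options.alpha))
            predictors = [p for p in PREDICTORS if p in set(sig)]
        for season in options.seasons:
            for predictor in predictors:
                slope_models[(season, predictor)] = fit_species_slopes(
                    designs[season], predictor, base_fit=fits[season]
                )
        if set(options.seasons) >= {"dry", "rainy"}:
            contrasts = []
            for predictor in predictors:
                try:
                    contrasts.append(
                        seasonal_paired_test(
                            slope_models[("dry", predictor)].coefficients,
                            slope_models[("rainy", predictor)].coefficients,
                            predictor,
                        )
                    )
                except InvalidArgumentError as exc:
                    log.warning("contrast for %s skipped: %s", predictor, exc)
            adjust_contrasts(contrasts)
            contrasts_rows = [vars(c) for c in contrasts]
            for season in options.seasons:
                for x_pred in [p for p in predictors if p in ABIOTIC]:
                    for y_pred in [p for p in predictors if p in BIOTIC]:
                        try:
                            t = tradeoff_regression(
                                slope_models[(season, x_pred)].coefficients,
                                slope_models[(season, y_pred)].coefficients,
                                season,
                                x_predictor=x_pred,
                                y_predictor=y_pred,
                            )
                            tradeoff_rows.append(vars(t))
                        except InvalidArgumentError as exc:
                            log.warning("trade-off %s~%s (%s) skipped: %s", y_pred, x_pred, season, exc)

    return AnalysisResult(
        fits=fits,
        importance=importance,
        grouped_importance=grouped,
        dispersion=dispersion,
        slope_models=slope_models,
        contrasts=pd.DataFrame(contrasts_rows),
        tradeoffs=pd.DataFrame(tradeoff_rows),
        radius_scan=scan_tables,
        selected_radius=selected_radius,
        distances_method=options.functional_method,
        designs=designs,
    )


# ---------------------------------------------------------------------------
# result persistence and manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(result: AnalysisResult, out_dir, options: AnalysisOptions,
                  input_files: dict[str, str] | None = None) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for season, fit in result.fits.items():
        p = out / f"coefficients_{season}.csv"
        fit.coefficients.to_csv(p, index=False)
        written.append(p)
    for season, imp in result.importance.items():
        p = out / f"importance_{season}.csv"
        imp.to_csv(p, index=False)
        written.append(p)
    for season, table in result.radius_scan.items():
        p = out / f"radius_scan_{season}.csv"
        table.to_csv(p, index=False)
        written.append(p)
    if result.slope_models:
        frames = []
        for (season, predictor), sm in result.slope_models.items():
            t = sm.coefficients.copy()
            t.insert(0, "season", season)
            t.insert(1, "predictor", predictor)
            t["lrt_chi2"] = sm.lrt_chi2
            t["lrt_p"] = sm.lrt_p
            t["fallback"] = sm.fallback
            frames.append(t)
        p = out / "species_coefficients.csv"
        pd.concat(frames, ignore_index=True).to_csv(p, index=False)
        written.append(p)
    if len(result.contrasts):
        p = out / "contrasts.csv"
        result.contrasts.to_csv(p, index=False)
        written.append(p)
    if len(result.tradeoffs):
        p = out / "tradeoffs.csv"
        result.tradeoffs.to_csv(p, index=False)
        written.append(p)
    diagnostics = {
        season: {
            "loglik": fit.loglik,
            "aic": fit.aic,
            "n_obs": fit.n_obs,
            "converged": fit.converged,
            "r2_marginal": fit.r2_marginal,
            "r2_conditional": fit.r2_conditional,
            "re_var": fit.re_var,
            "dispersion": list(result.dispersion.get(season, ())) or None,
            "selected_radius_m": result.selected_radius.get(season),
        }
        for season, fit in result.fits.items()
    }
    p = out / "diagnostics.json"
    p.write_text(json.dumps(diagnostics, indent=2, default=float))
    written.append(p)
    options_dict = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(options).items()}
    manifest = {
        "created_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "package_version": __version__,
        "seed": options.seed,
        "options": options_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(options_dict, sort_keys=True).encode()
        ).hexdigest(),
        "decisions": {
            "functional_distance_method": options.functional_method,
            "adult_abundance_convention": "stem count within radius",
            "d_min_m": options.d_min_m,
            "radius_m": options.radius_m,
            "importance_mode": options.importance_mode,
        },
        "inputs_sha256": {
            k: _sha256(Path(v)) for k, v in (input_files or {}).items() if Path(v).exists()
        },
        "outputs": sorted(str(p.relative_to(out)) for p in written),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest


# ---------------------------------------------------------------------------
# simulate / recover entry points
# ---------------------------------------------------------------------------

def run_simulate(config: SimulationConfig, out_dir, force: bool = False) -> dict[str, str]:
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise InvalidArgumentError(
            f"output directory {out} is not empty; pass force=True (--force) to overwrite"
        )
    study = simulate_study(config)
    files = write_study(study, out)
    config.to_yaml(out / "config.yml")
    files["config"] = str(out / "config.yml")
    checksums = {k: _sha256(Path(v)) for k, v in files.items()}
    manifest = {
        "created_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "files_sha256": checksums,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return files


def run_recovery(
    config: SimulationConfig,
    n_replicates: int,
    seed: int,
    contrast_predictor: str = "s_totpd",
    seasons: tuple[str, ...] = SEASONS,
) -> pd.DataFrame:
    """Simulate-then-fit loop reporting bias, RMSE and CI coverage per
    coefficient (raw per-unit scale) plus the seasonal-contrast sign rate.

    Coverage compares each replicate's Wald interval with the generator's
    truth expressed in that replicate's standardization units, which is exact
    under any monotone rescaling of the predictors.
    """
    if n_replicates < 2:
        raise InvalidArgumentError("n_replicates must be >= 2")
    rows = []
    sign_hits = []
    rng = substream(seed, "recover")
    slope = contrast_predictor in config.slope_sd
    theta0 = {s: None for s in seasons}
    for rep in range(n_replicates):
        cfg = SimulationConfig.from_dict(
            {**config.to_dict(), "seed": int(rng.integers(2**31))}
        )
        study = simulate_study(cfg)
        res = analyze_study(
            study,
            AnalysisOptions(
                seasons=seasons,
                do_radius_scan=False,
                do_importance=False,
                do_dispersion=False,
                do_species_effects=slope,
                slope_predictors=(contrast_predictor,) if slope else None,
                seed=cfg.seed,
            ),
        )
        for season in seasons:
            # with injected slope heterogeneity the generating model is the
            # random-slope model, so coverage is read off that fit
            fit = res.fits[season]
            if slope:
                sm = res.slope_models[(season, contrast_predictor)]
                if not sm.fallback and sm.fit is not None:
                    fit = sm.fit
            design = res.designs[season]
            for term in PREDICTORS:
                row = fit.coefficient(term)
                _, s_inf = design.scaling[term]
                truth_std = study.truth.config.beta(term, season) * (
                    s_inf / study.truth.scaling[season][term][1]
                )
                est, se = row["estimate"], row["se"]
                rows.append(
                    {
                        "replicate": rep,
                        "season": season,
                        "term": term,
                        "estimate_raw": est / s_inf,
                        "truth_raw": study.truth.true_beta_raw(term, season),
                        "covered": abs(est - truth_std) <= 1.959963984540054 * se,
                    }
                )
        if slope and set(seasons) >= {"dry", "rainy"}:
            c = seasonal_paired_test(
                res.slope_models[("dry", contrast_predictor)].coefficients,
                res.slope_models[("rainy", contrast_predictor)].coefficients,
                contrast_predictor,
            )
            true_diff = config.beta(contrast_predictor, "rainy") - config.beta(
                contrast_predictor, "dry"
            )
            sign_hits.append(np.sign(c.t_statistic) == np.sign(true_diff))
    detail = pd.DataFrame(rows)
    report = (
        detail.groupby(["season", "term"])
        .apply(
            lambda g: pd.Series(
                {
                    "bias": (g["estimate_raw"] - g["truth_raw"]).mean(),
                    "rmse": np.sqrt(((g["estimate_raw"] - g["truth_raw"]) ** 2).mean()),
                    "coverage": g["covered"].mean(),
                    "n_replicates": len(g),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    if sign_hits:
        report.attrs["contrast_sign_rate"] = float(np.mean(sign_hits))
        report.attrs["contrast_predictor"] = contrast_predictor
    return report
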