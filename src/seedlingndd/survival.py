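"""Season-level survival models: design assembly, fitting, diagnostics.

This is the community-level analysis: per season (dry or rainy), a Bernoulli
GLMM of seedling survival on log initial height, the six neighborhood
crowding metrics, canopy openness, three habitat principal components and
seasonal rainfall, with crossed random intercepts for species, quadrat and
census year.  Companion routines compute Nakagawa marginal/conditional R^2,
a parametric-bootstrap overdispersion check, hierarchical partitioning of
fixed-effect importance, and the AIC scan over adult-neighborhood radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import PREDICTORS, PREDICTOR_GROUPS
from .dataio import Study
from .distances import SpeciesDistances
from .errors import InvalidArgumentError, InvalidStateError
from .glmm import GLMMFit, REBlock, fit_laplace_glmm
from .habitat import PcaResult, assemble_habitat, topography_table
from .neighborhood import DEFAULT_D_MIN_M, DEFAULT_RADIUS_M, build_neighborhood_table

LOGIT_RESIDUAL_VAR = np.pi**2 / 3.0


@dataclass
class ModelDesign:
    """Standardized per-season design ready for fitting."""

    season: str
    y: np.ndarray
    X: pd.DataFrame                    # standardized predictor columns
    groups: pd.DataFrame               # species / quadrat_id / year per row
    scaling: dict[str, tuple[float, float]]
    ids: pd.DataFrame                  # seedling_id / interval_id per row
    pca: PcaResult | None = None
    raw: pd.DataFrame | None = None

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def standardize_like(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Apply this design's stored scaling to a raw predictor table."""
        out = {}
        for col in self.X.columns:
            m, s = self.scaling[col]
            out[col] = (raw[col].to_numpy(dtype=float) - m) / s
        return pd.DataFrame(out, index=raw.index)


@dataclass
class SurvivalFit:
    """Community-level fit results; diagnostics filled by their own routines."""

    season: str
    coefficients: pd.DataFrame         # term / estimate / se / z / p
    re_var: dict[str, float]
    loglik: float
    aic: float
    converged: bool
    n_obs: int
    r2_marginal: float
    r2_conditional: float
    design: ModelDesign = field(repr=False, default=None)
    glmm: GLMMFit = field(repr=False, default=None)
    dispersion: tuple[float, float] | None = None
    importance: pd.DataFrame | None = None

    def coefficient(self, term: str) -> pd.Series:
        row = self.coefficients[self.coefficients["term"] == term]
        if row.empty:
            raise InvalidArgumentError(f"no coefficient for term {term!r}")
        return row.iloc[0]

    def significant_predictors(self, alpha: float = 0.05) -> list[str]:
        c = self.coefficients
        keep = (c["p"] < alpha) & (c["term"] != "intercept")
        return [t for t in c.loc[keep, "term"] if t in PREDICTORS]


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def standardize_columns(
    raw: pd.DataFrame,
    columns: list[str],
    scaling: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """z-score columns (sample SD); with *scaling* given, reuse stored moments."""
    out = {}
    used = {}
    for col in columns:
        x = raw[col].to_numpy(dtype=float)
        if scaling is None:
            m = float(np.mean(x))
            s = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
            if not np.isfinite(s) or s < 1e-12:
                raise InvalidArgumentError(
                    f"predictor {col!r} has zero variance in this subset; cannot standardize"
                )
        else:
            m, s = scaling[col]
        out[col] = (x - m) / s
        used[col] = (m, s)
    return pd.DataFrame(out, index=raw.index), used


def prepare_design(
    censuses: pd.DataFrame,
    neighborhood: pd.DataFrame,
    topo: pd.DataFrame,
    soil: pd.DataFrame,
    canopy: pd.Series,
    rainfall_by_interval: dict[str, float],
    season: str,
    scaling: dict[str, tuple[float, float]] | None = None,
    n_components: int = 3,
) -> ModelDesign:
    """Join all predictor tables for one season and standardize.

    The habitat PCA is recomputed on the quadrats present in the season
    subset.  Initial height is log-transformed before standardization.  The
    per-column scaling is stored on the design so synthetic-truth comparisons
    can reuse it.
    """
    sub = censuses[censuses["season"] == season].copy()
    if sub.empty:
        raise InvalidArgumentError(f"no census rows for season {season!r}")
    merged = sub.merge(neighborhood, on=["seedling_id", "interval_id"], how="left", validate="1:1")
    lost = merged["s_con"].isna()
    if lost.any():
        ids = sorted(merged.loc[lost, "seedling_id"].unique()[:10])
        raise InvalidArgumentError(
            f"seedlings without neighborhood records in season {season!r}: {ids}"
        )
    habitat_df, pca = assemble_habitat(
        topo, soil, canopy, quadrats=sorted(set(sub["quadrat_id"])), n_components=n_components
    )
    merged = merged.merge(
        habitat_df.rename_axis("quadrat_id").reset_index(), on="quadrat_id", how="left"
    )
    missing_iv = sorted(set(merged["interval_id"]) - set(rainfall_by_interval))
    if missing_iv:
        raise InvalidArgumentError(f"intervals without a rainfall total: {missing_iv}")
    merged["rainfall"] = merged["interval_id"].map(rainfall_by_interval)
    merged["log_height"] = np.log(merged["height_cm"].to_numpy(dtype=float))
    raw = merged[PREDICTORS].copy()
    X, used_scaling = standardize_columns(raw, PREDICTORS, scaling)
    return ModelDesign(
        season=season,
        y=merged["y"].to_numpy(dtype=float),
        X=X,
        groups=merged[["species", "quadrat_id", "year"]].reset_index(drop=True),
        scaling=used_scaling,
        ids=merged[["seedling_id", "interval_id"]].reset_index(drop=True),
        pca=pca,
        raw=raw,
    )


def _blocks_from_design(
    design: ModelDesign, random_slopes: list[str] | None
) -> tuple[list[REBlock], dict[str, list[str]]]:
    levels = {}
    blocks = []
    slope_cols = list(random_slopes or [])
    if len(slope_cols) > 1:
        raise InvalidArgumentError("random slopes are added one predictor at a time")
    for name, col in (("species", "species"), ("quadrat", "quadrat_id"), ("year", "year")):
        labels = sorted(pd.unique(design.groups[col].astype(str)))
        codes = design.groups[col].astype(str).map({l: i for i, l in enumerate(labels)}).to_numpy()
        levels[name] = labels
        slope = None
        if name == "species" and slope_cols:
            slope = design.X[slope_cols[0]].to_numpy(dtype=float)
        blocks.append(REBlock(name=name, codes=codes, n_levels=len(labels), slope=slope))
    return blocks, levels


def fit_survival_glmm(
    design: ModelDesign,
    random_slopes: list[str] | None = None,
    columns: list[str] | None = None,
    theta0=None,
    fixed_theta=None,
    year_as_fixed: bool = False,
) -> SurvivalFit:
    """Fit the community survival GLMM on a prepared design.

    ``columns`` restricts the fixed effects (used by the importance
    partitioner); the intercept is always included.  ``year_as_fixed``
    demotes census year from a random intercept to fixed dummies, the
    recommended fallback when a season has very few year levels.
    """
    cols = list(columns) if columns is not None else list(design.X.columns)
    unknown = sorted(set(cols) - set(design.X.columns))
    if unknown:
        raise InvalidArgumentError(f"unknown design columns: {unknown}")
    X = np.column_stack([np.ones(design.n_obs)] + [design.X[c].to_numpy() for c in cols])
    names = ["intercept"] + cols
    blocks, levels = _blocks_from_design(design, random_slopes)
    if year_as_fixed:
        year_blk = blocks.pop()
        for lvl in levels["year"][1:]:
            X = np.column_stack([X, (design.groups["year"].astype(str) == lvl).to_numpy(float)])
            names.append(f"year_{lvl}")
    fit = fit_laplace_glmm(design.y, X, blocks, theta0=theta0, fixed_theta=fixed_theta)
    se = np.sqrt(np.diag(fit.cov_beta))
    z = fit.beta / se
    coef = pd.DataFrame(
        {
            "term": names,
            "estimate": fit.beta,
            "se": se,
            "z": z,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
        }
    )
    r2m, r2c = r2_nakagawa_from(fit)
    return SurvivalFit(
        season=design.season,
        coefficients=coef,
        re_var=fit.re_var,
        loglik=fit.loglik,
        aic=fit.aic,
        converged=fit.converged,
        n_obs=fit.n_obs,
        r2_marginal=r2m,
        r2_conditional=r2c,
        design=design,
        glmm=fit,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def r2_nakagawa_from(fit: GLMMFit) -> tuple[float, float]:
    """Marginal and conditional R^2 on the latent-logit scale.

    marginal = var(fixed predictor) / (var(fixed) + var(random) + pi^2/3);
    conditional adds the random-effect variance to the numerator.
    """
    var_fixed = float(np.var(fit.X @ fit.beta))
    var_random = fit.re_variance_row_mean()
    denom = var_fixed + var_random + LOGIT_RESIDUAL_VAR
    return var_fixed / denom, (var_fixed + var_random) / denom


def r2_nakagawa(fit: SurvivalFit) -> tuple[float, float]:
    if not fit.converged:
        raise InvalidStateError("r2_nakagawa requires a converged fit")
    return r2_nakagawa_from(fit.glmm)


def pearson_dispersion(fit: GLMMFit) -> float:
    """Pearson chi-square over residual degrees of freedom."""
    resid2 = (fit.y - fit.mu) ** 2 / (fit.mu * (1.0 - fit.mu))
    df = fit.n_obs - (fit.beta.size + fit.theta.size)
    return float(resid2.sum() / df)


def overdispersion_check(
    fit: SurvivalFit | GLMMFit, n_boot: int = 250, seed: int = 0
) -> tuple[float, float]:
    """Dispersion ratio and its two-sided parametric-bootstrap p-value.

    Bootstrap datasets are simulated from the fitted model (fresh random
    effects each draw), refit with the same structure, and the null
    distribution of the ratio compared against the observed one.
    """
    g = fit.glmm if isinstance(fit, SurvivalFit) else fit
    if isinstance(fit, SurvivalFit) and not fit.converged:
        raise InvalidStateError("overdispersion_check requires a converged fit")
    observed = pearson_dispersion(g)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_boot)
    for i in range(n_boot):
        y_star = g.simulate_response(rng)
        refit = fit_laplace_glmm(y_star, g.X, g.blocks, theta0=g.theta, beta0=g.beta)
        sims[i] = pearson_dispersion(refit)
    p_hi = (1 + np.sum(sims >= observed)) / (n_boot + 1)
    p_lo = (1 + np.sum(sims <= observed)) / (n_boot + 1)
    return observed, float(min(1.0, 2.0 * min(p_hi, p_lo)))


# ---------------------------------------------------------------------------
# relative importance
# ---------------------------------------------------------------------------

def partition_importance(
    fit: SurvivalFit,
    groups: dict[str, list[str]] | None = None,
    mode: str = "fixed-theta",
) -> pd.DataFrame:
    """Hierarchical partitioning of fixed-effect importance by marginal R^2.

    For every subset of predictor units the model is re-estimated and its
    marginal R^2 computed; each unit's share is the average of its R^2
    increment over all entry orderings (Chevan-Sutherland), normalized to sum
    to 100.  Units default to the height / biotic / habitat / rainfall
    predictor groups; pass ``{name: [name] for name in ...}`` for
    per-predictor partitioning (2^k refits -- refuse above 14 units).
    ``mode='fixed-theta'`` re-estimates only (beta, u) at the full-model
    variance parameters; ``mode='refit'`` re-optimizes them per subset.
    """
    if groups is None:
        groups = {k: [c for c in v if c in fit.design.X.columns] for k, v in PREDICTOR_GROUPS.items()}
        groups = {k: v for k, v in groups.items() if v}
    units = list(groups)
    k = len(units)
    if k > 14:
        raise InvalidArgumentError(
            f"{k} units would need 2^{k} refits; group predictors first"
        )
    if mode not in ("fixed-theta", "refit"):
        raise InvalidArgumentError(f"unknown importance mode {mode!r}")
    kwargs = {}
    if mode == "fixed-theta":
        kwargs["fixed_theta"] = fit.glmm.theta
    else:
        kwargs["theta0"] = fit.glmm.theta

    r2_of: dict[frozenset, float] = {frozenset(): 0.0}
    for mask in range(1, 2**k):
        subset = frozenset(units[i] for i in range(k) if mask >> i & 1)
        cols = [c for u in units for c in groups[u] if u in subset]
        sub_fit = fit_survival_glmm(fit.design, columns=cols, **kwargs)
        r2_of[subset] = sub_fit.r2_marginal

    from math import factorial

    shares = {}
    for i, unit in enumerate(units):
        others = [u for u in units if u != unit]
        total = 0.0
        for mask in range(2 ** (k - 1)):
            S = frozenset(others[j] for j in range(k - 1) if mask >> j & 1)
            w = factorial(len(S)) * factorial(k - 1 - len(S)) / factorial(k)
            total += w * (r2_of[S | {unit}] - r2_of[S])
        shares[unit] = total
    raw = np.array([shares[u] for u in units])
    raw = np.maximum(raw, 0.0)
    if raw.sum() <= 0:
        raise InvalidStateError("no fixed-effect explained variance to partition")
    out = pd.DataFrame(
        {
            "unit": units,
            "r2_increment": [shares[u] for u in units],
            "share_pct": 100.0 * raw / raw.sum(),
        }
    )
    return out


def grouped_importance(per_predictor: pd.DataFrame, groups: dict[str, list[str]]) -> pd.Series:
    """Aggregate per-predictor shares into named groups (percentages)."""
    lookup = {p: g for g, ps in groups.items() for p in ps}
    agg = per_predictor.assign(group=per_predictor["unit"].map(lookup)).groupby("group")[
        "share_pct"
    ].sum()
    return agg


# ---------------------------------------------------------------------------
# radius scan
# ---------------------------------------------------------------------------

def scan_radius(
    study: Study,
    distances: SpeciesDistances,
    season: str,
    radii=(5.0, 10.0, 15.0, 20.0),
    d_min_m: float = DEFAULT_D_MIN_M,
    quadrat_size_m: float = 2.0,
) -> tuple[pd.DataFrame, float]:
    """Refit the full survival model with adult metrics rebuilt at each radius.

    Returns the AIC table (one row per radius) and the selected radius: the
    smallest radius whose AIC is within 1e-6 of the minimum (ties break to
    the smaller neighborhood).
    """
    radii = list(radii)
    if any(r <= 0 for r in radii) or sorted(radii) != radii:
        raise InvalidArgumentError("radii must be positive and increasing")
    topo = topography_table(study.corner_elevations, side_m=study.subplot_size_m)
    rainfall = study.seasonal_rainfall()
    rows = []
    for r in radii:
        nbhd = build_neighborhood_table(
            study.censuses,
            study.stems,
            distances,
            plot_size_m=study.plot_size_m,
            subplot_size_m=study.subplot_size_m,
            quadrat_size_m=quadrat_size_m,
            radius_m=r,
            d_min_m=d_min_m,
        )
        try:
            design = prepare_design(
                study.censuses, nbhd, topo, study.soil, study.canopy, rainfall, season
            )
            fit = fit_survival_glmm(design)
            rows.append({"radius_m": r, "aic": fit.aic, "loglik": fit.loglik,
                         "converged": fit.converged, "error": ""})
        except Exception as exc:  # keep scanning the remaining radii
            rows.append({"radius_m": r, "aic": np.nan, "loglik": np.nan,
                         "converged": False, "error": str(exc)})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["aic"])
    if valid.empty:
        raise InvalidStateError("no radius produced a successful fit")
    best = valid["aic"].min()
    selected = float(valid.loc[valid["aic"] <= best + 1e-6, "radius_m"].min())
    return table, selected
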