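"""Species-level sensitivities, seasonal contrasts and trade-off regressions.

Species-specific coefficients are shrunken conditional modes: the model is
refit with a species-level random slope (correlated with the species random
intercept) for one predictor at a time, and each species' coefficient is the
community fixed slope plus that species' conditional mode, with a CI from
the conditional-mode SD.  Likelihood-ratio tests assess the slope term;
paired t-tests compare species coefficients between seasons (BH-FDR across
the tested predictors); ordinary least squares quantifies trade-offs between
sensitivities to biotic crowding and to abiotic drivers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError
from .glmm import ConvergenceError
from .survival import ModelDesign, SurvivalFit, fit_survival_glmm

Z95 = stats.norm.ppf(0.975)


@dataclass
class SlopeModel:
    """Random-slope refit for one predictor plus its LRT against intercepts-only."""

    predictor: str
    season: str
    coefficients: pd.DataFrame    # species / coefficient / ci_low / ci_high / n_individuals
    lrt_chi2: float
    lrt_df: int
    lrt_p: float
    fit: SurvivalFit | None = None
    fallback: bool = False        # True when the slope model failed to converge


@dataclass
class SeasonContrast:
    predictor: str
    t_statistic: float
    df: int
    p_raw: float
    n_pairs: int
    mean_difference: float        # rainy minus dry
    p_fdr: float = np.nan


@dataclass
class TradeoffRegression:
    season: str
    x_predictor: str
    y_predictor: str
    slope: float
    intercept: float
    r2: float
    p: float
    n_species: int


# ---------------------------------------------------------------------------

def fit_species_slopes(
    design: ModelDesign,
    predictor: str,
    base_fit: SurvivalFit | None = None,
) -> SlopeModel:
    """Species-specific coefficients for one standardized predictor.

    The LRT compares the random-slope model (slope variance + intercept-slope
    covariance, 2 extra parameters) against the random-intercepts model; the
    chi-square reference is conservative at the variance boundary (the usual
    mixture-of-chi-squares caveat).  On non-convergence the fixed slope is
    returned for every species with ``fallback=True``.
    """
    if predictor not in design.X.columns:
        raise InvalidArgumentError(f"predictor {predictor!r} not in the design")
    if base_fit is None:
        base_fit = fit_survival_glmm(design)
    species = sorted(pd.unique(design.groups["species"].astype(str)))
    n_ind = (
        design.ids.assign(species=design.groups["species"].astype(str))
        .groupby("species")["seedling_id"]
        .nunique()
    )

    def fallback_table() -> pd.DataFrame:
        row = base_fit.coefficient(predictor)
        return pd.DataFrame(
            {
                "species": species,
                "coefficient": row["estimate"],
                "ci_low": row["estimate"] - Z95 * row["se"],
                "ci_high": row["estimate"] + Z95 * row["se"],
                "n_individuals": [int(n_ind.get(s, 0)) for s in species],
            }
        )

    try:
        theta0 = np.concatenate([[base_fit.glmm.theta[0], 0.0, 0.3], base_fit.glmm.theta[1:]])
        slope_fit = fit_survival_glmm(design, random_slopes=[predictor], theta0=theta0)
        converged = slope_fit.converged
    except ConvergenceError:
        converged = False
        slope_fit = None
    if not converged:
        return SlopeModel(
            predictor=predictor,
            season=design.season,
            coefficients=fallback_table(),
            lrt_chi2=np.nan,
            lrt_df=2,
            lrt_p=np.nan,
            fit=slope_fit,
            fallback=True,
        )
    chi2 = max(0.0, 2.0 * (slope_fit.loglik - base_fit.loglik))
    lrt_p = float(stats.chi2.sf(chi2, df=2))
    modes = slope_fit.glmm.conditional_modes("species")
    fixed = float(slope_fit.coefficient(predictor)["estimate"])
    coef = fixed + modes["slope"]
    sd = modes["slope_sd"]
    table = pd.DataFrame(
        {
            "species": species,
            "coefficient": coef,
            "ci_low": coef - Z95 * sd,
            "ci_high": coef + Z95 * sd,
            "n_individuals": [int(n_ind.get(s, 0)) for s in species],
        }
    )
    return SlopeModel(
        predictor=predictor,
        season=design.season,
        coefficients=table,
        lrt_chi2=chi2,
        lrt_df=2,
        lrt_p=lrt_p,
        fit=slope_fit,
    )


# ---------------------------------------------------------------------------

def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, rank-monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def seasonal_paired_test(
    coeffs_dry: pd.DataFrame, coeffs_rainy: pd.DataFrame, predictor: str
) -> SeasonContrast:
    """Paired t-test of species coefficients, rainy minus dry.

    Species present in only one season drop out of the pairing; fewer than 3
    shared species or an exactly constant difference vector is an error.
    """
    merged = coeffs_dry.merge(coeffs_rainy, on="species", suffixes=("_dry", "_rainy"))
    n = len(merged)
    if n < 3:
        raise InvalidArgumentError(
            f"paired test for {predictor!r} needs >= 3 species present in both seasons, got {n}"
        )
    diff = merged["coefficient_rainy"].to_numpy() - merged["coefficient_dry"].to_numpy()
    sd = diff.std(ddof=1)
    if sd < 1e-14:
        raise InvalidArgumentError(
            f"paired differences for {predictor!r} have zero variance; t is undefined"
        )
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return SeasonContrast(
        predictor=predictor,
        t_statistic=float(t),
        df=n - 1,
        p_raw=float(p),
        n_pairs=n,
        mean_difference=float(diff.mean()),
    )


def adjust_contrasts(contrasts: list[SeasonContrast]) -> list[SeasonContrast]:
    """BH-FDR across the family of predictors tested in one analysis."""
    adjusted = fdr_adjust([c.p_raw for c in contrasts])
    for c, q in zip(contrasts, adjusted):
        c.p_fdr = float(q)
    return contrasts


# ---------------------------------------------------------------------------

def tradeoff_regression(
    coeffs_x: pd.DataFrame,
    coeffs_y: pd.DataFrame,
    season: str,
    x_predictor: str = "",
    y_predictor: str = "",
) -> TradeoffRegression:
    """OLS of y-sensitivity on x-sensitivity across species (one season)."""
    merged = coeffs_x.merge(coeffs_y, on="species", suffixes=("_x", "_y"))
    n = len(merged)
    if n < 3:
        raise InvalidArgumentError(f"trade-off regression needs >= 3 matched species, got {n}")
    x = merged["coefficient_x"].to_numpy()
    y = merged["coefficient_y"].to_numpy()
    if x.std(ddof=1) < 1e-14:
        raise InvalidArgumentError("x sensitivities are constant; slope undefined")
    res = stats.linregress(x, y)
    return TradeoffRegression(
        season=season,
        x_predictor=x_predictor,
        y_predictor=y_predictor,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n_species=n,
    )
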