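"""Synthetic forest community with known survival-model ground truth.

Every downstream stage can be exercised end-to-end on data whose generating
parameters are known exactly: a pure-birth phylogeny, Brownian leaf traits,
a smooth terrain with spatially structured soil and canopy, a Thomas-cluster
stem map, and seedling survival histories drawn from the same logistic mixed
model the inference side fits (true betas per season, random intercepts for
species / quadrat / census year, optional per-species slope heterogeneity).

Predictors entering the generative logit are built by the *same* habitat,
distance and neighborhood modules used for inference, standardized with a
per-season scaling computed from the season's first-interval cohort (the
only cohort known before outcomes are drawn; rainfall, constant within a
cohort, is scaled by the configured per-interval totals instead).  The
scaling, raw design, latent logits and random-effect draws are all stored in
the study truth so tests can compare estimates to truth on the raw
(per-unit) scale without any standardization ambiguity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .config import PREDICTORS, SOIL_VARIABLES, SimulationConfig
from .dataio import Study, quadrat_centers, quadrat_id, read_newick
from .distances import SpeciesDistances, build_species_distances
from .errors import InvalidArgumentError, InvalidStateError
from .habitat import assemble_habitat, topography_table
from .neighborhood import DEFAULT_D_MIN_M, DEFAULT_RADIUS_M, _adult_summaries
from .survival import standardize_columns


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, stable random substream derived from (seed, module name)."""
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


# ---------------------------------------------------------------------------
# phylogeny and traits
# ---------------------------------------------------------------------------

def simulate_phylogeny(n_species: int, birth_rate: float, seed: int) -> str:
    """Ultrametric pure-birth (Yule) tree as newick text, tips sp001..spNNN.

    Lineages split at rate ``birth_rate`` each; after the n-th lineage
    appears, one further exponential wait sets the present so terminal
    branches are never zero.  Tip labels are assigned in ladder traversal
    order, so equal seeds give byte-identical newick.
    """
    if n_species < 2:
        raise InvalidArgumentError("n_species must be >= 2")
    if birth_rate <= 0:
        raise InvalidArgumentError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    # node records: birth time, children ids (empty = tip so far)
    birth = [0.0, 0.0]
    children: list[list[int]] = [[], []]
    alive = [0, 1]  # the root split starts the clock at t = 0
    t = 0.0
    while len(alive) < n_species:
        k = len(alive)
        t += rng.exponential(1.0 / (birth_rate * k))
        which = int(rng.integers(k))
        node = alive.pop(which)
        left, right = len(birth), len(birth) + 1
        birth.extend([t, t])
        children[node] = [left, right]
        children.extend([[], []])
        alive.extend([left, right])
    t += rng.exponential(1.0 / (birth_rate * n_species))

    counter = {"tip": 0}

    def newick(node: int) -> str:
        if not children[node]:
            counter["tip"] += 1
            return f"sp{counter['tip']:03d}:{t - birth[node]:.10f}"
        inner = ",".join(newick(c) for c in children[node])
        length = birth[children[node][0]] - birth[node]
        return f"({inner}):{length:.10f}"

    left = newick(0)
    right = newick(1)
    return f"({left},{right});"


def simulate_traits(newick: str, sigma2: float, n_traits: int, seed: int) -> pd.DataFrame:
    """Independent Brownian-motion traits along the tree, rows keyed by tip.

    Trait units are abstract; downstream standardization removes scale.
    """
    if sigma2 < 0:
        raise InvalidArgumentError("sigma2 must be >= 0")
    if n_traits < 1:
        raise InvalidArgumentError("n_traits must be >= 1")
    tree = read_newick(newick).tree
    rng = np.random.default_rng(seed)
    values: dict[int, np.ndarray] = {}
    rows = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = np.zeros(n_traits)
        else:
            length = node.edge.length or 0.0
            step = rng.standard_normal(n_traits) * np.sqrt(sigma2 * length)
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            rows[node.taxon.label] = values[id(node)]
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "species"
    out.columns = [f"trait{k + 1}" for k in range(n_traits)]
    return out


# ---------------------------------------------------------------------------
# terrain, soil, canopy
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, n_waves: int = 6):
    """Random unit-variance smooth surface: a sum of oriented sinusoids."""
    wavelengths = np.exp(rng.uniform(np.log(60.0), np.log(250.0), n_waves))
    angles = rng.uniform(0, 2 * np.pi, n_waves)
    phases = rng.uniform(0, 2 * np.pi, n_waves)
    amps = rng.uniform(0.5, 1.0, n_waves)
    norm = np.sqrt(np.sum(amps**2) / 2.0)

    def f(x, y):
        total = np.zeros(np.broadcast(x, y).shape)
        for lam, ang, ph, a in zip(wavelengths, angles, phases, amps):
            total = total + a * np.sin(
                2 * np.pi * (np.cos(ang) * x + np.sin(ang) * y) / lam + ph
            )
        return total / norm

    return f


def simulate_terrain(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Corner-elevation grid (m) at subplot corners plus the continuous DEM.

    The surface combines a south-to-north trend (the plot is high in the
    north) with smooth random relief; ``terrain_amplitude_m`` scales both, so
    zero amplitude is a perfectly flat plot.
    """
    rng = rng if rng is not None else substream(config.seed, "terrain")
    lx, ly = config.plot_size_m
    nx, ny = config.n_subplots
    f = _smooth_field(rng)
    amp = config.terrain_amplitude_m

    def dem(x, y):
        return 1200.0 + amp * (0.6 * (np.asarray(y) / ly - 0.5) + 0.4 * f(x, y))

    xs = np.arange(nx + 1) * config.subplot_size_m
    ys = np.arange(ny + 1) * config.subplot_size_m
    gx, gy = np.meshgrid(xs, ys)
    return dem(gx, gy), dem


#: Latent-factor loadings of the ten soil variables (columns: an
#: elevation-tied factor, a fertility factor, a cation factor).
_SOIL_LOADINGS = np.array(
    [
        # temperature, moisture, ph, ec, omc, ap, ak, tn, tp, tk
        [-0.7, 0.1, 0.0],
        [0.8, 0.2, 0.0],
        [-0.5, -0.2, 0.1],
        [0.1, 0.0, 0.6],
        [0.2, 0.8, 0.0],
        [0.0, 0.5, 0.2],
        [0.0, 0.1, 0.5],
        [0.3, 0.6, 0.0],
        [0.0, 0.4, 0.3],
        [0.1, 0.0, 0.4],
    ]
)

_SOIL_MEANS = np.array([16.0, 25.0, 4.8, 80.0, 6.0, 8.0, 120.0, 0.25, 0.04, 1.2])
_SOIL_SCALES = np.array([1.5, 6.0, 0.4, 25.0, 2.0, 4.0, 40.0, 0.08, 0.015, 0.4])


def simulate_soil(
    config: SimulationConfig,
    quadrat_elevation: pd.Series,
    rng: np.random.Generator | None = None,
    loadings: np.ndarray | None = None,
    noise_sd: float = 0.5,
) -> pd.DataFrame:
    """Ten soil variables per quadrat from a low-rank spatial factor model.

    Factor 1 is the standardized quadrat elevation (so the habitat PCA's
    first axis tracks elevation); the remaining factors are Gaussian-process
    draws with squared-exponential correlation of range
    ``soil_spatial_range_m``.  ``loadings`` overrides the built-in 10 x k
    pattern (used to build degenerate one-factor test cases).
    """
    rng = rng if rng is not None else substream(config.seed, "soil")
    load = _SOIL_LOADINGS if loadings is None else np.asarray(loadings, dtype=float)
    n_factors = load.shape[1]
    centers = quadrat_centers(config.plot_size_m, config.subplot_size_m, config.quadrat_size_m)
    centers = centers.loc[quadrat_elevation.index]
    nq = len(centers)
    elev = quadrat_elevation.to_numpy(dtype=float)
    e_sd = elev.std(ddof=1)
    factors = np.zeros((nq, n_factors))
    factors[:, 0] = (elev - elev.mean()) / e_sd if e_sd > 1e-12 else 0.0
    if n_factors > 1:
        xy = centers[["cx", "cy"]].to_numpy()
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        cov = np.exp(-d2 / (2.0 * config.soil_spatial_range_m**2)) + 1e-8 * np.eye(nq)
        chol = np.linalg.cholesky(cov)
        for k in range(1, n_factors):
            factors[:, k] = chol @ rng.standard_normal(nq)
    z = factors @ load.T + noise_sd * rng.standard_normal((nq, load.shape[0]))
    values = _SOIL_MEANS[: load.shape[0]] + _SOIL_SCALES[: load.shape[0]] * z
    out = pd.DataFrame(values, index=quadrat_elevation.index, columns=SOIL_VARIABLES[: load.shape[0]])
    out.index.name = "quadrat_id"
    return out


def simulate_canopy(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.Series:
    """Canopy openness fraction in (0, 1) per quadrat: patchy understory light."""
    rng = rng if rng is not None else substream(config.seed, "canopy")
    centers = quadrat_centers(config.plot_size_m, config.subplot_size_m, config.quadrat_size_m)
    f = _smooth_field(rng, n_waves=8)
    g = f(centers["cx"].to_numpy(), centers["cy"].to_numpy())
    openness = expit(-1.6 + 0.7 * g + 0.35 * rng.standard_normal(len(centers)))
    out = pd.Series(np.clip(openness, 1e-4, 1 - 1e-4), index=centers.index, name="canopy_openness")
    return out


# ---------------------------------------------------------------------------
# stem map
# ---------------------------------------------------------------------------

def species_labels(n_species: int) -> list[str]:
    return [f"sp{k + 1:03d}" for k in range(n_species)]


def rank_abundances(config: SimulationConfig) -> np.ndarray:
    w = np.exp(-config.abundance_decay * np.arange(config.n_species))
    return w / w.sum()


def simulate_stem_map(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Thomas-cluster stem map: clustered conspecific adults, DBH >= 1 cm.

    Per species, cluster parents are uniform over the plot and offspring are
    Gaussian around them (scale ``cluster_scale_m``), wrapped toroidally so
    the realized intensity matches ``stem_intensity`` x plot area in
    expectation.  DBH is left-truncated lognormal at the 1 cm tagging
    threshold.
    """
    rng = rng if rng is not None else substream(config.seed, "stems")
    lx, ly = config.plot_size_m
    expected_total = config.stem_intensity * lx * ly
    weights = rank_abundances(config)
    labels = species_labels(config.n_species)
    mu, sd = config.dbh_lognorm
    q_min = stats.norm.cdf((np.log(1.0) - mu) / sd)
    xs, ys, sps = [], [], []
    for sp, w in zip(labels, weights):
        lam_parents = expected_total * w / config.mean_offspring
        n_parents = rng.poisson(lam_parents)
        if n_parents == 0:
            continue
        px = rng.uniform(0, lx, n_parents)
        py = rng.uniform(0, ly, n_parents)
        n_off = rng.poisson(config.mean_offspring, n_parents)
        for k in range(n_parents):
            if n_off[k] == 0:
                continue
            ox = np.mod(px[k] + rng.normal(0, config.cluster_scale_m, n_off[k]), lx)
            oy = np.mod(py[k] + rng.normal(0, config.cluster_scale_m, n_off[k]), ly)
            xs.append(ox)
            ys.append(oy)
            sps.extend([sp] * n_off[k])
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    n = len(x)
    q = q_min + rng.uniform(0, 1, n) * (1 - q_min)
    dbh = np.exp(mu + sd * stats.norm.ppf(q))
    return pd.DataFrame(
        {
            "stem_id": [f"s{k + 1:06d}" for k in range(n)],
            "species": sps,
            "x": x,
            "y": y,
            "dbh_cm": np.maximum(dbh, 1.0),
        }
    )


# ---------------------------------------------------------------------------
# seedlings and survival
# ---------------------------------------------------------------------------

def _truncated_lognormal(rng, mu, sd, minimum, size):
    q_min = stats.norm.cdf((np.log(minimum) - mu) / sd)
    q = q_min + rng.uniform(0, 1, size) * (1 - q_min)
    return np.maximum(np.exp(mu + sd * stats.norm.ppf(q)), minimum)


def _initial_seedlings(
    config: SimulationConfig,
    stems: pd.DataFrame,
    centers: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Initial cohort: Poisson counts per quadrat; species mix half global
    rank abundance, half local adult composition within 20 m."""
    labels = species_labels(config.n_species)
    sp_index = {s: k for k, s in enumerate(labels)}
    global_w = rank_abundances(config)
    local = np.zeros((len(centers), config.n_species))
    sx, sy = stems["x"].to_numpy(), stems["y"].to_numpy()
    scode = stems["species"].map(sp_index).to_numpy()
    for qi, (cx, cy) in enumerate(zip(centers["cx"], centers["cy"])):
        keep = np.hypot(sx - cx, sy - cy) <= DEFAULT_RADIUS_M
        if keep.any():
            counts = np.bincount(scode[keep], minlength=config.n_species)
            local[qi] = counts / counts.sum()
        else:
            local[qi] = global_w
    rows = []
    sid = 0
    mean_per_quadrat = config.seedling_mean_per_quadrat * config.scale
    mu_h, sd_h = config.height_lognorm
    for qi, qid in enumerate(centers.index):
        n = rng.poisson(mean_per_quadrat)
        if n == 0:
            continue
        w = 0.5 * global_w + 0.5 * local[qi]
        sp = rng.choice(config.n_species, size=n, p=w / w.sum())
        h = _truncated_lognormal(rng, mu_h, sd_h, config.min_height_cm, n)
        for k in range(n):
            sid += 1
            rows.append(
                {
                    "seedling_id": f"q{sid:05d}",
                    "species": labels[sp[k]],
                    "quadrat_id": qid,
                    "height_cm": float(h[k]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class StudyTruth:
    """Everything the generator knows that the analyst must estimate."""

    config: SimulationConfig
    scaling: dict[str, dict[str, tuple[float, float]]]   # season -> column -> (mean, sd)
    design_raw: pd.DataFrame        # per row: ids, season + raw predictor values
    design_std: pd.DataFrame        # the standardized design the logits used
    eta_fixed: np.ndarray           # beta0 + sum beta * x_std (no random effects)
    eta_full: np.ndarray            # eta_fixed + random intercepts (+ slope deviations)
    re_draws: dict[str, pd.Series]
    slope_draws: dict[tuple[str, str], pd.Series] = field(default_factory=dict)

    def true_beta_std(self, predictor: str, season: str) -> float:
        return self.config.beta(predictor, season)

    def true_beta_raw(self, predictor: str, season: str) -> float:
        """Truth on the per-raw-unit scale (scale-free across standardizations)."""
        _, sd = self.scaling[season][predictor]
        return self.config.beta(predictor, season) / sd


@dataclass
class SyntheticStudy(Study):
    truth: StudyTruth = None


def simulate_survival(
    config: SimulationConfig,
    stems: pd.DataFrame,
    newick: str,
    traits: pd.DataFrame,
    corner_elevations: np.ndarray,
    soil: pd.DataFrame,
    canopy: pd.Series,
    distances: SpeciesDistances | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, StudyTruth]:
    """Draw seedling survival histories from the true logistic mixed model.

    Intervals run in chronological order; a seedling that dies is absent from
    later censuses.  Optional Poisson recruitment adds new seedlings at later
    interval starts.  Returns the census table plus the full ground truth.
    """
    rng = rng if rng is not None else substream(config.seed, "survival")
    labels = species_labels(config.n_species)
    if distances is None:
        distances = build_species_distances(read_newick(newick), traits, species=labels)
    centers = quadrat_centers(config.plot_size_m, config.subplot_size_m, config.quadrat_size_m)
    topo = topography_table(corner_elevations, side_m=config.subplot_size_m)
    habitat_df, _ = assemble_habitat(topo, soil, canopy)
    habitat_df = habitat_df.loc[centers.index]
    sp_index = {s: k for k, s in enumerate(labels)}
    q_index = {q: k for k, q in enumerate(centers.index)}
    ba_w, a_totpd_q, a_totfd_q, _ = _adult_summaries(
        stems, centers, labels, distances, DEFAULT_RADIUS_M, DEFAULT_D_MIN_M
    )
    dp = distances.phylo.loc[labels, labels].to_numpy()
    df_ = distances.func.loc[labels, labels].to_numpy()

    intervals = config.interval_labels()
    # random effects
    re_draws = {
        "species": pd.Series(
            rng.normal(0, config.re_sd.get("species", 0.0), config.n_species), index=labels
        ),
        "quadrat": pd.Series(
            rng.normal(0, config.re_sd.get("quadrat", 0.0), len(centers)), index=centers.index
        ),
        "year": pd.Series(
            rng.normal(0, config.re_sd.get("year", 0.0), len({y for _, _, y in intervals})),
            index=sorted({str(y) for _, _, y in intervals}),
        ),
    }
    slope_draws: dict[tuple[str, str], pd.Series] = {}
    for predictor, sd in config.slope_sd.items():
        for season in ("dry", "rainy"):
            slope_draws[(predictor, season)] = pd.Series(
                rng.normal(0, sd, config.n_species), index=labels
            )

    alive = _initial_seedlings(config, stems, centers, rng)
    if alive.empty:
        raise InvalidStateError("no seedlings were generated; raise seedling_mean_per_quadrat")
    scaling: dict[str, dict[str, tuple[float, float]]] = {}
    season_rainfall: dict[str, list[float]] = {"dry": [], "rainy": []}
    for k, (_, season, _) in enumerate(intervals):
        season_rainfall[season].append(float(config.rainfall_by_interval[k]))

    census_rows = []
    raw_rows = []
    std_rows = []
    eta_fixed_all = []
    eta_full_all = []
    next_id = len(alive)

    for k, (interval_id, season, year) in enumerate(intervals):
        if alive.empty:
            break
        qcode = alive["quadrat_id"].map(q_index).to_numpy()
        scode = alive["species"].map(sp_index).to_numpy()
        seed_counts = np.zeros((len(centers), config.n_species))
        np.add.at(seed_counts, (qcode, scode), 1.0)
        raw = pd.DataFrame(
            {
                "log_height": np.log(alive["height_cm"].to_numpy()),
                "s_con": seed_counts[qcode, scode] - 1.0,
                "a_con": ba_w[qcode, scode],
                "s_totpd": (seed_counts @ dp)[qcode, scode],
                "a_totpd": a_totpd_q[qcode, scode],
                "s_totfd": (seed_counts @ df_)[qcode, scode],
                "a_totfd": a_totfd_q[qcode, scode],
                "canopy": habitat_df["canopy"].to_numpy()[qcode],
                "pca1": habitat_df["pca1"].to_numpy()[qcode],
                "pca2": habitat_df["pca2"].to_numpy()[qcode],
                "pca3": habitat_df["pca3"].to_numpy()[qcode],
                "rainfall": float(config.rainfall_by_interval[k]),
            }
        )
        if season not in scaling:
            sc = {}
            for col in PREDICTORS:
                if col == "rainfall":
                    vals = np.asarray(season_rainfall[season])
                    m = float(vals.mean())
                    s = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
                else:
                    x = raw[col].to_numpy()
                    m = float(x.mean())
                    s = float(x.std(ddof=1))
                # a degenerate column contributes nothing rather than blowing up
                sc[col] = (m, s if s > 1e-12 else 1.0)
            scaling[season] = sc
        std, _ = standardize_columns(raw, PREDICTORS, scaling[season])
        betas = np.array([config.beta(col, season) for col in PREDICTORS])
        eta_fixed = config.intercept + std.to_numpy() @ betas
        eta = (
            eta_fixed
            + re_draws["species"].to_numpy()[scode]
            + re_draws["quadrat"].to_numpy()[qcode]
            + re_draws["year"][str(year)]
        )
        for (predictor, s_), draws in slope_draws.items():
            if s_ == season:
                eta = eta + draws.to_numpy()[scode] * std[predictor].to_numpy()
        y = (rng.random(len(alive)) < expit(eta)).astype(int)

        census_rows.append(
            pd.DataFrame(
                {
                    "seedling_id": alive["seedling_id"].to_numpy(),
                    "species": alive["species"].to_numpy(),
                    "quadrat_id": alive["quadrat_id"].to_numpy(),
                    "interval_id": interval_id,
                    "season": season,
                    "year": year,
                    "height_cm": alive["height_cm"].to_numpy(),
                    "y": y,
                }
            )
        )
        ids = pd.DataFrame(
            {
                "seedling_id": alive["seedling_id"].to_numpy(),
                "interval_id": interval_id,
                "season": season,
            }
        )
        raw_rows.append(pd.concat([ids, raw.reset_index(drop=True)], axis=1))
        std_rows.append(pd.concat([ids, std.reset_index(drop=True)], axis=1))
        eta_fixed_all.append(eta_fixed)
        eta_full_all.append(eta)

        alive = alive.loc[y == 1].reset_index(drop=True)
        if config.recruitment_rate > 0 and k + 1 < len(intervals):
            recruits = []
            mu_h, sd_h = config.height_lognorm
            weights = rank_abundances(config)
            for qid in centers.index:
                n_new = rng.poisson(config.recruitment_rate)
                for _ in range(n_new):
                    next_id += 1
                    sp = labels[int(rng.choice(config.n_species, p=weights))]
                    h = float(_truncated_lognormal(rng, mu_h, sd_h, config.min_height_cm, 1)[0])
                    recruits.append(
                        {
                            "seedling_id": f"q{next_id:05d}",
                            "species": sp,
                            "quadrat_id": qid,
                            "height_cm": h,
                        }
                    )
            if recruits:
                alive = pd.concat([alive, pd.DataFrame(recruits)], ignore_index=True)

    censuses = pd.concat(census_rows, ignore_index=True)
    truth = StudyTruth(
        config=config,
        scaling=scaling,
        design_raw=pd.concat(raw_rows, ignore_index=True),
        design_std=pd.concat(std_rows, ignore_index=True),
        eta_fixed=np.concatenate(eta_fixed_all),
        eta_full=np.concatenate(eta_full_all),
        re_draws=re_draws,
        slope_draws=slope_draws,
    )
    return censuses, truth


# ---------------------------------------------------------------------------
# rainfall table and full study assembly
# ---------------------------------------------------------------------------

def rainfall_table(config: SimulationConfig) -> pd.DataFrame:
    """Monthly rainfall whose seasonal totals equal ``rainfall_by_interval``.

    Each interval's total is spread evenly over its six months so the
    season-aggregation reader reproduces the configured totals exactly.
    """
    rows = []
    for k, (interval_id, season, year) in enumerate(config.interval_labels()):
        total = float(config.rainfall_by_interval[k])
        if season == "rainy":
            months = [(year, m) for m in (5, 6, 7, 8, 9, 10)]
        else:
            months = [(year, 11), (year, 12)] + [(year + 1, m) for m in (1, 2, 3, 4)]
        for y, m in months:
            rows.append({"year": y, "month": m, "rainfall_mm": total / 6.0})
    df = pd.DataFrame(rows).groupby(["year", "month"], as_index=False)["rainfall_mm"].sum()
    return df


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the complete synthetic study (a pure function of the config)."""
    newick = simulate_phylogeny(
        config.n_species, config.birth_rate, substream(config.seed, "phylogeny").integers(2**31)
    )
    traits = simulate_traits(
        newick, config.trait_sigma2, config.n_traits, substream(config.seed, "traits").integers(2**31)
    )
    corner, _dem = simulate_terrain(config)
    topo = topography_table(corner, side_m=config.subplot_size_m)
    soil = simulate_soil(config, topo["elevation_m"])
    canopy = simulate_canopy(config)
    stems = simulate_stem_map(config)
    censuses, truth = simulate_survival(
        config, stems, newick, traits, corner, soil, canopy
    )
    return SyntheticStudy(
        stems=stems,
        censuses=censuses,
        traits=traits,
        soil=soil,
        canopy=canopy,
        corner_elevations=corner,
        rainfall=rainfall_table(config),
        newick=newick,
        plot_size_m=config.plot_size_m,
        subplot_size_m=config.subplot_size_m,
        truth=truth,
    )
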