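"""Generator contracts: phylogeny, traits, terrain/soil, stems, survival."""

import numpy as np
import pandas as pd
import pytest

from conftest import tiny_config
from seedlingndd import (
    SimulationConfig,
    read_newick,
    simulate_phylogeny,
    simulate_study,
    simulate_traits,
)
from seedlingndd.config import PREDICTORS
from seedlingndd.dataio import aggregate_seasonal_rainfall, quadrat_centers
from seedlingndd.errors import InvalidArgumentError
from seedlingndd.habitat import habitat_pca, topography_table
from seedlingndd.survival import standardize_columns
from seedlingndd.synthetic import (
    rank_abundances,
    simulate_canopy,
    simulate_soil,
    simulate_stem_map,
    simulate_terrain,
)


class TestPhylogeny:
    def test_two_tips_ultrametric_identity(self):
        nwk = simulate_phylogeny(2, 1.0, seed=1)
        tree = read_newick(nwk)
        m = tree.cophenetic_matrix()
        depth = m.iloc[0, 1] / 2.0
        assert depth > 0
        # every tip is at the same depth from the root
        t = tree.tree
        t.calc_node_ages(ultrametricity_precision=1e-6)

    def test_study_species_count(self):
        tree = read_newick(simulate_phylogeny(56, 1.0, seed=2))
        assert len(tree.tips) == 56
        assert tree.tips[0] == "sp001" and tree.tips[-1] == "sp056"

    def test_byte_identical_under_seed(self):
        assert simulate_phylogeny(10, 1.2, seed=7) == simulate_phylogeny(10, 1.2, seed=7)
        assert simulate_phylogeny(10, 1.2, seed=7) != simulate_phylogeny(10, 1.2, seed=8)

    def test_too_few_species_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_phylogeny(1, 1.0, seed=0)


class TestTraits:
    def test_zero_rate_gives_identical_species(self):
        nwk = simulate_phylogeny(6, 1.0, seed=3)
        traits = simulate_traits(nwk, sigma2=0.0, n_traits=4, seed=4)
        assert np.allclose(traits.to_numpy().std(axis=0), 0.0)

    def test_nine_trait_matrix(self):
        nwk = simulate_phylogeny(5, 1.0, seed=5)
        traits = simulate_traits(nwk, 1.0, 9, seed=6)
        assert traits.shape == (5, 9)
        assert list(traits.index) == sorted(traits.index)

    def test_brownian_variance_law_two_tip_tree(self):
        """Across replicate simulations on a fixed depth-T two-tip tree, the
        tip-value variance approaches sigma2 * T (Brownian scaling)."""
        T = 1.7
        nwk = f"(A:{T},B:{T});"
        sigma2 = 0.9
        vals = [
            simulate_traits(nwk, sigma2, 1, seed=s).loc["A", "trait1"] for s in range(200)
        ]
        assert np.var(vals, ddof=1) == pytest.approx(sigma2 * T, rel=0.3)


class TestTerrainSoilCanopy:
    def test_flat_limit_kills_slope_and_convexity(self):
        cfg = tiny_config(terrain_amplitude_m=0.0)
        grid, _ = simulate_terrain(cfg)
        assert np.allclose(grid, grid.flat[0])
        topo = topography_table(grid, side_m=cfg.subplot_size_m)
        assert np.allclose(topo["slope_deg"], 0.0)
        assert np.allclose(topo["convexity_m"], 0.0)

    def test_single_dominant_factor_dominates_pca(self):
        """Soil built from one latent factor: the first principal component
        carries the bulk of the variance (spectrum oracle)."""
        cfg = tiny_config()
        grid, _ = simulate_terrain(cfg)
        topo = topography_table(grid, side_m=cfg.subplot_size_m)
        loadings = np.full((10, 1), 0.9)
        soil = simulate_soil(cfg, topo["elevation_m"], loadings=loadings, noise_sd=0.15)
        res = habitat_pca(soil, n_components=3)
        assert res.variance_explained[0] > 0.5
        # oracle: spectrum of the generating correlation 0.9^2/(0.9^2+0.15^2)
        rho = 0.81 / (0.81 + 0.15**2)
        expected_first = (1 + 9 * rho) / 10
        assert res.variance_explained[0] == pytest.approx(expected_first, abs=0.1)

    def test_canopy_range_contract(self):
        canopy = simulate_canopy(tiny_config())
        assert ((canopy > 0) & (canopy < 1)).all()


class TestStemMap:
    def test_all_dbh_tagged(self):
        stems = simulate_stem_map(tiny_config())
        assert (stems["dbh_cm"] >= 1.0).all()
        assert stems["x"].between(0, 80).all() and stems["y"].between(0, 80).all()

    def test_expected_count_matches_intensity(self):
        """Mean realized stem count over replicates ~ intensity x area."""
        cfg = tiny_config()
        expected = cfg.stem_intensity * 80 * 80
        counts = []
        for s in range(25):
            counts.append(len(simulate_stem_map(tiny_config(seed=s))))
        assert np.mean(counts) == pytest.approx(expected, rel=0.10)

    def test_large_cluster_scale_approaches_csr(self):
        """cluster_scale -> inf: nearest-neighbor distances match a matched
        uniform (binomial) point process within Monte-Carlo tolerance."""
        from scipy.spatial import cKDTree

        def mean_nn(x, y):
            pts = np.column_stack([x, y])
            d, _ = cKDTree(pts).query(pts, k=2)
            return d[:, 1].mean()

        rng = np.random.default_rng(0)
        obs, csr = [], []
        for s in range(6):
            stems = simulate_stem_map(tiny_config(seed=s, cluster_scale_m=1e5))
            obs.append(mean_nn(stems["x"].to_numpy(), stems["y"].to_numpy()))
            n = len(stems)
            csr.append(mean_nn(rng.uniform(0, 80, n), rng.uniform(0, 80, n)))
        assert np.mean(obs) == pytest.approx(np.mean(csr), rel=0.10)
        # and the default clustered pattern is clearly more aggregated
        clustered = [
            mean_nn(*simulate_stem_map(tiny_config(seed=s, cluster_scale_m=2.0))[["x", "y"]]
                    .to_numpy().T)
            for s in range(3)
        ]
        assert np.mean(clustered) < 0.9 * np.mean(csr)


class TestSurvivalGeneration:
    def test_null_model_survival_fraction(self):
        """All betas and random-effect SDs zero, intercept 2: realized
        survival ~ logistic(2) = 0.881."""
        cfg = tiny_config(
            seed=8,
            intercept=2.0,
            true_betas={},
            re_sd={"species": 0.0, "quadrat": 0.0, "year": 0.0},
            seedling_mean_per_quadrat=40.0,
        )
        study = simulate_study(cfg)
        assert study.censuses["y"].mean() == pytest.approx(0.8808, abs=0.02)

    def test_species_random_intercepts_spread_survival_rates(self):
        """Large species random intercepts spread per-species survival far
        beyond binomial sampling noise."""

        def species_rate_sd(sd):
            cfg = tiny_config(
                seed=9, true_betas={}, intercept=1.0,
                re_sd={"species": sd, "quadrat": 0.0, "year": 0.0},
                seedling_mean_per_quadrat=40.0, n_species=8,
            )
            study = simulate_study(cfg)
            rates = study.censuses.groupby("species")["y"].mean()
            return rates.std(ddof=1)

        assert species_rate_sd(1.5) > 3.0 * species_rate_sd(0.0)

    def test_deterministic_under_seed(self):
        a = simulate_study(tiny_config(seed=11))
        b = simulate_study(tiny_config(seed=11))
        pd.testing.assert_frame_equal(a.censuses, b.censuses)
        pd.testing.assert_frame_equal(a.stems, b.stems)
        assert a.newick == b.newick
        c = simulate_study(tiny_config(seed=12))
        assert not a.censuses.equals(c.censuses)

    def test_dead_seedlings_never_reappear(self, small_study):
        order = {iv: k for k, iv in enumerate(small_study.interval_order)}
        r = small_study.censuses["interval_id"].map(order)
        died = small_study.censuses.assign(_r=r).query("y == 0").groupby("seedling_id")["_r"].min()
        later = small_study.censuses.assign(_r=r).merge(
            died.rename("_dead"), on="seedling_id", how="left"
        )
        assert not ((later["_r"] > later["_dead"]) & later["_dead"].notna()).any()

    def test_recruitment_adds_seedlings(self):
        quiet = simulate_study(tiny_config(seed=13, recruitment_rate=0.0))
        busy = simulate_study(tiny_config(seed=13, recruitment_rate=2.0))
        assert busy.censuses["seedling_id"].nunique() > quiet.censuses["seedling_id"].nunique()


class TestStandardizationSymmetry:
    def test_latent_logits_reproduced_from_stored_scaling(self, small_study):
        """Applying the inference-side standardization with the generator's
        stored scaling to the generator's raw design reproduces the latent
        fixed-effect logits exactly."""
        truth = small_study.truth
        cfg = truth.config
        for season in ("dry", "rainy"):
            rows = truth.design_raw["season"] == season
            raw = truth.design_raw.loc[rows, PREDICTORS]
            std, _ = standardize_columns(raw, PREDICTORS, truth.scaling[season])
            betas = np.array([cfg.beta(c, season) for c in PREDICTORS])
            eta = cfg.intercept + std.to_numpy() @ betas
            assert np.abs(eta - truth.eta_fixed[rows.to_numpy()]).max() < 1e-10

    def test_inference_pipeline_reproduces_raw_predictors(self, small_study):
        """The analysis pipeline rebuilt from the written tables recomputes
        the same raw predictor values the generator used."""
        from test_survival import study_design

        truth = small_study.truth
        for season in ("dry", "rainy"):
            design = study_design(small_study, season)
            got = design.raw.copy()
            got[["seedling_id", "interval_id"]] = design.ids
            want = truth.design_raw[truth.design_raw["season"] == season]
            merged = want.merge(
                got, on=["seedling_id", "interval_id"], suffixes=("_gen", "_inf")
            )
            assert len(merged) == len(want)
            for col in PREDICTORS:
                if col.startswith("pca"):
                    # identical only when the season occupies every quadrat
                    continue
                assert np.allclose(
                    merged[f"{col}_gen"], merged[f"{col}_inf"], atol=1e-9
                ), col
            gen_quads = set(small_study.censuses["quadrat_id"])
            if gen_quads == set(small_study.soil.index):
                for col in ("pca1", "pca2", "pca3"):
                    assert np.allclose(merged[f"{col}_gen"], merged[f"{col}_inf"], atol=1e-8)


def test_rainfall_table_aggregates_back_to_config_totals(small_study):
    cfg = small_study.truth.config
    totals = aggregate_seasonal_rainfall(
        small_study.rainfall, [iv for iv, _, _ in cfg.interval_labels()]
    )
    for k, (iv, _, _) in enumerate(cfg.interval_labels()):
        assert totals[iv] == pytest.approx(cfg.rainfall_by_interval[k], abs=1e-9)


def test_rank_abundances_sum_to_one():
    w = rank_abundances(SimulationConfig(seed=0))
    assert w.sum() == pytest.approx(1.0)
    assert (np.diff(w) <= 0).all()
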