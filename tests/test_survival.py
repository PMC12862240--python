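"""Design assembly, R^2, dispersion, importance partitioning, radius scan."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from conftest import tiny_config, toy_design
from seedlingndd import (
    REBlock,
    build_species_distances,
    fit_laplace_glmm,
    read_newick,
    simulate_study,
)
from seedlingndd.config import PREDICTORS
from seedlingndd.errors import InvalidArgumentError
from seedlingndd.habitat import topography_table
from seedlingndd.neighborhood import build_neighborhood_table
from seedlingndd.survival import (
    fit_survival_glmm,
    overdispersion_check,
    partition_importance,
    pearson_dispersion,
    prepare_design,
    scan_radius,
)


def study_design(study, season="rainy"):
    dist = build_species_distances(
        read_newick(study.newick),
        study.traits,
        species=sorted(set(study.censuses["species"]) | set(study.stems["species"])),
    )
    nbhd = build_neighborhood_table(
        study.censuses, study.stems, dist,
        plot_size_m=study.plot_size_m, subplot_size_m=study.subplot_size_m,
    )
    topo = topography_table(study.corner_elevations, side_m=study.subplot_size_m)
    return prepare_design(
        study.censuses, nbhd, topo, study.soil, study.canopy,
        study.seasonal_rainfall(), season,
    )


class TestPrepareDesign:
    def test_columns_standardized_and_rows_complete(self, small_study):
        design = study_design(small_study, "rainy")
        rainy_rows = (small_study.censuses["season"] == "rainy").sum()
        assert design.n_obs == rainy_rows
        assert list(design.X.columns) == PREDICTORS
        assert np.abs(design.X.mean()).max() < 1e-10
        assert np.abs(design.X.std(ddof=1) - 1).max() < 1e-10

    def test_single_interval_season_fails_on_constant_rainfall(self):
        study = simulate_study(tiny_config(n_intervals=2, seed=5))
        with pytest.raises(InvalidArgumentError, match="rainfall"):
            study_design(study, "dry")

    def test_reuses_stored_scaling(self, small_study):
        design = study_design(small_study, "dry")
        again = design.standardize_like(design.raw)
        assert np.allclose(again.to_numpy(), design.X.to_numpy(), atol=1e-12)


class TestFitAndR2:
    def test_r2_identities(self, small_study):
        design = study_design(small_study, "rainy")
        fit = fit_survival_glmm(design)
        assert fit.converged
        assert 0.0 <= fit.r2_marginal <= fit.r2_conditional <= 1.0
        assert len(fit.coefficients) == len(PREDICTORS) + 1
        assert (np.array(list(fit.re_var.values())) >= 0).all()

    def test_null_betas_give_near_zero_marginal_r2(self):
        rng = np.random.default_rng(0)
        n = 1500
        X = pd.DataFrame({"x1": rng.standard_normal(n), "x2": rng.standard_normal(n)})
        y = (rng.random(n) < 0.7).astype(float)
        design = toy_design(X, y, rng)
        fit = fit_survival_glmm(design)
        assert fit.r2_marginal < 0.01
        # and with no random-effect variance, conditional ~ marginal
        assert fit.r2_conditional - fit.r2_marginal < 0.05

    def test_standardization_invariance(self):
        """Scaling a raw predictor by 10 leaves coefficient, loglik and
        importance share unchanged (z-scoring absorbs units)."""
        rng = np.random.default_rng(1)
        n = 800
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        y = (rng.random(n) < expit(0.3 + 0.7 * x1 - 0.4 * x2)).astype(float)
        d1 = toy_design(pd.DataFrame({"x1": x1, "x2": x2}), y, np.random.default_rng(2))
        d2 = toy_design(pd.DataFrame({"x1": 10 * x1, "x2": x2}), y, np.random.default_rng(2))
        f1, f2 = fit_survival_glmm(d1), fit_survival_glmm(d2)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
        assert f1.coefficient("x1")["estimate"] == pytest.approx(
            f2.coefficient("x1")["estimate"], abs=1e-6
        )
        i1 = partition_importance(f1, groups={"x1": ["x1"], "x2": ["x2"]})
        i2 = partition_importance(f2, groups={"x1": ["x1"], "x2": ["x2"]})
        assert np.allclose(
            i1["share_pct"].to_numpy(), i2["share_pct"].to_numpy(), atol=1e-6
        )


class TestImportance:
    def test_single_predictor_gets_everything(self):
        rng = np.random.default_rng(3)
        n = 600
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(0.2 + 0.8 * x)).astype(float)
        design = toy_design(pd.DataFrame({"x": x}), y, rng)
        fit = fit_survival_glmm(design)
        imp = partition_importance(fit, groups={"x": ["x"]})
        assert imp["share_pct"].iloc[0] == pytest.approx(100.0)

    def test_equal_orthogonal_predictors_split_evenly(self):
        rng = np.random.default_rng(4)
        n = 6000
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        y = (rng.random(n) < expit(0.6 * x1 + 0.6 * x2)).astype(float)
        design = toy_design(pd.DataFrame({"x1": x1, "x2": x2}), y, rng)
        fit = fit_survival_glmm(design)
        imp = partition_importance(fit, groups={"x1": ["x1"], "x2": ["x2"]})
        shares = imp.set_index("unit")["share_pct"]
        assert shares["x1"] == pytest.approx(50.0, abs=6.0)

    def test_shares_sum_to_100_and_nonnegative(self, small_study):
        design = study_design(small_study, "rainy")
        fit = fit_survival_glmm(design)
        imp = partition_importance(fit)
        assert imp["share_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        assert (imp["share_pct"] >= 0).all()
        assert set(imp["unit"]) == {"height", "biotic", "habitat", "rainfall"}

    def test_too_many_units_refused(self):
        rng = np.random.default_rng(5)
        cols = {f"x{i}": rng.standard_normal(100) for i in range(15)}
        y = (rng.random(100) < 0.6).astype(float)
        design = toy_design(pd.DataFrame(cols), y, rng)
        fit = fit_survival_glmm(design)
        with pytest.raises(InvalidArgumentError, match="group"):
            partition_importance(fit, groups={c: [c] for c in cols})


class TestOverdispersion:
    def small_fit(self, rng, misspecified=False, n=1500, G=30):
        x = rng.standard_normal(n)
        codes = rng.integers(0, G, n)
        eta = 0.4 + 0.6 * x + rng.normal(0, 0.4, G)[codes]
        if misspecified:
            # strong omitted structure: the fitted mean cannot track the
            # true success probabilities, inflating Pearson chi-square
            eta = eta + 2.5 * (x**2 - 1.0)
        y = (rng.random(n) < expit(eta)).astype(float)
        X = np.column_stack([np.ones(n), x])
        return fit_laplace_glmm(y, X, [REBlock("g", codes, G)])

    def test_wellspecified_ratio_near_one_and_p_valid(self):
        fit = self.small_fit(np.random.default_rng(6))
        ratio, p = overdispersion_check(fit, n_boot=40, seed=1)
        assert 0.8 < ratio < 1.2
        assert 0.0 <= p <= 1.0

    def test_overdispersion_from_misfit_detected(self):
        """Data with structure the model cannot absorb show ratio > 1 and a
        significant parametric-bootstrap p."""
        fit = self.small_fit(np.random.default_rng(7), misspecified=True, n=3000)
        assert pearson_dispersion(fit) > 1.0
        ratio, p = overdispersion_check(fit, n_boot=99, seed=2)
        assert p < 0.05


class TestScanRadius:
    def test_table_complete_and_monotone_tie_rule(self, small_study):
        dist = build_species_distances(
            read_newick(small_study.newick),
            small_study.traits,
            species=sorted(
                set(small_study.censuses["species"]) | set(small_study.stems["species"])
            ),
        )
        table, selected = scan_radius(
            small_study, dist, "rainy", radii=(5.0, 10.0, 15.0, 20.0)
        )
        assert list(table["radius_m"]) == [5.0, 10.0, 15.0, 20.0]
        assert table["aic"].notna().all()
        assert selected in {5.0, 10.0, 15.0, 20.0}
        assert table.loc[table["radius_m"] == selected, "aic"].iloc[0] <= table["aic"].min() + 1e-6

    def test_identical_designs_tie_to_smallest_radius(self, small_study, monkeypatch):
        """When rebuilt predictors are identical across radii the AICs tie
        exactly and the smallest neighborhood is selected."""
        import seedlingndd.survival as surv

        dist = build_species_distances(
            read_newick(small_study.newick),
            small_study.traits,
            species=sorted(
                set(small_study.censuses["species"]) | set(small_study.stems["species"])
            ),
        )
        real_build = surv.build_neighborhood_table

        def fixed_radius_build(*args, **kwargs):
            kwargs["radius_m"] = 20.0
            return real_build(*args, **kwargs)

        monkeypatch.setattr(surv, "build_neighborhood_table", fixed_radius_build)
        table, selected = scan_radius(small_study, dist, "rainy", radii=(5.0, 10.0, 20.0))
        assert table["aic"].max() - table["aic"].min() < 1e-6
        assert selected == 5.0

    def test_recovers_generating_radius(self):
        """Data generated with a real adult-density effect at 20 m: the AIC
        scan selects the 20 m radius in the majority of replicates."""
        import seedlingndd as S

        hits = 0
        for rep in range(7):
            cfg = S.SimulationConfig(
                seed=300 + rep,
                true_betas={"a_con": -0.8, "s_totpd": {"rainy": 0.9}},
            )
            study = S.simulate_study(cfg)
            dist = build_species_distances(
                read_newick(study.newick),
                study.traits,
                species=sorted(set(study.censuses.species) | set(study.stems.species)),
            )
            _, selected = scan_radius(study, dist, "rainy")
            hits += selected == 20.0
        assert hits >= 4

    def test_invalid_radii_rejected(self, small_study):
        with pytest.raises(InvalidArgumentError):
            scan_radius(small_study, None, "rainy", radii=(10.0, 5.0))
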