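"""Crowding metrics against per-individual brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from seedlingndd import build_species_distances, read_newick, simulate_phylogeny
from seedlingndd.dataio import quadrat_centers
from seedlingndd.neighborhood import (
    adult_conspecific_density,
    basal_area_m2,
    build_neighborhood_table,
    conspecific_seedling_density,
    heterospecific_crowding,
)
from seedlingndd.errors import InvalidArgumentError


def make_distances(n_species=5, seed=3):
    nwk = simulate_phylogeny(n_species, 1.0, seed=seed)
    tree = read_newick(nwk)
    rng = np.random.default_rng(seed)
    traits = pd.DataFrame(rng.standard_normal((n_species, 4)), index=tree.tips)
    traits.columns = [f"t{i}" for i in range(4)]
    return build_species_distances(tree, traits)


def random_stems(n, rng, species, plot=(200.0, 200.0)):
    return pd.DataFrame(
        {
            "stem_id": [f"s{i}" for i in range(n)],
            "species": rng.choice(species, n),
            "x": rng.uniform(0, plot[0], n),
            "y": rng.uniform(0, plot[1], n),
            "dbh_cm": 1.0 + rng.exponential(8.0, n),
        }
    )


class TestAdultConspecificDensity:
    def test_empty_neighborhood_is_zero(self):
        stems = pd.DataFrame(
            {"stem_id": ["s1"], "species": ["spa"], "x": [150.0], "y": [150.0], "dbh_cm": [10.0]}
        )
        assert adult_conspecific_density(stems, (10.0, 10.0), "spa") == 0.0
        assert adult_conspecific_density(stems, (150.0, 150.0), "spb") == 0.0

    def test_single_stem_arithmetic(self):
        # one conspecific stem of basal area 0.05 m^2 at 10 m -> 0.005
        dbh = 200.0 * np.sqrt(0.05 / np.pi)
        stems = pd.DataFrame(
            {"stem_id": ["s1"], "species": ["spa"], "x": [30.0], "y": [20.0], "dbh_cm": [dbh]}
        )
        got = adult_conspecific_density(stems, (20.0, 20.0), "spa")
        assert got == pytest.approx(0.005, abs=1e-12)

    def test_distance_floor_bounds_overhanging_stems(self):
        stems = pd.DataFrame(
            {"stem_id": ["s1"], "species": ["spa"], "x": [20.0], "y": [20.0], "dbh_cm": [10.0]}
        )
        got = adult_conspecific_density(stems, (20.0, 20.0), "spa", d_min_m=0.5)
        assert got == pytest.approx(basal_area_m2(10.0) / 0.5)

    def test_brute_force_oracle_500_stems(self):
        rng = np.random.default_rng(8)
        stems = random_stems(500, rng, ["spa", "spb", "spc"])
        center = (100.0, 100.0)
        expected = 0.0
        for r in stems.itertuples():
            d = np.hypot(r.x - center[0], r.y - center[1])
            if r.species == "spa" and d <= 20.0:
                expected += basal_area_m2(r.dbh_cm) / max(d, 0.5)
        got = adult_conspecific_density(stems, center, "spa")
        assert got == pytest.approx(expected, abs=1e-12)


class TestSeedlingDensity:
    def census(self):
        return pd.DataFrame(
            {
                "seedling_id": [f"q{i}" for i in range(6)],
                "species": ["spa", "spa", "spa", "spb", "spb", "spa"],
                "quadrat_id": ["r01c01"] * 5 + ["r01c02"],
            }
        )

    def test_counting_rules(self):
        c = self.census()
        # 3 conspecifics in the quadrat, self excluded -> 2
        assert conspecific_seedling_density(c, "q0") == 2
        # heterospecifics not counted
        assert conspecific_seedling_density(c, "q3") == 1
        # conspecific in the adjacent quadrat not counted
        assert conspecific_seedling_density(c, "q5") == 0

    def test_alone_in_quadrat(self):
        c = self.census().iloc[[5]]
        assert conspecific_seedling_density(c, "q5") == 0


class TestHeterospecificCrowding:
    def test_single_species_arithmetic(self):
        d = pd.DataFrame(
            [[0.0, 150.0], [150.0, 0.0]], index=["spa", "spb"], columns=["spa", "spb"]
        )
        counts = pd.Series({"spb": 2})
        assert heterospecific_crowding(counts, "spa", d) == pytest.approx(300.0)

    def test_conspecifics_contribute_nothing(self):
        d = pd.DataFrame(
            [[0.0, 150.0], [150.0, 0.0]], index=["spa", "spb"], columns=["spa", "spb"]
        )
        assert heterospecific_crowding(pd.Series({"spa": 7}), "spa", d) == 0.0

    def test_species_absent_from_matrix_named(self):
        d = pd.DataFrame([[0.0]], index=["spa"], columns=["spa"])
        with pytest.raises(InvalidArgumentError, match="spz"):
            heterospecific_crowding(pd.Series({"spz": 1}), "spa", d)

    def test_mixed_neighborhood_per_individual_oracle(self):
        dist = make_distances(4)
        rng = np.random.default_rng(1)
        individuals = rng.choice(dist.species, 40)
        focal = dist.species[0]
        expected = sum(
            dist.phylo.at[focal, sp] for sp in individuals if sp != focal
        )
        counts = pd.Series(individuals).value_counts()
        got = heterospecific_crowding(counts, focal, dist.phylo)
        assert got == pytest.approx(expected, abs=1e-10)


class TestNeighborhoodTable:
    def build(self, n_stems=400, n_seedlings=60, n_species=5, radius=20.0, seed=2):
        dist = make_distances(n_species, seed=seed)
        rng = np.random.default_rng(seed)
        stems = random_stems(n_stems, rng, dist.species)
        centers = quadrat_centers((200.0, 200.0), 20.0)
        quads = rng.choice(centers.index, n_seedlings)
        censuses = pd.DataFrame(
            {
                "seedling_id": [f"q{i}" for i in range(n_seedlings)],
                "species": rng.choice(dist.species, n_seedlings),
                "quadrat_id": quads,
                "interval_id": "dry-2020",
                "season": "dry",
                "year": 2020,
                "height_cm": 30.0,
                "y": 1,
            }
        )
        table = build_neighborhood_table(censuses, stems, dist, radius_m=radius)
        return dist, stems, censuses, centers, table

    def test_matches_per_individual_oracle(self):
        dist, stems, censuses, centers, table = self.build()
        table = table.set_index("seedling_id")
        for r in censuses.sample(12, random_state=0).itertuples():
            cx, cy = centers.loc[r.quadrat_id, ["cx", "cy"]]
            a_con = a_totpd = a_totfd = 0.0
            n_adults = 0
            for st in stems.itertuples():
                d = np.hypot(st.x - cx, st.y - cy)
                if d > 20.0:
                    continue
                n_adults += 1
                if st.species == r.species:
                    a_con += basal_area_m2(st.dbh_cm) / max(d, 0.5)
                a_totpd += dist.phylo.at[r.species, st.species]
                a_totfd += dist.func.at[r.species, st.species]
            s_con = s_totpd = s_totfd = 0.0
            for other in censuses.itertuples():
                if other.quadrat_id != r.quadrat_id or other.seedling_id == r.seedling_id:
                    continue
                if other.species == r.species:
                    s_con += 1
                s_totpd += dist.phylo.at[r.species, other.species]
                s_totfd += dist.func.at[r.species, other.species]
            row = table.loc[r.seedling_id]
            assert row["a_con"] == pytest.approx(a_con, abs=1e-10)
            assert row["a_totpd"] == pytest.approx(a_totpd, abs=1e-10)
            assert row["a_totfd"] == pytest.approx(a_totfd, abs=1e-10)
            assert row["s_con"] == pytest.approx(s_con)
            assert row["s_totpd"] == pytest.approx(s_totpd, abs=1e-10)
            assert row["s_totfd"] == pytest.approx(s_totfd, abs=1e-10)
            assert row["n_adult_neighbors"] == n_adults

    def test_radius_nesting_and_monotonicity(self):
        dist, stems, censuses, centers, t20 = self.build(radius=20.0)
        t10 = build_neighborhood_table(censuses, stems, dist, radius_m=10.0)
        for col in ("a_con", "a_totpd", "a_totfd", "n_adult_neighbors"):
            assert (t10[col].to_numpy() <= t20[col].to_numpy() + 1e-12).all()
        # adding a conspecific stem never decreases a_con
        focal = censuses.iloc[0]
        cx, cy = centers.loc[focal.quadrat_id, ["cx", "cy"]]
        extra = pd.DataFrame(
            {"stem_id": ["extra"], "species": [focal.species], "x": [cx + 3.0],
             "y": [cy], "dbh_cm": [15.0]}
        )
        t_plus = build_neighborhood_table(
            censuses, pd.concat([stems, extra], ignore_index=True), dist, radius_m=20.0
        )
        assert t_plus.loc[0, "a_con"] > t20.loc[0, "a_con"]

    def test_truncated_flag_geometry(self):
        dist, stems, censuses, centers, table = self.build()
        merged = table.merge(censuses[["seedling_id", "quadrat_id"]], on="seedling_id")
        cx = centers.loc[merged["quadrat_id"], "cx"].to_numpy()
        cy = centers.loc[merged["quadrat_id"], "cy"].to_numpy()
        near_edge = np.minimum.reduce([cx, cy, 200 - cx, 200 - cy]) < 20.0
        assert np.array_equal(merged["truncated"].to_numpy(), near_edge)

    def test_single_species_study_has_zero_heterospecific_metrics(self):
        dist = make_distances(2)
        one = [dist.species[0]]
        rng = np.random.default_rng(3)
        stems = random_stems(200, rng, one)
        censuses = pd.DataFrame(
            {
                "seedling_id": ["q0", "q1"],
                "species": one * 2,
                "quadrat_id": ["r05c05", "r05c05"],
                "interval_id": "dry-2020",
                "season": "dry",
                "year": 2020,
                "height_cm": 25.0,
                "y": 1,
            }
        )
        t = build_neighborhood_table(censuses, stems, dist)
        assert np.allclose(t[["s_totpd", "a_totpd", "s_totfd", "a_totfd"]], 0.0)
        assert (t["a_con"] > 0).all()

    def test_record_count_equals_living_rows(self, small_study):
        from seedlingndd import read_newick as rn

        dist = build_species_distances(
            rn(small_study.newick),
            small_study.traits,
            species=sorted(set(small_study.censuses["species"]) | set(small_study.stems["species"])),
        )
        t = build_neighborhood_table(
            small_study.censuses, small_study.stems, dist,
            plot_size_m=small_study.plot_size_m, subplot_size_m=small_study.subplot_size_m,
        )
        assert len(t) == len(small_study.censuses)
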