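"""Size classes, prey-length allometry, PPMR and guild clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guildshift import trophic


class TestSizeClasses:
    @pytest.mark.parametrize("length,expected", [
        (2.0, "larva"),
        (3.0, "small_juvenile"),       # boundary goes to the upper class
        (10.0, "small_juvenile"),
        (15.0, "juvenile_medium"),     # Lmat/2 boundary
        (20.0, "juvenile_medium"),
        (30.0, "medium"),              # Lmat boundary
        (40.0, "medium"),
        (50.0, "large"),               # Lmax/2 boundary
        (60.0, "large"),
    ])
    def test_lmat30_lmax100(self, length, expected):
        assert trophic.assign_size_class(length, 30.0, 100.0) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            trophic.assign_size_class(0.0, 30.0, 100.0)
        with pytest.raises(ValueError):
            trophic.assign_size_class(10.0, -1.0, 100.0)

    def test_breakpoint_repair_when_lmat_exceeds_half_lmax(self, caplog):
        # Lmat=60 > Lmax/2=50 violates the natural ordering; breakpoints sort
        with caplog.at_level("WARNING"):
            bps = trophic.size_class_breakpoints(60.0, 100.0)
        assert np.all(np.diff(bps) >= 0)
        assert "out of order" in caplog.text

    @given(lmat=st.floats(1.0, 80.0), lmax_mult=st.floats(1.0, 4.0),
           length=st.floats(0.01, 500.0))
    @settings(max_examples=200, deadline=None)
    def test_intervals_partition_positive_lengths(self, lmat, lmax_mult, length):
        """Every positive length maps to exactly one of the five classes and
        the class index never decreases with length."""
        lmax = lmat * lmax_mult
        sc = trophic.assign_size_class(length, lmat, lmax)
        assert sc in trophic.SIZE_CLASSES
        bigger = trophic.assign_size_class(length * 1.5, lmat, lmax)
        assert trophic.SIZE_CLASSES.index(bigger) >= trophic.SIZE_CLASSES.index(sc)


class TestPreyLength:
    def test_intercept_and_worked_value(self):
        assert trophic.predict_fish_prey_length(0.0) == pytest.approx(1.618)
        assert trophic.predict_fish_prey_length(100.0) == pytest.approx(22.188)

    def test_slope_per_cm(self):
        d = trophic.predict_fish_prey_length(11.0) - trophic.predict_fish_prey_length(10.0)
        assert d == pytest.approx(0.2057)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            trophic.predict_fish_prey_length(-1.0)


def _record(stomach_id=0, taxon="cod", plen=50.0, pmass=1000.0, items=((1, 10.0),)):
    return pd.DataFrame([
        {"stomach_id": stomach_id, "taxon": taxon, "size_class": "medium",
         "predator_length_cm": plen, "predator_mass_g": pmass,
         "prey_taxon": "prey_fish", "prey_group": "fish",
         "count": c, "prey_mass_g": m, "prey_length_cm": np.nan}
        for c, m in items])


class TestImputeMasses:
    def _params(self):
        return trophic.LengthMassParams(
            table=pd.DataFrame({"taxon": ["cod", "prey_fish"], "a": 0.01, "b": 3.0}),
            allow_default=False)

    def test_complete_record_unchanged(self):
        rec = _record()
        out = trophic.impute_masses(rec, self._params())
        pd.testing.assert_frame_equal(out, rec)

    def test_predator_mass_from_allometry(self):
        rec = _record(pmass=np.nan)
        out = trophic.impute_masses(rec, self._params())
        assert out["predator_mass_g"].iloc[0] == pytest.approx(0.01 * 50**3)  # 1250 g

    def test_fish_prey_mass_via_typical_prey_length(self):
        rec = _record(plen=40.0, items=((1, np.nan),))
        out = trophic.impute_masses(rec, self._params())
        assert out["prey_length_cm"].iloc[0] == pytest.approx(9.846)
        assert out["prey_mass_g"].iloc[0] == pytest.approx(0.01 * 9.846**3, rel=1e-6)  # 9.545 g

    def test_nonfish_prey_from_lookup(self):
        rec = _record(items=((3, np.nan),))
        rec["prey_group"] = "benthos"
        rec["prey_taxon"] = "worm"
        out = trophic.impute_masses(rec, self._params(), {"benthos": 0.4})
        assert out["prey_mass_g"].iloc[0] == pytest.approx(0.4)

    def test_unresolvable_taxon_drops_stomach(self, caplog):
        rec = _record(items=((1, np.nan),))
        rec["prey_group"] = "benthos"
        rec["prey_taxon"] = "mystery"
        with caplog.at_level("WARNING"):
            out = trophic.impute_masses(rec, self._params(), {})
        assert out.empty
        assert "dropped" in caplog.text


class TestStomachPPMR:
    def test_single_prey_exact_ratio(self):
        assert trophic.stomach_ppmr(_record(pmass=1000.0, items=((1, 10.0),))) == 100.0

    def test_hand_computed_weighted_mean(self):
        # M=1000; 10 prey of 1 g and 1 prey of 10 g -> (10*1000 + 10*100)/20 = 550
        rec = _record(pmass=1000.0, items=((10, 1.0), (1, 10.0)))
        assert trophic.stomach_ppmr(rec) == pytest.approx(550.0)

    def test_equal_prey_masses_cancel_counts(self):
        rec = _record(pmass=800.0, items=((3, 4.0), (7, 4.0)))
        assert trophic.stomach_ppmr(rec) == pytest.approx(200.0)

    def test_matches_algebraic_closed_form(self, rng):
        """Weighted mean equals M * sum(c) / sum(c*m) on random records."""
        for _ in range(200):
            n = rng.integers(1, 8)
            counts = rng.integers(1, 20, size=n)
            masses = rng.lognormal(0, 1, size=n)
            M = float(rng.lognormal(5, 1))
            rec = _record(pmass=M, items=tuple(zip(counts, masses)))
            expected = M * counts.sum() / (counts * masses).sum()
            assert trophic.stomach_ppmr(rec) == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_rescaling_counts(self, rng):
        counts = rng.integers(1, 10, size=5)
        masses = rng.lognormal(0, 1, size=5)
        a = trophic.stomach_ppmr(_record(items=tuple(zip(counts, masses))))
        b = trophic.stomach_ppmr(_record(items=tuple(zip(counts * 7, masses))))
        assert a == pytest.approx(b, rel=1e-12)


class TestSpeciesGuildPPMR:
    def test_mean_of_stomach_ppmrs(self):
        recs = pd.concat([
            _record(stomach_id=0, pmass=1000.0, items=((1, 10.0),)),   # 100
            _record(stomach_id=1, pmass=1500.0, items=((1, 5.0),)),    # 300
        ])
        out = trophic.species_guild_ppmr(recs)
        assert out["ppmr"].iloc[0] == pytest.approx(200.0)
        assert out["n_stomachs"].iloc[0] == 2

    def test_simulated_mean_recovers_generator_truth(self, rng):
        """200 single-prey stomachs with lognormal ratios: the species-level
        mean lands within 3 SE of the generating distribution's mean."""
        mu, sd, n = np.log(200.0), 0.5, 200
        ratios = rng.lognormal(mu, sd, size=n)
        recs = pd.concat([_record(stomach_id=i, pmass=float(r), items=((1, 1.0),))
                          for i, r in enumerate(ratios)])
        out = trophic.species_guild_ppmr(recs)
        true_mean = np.exp(mu + sd**2 / 2)
        se = true_mean * np.sqrt(np.exp(sd**2) - 1) / np.sqrt(n)
        assert abs(out["ppmr"].iloc[0] - true_mean) < 3 * se

    def test_degenerate_stomach_skipped(self, caplog):
        bad = _record(stomach_id=1, pmass=-5.0)
        recs = pd.concat([_record(stomach_id=0), bad])
        with caplog.at_level("WARNING"):
            out = trophic.species_guild_ppmr(recs)
        assert out["n_stomachs"].iloc[0] == 1


class TestDietMatrix:
    def test_pure_zooplankton_row(self):
        rec = _record()
        rec["prey_group"] = "zooplankton"
        diet = trophic.build_diet_matrix(rec)
        assert diet.iloc[0].tolist() == [100.0, 0.0, 0.0]

    def test_mixed_biomass_shares(self):
        rec = _record(items=((1, 30.0), (1, 70.0)))
        rec.loc[rec.index[1], "prey_group"] = "benthos"
        diet = trophic.build_diet_matrix(rec)
        assert diet.iloc[0]["benthos"] == pytest.approx(70.0)
        assert diet.iloc[0]["fish"] == pytest.approx(30.0)

    def test_rows_sum_to_100_on_random_input(self, stomach_table):
        diet = trophic.build_diet_matrix(stomach_table)
        assert np.allclose(diet.sum(axis=1), 100.0, atol=1e-6)
        assert (diet.to_numpy() >= 0).all()

    def test_row_order_invariance(self, stomach_table):
        shuffled = stomach_table.sample(frac=1.0, random_state=0)
        a = trophic.build_diet_matrix(stomach_table).sort_index()
        b = trophic.build_diet_matrix(shuffled).sort_index()
        pd.testing.assert_frame_equal(a, b)


def _diet_frame(rows, taxa=None):
    idx = pd.MultiIndex.from_tuples(
        [(taxa[i] if taxa else f"t{i}", "medium") for i in range(len(rows))],
        names=["taxon", "size_class"])
    return pd.DataFrame(rows, index=idx, columns=["zooplankton", "benthos", "fish"])


class TestClusterGuilds:
    def test_pure_diets_yield_matching_singletons(self):
        diet = _diet_frame([[100, 0, 0], [0, 100, 0], [0, 0, 100]])
        out = trophic.cluster_guilds(diet, k=3)
        assert set(out["guild"]) == {"planktivore", "benthivore", "piscivore"}
        assert out["cluster"].nunique() == 3

    def test_duplicated_rows_cluster_together(self):
        diet = _diet_frame([[80, 15, 5], [80, 15, 5], [5, 90, 5], [2, 10, 88]])
        out = trophic.cluster_guilds(diet, k=3)
        assert out["cluster"].iloc[0] == out["cluster"].iloc[1]

    def test_recovers_generating_guilds(self, rng):
        """60 diets drawn around three known mixture centres: >=95% of rows
        recover the guild of their generating centre."""
        centres = {"planktivore": [88, 9, 3], "benthivore": [4, 196, 24],
                   "piscivore": [4, 36, 120]}
        rows, truth = [], []
        for guild, alpha in centres.items():
            draws = rng.dirichlet(alpha, size=20) * 100
            rows.extend(draws.tolist())
            truth.extend([guild] * 20)
        out = trophic.cluster_guilds(_diet_frame(rows), k=3)
        assert (out["guild"].to_numpy() == np.array(truth)).mean() >= 0.95

    def test_shared_dominant_group_warns_and_suffixes(self):
        diet = _diet_frame([[100, 0, 0], [100, 0, 0], [55, 45, 0], [55, 45, 0],
                            [0, 0, 100], [0, 0, 100]])
        with pytest.warns(UserWarning, match="suffixing"):
            out = trophic.cluster_guilds(diet, k=3)
        assert {"planktivore_1", "planktivore_2"} <= set(out["guild"])

    def test_requires_k_rows(self):
        with pytest.raises(ValueError):
            trophic.cluster_guilds(_diet_frame([[100, 0, 0]]), k=3)

    def test_row_order_invariance(self, stomach_table):
        diet = trophic.build_diet_matrix(stomach_table)
        a = trophic.cluster_guilds(diet, k=3)["guild"].sort_index()
        b = trophic.cluster_guilds(diet.iloc[::-1], k=3)["guild"].sort_index()
        assert (a == b).all()
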