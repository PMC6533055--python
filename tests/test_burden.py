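from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from thalmap import burden
from thalmap.burden import (
    AlleleFrequencyVector,
    BurdenConfig,
    DemographySpec,
    affected_births,
    birth_surface,
    compare_scenarios,
    hwe_expansion,
    severe_genotype_frequencies,
)
from thalmap.geostat import PosteriorEnsemble
from thalmap.grids import rectangular_grid, surface_from_flat
from thalmap.synthetic import partition_provinces


def const_ensemble(grid, value, K=5, form=""):
    real = np.full((K, grid.n_rows, grid.n_cols), np.nan)
    real[:, grid.mask_array()] = value
    return PosteriorEnsemble(grid=grid, form=form, realisations=real, seed=0)


def random_ensemble(grid, rng, K=5, scale=0.1):
    real = np.full((K, grid.n_rows, grid.n_cols), np.nan)
    real[:, grid.mask_array()] = scale * rng.random((K, grid.n_unmasked))
    return PosteriorEnsemble(grid=grid, form="", realisations=real, seed=0)


class TestAlleleFrequencyVector:
    def test_s_is_derived_and_clamped(self):
        v = AlleleFrequencyVector.from_pqr(0.02, 0.1, 0.016)
        assert v.s == pytest.approx(0.864)
        v = AlleleFrequencyVector.from_pqr(0.5, 0.3, 0.2 + 1e-12)
        assert v.s == 0.0

    def test_simplex_violations_rejected(self):
        with pytest.raises(ValueError):
            AlleleFrequencyVector.from_pqr(0.6, 0.5, 0.2)
        with pytest.raises(ValueError):
            AlleleFrequencyVector(0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            AlleleFrequencyVector(-0.1, 0.5, 0.3, 0.3)


class TestHWEExpansion:
    def test_pure_p_gives_only_hydrops(self):
        g = hwe_expansion(AlleleFrequencyVector(1.0, 0.0, 0.0, 0.0))
        assert g["--/--"] == 1.0
        assert all(val == 0.0 for k, val in g.items() if k != "--/--")

    def test_equal_quarter_frequencies(self):
        g = hwe_expansion(AlleleFrequencyVector(0.25, 0.25, 0.25, 0.25))
        squares = ["--/--", "-a/-a", "aaND/aaND", "aa/aa"]
        for k, val in g.items():
            assert val == pytest.approx(0.0625 if k in squares else 0.125)
        assert sum(g.values()) == pytest.approx(1.0)

    def test_random_simplex_vectors_sum_to_one(self):
        rng = np.random.default_rng(1)
        draws = rng.dirichlet(np.ones(4), size=1000)
        for p, q, r, s in draws:
            total = sum(hwe_expansion(AlleleFrequencyVector(p, q, r, s)).values())
            assert abs(total - 1.0) < 1e-9


class TestSevereGenotypes:
    def test_random_mating_case(self):
        g = severe_genotype_frequencies(AlleleFrequencyVector.from_pqr(0.02, 0.10, 0.016), F=0.0)
        assert g.hydrops == pytest.approx(0.0004)
        assert g.hbh_del == pytest.approx(0.004)
        assert g.hbh_nondel == pytest.approx(0.00064)

    def test_consanguinity_case(self):
        g = severe_genotype_frequencies(AlleleFrequencyVector.from_pqr(0.1, 0.2, 0.05), F=0.1)
        assert g.hydrops == pytest.approx(0.019)
        assert g.hbh_del == pytest.approx(0.036)
        assert g.hbh_nondel == pytest.approx(0.009)

    def test_full_inbreeding_limit(self):
        g = severe_genotype_frequencies(AlleleFrequencyVector.from_pqr(0.3, 0.2, 0.1), F=1.0)
        assert g.hydrops == pytest.approx(0.3)
        assert g.hbh_del == 0.0 and g.hbh_nondel == 0.0

    def test_exact_rational_identities(self):
        """The F-adjustment formulas hold exactly in rational arithmetic:
        hydrops = p^2 + F p (1-p) and each HbH term carries a (1-F) factor."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            ints = rng.integers(1, 50, size=4)
            tot = int(ints.sum())
            p, q, r, s = (Fraction(int(i), tot) for i in ints)
            F = Fraction(int(rng.integers(0, 11)), 10)
            v = AlleleFrequencyVector(p, q, r, s)
            g = severe_genotype_frequencies(v, F)
            g0 = severe_genotype_frequencies(v, Fraction(0))
            assert g.hydrops == p * p + F * p * (1 - p)
            assert g.hbh_del == (1 - F) * g0.hbh_del
            assert g.hbh_nondel == (1 - F) * g0.hbh_nondel

    def test_f_out_of_range_rejected(self):
        v = AlleleFrequencyVector.from_pqr(0.1, 0.1, 0.1)
        with pytest.raises(ValueError):
            severe_genotype_frequencies(v, F=1.5)
        with pytest.raises(ValueError):
            BurdenConfig(F=-0.1)


class TestBirthSurface:
    def test_zero_rate_gives_zero_surface(self, grid8, const_surface):
        dem = DemographySpec(const_surface(grid8, 100.0, scale="persons"), 0.0)
        assert np.all(birth_surface(dem).unmasked() == 0)

    def test_uniform_population_unit_births(self, grid8, const_surface):
        dem = DemographySpec(const_surface(grid8, 100.0, scale="persons"), 0.01)
        assert np.allclose(birth_surface(dem).unmasked(), 1.0)

    def test_total_births_conserved(self, masked_grid):
        rng = np.random.default_rng(2)
        pop = surface_from_flat(masked_grid, rng.random(masked_grid.n_unmasked) * 1e4,
                                scale="persons")
        dem = DemographySpec(pop, 0.0105)
        assert birth_surface(dem).total() == pytest.approx(0.0105 * pop.total(), rel=1e-9)

    def test_per_1000_flag_and_validation(self, grid8, const_surface):
        pop = const_surface(grid8, 10.0, scale="persons")
        dem = DemographySpec(pop, 10.5, per_1000=True)
        assert dem.crude_birth_rate == pytest.approx(0.0105)
        with pytest.raises(ValueError):
            DemographySpec(pop, 10.5)  # per-person rate of 10.5 is implausible


class TestAffectedBirths:
    def test_constant_ensemble_single_province(self, grid8, const_surface):
        p = const_ensemble(grid8, 0.03)
        zero = const_ensemble(grid8, 0.0)
        births = const_surface(grid8, 1e4 / grid8.n_unmasked, scale="births")
        provinces = partition_provinces(grid8, 1, seed=0)
        table = affected_births(p, zero, zero, births, provinces).table
        hyd = table[(table["admin_unit"] == "National") & (table["genotype"] == "--/--")]
        assert hyd["mean"].iloc[0] == pytest.approx(0.0009 * 1e4)
        assert hyd["ci_upper"].iloc[0] - hyd["ci_lower"].iloc[0] == pytest.approx(0.0)
        hbh = table[table["genotype"] != "--/--"]
        assert np.allclose(hbh["mean"], 0.0)

    def test_doubling_births_doubles_every_entry(self, masked_grid):
        rng = np.random.default_rng(7)
        p, q, r = (random_ensemble(masked_grid, rng) for _ in range(3))
        births = surface_from_flat(masked_grid, rng.random(masked_grid.n_unmasked) * 100,
                                   scale="births")
        births2 = surface_from_flat(masked_grid, births.unmasked() * 2, scale="births")
        provinces = partition_provinces(masked_grid, 3, seed=1)
        t1 = affected_births(p, q, r, births, provinces).table
        t2 = affected_births(p, q, r, births2, provinces).table
        for col in ("mean", "ci_lower", "ci_upper"):
            np.testing.assert_allclose(t2[col], 2 * t1[col], rtol=1e-12)

    def test_matches_brute_force_triple_loop(self):
        """Independent realisation x cell x province loop on a 6x6 grid, K=5."""
        grid = rectangular_grid(100.0, 14.0, 0.5, 6, 6)
        rng = np.random.default_rng(11)
        # include draws that exceed the simplex to exercise renormalisation
        p = random_ensemble(grid, rng, scale=0.5)
        q = random_ensemble(grid, rng, scale=0.5)
        r = random_ensemble(grid, rng, scale=0.3)
        births = surface_from_flat(grid, rng.random(grid.n_unmasked) * 50, scale="births")
        provinces = partition_provinces(grid, 4, seed=2)
        cfg = BurdenConfig(F=0.05, level=0.9)
        result = affected_births(p, q, r, births, provinces, cfg)

        labels = provinces.label_flat()
        b = births.unmasked()
        K = p.K
        totals = {g: np.zeros((K, 4)) for g in ("--/--", "-a/--", "aaND/--")}
        nat = {g: np.zeros(K) for g in totals}
        for k in range(K):
            for c in range(grid.n_unmasked):
                pc, qc, rc = p.unmasked()[k, c], q.unmasked()[k, c], r.unmasked()[k, c]
                tot = pc + qc + rc
                if tot > 1.0:
                    pc, qc, rc = pc / tot, qc / tot, rc / tot
                g = {
                    "--/--": pc * pc + cfg.F * pc * (1 - pc),
                    "-a/--": 2 * pc * qc * (1 - cfg.F),
                    "aaND/--": 2 * pc * rc * (1 - cfg.F),
                }
                for geno, freq in g.items():
                    totals[geno][k, labels[c]] += freq * b[c]
                    nat[geno][k] += freq * b[c]
        tab = result.table.set_index(["admin_unit", "genotype"])
        for geno in totals:
            for prov in range(4):
                draws = totals[geno][:, prov]
                row = tab.loc[(f"province-{prov}", geno)]
                assert row["mean"] == pytest.approx(draws.mean(), abs=1e-9)
                assert row["ci_lower"] == pytest.approx(np.quantile(draws, 0.05), abs=1e-9)
                assert row["ci_upper"] == pytest.approx(np.quantile(draws, 0.95), abs=1e-9)
            assert tab.loc[("National", geno)]["mean"] == pytest.approx(
                nat[geno].mean(), abs=1e-9
            )
        assert result.renormalised_fraction > 0

    def test_one_minus_f_law_and_hydrops_monotonicity(self, masked_grid):
        rng = np.random.default_rng(13)
        p, q, r = (random_ensemble(masked_grid, rng, scale=0.2) for _ in range(3))
        births = surface_from_flat(masked_grid, np.full(masked_grid.n_unmasked, 10.0),
                                   scale="births")
        provinces = partition_provinces(masked_grid, 3, seed=4)
        t0 = affected_births(p, q, r, births, provinces, BurdenConfig(F=0.0)).table
        tF = affected_births(p, q, r, births, provinces, BurdenConfig(F=0.25)).table
        for geno in ("-a/--", "aaND/--"):
            a = tF[tF["genotype"] == geno].set_index("admin_unit")
            b0 = t0[t0["genotype"] == geno].set_index("admin_unit")
            np.testing.assert_allclose(a["mean"], 0.75 * b0["mean"], rtol=1e-12)
        hyd_F = tF[tF["genotype"] == "--/--"].set_index("admin_unit")["mean"]
        hyd_0 = t0[t0["genotype"] == "--/--"].set_index("admin_unit")["mean"]
        assert np.all(hyd_F.values >= hyd_0.values - 1e-15)

    def test_increasing_p_cannot_decrease_hydrops(self, masked_grid):
        rng = np.random.default_rng(17)
        p = random_ensemble(masked_grid, rng, scale=0.1)
        q = random_ensemble(masked_grid, rng, scale=0.1)
        r = random_ensemble(masked_grid, rng, scale=0.1)
        births = surface_from_flat(masked_grid, np.full(masked_grid.n_unmasked, 5.0),
                                   scale="births")
        provinces = partition_provinces(masked_grid, 2, seed=5)
        bigger = PosteriorEnsemble(
            grid=masked_grid, form="", seed=0,
            realisations=np.clip(p.realisations + 0.05, None, 1.0),
        )
        t1 = affected_births(p, q, r, births, provinces).table
        t2 = affected_births(bigger, q, r, births, provinces).table
        h1 = t1[t1["genotype"] == "--/--"]["mean"].values
        h2 = t2[t2["genotype"] == "--/--"]["mean"].values
        assert np.all(h2 >= h1)

    def test_province_means_sum_to_national(self, study_small):
        rng = np.random.default_rng(19)
        grid = study_small.population.grid
        p, q, r = (random_ensemble(grid, rng, scale=0.15) for _ in range(3))
        dem = DemographySpec(study_small.population, study_small.crude_birth_rate)
        table = affected_births(p, q, r, birth_surface(dem), study_small.provinces).table
        for geno in ("--/--", "-a/--", "aaND/--"):
            sub = table[table["genotype"] == geno]
            prov_sum = sub[sub["admin_unit"] != "National"]["mean"].sum()
            nat = sub[sub["admin_unit"] == "National"]["mean"].iloc[0]
            assert prov_sum == pytest.approx(nat, rel=1e-6)

    def test_mismatched_inputs_rejected(self, grid8, masked_grid, const_surface):
        p = const_ensemble(grid8, 0.1, K=5)
        q5 = const_ensemble(grid8, 0.1, K=4)
        births = const_surface(grid8, 1.0, scale="births")
        provinces = partition_provinces(grid8, 2, seed=0)
        with pytest.raises(ValueError, match="K"):
            affected_births(p, q5, p, births, provinces)
        p_other = const_ensemble(masked_grid, 0.1, K=5)
        with pytest.raises(ValueError, match="grid"):
            affected_births(p, p, p_other, births, provinces)
        bad = partition_provinces(grid8, 2, seed=0)
        bad.labels[4, 4] = -1
        with pytest.raises(ValueError, match="orphan"):
            affected_births(p, p, p, births, bad)


class TestCompareScenarios:
    def _table(self, grid, factor=1.0, k=2):
        rng = np.random.default_rng(23)
        p, q, r = (random_ensemble(grid, rng, scale=0.1) for _ in range(3))
        births = surface_from_flat(grid, np.full(grid.n_unmasked, 10.0 * factor),
                                   scale="births")
        return affected_births(p, q, r, births, partition_provinces(grid, k, seed=1))

    def test_identical_tables_have_zero_differences(self, grid8):
        t = self._table(grid8)
        diff = compare_scenarios(t, t)
        assert np.allclose(diff["abs_diff"], 0) and np.allclose(diff["rel_diff"], 0)

    def test_doubled_scenario_has_relative_difference_one(self, grid8):
        diff = compare_scenarios(self._table(grid8), self._table(grid8, factor=2.0))
        assert np.allclose(diff["rel_diff"], 1.0)

    def test_consanguinity_scales_combined_hbh_by_point_nine(self, grid8, const_surface):
        # deterministic single-province scenario: exact (1-F) factorisation
        p = const_ensemble(grid8, 0.03)
        q = const_ensemble(grid8, 0.08)
        r = const_ensemble(grid8, 0.02)
        births = const_surface(grid8, 10.0, scale="births")
        provinces = partition_provinces(grid8, 1, seed=0)
        base = affected_births(p, q, r, births, provinces, BurdenConfig(F=0.0))
        alt = affected_births(p, q, r, births, provinces, BurdenConfig(F=0.1))
        nat_b = base.national().set_index("genotype")["mean"]
        nat_a = alt.national().set_index("genotype")["mean"]
        ratio = (nat_a["-a/--"] + nat_a["aaND/--"]) / (nat_b["-a/--"] + nat_b["aaND/--"])
        assert ratio == pytest.approx(0.9, abs=1e-12)

    def test_index_mismatch_rejected(self, grid8):
        with pytest.raises(ValueError, match="indices"):
            compare_scenarios(self._table(grid8, k=2), self._table(grid8, k=3))
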