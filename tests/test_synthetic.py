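"""Generator contracts: determinism, standardisation, autocorrelation, truth
closed forms and sampling-bias behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import occutrait as ot
from occutrait.synthetic import generate_drivers, generate_species


def small_cfg(**kw):
    base = dict(grid_size=10, years=8, n_drivers=2, n_groups=2, species_per_group=5,
                n_traits=2, visits_per_year=40, seed=0)
    base.update(kw)
    return ot.WorldConfig(**base)


def brute_morans_i(field):
    """Lag-1 (rook) Moran's I by explicit neighbour enumeration."""
    z = field - field.mean()
    ny, nx = field.shape
    num = w = 0.0
    for i in range(ny):
        for j in range(nx):
            for di, dj in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                a, b = i + di, j + dj
                if 0 <= a < ny and 0 <= b < nx:
                    num += z[i, j] * z[a, b]
                    w += 1.0
    return (z.size / w) * num / (z * z).sum()


class TestDrivers:
    def test_fixed_seed_is_byte_identical(self):
        cfg = small_cfg(seed=42)
        a = generate_drivers(cfg)
        b = generate_drivers(small_cfg(seed=42))
        np.testing.assert_array_equal(a.values, b.values)

    def test_standardised_before_trend(self):
        cfg = small_cfg(grid_size=40, driver_trend=[0.0, 0.0])
        stack = generate_drivers(cfg)
        for j in range(cfg.n_drivers):
            assert abs(stack.values[j].mean()) < 1e-12
            assert stack.values[j].std() == pytest.approx(1.0, abs=1e-12)
            # per-year spatial means hover around zero (smoothing lowers the
            # effective dof, so the tolerance is generous)
            yearly = stack.values[j].reshape(cfg.years, -1).mean(axis=1)
            assert np.abs(yearly).max() < 0.6

    def test_configured_trend_appears_in_yearly_means(self):
        cfg = small_cfg(grid_size=30, driver_trend=[0.1, 0.0])
        stack = generate_drivers(cfg)
        yearly = stack.values[0].reshape(cfg.years, -1).mean(axis=1)
        slope = np.polyfit(np.arange(cfg.years), yearly, 1)[0]
        assert slope == pytest.approx(0.1, abs=0.05)

    def test_spatial_autocorrelation_positive_by_brute_force_morans_i(self):
        stack = generate_drivers(small_cfg(grid_size=20, smoothing_scale=3.0))
        assert brute_morans_i(stack.values[0, 0]) > 0.3
        # control: white noise has near-zero I under the same oracle
        noise = np.random.default_rng(0).standard_normal((20, 20))
        assert abs(brute_morans_i(noise)) < 0.15

    def test_degenerate_smoothing_rejected(self):
        with pytest.raises(ValueError, match="smoothing_scale"):
            generate_drivers(small_cfg(grid_size=8, smoothing_scale=8.0))

    def test_csv_round_trip(self, tmp_path):
        stack = generate_drivers(small_cfg())
        stack.write_csv(tmp_path / "drv.csv")
        back = ot.DriverStack.read_csv(tmp_path / "drv.csv")
        np.testing.assert_allclose(back.values, stack.values)
        assert back.driver_names == stack.driver_names


class TestSpecies:
    def test_within_group_standardisation(self):
        sp = generate_species(small_cfg(species_per_group=8))
        for g, sub in sp.frame.groupby("group"):
            t = sub[[f"trait_{m}" for m in range(2)]].to_numpy()
            np.testing.assert_allclose(t.mean(axis=0), 0.0, atol=1e-12)
            np.testing.assert_allclose(t.std(axis=0), 1.0, atol=1e-12)

    def test_single_species_group_degenerates_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero trait variance"):
            sp = generate_species(small_cfg(species_per_group=1))
        assert (sp.frame[["trait_0", "trait_1"]].to_numpy() == 0).all()

    def test_taxonomy_block_is_one_hot_within_group(self):
        sp = generate_species(small_cfg())
        tax = sp.frame[sp.taxonomy_names].to_numpy()
        np.testing.assert_array_equal(tax.sum(axis=1), 1.0)


class TestTruth:
    def test_all_zero_coefficients_give_half_probability(self):
        cfg = small_cfg(baseline_mean=0.0, baseline_sd=0.0)
        drv = generate_drivers(cfg)
        sp = generate_species(cfg)
        truth = ot.compute_truth(cfg, drv, sp)
        np.testing.assert_allclose(truth.probability, 0.5)

    def test_logit_closed_form_single_driver(self):
        cfg = small_cfg(n_drivers=1, beta=[1.0])
        drv = generate_drivers(cfg)
        # constant field of value 2 isolates logit = baseline + 2
        drv.values[:] = 2.0
        sp = generate_species(cfg)
        truth = ot.compute_truth(cfg, drv, sp)
        expected = expit(sp.baseline + 2.0)
        np.testing.assert_allclose(truth.probability[:, 0, 0, 0], expected, atol=1e-12)

    def test_probability_matches_brute_force_loop(self):
        cfg = small_cfg(beta=[0.5, -0.3], mediation_list=[(0, 1, 0.4)])
        drv = generate_drivers(cfg)
        sp = generate_species(cfg)
        truth = ot.compute_truth(cfg, drv, sp)
        traits = sp.trait_matrix(include_taxonomy=False)
        gamma = cfg.gamma
        s, yi, y, x = 3, 2, 4, 7
        logit = sp.baseline[s]
        for j in range(cfg.n_drivers):
            coef = cfg.beta[j] + float(gamma[j] @ traits[s])
            logit += coef * drv.values[j, yi, y, x]
        assert truth.probability[s, yi, y, x] == pytest.approx(expit(logit), abs=1e-12)

    def test_mediation_makes_trait_proportional_logit_slopes(self):
        cfg = small_cfg(beta=[0.0, 0.0], mediation_list=[(0, 0, 0.7)])
        sp = generate_species(cfg)
        traits = sp.trait_matrix(include_taxonomy=False)
        # d(logit)/d(driver0) = gamma * t_s0: correlation with the trait is +1
        slopes = 0.7 * traits[:, 0]
        r = np.corrcoef(traits[:, 0], slopes)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_identical_species_get_identical_probability_fields(self):
        cfg = small_cfg(beta=[0.5, -0.5])
        drv = generate_drivers(cfg)
        sp = generate_species(cfg)
        clone = sp.frame.copy()
        clone.iloc[1] = clone.iloc[0]
        clone.loc[1, "species"] = "clone"
        sp2 = ot.SpeciesTable(frame=clone, n_traits=cfg.n_traits)
        truth = ot.compute_truth(cfg, drv, sp2)
        np.testing.assert_array_equal(truth.probability[0], truth.probability[1])

    def test_true_assemblage_matches_brute_force_double_loop(self):
        cfg = small_cfg(beta=[0.5, -0.3], mediation_list=[(0, 0, 0.5)])
        drv = generate_drivers(cfg)
        sp = generate_species(cfg)
        truth = ot.compute_truth(cfg, drv, sp)
        traits = sp.trait_matrix(include_taxonomy=False)
        cuts = truth.region_cuts
        region_of_y = np.searchsorted(cuts, np.arange(cfg.grid_size), side="right")
        year1 = int(drv.years[1])
        sub = truth.assemblage.query("trait == 'trait_0' and region == 0 and year == @year1")
        expected = []
        for y in range(cfg.grid_size):
            if region_of_y[y] != 0:
                continue
            for x in range(cfg.grid_size):
                num = den = 0.0
                for s in range(len(sp.species)):
                    p = truth.probability[s, 1, y, x]
                    num += traits[s, 0] * p
                    den += p
                expected.append(num / den)
        assert sub["value"].iloc[0] == pytest.approx(np.mean(expected), abs=1e-10)


class TestSampling:
    def test_unbiased_sampling_is_latitudinally_uniform(self):
        """Chi-square across latitude bands non-significant at alpha=0.01 in
        >= 95% of 100 seeds under zero spatial bias."""
        n_ok = 0
        for seed in range(100):
            cfg = small_cfg(bias_south=0.0, bias_time=0.0, seed=seed,
                            n_groups=1, species_per_group=3, visits_per_year=60)
            drv = generate_drivers(cfg)
            sp = generate_species(cfg)
            truth = ot.compute_truth(cfg, drv, sp)
            _, visits = ot.sample_records(cfg, sp, truth)
            bands = visits["y"] // 2  # five 2-row bands on a 10-row grid
            counts = bands.value_counts().reindex(range(5), fill_value=0)
            p = stats.chisquare(counts).pvalue
            n_ok += p > 0.01
        assert n_ok >= 95

    def test_south_bias_concentrates_visits_south(self, tiny_world):
        v = tiny_world.visits
        south = (v["y"] < tiny_world.cfg.grid_size / 2).mean()
        assert south > 0.55

    def test_temporal_bias_grows_record_counts(self):
        slopes = []
        for seed in range(10):
            cfg = small_cfg(bias_time=0.15, seed=seed, n_groups=1, species_per_group=3)
            drv = generate_drivers(cfg)
            sp = generate_species(cfg)
            truth = ot.compute_truth(cfg, drv, sp)
            _, visits = ot.sample_records(cfg, sp, truth)
            counts = visits.groupby("year").size()
            slopes.append(np.polyfit(counts.index, counts.to_numpy(), 1)[0])
        assert np.mean(slopes) > 0
        assert sum(s > 0 for s in slopes) >= 9

    def test_full_list_occupancy_unbiased_for_truth(self):
        """With perfect detection and no bias, the empirical occupancy of
        full-list records estimates the mean true probability at the visited
        site-years (within binomial error)."""
        cfg = small_cfg(detection_prob=1.0, bias_south=0.0, bias_time=0.0,
                        n_fulllist_groups=2, beta=[0.5, -0.5], seed=11)
        drv = generate_drivers(cfg)
        sp = generate_species(cfg)
        truth = ot.compute_truth(cfg, drv, sp)
        records, visits = ot.sample_records(cfg, sp, truth)
        yi = visits["year"].to_numpy() - cfg.first_year
        p_true = truth.probability[:, yi, visits["y"].to_numpy(), visits["x"].to_numpy()]
        expected = p_true.mean()
        observed = records["status"].mean()
        n = len(records)
        tol = 4 * np.sqrt(expected * (1 - expected) / n)
        assert observed == pytest.approx(expected, abs=tol)

    def test_zero_visits_is_an_explicit_error(self):
        cfg = small_cfg(visits_per_year=1, years=1)
        drv = generate_drivers(cfg)
        sp = generate_species(cfg)
        truth = ot.compute_truth(cfg, drv, sp)
        cfg.visits_per_year = 0
        with pytest.raises(RuntimeError, match="zero visits"):
            # rebuild the yearly allocation with zero expected effort
            ot.sample_records(cfg, sp, truth)

    def test_world_determinism_end_to_end(self):
        cfg = small_cfg(seed=9)
        a = ot.generate_world(cfg)
        b = ot.generate_world(small_cfg(seed=9))
        pd.testing.assert_frame_equal(a[3], b[3])
        np.testing.assert_array_equal(a[2].probability, b[2].probability)


class TestConfigValidation:
    def test_bad_mediation_indices_rejected(self):
        with pytest.raises(ValueError, match="unknown driver"):
            small_cfg(mediation_list=[(9, 0, 1.0)])
        with pytest.raises(ValueError, match="unknown trait"):
            small_cfg(mediation_list=[(0, 9, 1.0)])

    def test_zero_traits_requires_no_mediation(self):
        with pytest.raises(ValueError):
            small_cfg(n_traits=0, mediation_list=[(0, 0, 1.0)])

    def test_detection_prob_bounds(self):
        with pytest.raises(ValueError):
            small_cfg(detection_prob=0.0)
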