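import itertools
import math

import numpy as np
import pandas as pd
import pytest

from strandage.io import ReadPatternSet, SampleMetadata
from strandage.singleread import (
    AgeGrid,
    SiteAgeModel,
    fit_site_models,
    grid_likelihoods,
    pattern_likelihood,
    predict_pattern_age,
    predict_sample_age,
    read_age_distribution,
    read_site_models,
    site_probability,
    write_site_models,
)
from strandage.simulate import SimulationSpec, sample_site_models, simulate_reads


def brute_force_pattern_age(models, pattern, grid=AgeGrid()):
    """Independent oracle: direct scalar scan of the grid with tie averaging."""
    best, tied = -1.0, []
    for a in grid.ages:
        pr = 1.0
        for m, ch in zip(models, pattern):
            p = min(max(m.slope * a + m.intercept, 0.0), 1.0)
            if ch == "1":
                pr *= p
            elif ch == "0":
                pr *= 1.0 - p
        if pr > best * (1 + 1e-12):
            best, tied = pr, [a]
        elif pr >= best * (1 - 1e-12):
            tied.append(a)
    if best == 0.0:
        return float("nan"), 0.0
    return float(np.mean(tied)), best


class TestSiteProbability:
    @pytest.mark.parametrize("slope,intercept,age,expected", [
        (0.01, -0.5, 20.0, 0.0),   # clips below
        (0.01, 0.5, 200.0, 1.0),   # clips above
        (0.005, 0.1, 60.0, 0.4),   # interior
    ])
    def test_clipping(self, slope, intercept, age, expected):
        m = SiteAgeModel("A", 1, slope, intercept)
        assert site_probability(m, age) == pytest.approx(expected)


class TestFitSiteModels:
    def _sets(self, freq_fn, ages, n_sites=2):
        """Pattern sets whose site frequencies equal freq_fn(age, site) exactly."""
        sets, rows = [], []
        for k, a in enumerate(ages):
            # 1000 reads per sample; site i methylated in round(f*1000) of them
            patterns = {}
            counts = [round(freq_fn(a, i) * 1000) for i in range(n_sites)]
            # construct reads site-by-site independently is impossible with
            # exact marginals for joint patterns; use per-site blocks instead
            for combo in itertools.product([0, 1], repeat=n_sites):
                # independent blocks: P(joint) = prod of marginals over 1000 reads
                n = 1000
                w = 1.0
                for i, c in enumerate(combo):
                    f = counts[i] / 1000
                    w *= f if c else 1 - f
                cnt = round(w * n)
                if cnt:
                    patterns["".join(map(str, combo))] = cnt
            sets.append(ReadPatternSet(f"s{k}", "A", n_sites, patterns))
        meta = SampleMetadata(pd.DataFrame(
            {"age": list(ages), "study": "x"},
            index=pd.Index([f"s{k}" for k in range(len(ages))], name="sample_id")))
        return sets, meta

    def test_exact_linear_frequencies_recovered(self):
        ages = [0.0, 25.0, 50.0, 100.0]
        sets, meta = self._sets(lambda a, i: 0.002 * a + 0.1, ages, n_sites=1)
        models = fit_site_models(sets, meta, min_count=1)
        assert models[0].slope == pytest.approx(0.002, abs=1e-9)
        assert models[0].intercept == pytest.approx(0.1, abs=1e-9)

    def test_constant_frequency_gives_zero_slope(self):
        ages = [10.0, 20.0, 30.0]
        sets, meta = self._sets(lambda a, i: 0.4, ages, n_sites=1)
        models = fit_site_models(sets, meta, min_count=1)
        assert models[0].slope == pytest.approx(0.0, abs=1e-12)
        assert models[0].intercept == pytest.approx(0.4, abs=1e-12)

    def test_two_samples_rejected(self):
        ages = [10.0, 20.0]
        sets, meta = self._sets(lambda a, i: 0.3, ages, n_sites=1)
        with pytest.raises(ValueError, match="at least 3"):
            fit_site_models(sets, meta, min_count=1)

    def test_model_file_round_trip(self, tmp_path):
        models = sample_site_models(5, seed=3)
        path = tmp_path / "models.tsv"
        write_site_models(models, path)
        assert read_site_models(path) == models


class TestPatternLikelihood:
    def test_power_of_half(self):
        models = [SiteAgeModel("A", i + 1, 0.0, 0.5) for i in range(4)]
        assert pattern_likelihood(models, "1010", 30.0) == pytest.approx(0.0625)

    def test_absorbing_zero(self):
        models = [SiteAgeModel("A", 1, 0.0, 0.0), SiteAgeModel("A", 2, 0.0, 0.5)]
        assert pattern_likelihood(models, "11", 50.0) == 0.0

    def test_missing_call_marginalized(self):
        models = [SiteAgeModel("A", 1, 0.0, 0.3), SiteAgeModel("A", 2, 0.0, 0.5)]
        assert pattern_likelihood(models, "1.", 10.0) == pytest.approx(0.3)

    @pytest.mark.parametrize("n_sites", [1, 4, 8, 12])
    def test_normalization_over_all_patterns(self, n_sites):
        models = sample_site_models(n_sites, seed=n_sites)
        patterns = ["".join(p) for p in itertools.product("01", repeat=n_sites)]
        lik = grid_likelihoods(models, patterns)
        totals = lik.sum(axis=0)
        assert np.max(np.abs(totals - 1.0)) < 1e-9

    def test_normalization_with_clipped_probabilities(self):
        # steep slopes force exact 0/1 clipping over most of the grid
        models = [SiteAgeModel("A", 1, 0.02, -0.5), SiteAgeModel("A", 2, -0.02, 1.2)]
        patterns = ["00", "01", "10", "11"]
        lik = grid_likelihoods(models, patterns)
        np.testing.assert_allclose(lik.sum(axis=0), 1.0, atol=1e-12)


class TestPredictPatternAge:
    def test_monotone_likelihood_maximized_at_boundary(self):
        m = [SiteAgeModel("A", 1, 1 / 200, 0.0)]
        assert predict_pattern_age(m, "1").age == 200.0
        assert predict_pattern_age(m, "0").age == 0.0

    def test_plateau_tie_averaging(self):
        # p = 1 for ages >= 100: all-methylated likelihood flat at 1 on 100..200
        m = [SiteAgeModel("A", 1, 0.01, 0.0)]
        res = predict_pattern_age(m, "1")
        assert res.age == pytest.approx(150.0)
        assert res.max_likelihood == 1.0

    def test_impossible_pattern_has_undefined_age(self):
        m = [SiteAgeModel("A", 1, 0.0, 0.0)]  # p = 0 at every age
        res = predict_pattern_age(m, "1")
        assert math.isnan(res.age)
        assert res.max_likelihood == 0.0

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        grid = AgeGrid()
        for trial in range(200):
            n_sites = int(rng.integers(1, 9))
            models = [SiteAgeModel("A", i + 1,
                                   float(rng.uniform(-0.01, 0.01)),
                                   float(rng.uniform(-0.2, 1.2)))
                      for i in range(n_sites)]
            pattern = "".join(rng.choice(["0", "1"], n_sites))
            res = predict_pattern_age(models, pattern, grid)
            oracle_age, oracle_max = brute_force_pattern_age(models, pattern, grid)
            assert res.max_likelihood == pytest.approx(oracle_max, rel=1e-9, abs=1e-300)
            if math.isnan(oracle_age):
                assert math.isnan(res.age)
            else:
                assert res.age == pytest.approx(oracle_age, abs=1e-9)

    def test_grid_refinement_stability(self):
        models = sample_site_models(10, seed=4)
        spec_reads = simulate_reads(SimulationSpec(models, [50.0], 50, seed=4))
        coarse = AgeGrid(step=1.0)
        fine = AgeGrid(step=0.25)
        for pattern in spec_reads[0].patterns:
            a1 = predict_pattern_age(models, pattern, coarse).age
            a2 = predict_pattern_age(models, pattern, fine).age
            if not (math.isnan(a1) or a1 in (0.0, 200.0)):
                assert abs(a1 - a2) <= 0.5

    def test_single_site_age_nondecreasing_in_methylated_count(self):
        models = [SiteAgeModel("A", i + 1, 0.004, 0.1) for i in range(6)]
        ages = []
        for k in range(7):
            pattern = "1" * k + "0" * (6 - k)
            ages.append(predict_pattern_age(models, pattern).age)
        assert all(b >= a for a, b in zip(ages, ages[1:]))


class TestPredictSampleAge:
    def test_weighted_mean_of_pattern_ages(self):
        # single site, slope 1/200: "1" -> 200, "0" -> 0
        m = [SiteAgeModel("A", 1, 1 / 200, 0.0)]
        rps = ReadPatternSet("S1", "A", 1, {"1": 3, "0": 1})
        pred = predict_sample_age(m, rps)
        assert pred.age == pytest.approx(150.0)
        assert pred.n_reads_used == 4

    def test_single_pattern_returns_its_age(self):
        m = [SiteAgeModel("A", 1, 1 / 200, 0.0)]
        pred = predict_sample_age(m, ReadPatternSet("S1", "A", 1, {"1": 7}))
        assert pred.age == 200.0

    def test_missing_policy_drop_excludes_reads(self):
        m = [SiteAgeModel("A", 1, 1 / 200, 0.0), SiteAgeModel("A", 2, 0.0, 0.5)]
        rps = ReadPatternSet("S1", "A", 2, {"1.": 5, "10": 5})
        dropped = predict_sample_age(m, rps, missing_policy="drop")
        assert dropped.n_reads_excluded == 5
        assert dropped.n_reads_used == 5
        marginalized = predict_sample_age(m, rps, missing_policy="marginalize")
        assert marginalized.n_reads_used == 10

    def test_all_impossible_gives_missing_prediction(self):
        m = [SiteAgeModel("A", 1, 0.0, 0.0)]
        pred = predict_sample_age(m, ReadPatternSet("S1", "A", 1, {"1": 4}))
        assert math.isnan(pred.age)
        assert pred.n_reads_excluded == 4

    def test_simulated_donor_recovered_near_truth(self):
        models = sample_site_models(36, seed=21)
        sets = simulate_reads(SimulationSpec(models, [60.0], 1000, seed=21))
        pred = predict_sample_age(models, sets[0])
        assert abs(pred.age - 60.0) < 5.0

    def test_more_reads_shrink_sampling_variance(self):
        models = sample_site_models(20, seed=6)
        spreads = {}
        for n_reads in (100, 1600):
            estimates = []
            for rep in range(8):
                sets = simulate_reads(SimulationSpec(
                    models, [50.0], n_reads, seed=1000 + 16 * rep + n_reads))
                estimates.append(predict_sample_age(models, sets[0]).age)
            spreads[n_reads] = np.var(estimates)
        # 16x the reads: variance should drop clearly (~16x in expectation)
        assert spreads[1600] < spreads[100] / 2


class TestReadAgeDistribution:
    def _results(self, models, rps):
        return predict_sample_age(models, rps).results

    def test_single_bin_gets_all_mass(self):
        m = [SiteAgeModel("A", 1, 1 / 200, 0.0)]
        results = self._results(m, ReadPatternSet("S", "A", 1, {"1": 9}))
        edges, mass = read_age_distribution(results)
        assert mass.sum() == pytest.approx(1.0)
        assert mass[-1] == pytest.approx(1.0)  # age 200 lands in the closed last bin

    def test_multiplicity_weighting(self):
        m = [SiteAgeModel("A", 1, 1 / 200, 0.0)]
        results = self._results(m, ReadPatternSet("S", "A", 1, {"1": 3, "0": 1}))
        edges, mass = read_age_distribution(results)
        assert mass[0] == pytest.approx(0.25)      # age 0 bin
        assert mass[-1] == pytest.approx(0.75)     # age 200 in the closed last bin

    def test_masses_always_sum_to_one(self):
        models = sample_site_models(12, seed=9)
        sets = simulate_reads(SimulationSpec(models, [40.0], 500, seed=9))
        results = self._results(models, sets[0])
        _, mass = read_age_distribution(results)
        assert mass.sum() == pytest.approx(1.0)


class TestEndToEndRecovery:
    def test_held_out_donor_ages_recovered(self):
        """Fit site models on half the simulated donors, predict the rest;
        correlation with true age must be high and median error small."""
        rng = np.random.default_rng(7)
        models = sample_site_models(36, seed=7)
        ages = rng.uniform(20, 80, 20)
        sets = simulate_reads(SimulationSpec(models, list(ages), 400, seed=7))
        meta = SampleMetadata(pd.DataFrame(
            {"age": ages, "study": "sim"},
            index=pd.Index([s.sample_id for s in sets], name="sample_id")))
        fitted = fit_site_models(sets[:10], meta, min_count=1)
        preds = np.array([predict_sample_age(fitted, s).age for s in sets[10:]])
        truth = ages[10:]
        r2 = np.corrcoef(preds, truth)[0, 1] ** 2
        assert r2 >= 0.9
        assert np.median(np.abs(preds - truth)) <= 5.0
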