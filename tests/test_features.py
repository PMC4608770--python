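"""Feature operators against hand arithmetic and brute-force oracles."""

import math

import numpy as np
import pytest

from painfeat.features import (
    BaselineReference,
    FeatureConfig,
    amplitude_features,
    approximate_entropy,
    coherence_features,
    extract_feature_vector,
    feature_group_counts,
    frequency_features,
    fuzzy_entropy,
    lag_dependence_features,
    mutual_information,
    rr_features,
    sample_entropy,
    shannon_entropy,
    similarity_correlation,
    spectral_entropy,
    standard_feature_names,
    stationarity_features,
    variability_features,
    znorm_per_person,
)

FS = 512.0


# ---------------------------------------------------------------------------
# brute-force double-loop oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def apen_oracle(x, m, r):
    n = len(x)

    def phi(mm):
        total = 0.0
        for i in range(n - mm + 1):
            c = 0
            for j in range(n - mm + 1):
                d = max(abs(x[i + k] - x[j + k]) for k in range(mm))
                if d <= r:
                    c += 1
            total += math.log(c / (n - mm + 1))
        return total / (n - mm + 1)

    return phi(m) - phi(m + 1)


def sampen_oracle(x, m, r):
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    return -math.log(a / b)


def fuzzyen_oracle(x, m, r, nf):
    n = len(x)

    def phi(mm):
        temps = []
        for i in range(n - m):
            t = x[i:i + mm]
            temps.append([v - sum(t) / mm for v in t])
        sims = []
        for i in range(len(temps)):
            for j in range(i + 1, len(temps)):
                d = max(abs(a - b) for a, b in zip(temps[i], temps[j]))
                sims.append(math.exp(-((d / r) ** nf)))
        return sum(sims) / len(sims)

    return math.log(phi(m) / phi(m + 1))


@pytest.fixture(scope="module")
def entropy_fixture():
    x = np.array([85.0, 80.0, 89.0] * 17)
    return x, 0.2 * np.std(x)


class TestTemplateEntropies:
    def test_apen_matches_bruteforce(self, entropy_fixture):
        x, r = entropy_fixture
        assert approximate_entropy(x, 2, r=r) == pytest.approx(
            apen_oracle(list(x), 2, r), abs=1e-10)

    def test_sampen_matches_bruteforce(self, entropy_fixture):
        x, r = entropy_fixture
        assert sample_entropy(x, 2, r=r) == pytest.approx(
            sampen_oracle(list(x), 2, r), abs=1e-10)

    def test_fuzzyen_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        r = 0.2 * np.std(x)
        assert fuzzy_entropy(x, 2, r=r, n_fuzzy=2) == pytest.approx(
            fuzzyen_oracle(list(x), 2, r, 2), abs=1e-10)

    @pytest.mark.parametrize("fn", [approximate_entropy, sample_entropy, fuzzy_entropy])
    def test_constant_signal_zero(self, fn):
        assert fn(np.full(60, 7.0)) == 0.0

    def test_noise_more_irregular_than_sine(self):
        """ApEn orders white noise above an equal-variance sine."""
        t = np.arange(300) / FS
        sine = np.sin(2 * np.pi * 20 * t)
        wins = 0
        for k in range(20):
            noise = np.random.default_rng(300 + k).standard_normal(300)
            noise *= np.std(sine) / np.std(noise)
            if approximate_entropy(noise) > approximate_entropy(sine):
                wins += 1
        assert wins >= 19

    def test_sampen_shift_invariant(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.standard_normal(80)
            r = 0.5 * np.std(x)  # wide tolerance so matches always exist
            assert sample_entropy(x, 2, r=r) == pytest.approx(
                sample_entropy(x + 123.4, 2, r=r), abs=1e-12)

    def test_fuzzyen_continuous_under_perturbation(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(120)
        base = fuzzy_entropy(x)
        y = x.copy()
        y[60] += 0.01 * np.std(x)
        assert abs(fuzzy_entropy(y) - base) < 0.1 * abs(base)


class TestDistributionEntropies:
    def test_shannon_two_equal_bins(self):
        x = np.array([0.0] * 50 + [1.0] * 50)
        assert shannon_entropy(x, bins=2) == pytest.approx(math.log(2), abs=1e-12)

    def test_shannon_constant_zero(self):
        assert shannon_entropy(np.full(100, 2.5)) == 0.0

    def test_shannon_uniform_over_bins(self):
        b = 16
        x = np.repeat(np.arange(b), 10) + 0.5  # 10 values per bin exactly
        assert shannon_entropy(x, bins=b) == pytest.approx(math.log(b), abs=1e-9)

    def test_spectral_entropy_sine_low_noise_high(self):
        t = np.arange(0, 5.5, 1 / FS)
        sine = np.sin(2 * np.pi * 50 * t)
        noise = np.random.default_rng(1).standard_normal(len(t))
        assert spectral_entropy(sine, FS) < 0.2
        assert spectral_entropy(noise, FS) > 0.85

    def test_spectral_entropy_scale_invariant(self):
        x = np.random.default_rng(2).standard_normal(2816)
        assert spectral_entropy(x, FS) == pytest.approx(
            spectral_entropy(7.7 * x, FS), abs=1e-12)


class TestAmplitude:
    def test_constant_segment(self):
        out = amplitude_features(np.full(100, 3.0))
        assert out["Peak"] == 3.0
        assert out["PeakToPeak"] == 0.0
        assert out["RootMeanSquare"] == 3.0
        assert out["MeanAbsoluteValueFirstDiff"] == 0.0
        assert out["MeanAbsoluteValueSecondDiff"] == 0.0

    def test_hand_arithmetic(self):
        out = amplitude_features(np.array([1.0, -2.0, 3.0]))
        assert out["PeakToPeak"] == 5.0
        assert out["MeanAbsoluteValue"] == 2.0
        assert out["MeanAbsoluteValueFirstDiff"] == 4.0  # (3 + 5)/2

    def test_against_independent_reimplementation(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            x = rng.standard_normal(rng.integers(10, 200))
            out = amplitude_features(x)
            assert out["Peak"] == pytest.approx(x.max())
            assert out["PeakToPeak"] == pytest.approx(x.max() - x.min())
            assert out["RootMeanSquare"] == pytest.approx(
                math.sqrt(sum(v * v for v in x) / len(x)))
            assert out["MeanAbsoluteValue"] == pytest.approx(
                sum(abs(v) for v in x) / len(x))
            d1 = [abs(x[i + 1] - x[i]) for i in range(len(x) - 1)]
            assert out["MeanAbsoluteValueFirstDiff"] == pytest.approx(sum(d1) / len(d1))
            d2 = [abs(x[i + 2] - 2 * x[i + 1] + x[i]) for i in range(len(x) - 2)]
            assert out["MeanAbsoluteValueSecondDiff"] == pytest.approx(sum(d2) / len(d2))

    def test_time_reversal_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(500)
        a, b = amplitude_features(x), amplitude_features(x[::-1])
        for k, v in a.items():
            assert b[k] == pytest.approx(v, rel=1e-12), k


class TestFrequency:
    def test_pure_sine_closed_form(self):
        t = np.arange(0, 5.5, 1 / FS)  # 50 Hz falls on an exact DFT bin
        x = np.sin(2 * np.pi * 50 * t)
        out = frequency_features(x, FS)
        df = FS / len(t)
        assert out["ModeFrequency"] == pytest.approx(50.0, abs=df)
        assert out["MeanFrequency"] == pytest.approx(50.0, abs=df)
        assert out["MedianFrequency"] == pytest.approx(50.0, abs=df)
        assert out["CentralFrequency"] == pytest.approx(50.0, abs=df)
        assert out["ZeroCrossings"] == pytest.approx(2 * 50 * 5.5, abs=1)

    def test_equal_sines_symmetric_mean(self):
        t = np.arange(0, 5.5, 1 / FS)
        x = np.sin(2 * np.pi * 40 * t) + np.sin(2 * np.pi * 60 * t)
        out = frequency_features(x, FS)
        assert out["MeanFrequency"] == pytest.approx(50.0, abs=FS / len(t))

    def test_white_noise_median_near_quarter_fs(self):
        x = np.random.default_rng(3).standard_normal(2816)
        out = frequency_features(x, FS)
        assert out["MedianFrequency"] == pytest.approx(FS / 4, rel=0.1)

    def test_printed_central_frequency_variant(self):
        t = np.arange(0, 5.5, 1 / FS)
        x = np.sin(2 * np.pi * 50 * t)
        out = frequency_features(x, FS, FeatureConfig(cf_printed_variant=True))
        # single-bin band: fh == fl, so the printed half-difference is 0
        assert out["CentralFrequency"] == pytest.approx(out["Bandwidth"] / 2)


class TestStationarity:
    def test_constant_signal_dispersion_zero(self):
        out = stationarity_features(np.full(2816, 1.5), FS)
        assert out["StandardDeviationOfMeanVector"] == 0.0
        assert out["StandardDeviationOfStdVector"] == 0.0

    def test_amplitude_step_raises_area(self):
        """A variance step mid-segment reads as less stationary than noise."""
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(10):
            stat = rng.standard_normal(2816)
            step = rng.standard_normal(2816)
            step[1408:] *= 2.0
            a_stat = stationarity_features(stat, FS)["AreaOfStationarityDegree"]
            a_step = stationarity_features(step, FS)["AreaOfStationarityDegree"]
            hits += a_step > a_stat
        assert hits >= 9

    def test_stationary_noise_small_dispersion(self):
        rng = np.random.default_rng(22)
        out = stationarity_features(rng.standard_normal(2816), FS)
        # subsegment means fluctuate ~ 1/sqrt(256); generous ceiling
        assert out["StandardDeviationOfMeanVector"] < 0.2
        assert abs(out["StandardDeviationOfStdVector"]) < 0.2


class TestLagDependence:
    def test_ar1_strongly_dependent(self):
        rng = np.random.default_rng(31)
        x = np.zeros(3000)
        for i in range(1, len(x)):
            x[i] = 0.9 * x[i - 1] + rng.standard_normal()
        out = lag_dependence_features(x, K=10)
        assert out["LagDependenceValues"] > 0.5

    def test_white_noise_weakly_dependent(self):
        x = np.random.default_rng(32).standard_normal(3000)
        out = lag_dependence_features(x, K=10)
        assert out["LagDependenceValues"] < 0.1

    def test_quadratic_nests_linear(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            x = rng.standard_normal(400)
            out = lag_dependence_features(x, K=5)
            assert out["PolynomialLagDependenceValues"] >= \
                out["LagDependenceValues"] - 1e-9


class TestVariability:
    def test_hand_arithmetic(self):
        out = variability_features(np.array([1.0, 2, 3, 4, 5]))
        assert out["Variance"] == pytest.approx(2.5)
        assert out["StandardDeviation"] == pytest.approx(math.sqrt(2.5))
        assert out["Range"] == 4.0

    def test_constant_all_zero(self):
        out = variability_features(np.full(50, 9.9))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in out.values())

    def test_semi_interquartile_of_standard_normal(self):
        x = np.random.default_rng(41).standard_normal(100_000)
        out = variability_features(x)
        assert out["SemiInterquartileRange"] == pytest.approx(0.6745, abs=0.02)


class TestRRFeatures:
    def test_constant_rr(self):
        out = rr_features(np.array([800.0, 800, 800]))
        assert out["MeanRR"] == pytest.approx(800.0)
        assert out["RMSSD"] == 0.0
        assert out["SlopeRR"] == pytest.approx(0.0, abs=1e-9)

    def test_rmssd_hand_value(self):
        out = rr_features(np.array([800.0, 810, 790]))
        assert out["RMSSD"] == pytest.approx(math.sqrt(250), abs=1e-9)  # ~15.811

    def test_linear_trend_slope(self):
        out = rr_features(np.array([700.0, 710, 720, 730]))
        assert out["SlopeRR"] == pytest.approx(10.0, abs=1e-9)

    def test_too_few_intervals_sentinel(self):
        out = rr_features(np.array([800.0, 810]))
        assert all(np.isnan(v) for v in out.values())


class TestSimilarity:
    def test_coherence_identical_signals_unity(self):
        x = np.random.default_rng(51).standard_normal(2816)
        out = coherence_features(x, x, FS)
        for k, v in out.items():
            assert v == pytest.approx(1.0, abs=1e-10), k

    def test_coherence_independent_low(self):
        rng = np.random.default_rng(52)
        out = coherence_features(rng.standard_normal(2816),
                                 rng.standard_normal(2816), FS)
        assert out["CoherenceMean"] < 0.3

    def test_coherence_delay_invariant(self):
        x = np.random.default_rng(53).standard_normal(2816 + 5)
        out = coherence_features(x[5:], x[:-5], FS)
        assert out["CoherenceMean"] > 0.9

    def test_correlation_self_and_negation(self):
        x = np.random.default_rng(54).standard_normal(1000)
        assert similarity_correlation(x, x) == pytest.approx(1.0)
        assert similarity_correlation(x, -x) == pytest.approx(-1.0)

    def test_correlation_null_distribution(self):
        hits = 0
        trials = 40
        for k in range(trials):
            rng = np.random.default_rng(600 + k)
            r = similarity_correlation(rng.standard_normal(2816),
                                       rng.standard_normal(2816))
            hits += abs(r) < 0.06
        assert hits >= 0.95 * trials

    def test_mutual_information_self_equals_entropy(self):
        x = np.random.default_rng(55).standard_normal(2816)
        counts, _ = np.histogram(x, bins=16)
        p = counts[counts > 0] / counts.sum()
        h = -np.sum(p * np.log(p))
        assert mutual_information(x, x, bins=16) == pytest.approx(h, abs=1e-12)

    def test_mutual_information_independent_small(self):
        rng = np.random.default_rng(56)
        i = mutual_information(rng.standard_normal(2816),
                               rng.standard_normal(2816), bins=16)
        assert 0 <= i < 0.05  # histogram bias ~ (B-1)^2 / 2N

    def test_mutual_information_symmetric(self):
        rng = np.random.default_rng(57)
        for _ in range(20):
            a, b = rng.standard_normal((2, 500))
            assert mutual_information(a, b) == pytest.approx(
                mutual_information(b, a), abs=1e-12)


class TestAssembly:
    def test_standard_vector_has_159_features(self, preprocessed0, baseline_ref,
                                              feature_cfg):
        vec = extract_feature_vector(preprocessed0.windows[0], baseline_ref,
                                     preprocessed0.rr, feature_cfg)
        assert len(vec) == 159
        assert feature_group_counts(list(vec)) == {
            "amplitude": 40, "frequency": 24, "stationarity": 24,
            "entropy": 20, "linearity": 8, "variability": 19, "similarity": 24}

    def test_canonical_names_present(self):
        names = standard_feature_names()
        assert len(names) == 159
        assert "Zygomaticus_Similarity_Correlation" in names
        assert "Corrugator_Amplitude_Peak" in names
        assert "ECG_Variability_MeanRR" in names

    def test_waveform_only_config_has_156(self, preprocessed0, baseline_ref,
                                          feature_cfg):
        win = preprocessed0.windows[0]
        import copy
        w2 = copy.copy(win)
        w2.segments = {k: v for k, v in win.segments.items() if k != "ecg"}
        vec = extract_feature_vector(w2, baseline_ref, preprocessed0.rr, feature_cfg)
        assert len(vec) == 156

    def test_vector_order_matches_canonical(self, preprocessed0, baseline_ref,
                                            feature_cfg):
        vec = extract_feature_vector(preprocessed0.windows[0], baseline_ref,
                                     preprocessed0.rr, feature_cfg)
        assert list(vec) == standard_feature_names()


class TestZnorm:
    def test_per_subject_standardization(self):
        import pandas as pd
        rng = np.random.default_rng(61)
        m = pd.DataFrame({
            "subject_id": ["a"] * 20 + ["b"] * 20,
            "class_label": ["B", "T4"] * 20,
            "f1": np.concatenate([rng.normal(5, 2, 20), rng.normal(-3, 0.5, 20)]),
            "f2": rng.standard_normal(40),
        })
        z = znorm_per_person(m)
        for sid in ("a", "b"):
            g = z[z.subject_id == sid]
            for c in ("f1", "f2"):
                assert abs(g[c].mean()) < 1e-10
                assert g[c].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_constant_column_becomes_zero(self):
        import pandas as pd
        m = pd.DataFrame({"subject_id": ["a"] * 5, "class_label": ["B"] * 5,
                          "f1": [3.3] * 5})
        z = znorm_per_person(m)
        assert (z["f1"] == 0.0).all()

    def test_single_subject_equals_global_zscore(self):
        import pandas as pd
        rng = np.random.default_rng(62)
        x = rng.standard_normal(30)
        m = pd.DataFrame({"subject_id": ["a"] * 30, "class_label": ["B"] * 30,
                          "f1": x})
        z = znorm_per_person(m)
        np.testing.assert_allclose(z["f1"], (x - x.mean()) / x.std(), atol=1e-12)
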