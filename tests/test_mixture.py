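import math

import numpy as np
import pytest

from libramix import (
    MixtureParams,
    NBParams,
    assign_labels,
    classify,
    fit_mixture,
    fit_nb_mle,
    init_from_control,
    init_percentile,
    mixture_nll,
    mixture_pmf,
    nb_pmf,
    posterior,
)
from libramix.mixture import NOISE, SIGNAL, mixture_logpmf


def labeled(omega, comp1, comp2):
    return assign_labels(MixtureParams(omega, comp1, comp2))


class TestMixturePmf:
    def test_identical_components_equals_single(self):
        comp = NBParams(3, 0.4)
        mix = MixtureParams(0.3, comp, comp)
        for k in range(30):
            assert mixture_pmf(k, mix) == pytest.approx(nb_pmf(k, comp), rel=1e-12)

    def test_normalization(self):
        mix = MixtureParams(0.6, NBParams(2, 0.7), NBParams(20, 0.2))
        assert mixture_pmf(np.arange(4000), mix).sum() == pytest.approx(1.0, abs=1e-8)

    def test_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mix = MixtureParams(rng.uniform(0.05, 0.95),
                                NBParams(rng.uniform(0.5, 10), rng.uniform(0.1, 0.9)),
                                NBParams(rng.uniform(0.5, 30), rng.uniform(0.1, 0.9)))
            ks = np.arange(0, 100, 3)
            expected = (mix.omega * nb_pmf(ks, mix.comp1)
                        + (1 - mix.omega) * nb_pmf(ks, mix.comp2))
            np.testing.assert_allclose(mixture_pmf(ks, mix), expected, rtol=1e-12)


class TestMixtureNll:
    def test_identical_components_equals_single_nb_nll(self):
        comp = NBParams(4, 0.5)
        mix = MixtureParams(0.25, comp, comp)
        counts = np.array([0, 1, 1, 3, 8])
        from libramix import nb_logpmf
        assert mixture_nll(counts, mix) == pytest.approx(
            -nb_logpmf(counts, comp).sum(), rel=1e-12)

    def test_matches_naive_log_oracle(self):
        mix = MixtureParams(0.4, NBParams(2, 0.6), NBParams(15, 0.25))
        counts = np.array([0, 2, 5, 40, 80, 80])
        naive = -sum(math.log(mixture_pmf(int(k), mix)) for k in counts)
        assert mixture_nll(counts, mix) == pytest.approx(naive, rel=1e-9)

    def test_additivity_of_duplicated_count(self):
        mix = MixtureParams(0.4, NBParams(2, 0.6), NBParams(15, 0.25))
        base = mixture_nll([3, 7], mix)
        contribution = -mixture_logpmf(7, mix)
        assert mixture_nll([3, 7, 7], mix) == pytest.approx(base + contribution)


class TestInit:
    def test_control_init_recovers_noise_params(self):
        rng = np.random.default_rng(21)
        control = rng.negative_binomial(2, 0.6, 3000)
        donor = np.concatenate([rng.negative_binomial(2, 0.6, 1000),
                                rng.negative_binomial(20, 0.2, 300)])
        init = init_from_control(control, donor)
        assert init.comp1.n == pytest.approx(2, rel=0.2)
        assert init.comp1.p == pytest.approx(0.6, abs=0.03)
        assert init.omega == 0.1

    def test_empty_control_falls_back_to_percentile(self):
        rng = np.random.default_rng(22)
        donor = np.concatenate([rng.negative_binomial(2, 0.7, 900),
                                rng.negative_binomial(20, 0.2, 100)])
        assert init_from_control([], donor) == init_percentile(donor, 0.1)

    def test_percentile_partition_means(self):
        # 90/10 mixture split at the 90th percentile: the two part fits
        # should land near the generating component means (0.857 and 80)
        rng = np.random.default_rng(23)
        donor = np.concatenate([rng.negative_binomial(2, 0.7, 4500),
                                rng.negative_binomial(20, 0.2, 500)])
        init = init_percentile(donor, 0.1)
        noise_mean = 2 * 0.3 / 0.7
        signal_mean = 20 * 0.8 / 0.2
        se_lo = donor[donor <= np.percentile(donor, 90)].std() / math.sqrt(4500)
        assert abs(init.comp1.mean - noise_mean) < max(2 * se_lo, 0.3)
        assert init.comp2.mean == pytest.approx(signal_mean, rel=0.15)

    def test_split_point_matches_sort_oracle(self):
        # linear interpolation between order statistics, computed by hand
        rng = np.random.default_rng(24)
        donor = rng.integers(0, 100, 500)
        q = 0.8
        s = np.sort(donor)
        pos = q * (len(s) - 1)
        lo, frac = int(pos), pos - int(pos)
        oracle_cut = s[lo] + frac * (s[min(lo + 1, len(s) - 1)] - s[lo])
        assert np.percentile(donor, 100 * q) == pytest.approx(oracle_cut)
        init = init_percentile(donor, 1 - q)
        lower_n = (donor <= oracle_cut).sum()
        assert lower_n == (donor <= np.percentile(donor, 100 * q)).sum()
        assert init.omega == pytest.approx(1 - q)

    def test_all_equal_counts_uses_moment_fallback(self):
        init = init_percentile(np.array([3] * 50), 0.1)
        assert init.comp1.n > 0 and 0 < init.comp1.p < 1

    def test_omega_equals_omega0_exactly(self):
        rng = np.random.default_rng(25)
        donor = rng.negative_binomial(5, 0.4, 200)
        assert init_percentile(donor, 0.17).omega == 0.17


class TestFitMixture:
    def test_parameter_recovery(self, mixture_sample):
        counts, _, truth = mixture_sample
        fit, diag = fit_mixture(counts, init_percentile(counts, 0.1))
        fit = assign_labels(fit)
        assert abs(fit.noise_weight - truth["omega_noise"]) < 0.05
        assert fit.noise.n == pytest.approx(truth["noise"].n, rel=0.35)
        assert fit.signal.n == pytest.approx(truth["signal"].n, rel=0.25)

    def test_fitted_nll_not_worse_than_init(self, mixture_sample):
        counts, _, _ = mixture_sample
        init = init_percentile(counts, 0.1)
        fit, diag = fit_mixture(counts, init)
        assert diag.nll <= mixture_nll(counts, init) + 1e-9

    def test_swapped_init_same_labeled_params(self, mixture_sample):
        counts, _, _ = mixture_sample
        init = init_percentile(counts, 0.1)
        swapped = MixtureParams(1 - init.omega, init.comp2, init.comp1)
        a = assign_labels(fit_mixture(counts, init)[0])
        b = assign_labels(fit_mixture(counts, swapped)[0])
        assert a.noise_weight == pytest.approx(b.noise_weight, abs=0.01)
        assert a.noise.n == pytest.approx(b.noise.n, rel=0.05)
        assert a.signal.n == pytest.approx(b.signal.n, rel=0.05)

    def test_control_and_percentile_init_agree(self, well_separated):
        # mirrors the finding that biased and unbiased fits give the same
        # answer when the components are well separated
        matrix, _, truth = well_separated
        counts = matrix.counts[~truth.is_control, 0]
        control = matrix.counts[truth.is_control, 0]
        a = assign_labels(fit_mixture(counts, init_from_control(control, counts))[0])
        b = assign_labels(fit_mixture(counts, init_percentile(counts, 0.1))[0])
        assert a.noise_weight == pytest.approx(b.noise_weight, abs=0.02)
        assert a.signal.mean == pytest.approx(b.signal.mean, rel=0.05)


class TestLabels:
    def test_higher_median_is_signal(self):
        mix = assign_labels(MixtureParams(0.5, NBParams(2, 0.7), NBParams(20, 0.2)))
        assert mix.labels == (NOISE, SIGNAL)
        mix = assign_labels(MixtureParams(0.5, NBParams(20, 0.2), NBParams(2, 0.7)))
        assert mix.labels == (SIGNAL, NOISE)

    def test_identical_components_deterministic_tiebreak(self):
        comp = NBParams(3, 0.5)
        mix = assign_labels(MixtureParams(0.4, comp, comp))
        assert mix.labels == (NOISE, SIGNAL)

    def test_invariant_under_component_permutation(self):
        a = assign_labels(MixtureParams(0.3, NBParams(2, 0.7), NBParams(20, 0.2)))
        b = assign_labels(MixtureParams(0.7, NBParams(20, 0.2), NBParams(2, 0.7)))
        assert a.noise == b.noise and a.signal == b.signal
        assert a.noise_weight == pytest.approx(b.noise_weight)


class TestPosterior:
    def test_identical_components_constant_complement(self):
        comp = NBParams(3, 0.5)
        mix = assign_labels(MixtureParams(0.4, comp, comp))
        for k in [0, 1, 5, 50]:
            p_n, p_s = posterior(k, mix)
            assert p_s == pytest.approx(1 - mix.noise_weight, rel=1e-12)

    def test_vanishing_noise_weight_limit(self):
        mix = assign_labels(MixtureParams(1e-8, NBParams(2, 0.7), NBParams(20, 0.2)))
        _, p_s = posterior(10, mix)
        assert p_s > 0.999

    def test_sums_to_one_exactly(self):
        mix = assign_labels(MixtureParams(0.6, NBParams(2, 0.7), NBParams(20, 0.2)))
        p_n, p_s = posterior(np.arange(200), mix)
        np.testing.assert_array_equal(p_n + p_s, np.ones(200))

    def test_matches_direct_ratio_oracle(self):
        mix = assign_labels(MixtureParams(0.6, NBParams(2, 0.7), NBParams(20, 0.2)))
        for k in range(0, 120, 5):
            expected = (mix.noise_weight * nb_pmf(k, mix.noise)
                        / mixture_pmf(k, mix))
            p_n, _ = posterior(k, mix)
            assert p_n == pytest.approx(expected, rel=1e-10)

    def test_unlabeled_params_rejected(self):
        mix = MixtureParams(0.5, NBParams(2, 0.7), NBParams(20, 0.2))
        with pytest.raises(ValueError, match="unlabeled"):
            posterior(3, mix)

    def test_monotone_in_k_for_shared_n(self):
        # shared dispersion, stochastically larger signal => monotone
        # likelihood ratio => nondecreasing p_signal
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = rng.uniform(0.3, 30)
            p_s = rng.uniform(0.05, 0.9)
            p_n = rng.uniform(p_s + 0.01, 0.99)
            mix = assign_labels(MixtureParams(rng.uniform(0.05, 0.95),
                                              NBParams(n, p_n), NBParams(n, p_s)))
            _, ps = posterior(np.arange(501), mix)
            assert np.all(np.diff(ps) >= -1e-12)


class TestClassify:
    def test_boundary_threshold_inclusive(self):
        comp = NBParams(3, 0.5)
        mix = assign_labels(MixtureParams(0.4, comp, comp))  # p_signal = 0.6
        res = classify([1, 2], mix, threshold=0.6)
        assert list(res.calls) == ["signal", "signal"]

    def test_extreme_thresholds(self):
        mix = assign_labels(MixtureParams(0.6, NBParams(2, 0.7), NBParams(20, 0.2)))
        counts = np.arange(50)
        assert all(classify(counts, mix, 0.0).calls == "signal")
        assert all(classify(counts, mix, 1.0001).calls == "noise")

    def test_accuracy_on_well_separated_truth(self, mixture_sample):
        counts, labels, _ = mixture_sample
        fit = assign_labels(fit_mixture(counts, init_percentile(counts, 0.1))[0])
        res = classify(counts, fit, 0.5)
        accuracy = np.mean((res.calls == "signal") == labels)
        assert accuracy >= 0.95
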