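"""ISI decoder: densities, Bayes posteriors, CV accuracy, controls, ensembles."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from spikeflex.decoder import (
    DEFAULT_BANDWIDTH_GRID,
    EnsembleRecord,
    categorize_ensemble,
    crossval_decode,
    decode_ensemble,
    decode_trial,
    extract_isis,
    fit_isi_density,
    make_synthetic_control,
    sample_ensembles,
    select_bandwidth,
    significance_vs_control,
    task_encoder_threshold,
)


class TestExtractIsis:
    def test_three_spikes(self):
        st = np.array([0.10, 0.25, 0.45])
        np.testing.assert_allclose(extract_isis(st, 0.0, 1.0), [0.15, 0.20])

    @pytest.mark.parametrize("st", [np.array([]), np.array([0.5])])
    def test_fewer_than_two_spikes_empty(self, st):
        assert extract_isis(st, 0.0, 1.0).size == 0

    def test_matches_direct_recomputation(self, rng):
        st = np.sort(rng.uniform(0, 10, 200))
        t0, t1 = 2.0, 7.0
        oracle = np.diff(st[(st >= t0) & (st <= t1)])
        np.testing.assert_allclose(extract_isis(st, t0, t1), oracle)


class TestIsiDensity:
    def test_density_integrates_to_one(self, rng):
        isis = rng.lognormal(-3.0, 0.7, 300)
        dens = fit_isi_density(isis, seed=0)
        grid = np.logspace(-5, 1.5, 4000)
        integral = np.trapezoid(dens.pdf(grid), grid)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_cv_score_of_chosen_bandwidth_beats_endpoints(self, rng):
        """The selected bandwidth's CV likelihood >= the grid endpoints'."""
        z = np.log(rng.lognormal(-3.0, 0.7, 200))
        grid = DEFAULT_BANDWIDTH_GRID

        def cv_score(h, seed=11):
            # same fold construction as the implementation
            from sklearn.neighbors import KernelDensity

            perm = np.random.default_rng(seed).permutation(z.size)
            total = 0.0
            for test in np.array_split(perm, 5):
                train = np.setdiff1d(perm, test, assume_unique=True)
                kde = KernelDensity(bandwidth=h).fit(z[train, None])
                total += np.maximum(
                    kde.score_samples(z[test, None]), np.log(1e-12)
                ).sum()
            return total

        chosen = select_bandwidth(z, seed=11)
        assert cv_score(chosen) >= cv_score(grid[0]) - 1e-9
        assert cv_score(chosen) >= cv_score(grid[-1]) - 1e-9

    def test_duplicating_data_does_not_widen_bandwidth(self, rng):
        isis = rng.lognormal(-3.0, 0.5, 150)
        bw1 = fit_isi_density(isis, seed=3).bandwidth
        bw2 = fit_isi_density(np.tile(isis, 2), seed=3).bandwidth
        assert bw2 <= bw1

    def test_few_isis_fall_back_to_widest_bandwidth(self, rng):
        with pytest.warns(UserWarning):
            dens = fit_isi_density(rng.lognormal(-3, 0.5, 4), seed=0)
        assert dens.bandwidth == DEFAULT_BANDWIDTH_GRID.max()


class _StubDensity:
    """Fixed-density stand-in for posterior arithmetic tests."""

    def __init__(self, value):
        self.value = value

    def log_pdf(self, isis):
        return np.full(np.asarray(isis).size, np.log(self.value))


class TestDecodeTrial:
    def test_empty_isis_returns_priors(self):
        dens = {"target": _StubDensity(1.0), "nontarget": _StubDensity(2.0)}
        post = decode_trial(dens, np.empty(0), {"target": 0.5, "nontarget": 0.5})
        assert post == {"target": 0.5, "nontarget": 0.5}

    def test_two_to_one_density_ratio(self):
        dens = {"target": _StubDensity(2.0), "nontarget": _StubDensity(1.0)}
        post = decode_trial(dens, np.array([0.1]), {"target": 0.5, "nontarget": 0.5})
        assert post["target"] == pytest.approx(2.0 / 3.0)

    def test_log_space_matches_linear_product_oracle(self, rng):
        isis_t = rng.lognormal(-3.5, 0.5, 200)
        isis_nt = rng.lognormal(-2.5, 0.5, 200)
        dens = {
            "target": fit_isi_density(isis_t, seed=1, condition="target"),
            "nontarget": fit_isi_density(isis_nt, seed=2, condition="nontarget"),
        }
        priors = {"target": 0.4, "nontarget": 0.6}
        trial = rng.lognormal(-3.0, 0.5, 5)
        post = decode_trial(dens, trial, priors)
        # brute-force product in linear space
        lin = {
            c: priors[c] * np.prod(dens[c].pdf(trial)) for c in dens
        }
        z = sum(lin.values())
        for c in dens:
            assert post[c] == pytest.approx(lin[c] / z, abs=1e-9)
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)


def _labels(n):
    return np.array(["target", "nontarget"] * (n // 2))


def _isi_tables(rng, n_trials, mu_t, mu_nt, n_per=12, sigma=0.4):
    labels = _labels(n_trials)
    tables = [
        rng.lognormal(mu_t if l == "target" else mu_nt, sigma, n_per)
        for l in labels
    ]
    return tables, labels


class TestCrossvalDecode:
    def test_shuffled_labels_decode_at_chance(self):
        # single datasets fluctuate a few points around chance; the mean
        # over independent label-free datasets settles at 50%
        accs = []
        for rep in range(60):
            r = np.random.default_rng(1000 + rep)
            tables, labels = _isi_tables(r, 100, -3.0, -3.0)
            accs.append(
                crossval_decode(tables, labels, iterations=1, seed=rep).mean_accuracy
            )
        assert np.mean(accs) == pytest.approx(0.5, abs=0.02)

    def test_disjoint_supports_decode_near_perfectly(self, rng):
        tables, labels = _isi_tables(rng, 60, -5.5, -1.5, sigma=0.2)
        res = crossval_decode(tables, labels, iterations=5, seed=4)
        assert res.mean_accuracy >= 0.95

    def test_seeded_reproducibility(self, rng):
        tables, labels = _isi_tables(rng, 40, -3.5, -2.5)
        r1 = crossval_decode(tables, labels, iterations=5, seed=9)
        r2 = crossval_decode(tables, labels, iterations=5, seed=9)
        np.testing.assert_array_equal(r1.accuracy_samples, r2.accuracy_samples)

    def test_insufficient_trials_error(self, rng):
        tables, labels = _isi_tables(rng, 10, -3.0, -3.0)
        with pytest.raises(ValueError):
            crossval_decode(tables, labels, k=10, iterations=1, seed=0)


class TestSyntheticControl:
    def test_per_trial_count_matches_rate(self, rng):
        tables, _ = _isi_tables(rng, 200, -3.0, -3.0, n_per=20)
        durs = np.array([t.sum() for t in tables])  # observed trial spans
        surro = make_synthetic_control(tables, durs, seed=0)
        real_mean = np.mean([len(t) for t in tables])
        surro_mean = np.mean([len(s) for s in surro])
        assert surro_mean == pytest.approx(real_mean, rel=0.15)

    def test_pooled_distribution_converges(self, rng):
        from scipy.stats import ks_2samp

        def ks_for(n_trials, seed):
            tables, _ = _isi_tables(rng, n_trials, -3.0, -3.0, n_per=15)
            surro = make_synthetic_control(tables, np.full(n_trials, 0.8), seed=seed)
            return ks_2samp(
                np.concatenate(tables), np.concatenate(surro)
            ).statistic

        small = ks_for(20, 1)
        large = ks_for(400, 2)
        assert large < small

    def test_trial_durations_respected(self, rng):
        tables, _ = _isi_tables(rng, 40, -3.0, -3.0)
        durs = np.full(40, 0.5)
        surro = make_synthetic_control(tables, durs, seed=3)
        for s in surro:
            assert s.sum() <= 0.5

    def test_empty_pool_error(self):
        with pytest.raises(ValueError):
            make_synthetic_control([np.empty(0)], [1.0], seed=0)


class TestSignificance:
    def test_identical_distributions_not_significant(self, rng):
        x = rng.normal(0.5, 0.05, 200)
        p, sig = significance_vs_control(x, x.copy())
        assert p > 0.9
        assert not sig

    def test_separated_distributions_tiny_p(self, rng):
        a = rng.normal(0.9, 0.01, 100)
        b = rng.normal(0.5, 0.01, 100)
        p, sig = significance_vs_control(a, b)
        assert p < 1e-10
        assert sig

    def test_u_statistic_matches_pair_enumeration(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, rng.integers(3, 6))
            b = rng.normal(0.5, 1, rng.integers(3, 6))
            u_oracle = sum(
                1.0 if x > y else (0.5 if x == y else 0.0)
                for x, y in itertools.product(a, b)
            )
            assert mannwhitneyu(a, b).statistic == pytest.approx(u_oracle)


class TestTaskEncoderThreshold:
    def test_fifth_percentile_gap(self):
        below = np.concatenate([np.full(6, 0.44), np.linspace(0.45, 0.5, 95)])
        thr = task_encoder_threshold(below)
        assert thr == pytest.approx(0.56, abs=1e-9)

    def test_degenerate_at_chance(self):
        thr = task_encoder_threshold(np.full(30, 0.5))
        assert thr == pytest.approx(0.5)

    def test_reflection_preserves_gap(self, rng):
        below = 0.5 - np.abs(rng.normal(0, 0.02, 50))
        gap = 0.5 - np.percentile(below, 5)
        reflected = 0.5 + (0.5 - below)  # above-chance mirror
        assert np.percentile(reflected, 95) - 0.5 == pytest.approx(gap, abs=1e-12)
        assert task_encoder_threshold(below) == pytest.approx(0.5 + gap)

    def test_too_few_below_chance_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(task_encoder_threshold(np.array([0.4, 0.45])))


class TestEnsembles:
    def test_sample_count_equals_session_size(self):
        ids = [f"u{i}" for i in range(20)]
        recs = sample_ensembles(ids, n1=5, seed=0)
        assert len(recs) == 20
        for r in recs:
            assert len(set(r.members)) == 5

    def test_full_population_when_n1_equals_n2(self):
        ids = [f"u{i}" for i in range(6)]
        recs = sample_ensembles(ids, n1=6, seed=1)
        for r in recs:
            assert sorted(r.members) == ids

    def test_uniform_representation(self):
        ids = [f"u{i}" for i in range(10)]
        counts = {u: 0 for u in ids}
        n_draws = 50
        for s in range(n_draws):
            for r in sample_ensembles(ids, n1=4, seed=s):
                for m in r.members:
                    counts[m] += 1
        freqs = np.array(list(counts.values())) / (n_draws * 10)
        assert np.allclose(freqs, 0.4, atol=0.05)

    def test_oversized_ensemble_error(self):
        with pytest.raises(ValueError):
            sample_ensembles(["a", "b"], n1=3, seed=0)

    @pytest.mark.parametrize(
        "frac_ncr,expected",
        [
            (0.25, "CR_ensemble"),
            (0.30, "CR_ensemble"),
            (0.60, "mixed"),
            (0.75, "uncategorized"),
            (0.40, "uncategorized"),
            (0.85, "NCR_ensemble"),
        ],
    )
    def test_categorize(self, frac_ncr, expected):
        n = 20
        k = int(round(frac_ncr * n))
        labels = ["NCR"] * k + ["CR"] * (n - k)
        assert categorize_ensemble(labels) == expected


class TestEnsembleDecoding:
    def test_size_one_ensemble_identical_to_single_cell(self, rng):
        tables, labels = _isi_tables(rng, 40, -3.5, -2.5)
        single = crossval_decode(tables, labels, iterations=5, seed=21)
        ens = decode_ensemble([tables], labels, iterations=5, seed=21)
        np.testing.assert_array_equal(single.accuracy_samples, ens.accuracy_samples)

    def test_empty_member_contributes_nothing(self, rng):
        tables, labels = _isi_tables(rng, 40, -3.5, -2.5)
        empty = [np.empty(0)] * 40
        with_empty = decode_ensemble([tables, empty], labels, iterations=5, seed=21)
        without = decode_ensemble([tables], labels, iterations=5, seed=21)
        np.testing.assert_array_equal(
            with_empty.accuracy_samples, without.accuracy_samples
        )

    def test_two_informative_units_beat_the_best_single(self, rng):
        gains = []
        for rep in range(8):
            r = np.random.default_rng(500 + rep)
            t1, labels = _isi_tables(r, 40, -3.2, -2.8)
            t2, _ = _isi_tables(r, 40, -3.2, -2.8)
            a1 = crossval_decode(t1, labels, iterations=5, seed=rep).mean_accuracy
            a2 = crossval_decode(t2, labels, iterations=5, seed=rep).mean_accuracy
            ens = decode_ensemble(
                [t1, t2], labels, iterations=5, seed=rep
            ).mean_accuracy
            gains.append(ens - max(a1, a2))
        assert np.mean(gains) > -0.01  # pooling evidence does not hurt on average
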