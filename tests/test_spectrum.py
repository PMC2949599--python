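"""Period sweep, Monte-Carlo calibration and harmonic peak reading."""

import numpy as np
import pytest
from scipy.stats import ks_2samp, kstest

import solscm as scm
from solscm import (
    SiteSequence,
    SolenoidalSpectrum,
    compute_psos,
    compute_sos,
    family_correction,
    find_peaks,
    main_period,
    null_ensemble,
    solenoidal_spectrum,
)
from solscm.spectrum import null_ensemble_discrete


class TestComputeSos:
    def test_comb_global_maximum_plateau(self, comb_sites, benchmark_grid):
        """A perfect comb aligns exactly at the planted spacing and at each
        of its divisors; the plateau's largest member is the fundamental."""
        scores = compute_sos(comb_sites, benchmark_grid)
        top = scores.max()
        plateau = benchmark_grid[scores >= top * (1 - 1e-12)]
        np.testing.assert_array_equal(plateau, [2000, 2500, 5000, 10000])

    def test_single_period_grid(self, comb_sites):
        scores = compute_sos(comb_sites, [9000.0])
        assert scores.shape == (1,)
        assert scores[0] == pytest.approx(scm.scs_score(comb_sites, 9000.0))

    def test_harmonic_of_comb_beats_null_mean(self, comb_sites):
        null = null_ensemble(comb_sites.n, 1, R=500, seed=3)
        scores = compute_sos(comb_sites, [10000.0, 20000.0])
        assert (scores > null.mean()).all()

    def test_empty_grid_rejected(self, comb_sites):
        with pytest.raises(ValueError, match="empty"):
            compute_sos(comb_sites, [])


class TestNullEnsemble:
    def test_deterministic_under_seed(self):
        a = null_ensemble(20, 1, R=200, seed=7)
        b = null_ensemble(20, 1, R=200, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_warns_on_few_replicates(self):
        with pytest.warns(UserWarning, match="resolution"):
            null_ensemble(20, 1, R=50, seed=1)

    def test_continuous_and_discrete_nulls_agree(self):
        """Uniform integer positions reduced modulo P differ from the
        continuous circle null only by O(P/L) discretization."""
        cont = null_ensemble(25, 1, R=800, seed=5)
        disc = null_ensemble_discrete(25, 1, period=10000, length=10**6, R=800, seed=6)
        assert ks_2samp(cont, disc).pvalue > 0.01

    def test_null_is_period_independent(self):
        """Ensembles generated at two nominal periods are exchangeable, so a
        single ensemble per (N, J) calibrates the whole grid."""
        a = null_ensemble_discrete(25, 1, period=3000, length=10**6, R=800, seed=8)
        b = null_ensemble_discrete(25, 1, period=17000, length=10**6, R=800, seed=9)
        assert ks_2samp(a, b).pvalue > 0.01


class TestComputePsos:
    def test_addone_extremes(self):
        null = np.arange(100, dtype=float)
        assert compute_psos([1000.0], null)[0] == pytest.approx(1 / 101)
        assert compute_psos([-5.0], null)[0] == pytest.approx(1.0)

    def test_median_null_score_near_half(self):
        null = null_ensemble(20, 1, R=999, seed=2)
        p = compute_psos([np.median(null)], null)[0]
        assert abs(p - 0.5) < 2 / np.sqrt(999)

    def test_mismatched_null_meta_rejected(self):
        with pytest.raises(ValueError, match="different N"):
            compute_psos([1.0], np.ones(100), n_sites=20, null_meta={"n_sites": 30, "J": 1})

    def test_pvalues_uniform_under_null(self):
        """Observed uniform-random scores fall at uniform quantiles of the
        ensemble (null self-consistency over 200 trials)."""
        null = null_ensemble(30, 1, R=2000, seed=20)
        obs = null_ensemble(30, 1, R=200, seed=21)
        assert kstest(compute_psos(obs, null), "uniform").pvalue > 0.01

    def test_noise_false_positive_rate(self):
        """Fraction of grid periods with p < 0.05 for pure noise: 0.05 +- 0.02
        averaged over 50 replicates."""
        rng = np.random.default_rng(30)
        grid = np.arange(2000, 12000, 200, dtype=float)
        null = null_ensemble(30, 1, R=1000, seed=31)
        fractions = []
        for _ in range(50):
            sites = SiteSequence(10**6, rng.choice(10**6, size=30, replace=False))
            p = compute_psos(compute_sos(sites, grid, J=1), null)
            fractions.append(np.mean(p < 0.05))
        assert abs(np.mean(fractions) - 0.05) < 0.02


class TestFamilyCorrection:
    @pytest.mark.parametrize(
        "p_star, n_peaks, expected",
        [(0.05, 1, 0.05), (0.0, 17, 0.0), (0.01, 10, 0.09561792499119552), (1.0, 3, 1.0)],
    )
    def test_direct_evaluation(self, p_star, n_peaks, expected):
        assert family_correction(p_star, n_peaks) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            family_correction(1.5, 2)
        with pytest.raises(ValueError):
            family_correction(0.1, 0)


class TestFindPeaks:
    def test_comb_harmonics_grouped_under_one_fundamental(
        self, comb_sites, benchmark_grid
    ):
        spec = solenoidal_spectrum(comb_sites, benchmark_grid, R=500, seed=40)
        peaks = find_peaks(spec)
        assert len(peaks) > 1
        assert len({pk.group_id for pk in peaks}) == 1
        assert peaks.fundamentals == [10000.0]
        # every retained peak is integer-ratio related to some family member
        # (families are connected components, so the relation is transitive)
        periods = [pk.period for pk in peaks]
        for a in periods:
            related = False
            for b in periods:
                if a == b:
                    continue
                hi, lo = max(a, b), min(a, b)
                related |= abs(hi / (round(hi / lo) * lo) - 1) <= 0.02
            assert related

    def test_flat_spectrum_mostly_empty(self):
        rng = np.random.default_rng(50)
        grid = np.arange(2000, 12000, 100, dtype=float)
        n_families = []
        for r in range(10):
            sites = SiteSequence(10**6, rng.choice(10**6, size=30, replace=False))
            spec = solenoidal_spectrum(sites, grid, R=1000, seed=500 + r)
            n_families.append(len(find_peaks(spec).fundamentals))
        assert sum(n == 0 for n in n_families) >= 7

    def test_two_comb_mixture_two_groups(self, two_train_mixture, benchmark_grid):
        mix, _ = two_train_mixture
        spec = solenoidal_spectrum(mix.sites, benchmark_grid, R=1000, seed=41)
        peaks = find_peaks(spec, sites=mix.sites)
        assert sorted(peaks.fundamentals) == [7270.0, 10000.0]

    def test_main_period_requires_a_peak(self):
        pvals = np.array([0.5, 0.4, 0.5])
        flat = SolenoidalSpectrum(
            periods=np.array([10.0, 20.0, 30.0]),
            scores=np.array([1.0, 1.1, 1.0]),
            n_sites=5,
            J=1,
            pvalues=pvals,
            neglog10p=-np.log10(pvals),
        )
        with pytest.raises(ValueError, match="no significant peak"):
            main_period(flat)


class TestSpectrumContainer:
    def test_neglog10p_matches_pvalues(self, comb_sites):
        spec = solenoidal_spectrum(comb_sites, np.arange(5000, 15000, 500.0), R=200, seed=1)
        np.testing.assert_allclose(spec.neglog10p, -np.log10(spec.pvalues))
        assert ((spec.pvalues > 0) & (spec.pvalues <= 1)).all()

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            SolenoidalSpectrum(
                periods=np.array([30.0, 20.0]),
                scores=np.array([1.0, 2.0]),
                n_sites=5,
                J=1,
            )
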