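"""Synthetic RIL generator and power-study machinery."""

import numpy as np
import pytest

from covqtl.growth import logistic
from covqtl.simulate import (
    PHI_BY_SCENARIO,
    ScenarioSpec,
    anova_statistics,
    simulate_dataset,
    simulate_genotypes,
    simulate_phenotypes,
)


class TestGenotypes:
    def test_allele_frequency_near_half(self):
        G = simulate_genotypes(2000, 50, rng=1)
        freq = G.mean(axis=0)
        # 3 binomial SD around 0.5 at n = 2000
        sd = np.sqrt(0.25 / 2000)
        assert np.all(np.abs(freq - 0.5) < 3 * sd + 0.02)

    def test_adjacent_marker_correlation(self):
        """Adjacent markers correlate at about 1 - 2c for recombination
        fraction c (pooled over marker pairs)."""
        G = simulate_genotypes(3000, 200, rng=2, recomb=0.05).astype(float)
        cors = [np.corrcoef(G[:, m], G[:, m + 1])[0, 1] for m in range(199)]
        assert np.mean(cors) == pytest.approx(0.9, abs=0.01)

    def test_single_marker(self):
        G = simulate_genotypes(10, 1, rng=3)
        assert G.shape == (10, 1)

    def test_deterministic_under_seed(self):
        a = simulate_genotypes(50, 20, rng=7)
        b = simulate_genotypes(50, 20, rng=7)
        assert np.array_equal(a, b)


class TestScenarioSpec:
    def test_phi_by_scenario(self):
        assert [PHI_BY_SCENARIO[k] for k in (1, 2, 3, 4)] == [0.65, 0.4, 0.2, 0.0]

    def test_sigma2_y_solves_heritability(self):
        for h2 in (0.05, 0.10):
            spec = ScenarioSpec.for_scenario(1, 100, h2)
            sg2 = spec.mean_curve_variance()
            s2 = spec.sigma2_y()
            assert sg2 / (sg2 + s2) == pytest.approx(h2, rel=1e-9)

    def test_static_split_matches_heritability_and_opposes_curve(self):
        spec = ScenarioSpec.for_scenario(2, 100, 0.10)
        mz1, mz2 = spec.mu_z()
        d = (mz2 - mz1) / 2
        assert d > 0  # taller curve (genotype 1) gets the smaller dry weight
        assert d**2 / (d**2 + spec.sigma2_z) == pytest.approx(0.10, rel=1e-9)

    def test_h2_zero_removes_all_genetic_effects(self):
        spec = ScenarioSpec.for_scenario(1, 100, 0.0)
        c1, c2 = spec.genotype_curves()
        assert c1 == c2
        assert spec.mu_z()[0] == spec.mu_z()[1]


@pytest.fixture(scope="module")
def big():
    spec = ScenarioSpec.for_scenario(1, 5000, 0.10, n_markers=3, causal_index=1)
    G, data = simulate_dataset(spec, 77)
    return spec, G, data


class TestPhenotypeGenerator:
    def _residuals(self, spec, G, data):
        c1, c2 = spec.genotype_curves()
        mz = spec.mu_z()
        g = G[:, spec.causal]
        mu_y = np.vstack(
            [logistic(data.grid.times, c1), logistic(data.grid.times, c2)]
        )
        ey = data.y - mu_y[g]
        ez = data.z - np.asarray(mz)[g]
        return ey, ez

    def test_lag1_residual_covariance(self, big):
        """Pooled lag-1 residual covariance matches sigma2_y * rho_y within
        2% (all adjacent time pairs pooled, n = 5000)."""
        spec, G, data = big
        ey, _ = self._residuals(spec, G, data)
        lag1 = float(np.mean(ey[:, 1:] * ey[:, :-1]))
        assert lag1 == pytest.approx(spec.sigma2_y() * spec.rho_y, rel=0.02)

    def test_cross_correlation_matches_phi(self, big):
        spec, G, data = big
        ey, ez = self._residuals(spec, G, data)
        r = np.corrcoef(ey[:, -1], ez)[0, 1]
        assert r == pytest.approx(0.65, abs=0.03)

    def test_scenario_four_uncorrelated(self):
        spec = ScenarioSpec.for_scenario(4, 5000, 0.10, n_markers=3, causal_index=1)
        G, data = simulate_dataset(spec, 78)
        ey, ez = self._residuals(spec, G, data)
        assert np.corrcoef(ey[:, -1], ez)[0, 1] == pytest.approx(0.0, abs=0.03)

    def test_datasets_identical_under_same_seed(self):
        spec = ScenarioSpec.for_scenario(2, 40, 0.05, n_markers=10)
        G1, d1 = simulate_dataset(spec, 5)
        G2, d2 = simulate_dataset(spec, 5)
        assert np.array_equal(G1, G2)
        assert np.array_equal(d1.y, d2.y) and np.array_equal(d1.z, d2.z)

    def test_generator_round_trip_recovers_covariance(self):
        """Fitting the generating model at the causal marker of a large
        dataset recovers the covariance parameters within 5% relative
        error (correlations within 0.05 absolute)."""
        from covqtl.data import MarkerPartition
        from covqtl.likelihood import fit_marker

        spec = ScenarioSpec.for_scenario(1, 2000, 0.10, n_markers=3, causal_index=1)
        G, data = simulate_dataset(spec, 123)
        part = MarkerPartition.from_genotypes(G[:, 1])
        fit = fit_marker(data, part)
        assert fit.cov.sigma2_y == pytest.approx(spec.sigma2_y(), rel=0.05)
        assert fit.cov.sigma2_z == pytest.approx(spec.sigma2_z, rel=0.08)
        assert fit.cov.rho_y == pytest.approx(spec.rho_y, abs=0.05)
        assert fit.cov.phi == pytest.approx(spec.phi, abs=0.05)


class TestAnova:
    def test_matches_scipy_f_oneway(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(4)
        z = rng.normal(size=80)
        g = rng.integers(0, 2, 80)
        F = anova_statistics(z, g)
        ref = f_oneway(z[g == 0], z[g == 1]).statistic
        assert F[0] == pytest.approx(ref, rel=1e-10)

    def test_monomorphic_marker_zero(self):
        z = np.random.default_rng(1).normal(size=20)
        assert anova_statistics(z, np.zeros(20, dtype=int))[0] == 0.0


class TestPowerMonotonicity:
    def test_detections_increase_with_heritability(self):
        """At fixed thresholds, the causal-marker joint LR distribution is
        stochastically larger under higher curve heritability."""
        from covqtl.data import MarkerPartition
        from covqtl.likelihood import fit_marker, fit_null
        from covqtl.scan import _lr

        lrs = {}
        for h2 in (0.05, 0.10):
            spec = ScenarioSpec.for_scenario(1, 100, h2, n_markers=5, causal_index=2)
            vals = []
            for s in range(25):
                G, data = simulate_dataset(spec, 9000 + s)
                part = MarkerPartition.from_genotypes(G[:, 2])
                full = fit_marker(data, part)
                vals.append(_lr(full, fit_null(data)))
            lrs[h2] = np.median(vals)
        assert lrs[0.10] > lrs[0.05]
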