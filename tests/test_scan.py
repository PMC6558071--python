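"""Genome scan: LR tests, thresholds, classification, trajectories."""

import numpy as np
import pytest

from covqtl.data import LongitudinalDataset, MarkerPartition
from covqtl.growth import LogisticParams, TimeGrid, logistic
from covqtl.likelihood import fit_marker, fit_null
from covqtl.scan import (
    PERM_OPTIM,
    batch_scan_max_lr,
    classify_qtl,
    effect_and_heritability,
    lr_overall,
    permutation_threshold,
    scan_markers,
    subtest_thresholds_chisq,
)
from covqtl.scan import test_biomass as biomass_lr
from covqtl.scan import test_growth as growth_lr
from conftest import make_dataset

WEEKS = TimeGrid(np.arange(1.0, 10.0))


class TestOverallLR:
    def test_single_class_gives_zero(self):
        data, g, _ = make_dataset(n=30, seed=1)
        null = fit_null(data)
        same = fit_marker(data, None, model="null")
        assert 2 * (same.log_lik - null.log_lik) == pytest.approx(0.0, abs=1e-4)

    def test_strong_effect_detected(self):
        data, g, part = make_dataset(n=120, seed=6)
        lr, full = lr_overall(data, part)
        assert lr is not None and lr > 30  # far above any 5% threshold here

    def test_sub_lrs_bounded_by_overall(self):
        """Both constrained models nest between the null and the full
        model, so each sub-test LR is at most the overall LR."""
        data, g, part = make_dataset(n=80, seed=10)
        lr, full = lr_overall(data, part)
        lg = growth_lr(data, part, full)
        lb = biomass_lr(data, part, full)
        assert lg <= lr + 1e-4
        assert lb <= lr + 1e-4
        assert lg >= -1e-6 and lb >= -1e-6

    def test_selectivity_static_only_effect(self):
        """Identical curves but different static means: the static sub-test
        carries the signal, the curve sub-test stays small."""
        p = LogisticParams(50, 12, 0.65)
        data, g, part = make_dataset(
            n=200, curves=(p, p), mu_z=(4.4, 5.7), cov=(6.0, 0.6, 0.3, 1.0), seed=5
        )
        lr, full = lr_overall(data, part)
        lg = growth_lr(data, part, full)
        lb = biomass_lr(data, part, full)
        tg, tb = subtest_thresholds_chisq(2)
        assert lb > tb
        assert lg < lb

    def test_selectivity_curve_only_effect(self):
        data, g, part = make_dataset(
            n=200,
            curves=(LogisticParams(55, 12, 0.7), LogisticParams(45, 12, 0.6)),
            mu_z=(5.0, 5.0),
            seed=5,
        )
        lr, full = lr_overall(data, part)
        lg = growth_lr(data, part, full)
        lb = biomass_lr(data, part, full)
        tg, tb = subtest_thresholds_chisq(2)
        assert lg > tg
        assert lb < lg


class TestClassification:
    """The classification contract on the three worked cases: a marker
    whose curve sub-test alone rejects is a growth QTL; both rejecting
    means pleiotropy; a significant marker where neither marginal test
    rejects is a covariation QTL."""

    TG, TB = subtest_thresholds_chisq(2)

    def test_growth_only(self):
        assert classify_qtl(True, self.TG + 5, self.TB - 1, self.TG, self.TB) == "growth"

    def test_biomass_only(self):
        assert classify_qtl(True, self.TG - 1, self.TB + 5, self.TG, self.TB) == "biomass"

    def test_both_reject_pleiotropic(self):
        assert (
            classify_qtl(True, self.TG + 5, self.TB + 5, self.TG, self.TB)
            == "pleiotropic"
        )

    def test_neither_rejects_covariation(self):
        assert (
            classify_qtl(True, self.TG - 1, self.TB - 1, self.TG, self.TB)
            == "covariation"
        )

    def test_not_significant_is_none(self):
        assert classify_qtl(False, 100.0, 100.0, self.TG, self.TB) == "none"

    def test_missing_subtest_unclassified(self):
        assert classify_qtl(True, None, 1.0, self.TG, self.TB) == "unclassified"

    def test_pure_function(self):
        args = (True, 10.0, 2.0, self.TG, self.TB)
        assert classify_qtl(*args) == classify_qtl(*args)


class TestPermutationThreshold:
    def test_identical_phenotypes_give_zero_threshold(self):
        n, T = 30, 5
        grid = TimeGrid(np.arange(1.0, T + 1.0))
        y = np.tile(np.linspace(2, 10, T), (n, 1))
        data = LongitudinalDataset(y=y, z=np.full(n, 5.0), grid=grid)
        g = np.repeat([0, 1], n // 2)
        thr = permutation_threshold(data, g, n_perm=20, alpha=0.5, seed=1, engine="scipy")
        assert thr == pytest.approx(0.0, abs=1e-3)

    def test_median_at_alpha_half(self):
        data, g, _ = make_dataset(n=30, seed=2)
        thr, maxima = permutation_threshold(
            data, g, n_perm=20, alpha=0.5, seed=3, return_maxima=True
        )
        assert thr == pytest.approx(np.median(maxima))

    def test_too_few_permutations_rejected(self):
        data, g, _ = make_dataset(n=20, seed=2)
        with pytest.raises(ValueError):
            permutation_threshold(data, g, n_perm=10, alpha=0.05)

    def test_engines_agree(self):
        """The lockstep engine and the per-marker scipy path give matching
        permutation maxima distributions (same permutations, same fits)."""
        data, g, _ = make_dataset(n=40, seed=12)
        G = np.column_stack([g, np.roll(g, 7)])
        t1, m1 = permutation_threshold(
            data, G, n_perm=24, alpha=0.25, seed=9, engine="batch", return_maxima=True
        )
        t2, m2 = permutation_threshold(
            data, G, n_perm=24, alpha=0.25, seed=9, engine="scipy",
            return_maxima=True, optim=PERM_OPTIM,
        )
        assert m1 == pytest.approx(m2, abs=0.05)
        assert t1 == pytest.approx(t2, abs=0.05)


class TestSubtestPermutationMode:
    def test_marker_local_quantiles_positive_and_ordered(self):
        """Permutation critical values for the curve sub-test (3 df worth
        of constraint) exceed those of the one-parameter static sub-test,
        and both are positive."""
        from covqtl.scan import subtest_thresholds_permutation

        data, g, part = make_dataset(n=40, seed=31)
        tg, tb = subtest_thresholds_permutation(
            data, part, n_perm=20, alpha=0.25, seed=2
        )
        assert tg > 0 and tb > 0
        assert tg > tb

    def test_rejects_too_few_permutations(self):
        from covqtl.scan import subtest_thresholds_permutation

        data, g, part = make_dataset(n=30, seed=32)
        with pytest.raises(ValueError):
            subtest_thresholds_permutation(data, part, n_perm=5, alpha=0.05)


class TestScan:
    def test_order_invariance_and_skips(self):
        data, g, _ = make_dataset(n=40, seed=20)
        rare = np.zeros_like(g)
        rare[:3] = 1  # class below min_class_size -> skipped
        G = np.column_stack([g, rare])
        res = scan_markers(data, G, ["a", "b"], subtests=False)
        assert res[1].skipped
        res_rev = scan_markers(data, G[:, ::-1], ["b", "a"], subtests=False)
        assert res[0].lr_overall == pytest.approx(res_rev[1].lr_overall, abs=1e-6)

    def test_batch_scan_matches_scipy_scan(self):
        data, g, _ = make_dataset(n=60, seed=21)
        G = np.column_stack([g, np.roll(g, 11), np.roll(g, 29)])
        res = scan_markers(data, G, subtests=False)
        mx = max(r.lr_overall for r in res)
        assert batch_scan_max_lr(data, G) == pytest.approx(mx, abs=0.05)

    def test_missing_genotypes_handled(self):
        data, g, _ = make_dataset(n=40, seed=22)
        gm = g.astype(int).copy()
        gm[:4] = -1  # missing calls: those individuals drop from this marker
        res = scan_markers(data, gm, subtests=False)
        assert not res[0].skipped
        assert np.isfinite(res[0].lr_overall)


class TestEffectTrajectories:
    def test_identical_curves_zero_effect(self):
        p = LogisticParams(50, 10, 0.6)
        data, g, part = make_dataset(n=60, curves=(p, p), mu_z=(5.0, 5.0), seed=3)
        fit = fit_marker(data, part)
        traj = effect_and_heritability(fit, WEEKS, part.class_counts / part.n)
        assert np.abs(traj.effect).max() < 1.0
        assert traj.heritability.max() < 0.05

    def test_closed_form_balanced_case(self):
        """With equal frequencies and a constant curve gap 2*delta the
        genetic variance is delta^2 and H^2 = delta^2/(delta^2+sigma2_y)."""
        from covqtl.likelihood import JointModelFit
        from covqtl.covariance import CovParams

        # construct a fit object directly: two flat "curves" via huge r
        p1 = LogisticParams(12.0, 1e-9, 5.0)  # ~ constant 12
        p2 = LogisticParams(8.0, 1e-9, 5.0)  # ~ constant 8
        fit = JointModelFit(
            per_genotype=[(p1, 6.0), (p2, 4.0)],
            cov=CovParams(4.0, 0.5, 0.2, 1.0),
            sigma2_y=4.0,
            rho_y=0.5,
            log_lik=0.0,
            n_params=12,
            converged=True,
            model="full",
            include_static=True,
        )
        traj = effect_and_heritability(fit, WEEKS, np.array([0.5, 0.5]))
        assert traj.effect == pytest.approx(np.full(9, 2.0), rel=1e-6)
        assert traj.heritability == pytest.approx(np.full(9, 4.0 / 8.0), rel=1e-6)
        assert traj.effect_z == pytest.approx(1.0)
        assert traj.heritability_z == pytest.approx(1.0 / 2.0)

    def test_heritability_in_unit_interval_and_growing_effect(self):
        """A curve gap that widens over time yields a non-decreasing
        heritability trajectory (monotone within fit noise)."""
        data, g, part = make_dataset(
            n=300,
            curves=(LogisticParams(60, 12, 0.75), LogisticParams(42, 12, 0.55)),
            seed=30,
        )
        fit = fit_marker(data, part)
        traj = effect_and_heritability(fit, WEEKS, part.class_counts / part.n)
        assert ((traj.heritability >= 0) & (traj.heritability <= 1)).all()
        assert traj.heritability[-1] > traj.heritability[0]
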