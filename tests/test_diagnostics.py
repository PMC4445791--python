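import numpy as np
import pandas as pd
import pytest

from mlirt.diagnostics import (DiagnosticsReport, bifactor_check,
                               local_dependence, monotonicity_check,
                               polychoric_matrix, robustness_check,
                               run_diagnostics, select_items)
from mlirt.factor import (_biquartimin_criterion, minres_factor,
                          polychoric_corr, rotate_bifactor)

from conftest import make_rm


def discretize_factor_data(loadings, n, seed, cuts=(-0.6, 0.7)):
    """Ordinal data from a linear factor model with given loading matrix."""
    rng = np.random.default_rng(seed)
    lam = np.asarray(loadings, dtype=float)
    K, m = lam.shape
    f = rng.standard_normal((n, m))
    uniq = np.sqrt(np.clip(1 - (lam**2).sum(axis=1), 0.05, 1))
    lat = f @ lam.T + uniq * rng.standard_normal((n, K))
    return np.digitize(lat, cuts)


class TestPolychoric:
    def test_diagonal_is_one(self, small_dataset):
        R = polychoric_matrix(small_dataset.rm_bio)
        np.testing.assert_allclose(np.diag(R.to_numpy()), 1.0)
        np.testing.assert_allclose(R.to_numpy(), R.to_numpy().T, atol=1e-12)

    def test_recovers_generating_correlation(self):
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal([0, 0], [[1, .5], [.5, 1]], size=2000)
        x = np.digitize(z[:, 0], [-0.5, 0.8])
        y = np.digitize(z[:, 1], [-0.5, 0.8])
        assert polychoric_corr(x, y) == pytest.approx(0.5, abs=0.05)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, 5000)
        y = rng.integers(0, 3, 5000)
        assert abs(polychoric_corr(x, y)) < 0.05

    def test_low_bias_at_large_n(self):
        rng = np.random.default_rng(3)
        z = rng.multivariate_normal([0, 0], [[1, .6], [.6, 1]], size=20_000)
        x = np.digitize(z[:, 0], [-0.3, 1.0])
        y = np.digitize(z[:, 1], [0.0, 0.9])
        assert abs(polychoric_corr(x, y) - 0.6) < 0.02

    def test_single_category_item_excluded(self):
        vals = np.column_stack([np.zeros(200, int),
                                np.tile([0, 1, 2, 1], 50),
                                np.tile([0, 2, 1, 0], 50)])
        rm = make_rm(vals)
        with pytest.warns(UserWarning, match="single observed category"):
            R = polychoric_matrix(rm)
        assert list(R.index) == ["i1", "i2"]


class TestBifactor:
    def test_one_factor_data_judged_unidimensional(self):
        lam = np.linspace(0.6, 0.8, 12)[:, None]
        vals = discretize_factor_data(lam, 4000, seed=4)
        domains = ["mob"] * 4 + ["care"] * 4 + ["comm"] * 4
        rm = make_rm(vals, domains=domains)
        R = polychoric_matrix(rm)
        load, flags = bifactor_check(R, dict(zip(R.index, domains)))
        assert not any(flags.values())
        assert (load["general"] > 0.5).all()

    def test_strong_domain_factor_flagged(self):
        # mobility items: general 0.35, group 0.75; others general only
        lam = np.zeros((12, 2))
        lam[:, 0] = 0.65
        lam[:4, 0] = 0.35
        lam[:4, 1] = 0.75
        vals = discretize_factor_data(lam, 4000, seed=5)
        domains = ["mob"] * 4 + ["care"] * 4 + ["comm"] * 4
        rm = make_rm(vals, domains=domains)
        R = polychoric_matrix(rm)
        load, flags = bifactor_check(R, dict(zip(R.index, domains)))
        assert flags["mob"]
        assert not flags["care"] and not flags["comm"]

    def test_rotation_fixed_point(self):
        """Rotating an already bifactor-patterned matrix does not change the
        criterion value."""
        lam = np.zeros((9, 3))
        lam[:, 0] = 0.6
        lam[:3, 1] = 0.5
        lam[3:6, 2] = 0.5
        rotated = rotate_bifactor(lam)
        f0, _ = _biquartimin_criterion(lam)
        f1, _ = _biquartimin_criterion(rotated)
        assert f1 == pytest.approx(f0, abs=1e-6)


class TestLocalDependence:
    def _R(self, lam2=None, n=5000, seed=6):
        lam = np.full((8, 1), 0.65)
        if lam2 is not None:
            lam = np.hstack([lam, lam2])
        vals = discretize_factor_data(lam, n, seed=seed)
        return polychoric_matrix(make_rm(vals))

    def test_one_factor_data_has_no_flags(self):
        _, flagged, subsets = local_dependence(self._R())
        assert flagged == [] and subsets == []

    def test_doublet_pair_flagged(self):
        lam2 = np.zeros((8, 1))
        lam2[[0, 1], 0] = 0.7   # extra shared factor for items 0 and 1
        _, flagged, subsets = local_dependence(self._R(lam2))
        assert ("i0", "i1") in flagged
        assert ["i0", "i1"] in subsets

    def test_threshold_one_never_flags(self):
        lam2 = np.zeros((8, 1))
        lam2[[0, 1], 0] = 0.7
        _, flagged, _ = local_dependence(self._R(lam2), threshold=1.0)
        assert flagged == []

    def test_flags_invariant_to_item_order(self):
        lam2 = np.zeros((8, 1))
        lam2[[0, 1], 0] = 0.7
        R = self._R(lam2)
        perm = list(R.index[::-1])
        Rp = R.loc[perm, perm]
        _, f1, _ = local_dependence(R)
        _, f2, _ = local_dependence(Rp)
        assert {frozenset(p) for p in f1} == {frozenset(p) for p in f2}

    def test_too_few_items_rejected(self):
        R = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            local_dependence(R)


class TestMonotonicity:
    def _grm_values(self, n=5000, seed=7, K=6):
        rng = np.random.default_rng(seed)
        theta = rng.standard_normal(n)
        lam = rng.uniform(0.5, 0.8, K)
        lat = lam * theta[:, None] + \
            np.sqrt(1 - lam**2) * rng.standard_normal((n, K))
        return np.digitize(lat, [-0.6, 0.7])

    def test_monotone_items_pass(self):
        rm = make_rm(self._grm_values())
        verdicts = monotonicity_check(rm)
        assert all(v.passed for v in verdicts.values())

    def test_reversed_item_fails(self):
        vals = self._grm_values()
        vals[:, 2] = 2 - vals[:, 2]
        verdicts = monotonicity_check(make_rm(vals))
        assert verdicts["i2"].passed is False
        assert sum(v.passed for v in verdicts.values() if v.passed) == 5

    def test_constant_item_passes(self):
        vals = self._grm_values(n=1000)
        vals[:, 0] = 1
        verdicts = monotonicity_check(make_rm(vals), min_bin_size=50)
        assert verdicts["i0"].passed is True

    def test_too_few_persons_indeterminate(self):
        rm = make_rm([[0, 1], [1, 2], [2, 0]])
        verdicts = monotonicity_check(rm, min_bin_size=50)
        assert all(v.verdict == "indeterminate" for v in verdicts.values())

    def test_invariant_to_person_permutation(self):
        vals = self._grm_values(n=2000)
        rm1 = make_rm(vals)
        rng = np.random.default_rng(8)
        rm2 = make_rm(vals[rng.permutation(2000)])
        v1 = monotonicity_check(rm1)
        v2 = monotonicity_check(rm2)
        for k in v1:
            assert v1[k].passed == v2[k].passed
            np.testing.assert_allclose(v1[k].item_means, v2[k].item_means)


class TestSelectionAndRobustness:
    def _report(self, ld_subsets=(), mono_fail=()):
        items = [f"i{k}" for k in range(5)]
        rep = DiagnosticsReport(item_ids=items,
                                polychoric=pd.DataFrame(np.eye(5),
                                                        index=items,
                                                        columns=items))
        rep.ld_subsets = [list(s) for s in ld_subsets]
        from mlirt.diagnostics import MonotonicityVerdict
        rep.monotonicity = {
            k: MonotonicityVerdict(k, k not in mono_fail, np.array([]),
                                   np.array([]), 0.0)
            for k in items}
        return rep

    def test_no_flags_retains_everything(self):
        rep = self._report()
        disc = pd.Series(1.0, index=rep.item_ids)
        assert select_items(rep, disc) == rep.item_ids

    def test_subset_keeps_most_discriminating(self):
        rep = self._report(ld_subsets=[["i1", "i2", "i3"]])
        disc = pd.Series([1.0, 1.2, 2.4, 0.9, 1.0], index=rep.item_ids)
        retained = select_items(rep, disc)
        assert "i2" in retained
        assert "i1" not in retained and "i3" not in retained

    def test_monotonicity_failure_never_retained(self):
        rep = self._report(ld_subsets=[["i1", "i2"]], mono_fail=("i0", "i2"))
        disc = pd.Series([1.0, 1.0, 9.0, 1.0, 1.0], index=rep.item_ids)
        retained = select_items(rep, disc)
        assert "i0" not in retained and "i2" not in retained
        assert "i1" in retained   # best remaining in its subset

    def test_robustness_identical(self):
        s = pd.Series(np.linspace(-2, 2, 100))
        r = robustness_check(s, s.copy())
        assert r.robust and r.correlation == pytest.approx(1.0)
        assert r.mean_abs_diff == 0.0

    def test_robustness_small_noise(self):
        rng = np.random.default_rng(9)
        s = pd.Series(rng.standard_normal(1000))
        r = robustness_check(s, s + rng.normal(0, 0.01, 1000))
        assert r.robust

    def test_robustness_anticorrelated(self):
        s = pd.Series(np.linspace(-2, 2, 100))
        r = robustness_check(s, -s)
        assert not r.robust

    def test_person_mismatch_rejected(self):
        a = pd.Series([1.0, 2.0], index=["p1", "p2"])
        b = pd.Series([1.0, 2.0], index=["p1", "p3"])
        with pytest.raises(ValueError):
            robustness_check(a, b)


def test_run_diagnostics_end_to_end(small_dataset):
    report = run_diagnostics(small_dataset.rm_bio, min_bin_size=30)
    assert report.polychoric.shape[0] == 15
    assert set(report.monotonicity) == set(report.item_ids)
    d = report.to_dict()
    assert "local_dependence_subsets" in d and "monotonicity" in d
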