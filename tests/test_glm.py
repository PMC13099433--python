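import numpy as np
import pytest
from scipy import stats

import efpcouple as ec
from efpcouple.datasets import BOLDDataset
from efpcouple.efp import EFPTimecourse
from efpcouple.glm import (
    GLMConfig,
    align_efp_to_volumes,
    fdr_bh,
    first_level_glm,
    group_one_sample,
    group_paired_contrast,
    prepare_voxel_signals,
)
from efpcouple.synthetic import _lattice_coords


def _dataset(data, tr=1.5):
    data = np.atleast_2d(data)
    return BOLDDataset(data=data, tr=tr, voxel_coords=_lattice_coords(data.shape[0]))


def _efp(values, tr=1.5):
    """EFP covering the whole volume grid (no warm-up) for unit tests."""
    return EFPTimecourse(np.asarray(values, dtype=float), dt=tr, t0=0.0)


def ols_oracle(y, x):
    """Closed-form normal equations for y ~ [x, 1], plus t for the slope."""
    n = len(y)
    X = np.column_stack([x, np.ones(n)])
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ coef
    dof = n - 2
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return coef[0], coef[0] / np.sqrt(cov[0, 0])


class TestPrepare:
    def test_linear_ramp_removed(self):
        ramp = 3.0 + 0.5 * np.arange(100)
        out = prepare_voxel_signals(_dataset(ramp), GLMConfig(highpass_hz=0.0))
        assert np.max(np.abs(out.data)) < 1e-9

    def test_output_is_demeaned(self, rng):
        out = prepare_voxel_signals(_dataset(rng.standard_normal((5, 80))))
        assert np.max(np.abs(out.data.mean(axis=1))) < 1e-9

    def test_highpass_attenuates_slow_drift_more_than_signal(self):
        n, tr = 400, 1.5
        t = np.arange(n) * tr
        slow = np.sin(2 * np.pi * 0.0005 * t)
        fast = np.sin(2 * np.pi * 0.05 * t)
        out = prepare_voxel_signals(_dataset(np.vstack([slow, fast])))
        ratio = out.data[0].var() / out.data[1].var()
        assert ratio < 0.25

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError):
            prepare_voxel_signals(_dataset(np.ones((2, 3))))


class TestFirstLevel:
    def test_noise_free_slope_recovered_exactly(self, rng):
        x = rng.standard_normal(100)
        bold = _dataset(2.0 * x + 5.0)
        cfg = GLMConfig(highpass_hz=0.0, detrend=False, standardize_regressor=False)
        em = first_level_glm(bold, _efp(x), cfg)
        assert em.beta[0] == pytest.approx(2.0, abs=1e-9)

    def test_orthogonal_voxel_has_zero_beta(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        xc = x - x.mean()
        y = y - y.mean() - (y - y.mean()) @ xc / (xc @ xc) * xc  # residualized
        cfg = GLMConfig(highpass_hz=0.0, detrend=False, standardize_regressor=False)
        em = first_level_glm(_dataset(y), _efp(x), cfg)
        assert abs(em.beta[0]) < 1e-9

    def test_matches_closed_form_ols_oracle(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal((8, 50))
        cfg = GLMConfig(highpass_hz=0.0, detrend=False, demean=False,
                        standardize_regressor=False)
        em = first_level_glm(_dataset(y), _efp(x), cfg)
        for v in range(8):
            beta_ref, t_ref = ols_oracle(y[v], x)
            assert em.beta[v] == pytest.approx(beta_ref, abs=1e-10)
            assert em.tstat[v] == pytest.approx(t_ref, abs=1e-10)
        assert em.dof == 48

    def test_zero_variance_regressor_rejected(self):
        with pytest.raises(ValueError):
            first_level_glm(_dataset(np.random.default_rng(0).standard_normal(50)),
                            _efp(np.ones(50)))

    def test_warmup_volumes_dropped_by_alignment(self):
        bold = _dataset(np.random.default_rng(0).standard_normal((2, 40)))
        efp = EFPTimecourse(np.arange(32.0), dt=1.5, t0=12.0)
        vol_idx, vals = align_efp_to_volumes(efp, bold)
        assert vol_idx[0] == 8  # volume at t = 12 s pairs with the first value
        assert len(vol_idx) == 32
        assert np.array_equal(vals, np.arange(32.0))


class TestGroup:
    def _maps(self, betas):
        return [
            ec.EffectMap(beta=b, tstat=np.zeros_like(b), dof=50, subject_id=f"s{i}")
            for i, b in enumerate(betas)
        ]

    def test_sign_symmetric_betas_give_t0_p1(self, rng):
        b = rng.standard_normal((5, 20))
        maps = self._maps(np.vstack([b, -b]))
        res = group_one_sample(maps)
        assert np.allclose(res.t, 0.0)
        assert np.allclose(res.p, 1.0)

    def test_matches_independent_t_statistic_oracle(self, rng):
        betas = 0.5 + 0.1 * rng.standard_normal((20, 30))
        res = group_one_sample(self._maps(betas))
        for v in range(30):
            col = betas[:, v]
            t_ref = col.mean() / (col.std(ddof=1) / np.sqrt(len(col)))
            p_ref = 2 * stats.t.sf(abs(t_ref), df=19)
            assert res.t[v] == pytest.approx(t_ref, abs=1e-10)
            assert res.p[v] == pytest.approx(p_ref, abs=1e-10)

    def test_degenerate_zero_variance_voxel_flagged_never_significant(self):
        maps = self._maps(np.ones((3, 4)))
        res = group_one_sample(maps)
        assert res.degenerate.all()
        assert np.allclose(res.p, 1.0)
        assert not res.sig_mask.any()

    def test_paired_contrast_of_identical_maps_is_null(self, rng):
        maps = self._maps(rng.standard_normal((6, 10)))
        res = group_paired_contrast(maps, maps)
        assert np.allclose(res.t, 0.0)

    def test_paired_contrast_matches_formula_oracle(self, rng):
        a = rng.standard_normal((10, 15))
        b = a - (0.2 + 0.01 * rng.standard_normal((10, 15)))
        res = group_paired_contrast(self._maps(a), self._maps(b))
        d = a - b
        for v in range(15):
            t_ref = d[:, v].mean() / (d[:, v].std(ddof=1) / np.sqrt(10))
            assert res.t[v] == pytest.approx(t_ref, abs=1e-10)

    def test_paired_contrast_is_antisymmetric(self, rng):
        a = self._maps(rng.standard_normal((8, 12)))
        b = self._maps(rng.standard_normal((8, 12)))
        assert np.array_equal(group_paired_contrast(a, b).t,
                              -group_paired_contrast(b, a).t)

    def test_subject_order_mismatch_rejected(self, rng):
        a = self._maps(rng.standard_normal((4, 5)))
        b = list(reversed(self._maps(rng.standard_normal((4, 5)))))
        with pytest.raises(ValueError):
            group_paired_contrast(a, b)


def bh_oracle(p, q):
    """Brute-force step-up: largest k with p_(k) <= k q / m rejects p_(1..k)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestFDR:
    def test_single_marginal_p_not_rejected(self):
        rej, _ = fdr_bh([0.06], 0.05)
        assert not rej.any()

    def test_step_up_rescues_ordered_block(self):
        rej, _ = fdr_bh([0.01, 0.02, 0.03, 0.04], 0.05)
        assert rej.all()  # largest k with p_(k) <= k*0.05/4 is k = 4

    def test_all_zero_p_all_rejected(self):
        rej, _ = fdr_bh(np.zeros(10), 0.05)
        assert rej.all()

    def test_matches_brute_force_step_up_oracle(self, rng):
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            p[rng.uniform(size=len(p)) < 0.3] /= 50  # sprinkle signal
            rej, _ = fdr_bh(p, 0.05)
            assert np.array_equal(rej, bh_oracle(p, 0.05))

    def test_subset_restriction_corrects_within_subset_only(self, rng):
        p = rng.uniform(size=30)
        subset = np.arange(5, 15)
        rej, q = fdr_bh(p, 0.05, subset=subset)
        assert not rej[:5].any() and not rej[15:].any()
        assert np.isnan(q[:5]).all()
        assert np.array_equal(rej[subset], bh_oracle(p[subset], 0.05))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestNullCalibration:
    def test_group_type_one_error_and_fdp_under_null(self):
        """Null cohorts: uncorrected group p < .05 rate ~5%, FDR controls FDP."""
        rng = np.random.default_rng(0)
        n_seeds, n_subj, n_vox, n_vol = 200, 20, 500, 120
        rates, fdps = [], []
        for s in range(n_seeds):
            betas = np.empty((n_subj, n_vox))
            for i in range(n_subj):
                y = rng.standard_normal((n_vox, n_vol))
                x = rng.standard_normal(n_vol)
                em = first_level_glm(
                    _dataset(y), _efp(x), GLMConfig(highpass_hz=0.0, detrend=False)
                )
                betas[i] = em.beta
            res = group_one_sample(
                [ec.EffectMap(beta=b, tstat=b, dof=n_vol - 2, subject_id=f"s{i}")
                 for i, b in enumerate(betas)]
            )
            rates.append(np.mean(res.p < 0.05))
            n_rej = res.sig_mask.sum()
            fdps.append(1.0 if n_rej else 0.0)  # every rejection is false here
        assert 0.035 <= np.mean(rates) <= 0.065
        assert np.mean(fdps) <= 0.1
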