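"""Metric suite: RMSE, percent errors, DTI fit, peaks, post-hoc adversary."""

import numpy as np
import pytest

from dmriharm.evaluation import (
    ablation_delta,
    angular_deflection,
    ape,
    cv,
    dti_fit,
    pe,
    posthoc_adversary,
    rmse_map,
    sh_peaks,
)
from dmriharm.pipeline import DWIVolume
from dmriharm.sh import fit_sh
from dmriharm.sphere import symmetrized_sphere
from dmriharm.synthetic import (
    SiteProfile,
    WM_EIGENVALUES,
    generate_site_volume,
    make_crossing_phantom,
    make_scheme,
)


@pytest.fixture(scope="module")
def vol_pair(two_site_profiles):
    ph = make_crossing_phantom((6, 6, 6), seed=8)
    prof = SiteProfile("X", two_site_profiles[0].scheme, snr=np.inf)
    truth = generate_site_volume(ph, prof, seed=0, noise_free=True)
    pred = DWIVolume(data=truth.data + 0.05, scheme=truth.scheme,
                     mask=truth.mask, affine=truth.affine)
    return pred, truth


class TestRMSE:
    def test_identical_zero(self, vol_pair):
        _, truth = vol_pair
        assert not rmse_map(truth, truth).any()

    def test_constant_offset(self, vol_pair):
        pred, truth = vol_pair
        r = rmse_map(pred, truth)
        assert np.allclose(r[truth.mask], 0.05)
        assert np.all(r[~truth.mask] == 0)

    def test_matches_elementwise_oracle(self, vol_pair, rng):
        _, truth = vol_pair
        noisy = DWIVolume(data=truth.data + rng.normal(0, 0.1, truth.data.shape),
                          scheme=truth.scheme, mask=truth.mask)
        r = rmse_map(noisy, truth)
        v = tuple(np.argwhere(truth.mask)[4])
        expected = np.sqrt(np.mean((noisy.data[v] - truth.data[v]) ** 2))
        assert r[v] == pytest.approx(expected)

    def test_scheme_mismatch_rejected(self, vol_pair, two_site_profiles):
        pred, truth = vol_pair
        other = DWIVolume(
            data=np.ones(truth.spatial_shape + (len(two_site_profiles[1].scheme),)),
            scheme=two_site_profiles[1].scheme, mask=truth.mask)
        with pytest.raises(ValueError):
            rmse_map(other, truth)


class TestPercentErrors:
    def test_ape_simple_cases(self, rng):
        t = rng.uniform(0.5, 1.5, 100)
        assert ape(1.5 * t, t)[0] == pytest.approx(0.5)
        assert ape(t, t)[0] == pytest.approx(0.0)

    def test_pe_sign_convention(self, rng):
        t = rng.uniform(0.5, 1.5, 100)
        assert pe(0.5 * t, t)[0] == pytest.approx(-0.5)  # truth greater => negative
        assert pe(t, t)[0] == pytest.approx(0.0)

    def test_pe_equals_ape_for_overestimates(self, rng):
        t = rng.uniform(0.5, 1.5, 50)
        p = t * rng.uniform(1.0, 2.0, 50)
        assert pe(p, t)[0] == pytest.approx(ape(p, t)[0])

    def test_cv_simple_cases(self):
        t = np.ones(50)
        assert cv(np.full(50, 1.1), t) == pytest.approx(0.1)
        assert cv(t, t) == 0.0

    def test_cv_matches_formula(self, rng):
        t = rng.uniform(0.5, 2.0, 200)
        p = t + rng.normal(0, 0.2, 200)
        assert cv(p, t) == pytest.approx(
            np.sqrt(np.mean((p - t) ** 2)) / t.mean())

    def test_ape_inflates_near_zero_truth_cv_stays_bounded(self, rng):
        """Overestimating tiny truths blows up APE but not CV."""
        t = np.full(200, 1e-3)
        p = t + 5e-3  # small absolute, huge relative error
        a, _ = ape(p, t)
        assert a > 1.0  # "above 100%"
        assert cv(p, t) == pytest.approx(5.0)  # bounded by mean normalization
        # against a healthy-magnitude map the same absolute error is benign
        t2 = np.ones(200)
        assert ape(t2 + 5e-3, t2)[0] < 0.01

    def test_floor_exclusion_counted(self):
        t = np.array([0.0, 1.0, 1.0])
        a, n_excl = ape(np.array([1.0, 1.0, 1.0]), t)
        assert n_excl == 1 and a == 0.0

    def test_all_below_floor_rejected(self):
        with pytest.raises(ValueError):
            ape(np.ones(3), np.zeros(3))
        with pytest.raises(ValueError):
            cv(np.ones(3), np.zeros(3))

    def test_voxel_permutation_invariance(self, rng):
        t = rng.uniform(0.5, 2.0, 100)
        p = t + rng.normal(0, 0.1, 100)
        perm = rng.permutation(100)
        assert ape(p, t)[0] == pytest.approx(ape(p[perm], t[perm])[0])
        assert cv(p, t) == pytest.approx(cv(p[perm], t[perm]))


class TestDTIFit:
    def test_isotropic_tensor(self):
        d = 0.8e-3
        scheme = make_scheme(30, seed=21)
        ph = make_crossing_phantom((5, 5, 5), seed=0, orientation_jitter_deg=0)
        iso = np.eye(3) * d
        ph.tensors[..., 0, :, :] = iso
        ph.tensors[..., 1, :, :] = iso
        vol = generate_site_volume(ph, SiteProfile("i", scheme, snr=np.inf), 0)
        fa, md, _ = dti_fit(vol)
        m = vol.mask
        assert np.abs(fa[m]).max() < 1e-6
        assert np.allclose(md[m], d, rtol=1e-6)

    def test_single_fiber_closed_form_fa_and_direction(self):
        lam = np.array(WM_EIGENVALUES)
        scheme = make_scheme(60, seed=22)
        ph = make_crossing_phantom((5, 5, 5), seed=0, orientation_jitter_deg=0)
        ph.fractions[..., 0] = 1.0
        ph.fractions[..., 1] = 0.0
        vol = generate_site_volume(ph, SiteProfile("f", scheme, snr=np.inf), 0)
        fa, md, pd = dti_fit(vol)
        m = vol.mask
        lam_bar = lam.mean()
        fa_expected = np.sqrt(1.5 * np.sum((lam - lam_bar) ** 2)
                              / np.sum(lam**2))
        assert np.allclose(fa[m], fa_expected, atol=1e-6)
        assert np.allclose(md[m], lam_bar, rtol=1e-6)
        # principal direction is +-x for the x-fiber component
        ang = np.degrees(np.arccos(np.clip(np.abs(pd[m][:, 0]), 0, 1)))
        assert ang.max() < 1.0

    def test_b0_only_rejected(self):
        from dmriharm.sh import GradientScheme

        scheme = GradientScheme([0.0, 0.0], [[0, 0, 0], [0, 0, 0]],
                                [True, True])
        vol = DWIVolume(data=np.ones((2, 2, 2, 2)), scheme=scheme,
                        mask=np.ones((2, 2, 2), bool))
        with pytest.raises(ValueError):
            dti_fit(vol)


class TestAngularDeflection:
    @staticmethod
    def _peak_function(direction, spec):
        """SH coefficients of a sharp symmetric lobe along `direction`."""
        dense = symmetrized_sphere(600)
        vals = np.exp(8.0 * ((dense @ direction) ** 2 - 1.0))
        return fit_sh(vals, dense, spec)

    def test_identical_zero(self, spec):
        c = self._peak_function(np.array([0.0, 0.0, 1.0]), spec)
        assert angular_deflection(c, c, spec)[0] == pytest.approx(0.0, abs=0.5)

    def test_orthogonal_peaks_90deg(self, spec):
        cz = self._peak_function(np.array([0.0, 0.0, 1.0]), spec)
        cx = self._peak_function(np.array([1.0, 0.0, 0.0]), spec)
        assert angular_deflection(cz, cx, spec)[0] == pytest.approx(90.0, abs=1.0)

    def test_antipodal_fold(self, spec):
        v = np.array([0.3, -0.5, 0.8])
        v /= np.linalg.norm(v)
        cp = self._peak_function(v, spec)
        cm = self._peak_function(-v, spec)
        assert angular_deflection(cp, cm, spec)[0] == pytest.approx(0.0, abs=0.5)

    def test_known_rotation_angle(self, spec):
        a = np.array([0.0, 0.0, 1.0])
        th = np.deg2rad(30)
        b = np.array([np.sin(th), 0.0, np.cos(th)])
        ca, cb = self._peak_function(a, spec), self._peak_function(b, spec)
        assert angular_deflection(ca, cb, spec)[0] == pytest.approx(30.0, abs=1.0)

    def test_peak_finding_crossing(self, spec):
        """A 90-degree two-lobe function yields two distinct peaks."""
        dense = symmetrized_sphere(600)
        vals = (np.exp(8.0 * ((dense @ [1, 0, 0]) ** 2 - 1.0))
                + np.exp(8.0 * ((dense @ [0, 1, 0]) ** 2 - 1.0)))
        c = fit_sh(vals, dense, spec)
        peaks = sh_peaks(c, spec)
        assert len(peaks) == 2
        found = np.abs(peaks @ np.array([[1, 0, 0], [0, 1, 0]]).T).max(axis=0)
        assert np.all(found > np.cos(np.deg2rad(3.0)))


class TestPosthocAdversary:
    def test_permuted_labels_chance(self, rng):
        codes = rng.standard_normal((1200, 8))
        labels = rng.permutation(np.repeat([0, 1], 600))
        acc = posthoc_adversary(codes, labels, seed=0)
        se = np.sqrt(0.5 * 0.5 / 360)
        assert abs(acc - 0.5) < 4 * se

    def test_label_embedded_codes_separable(self, rng):
        labels = np.repeat([0, 1, 2], 300)
        codes = rng.standard_normal((900, 8)) * 0.1
        codes[:, 0] += labels  # direct embedding
        assert posthoc_adversary(codes, labels, seed=0) > 0.95

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            posthoc_adversary(rng.standard_normal((10, 4)), np.zeros(10))

    def test_seed_reproducible(self, rng):
        codes = rng.standard_normal((400, 6))
        labels = np.repeat([0, 1], 200)
        assert (posthoc_adversary(codes, labels, seed=3)
                == posthoc_adversary(codes, labels, seed=3))


class TestAblationDelta:
    def test_identical_models_zero(self, vol_pair):
        pred, truth = vol_pair
        assert ablation_delta(pred, pred, truth) == 0.0

    def test_sign_convention(self, vol_pair):
        """Strictly worse ablated model gives a negative delta."""
        pred, truth = vol_pair
        worse = DWIVolume(data=truth.data + 0.2, scheme=truth.scheme,
                          mask=truth.mask)
        assert ablation_delta(pred, worse, truth) < 0
        assert ablation_delta(worse, pred, truth) > 0
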