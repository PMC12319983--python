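"""Synthetic phantom generation, corruption forward model, blip pairs."""

import numpy as np
import pytest

import dwimoco as dm
from dwimoco.phantom import (
    CorruptionSpec,
    PhantomSpec,
    burst_motion_trace,
    make_phantom,
    simulate_blip_pair,
    simulate_series,
)


def _tensor_fit_fa(signals, bvals, bvecs, s0):
    """Log-linear least-squares tensor fit returning FA (oracle)."""
    y = -np.log(np.maximum(signals, 1e-12) / s0) / bvals
    G = np.column_stack([
        bvecs[:, 0] ** 2, bvecs[:, 1] ** 2, bvecs[:, 2] ** 2,
        2 * bvecs[:, 0] * bvecs[:, 1], 2 * bvecs[:, 0] * bvecs[:, 2],
        2 * bvecs[:, 1] * bvecs[:, 2],
    ])
    d = np.linalg.lstsq(G, y, rcond=None)[0]
    D = np.array([[d[0], d[3], d[4]], [d[3], d[1], d[5]],
                  [d[4], d[5], d[2]]])
    ev = np.linalg.eigvalsh(D)
    md = ev.mean()
    return np.sqrt(1.5 * np.sum((ev - md) ** 2) / np.sum(ev ** 2))


class TestMakePhantom:
    def test_deterministic_for_seed(self):
        a = make_phantom(PhantomSpec(seed=3))
        b = make_phantom(PhantomSpec(seed=3))
        assert np.array_equal(a.s0, b.s0)
        assert np.array_equal(a.tensors, b.tensors)

    def test_isotropic_region_signal_direction_independent(self, phantom):
        sel = phantom.regions == 1
        rng = np.random.default_rng(0)
        sigs = []
        for _ in range(5):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            sigs.append(phantom.signal(900.0, u)[sel])
        for s in sigs[1:]:
            np.testing.assert_allclose(s, sigs[0], rtol=1e-12)

    def test_single_tensor_closed_form_along_principal_axis(self, phantom):
        sel = phantom.regions == 3  # fibers along x
        sig = phantom.signal(900.0, np.array([1.0, 0, 0]))
        expected = phantom.s0[sel] * np.exp(-900.0 * 1.7e-3)
        np.testing.assert_allclose(sig[sel], expected, rtol=1e-12)

    def test_crossing_region_has_lower_fa(self, phantom):
        rng = np.random.default_rng(1)
        dirs = rng.standard_normal((30, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        b = np.full(30, 900.0)

        def region_fa(label):
            vox = np.argwhere(phantom.regions == label)[0]
            s0 = phantom.s0[tuple(vox)]
            sig = np.array([
                phantom.signal(900.0, u)[tuple(vox)] for u in dirs
            ])
            return _tensor_fit_fa(sig, b, dirs, s0)

        assert region_fa(5) < region_fa(3)
        assert region_fa(3) > 0.5

    def test_mask_and_region_consistency(self, phantom):
        assert phantom.mask.sum() > 500
        assert set(np.unique(phantom.regions)) == {0, 1, 2, 3, 4, 5}


class TestSimulateSeries:
    def test_noiseless_uncorrupted_equals_clean_forward(self, phantom,
                                                        small_scheme):
        series, truth = simulate_series(phantom, small_scheme,
                                        CorruptionSpec())
        np.testing.assert_array_equal(series.intensities, truth["clean"])

    def test_dropout_attenuates_slice_mean(self, phantom, small_scheme):
        drop = [(2, 16, 0.2)]
        series, truth = simulate_series(
            phantom, small_scheme, CorruptionSpec(dropouts=drop))
        clean_mean = truth["clean"][:, :, 16, 2].mean()
        assert series.intensities[:, :, 16, 2].mean() == pytest.approx(
            0.2 * clean_mean, rel=1e-12)

    def test_hyperintense_slice_gain(self, phantom, small_scheme):
        series, truth = simulate_series(
            phantom, small_scheme,
            CorruptionSpec(hyperintense=[(1, 16, 1.8)]))
        np.testing.assert_allclose(
            series.intensities[:, :, 16, 1],
            1.8 * truth["clean"][:, :, 16, 1], rtol=1e-12)

    def test_rician_mean_matches_moment_formula(self):
        """Mean of repeated noisy b=0 measurements matches the Rician
        moment <M> = sigma sqrt(pi/2) L_{1/2}(-theta^2/2) within 1%."""
        from scipy.special import i0e, i1e

        small = make_phantom(PhantomSpec(shape=(8, 8, 8)))
        scheme = dm.GradientScheme([0.0] * 10000, np.zeros((10000, 3)))
        sigma = 5.0
        series, truth = simulate_series(small, scheme,
                                        CorruptionSpec(sigma=sigma, seed=9))
        vox = tuple(np.argwhere(small.regions == 1)[0])
        eta = truth["clean"][vox][0]
        t2 = (eta / sigma) ** 2
        x = t2 / 4
        # exp(-t2/4) * I_k(t2/4) expressed through the scaled Bessels
        expected = sigma * np.sqrt(np.pi / 2) * (
            (1 + t2 / 2) * i0e(x) + (t2 / 2) * i1e(x))
        measured = series.intensities[vox].mean()
        assert measured == pytest.approx(expected, rel=0.01)

    def test_deterministic_for_seed(self, phantom, small_scheme):
        spec = CorruptionSpec(sigma=2.0, seed=4)
        a, _ = simulate_series(phantom, small_scheme, spec)
        b, _ = simulate_series(phantom, small_scheme,
                               CorruptionSpec(sigma=2.0, seed=4))
        assert np.array_equal(a.intensities, b.intensities)

    def test_motion_length_mismatch_rejected(self, phantom, small_scheme):
        with pytest.raises(ValueError):
            simulate_series(phantom, small_scheme,
                            CorruptionSpec(motion=np.zeros((3, 6))))

    def test_invalid_corruptions_rejected(self):
        with pytest.raises(ValueError):
            CorruptionSpec(dropouts=[(0, 0, 1.5)])
        with pytest.raises(ValueError):
            CorruptionSpec(hyperintense=[(0, 0, 0.5)])
        with pytest.raises(ValueError):
            CorruptionSpec(sigma=-1.0)


class TestBurstMotion:
    def test_bounds_and_baseline(self):
        tr = burst_motion_trace(95, seed=0)
        assert np.all(np.abs(tr[:, :3]) <= 20.0)
        assert np.all(np.abs(tr[:, 3:]) <= 24.0)
        # a decent portion of volumes stays near the baseline pose
        quiet = np.sum(np.linalg.norm(tr[:, :3], axis=1) < 3.0)
        assert quiet > 95 // 2
        # bursts exercise a substantial part of the stated range
        assert np.max(np.abs(tr[:, :3])) > 8.0
        assert np.max(np.abs(tr[:, 3:])) > 9.6

    def test_deterministic(self):
        assert np.array_equal(burst_motion_trace(50, seed=5),
                              burst_motion_trace(50, seed=5))


class TestBlipPair:
    @pytest.fixture
    def volume(self, phantom):
        return phantom.signal(0, np.zeros(3))

    def test_zero_fieldmap_identity(self, volume):
        plus, minus = simulate_blip_pair(volume, np.zeros_like(volume))
        np.testing.assert_allclose(plus, volume, atol=1e-12)
        np.testing.assert_allclose(minus, volume, atol=1e-12)

    def test_mass_preserved(self, volume):
        x = np.linspace(-1, 1, 32)
        fmap = 40.0 * np.exp(-(np.add.outer(
            np.add.outer(x ** 2, x ** 2), x ** 2)) / 0.3)
        plus, minus = simulate_blip_pair(volume, fmap, pe_axis=1,
                                         readout_scale=0.05)
        for warped in (plus, minus):
            assert warped.sum() == pytest.approx(volume.sum(), rel=1e-3)

    def test_opposed_blips_displace_symmetrically(self):
        vol = np.zeros((16, 16, 16))
        vol[8, 8, 8] = 100.0
        fmap = np.full_like(vol, 30.0)
        plus, minus = simulate_blip_pair(vol, fmap, pe_axis=1,
                                         readout_scale=0.08)
        y = np.arange(16)

        def centroid(w):
            line = w.sum(axis=(0, 2))
            return (y * line).sum() / line.sum()

        d = 30.0 * 0.08
        assert centroid(plus) == pytest.approx(8 + d, abs=1e-6)
        assert centroid(minus) == pytest.approx(8 - d, abs=1e-6)

    def test_excessive_displacement_rejected(self, volume):
        fmap = np.full_like(volume, 1000.0)
        with pytest.raises(ValueError, match="half the field of view"):
            simulate_blip_pair(volume, fmap, readout_scale=0.05)
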