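import numpy as np
import pytest

import latnet as ln
from latnet.analysis import (
    distance_profile, fit_gaussian_profile, orientation_dependence,
    sigma_to_microns,
)


def _oriented_indices(bank):
    return np.flatnonzero(bank.oriented_mask())


class TestOrientationDependence:
    def test_constant_tensor_uniform_bins(self, bank):
        W = np.full((18, 18, 5, 5), 0.2)
        bins = orientation_dependence(W, bank, sign="positive")
        assert bins[0.0] == pytest.approx(bins[45.0], abs=1e-12)
        assert bins[45.0] == pytest.approx(bins[90.0], abs=1e-12)

    def test_circular_distance_binning(self, bank):
        # pair (0 deg, 135 deg) must land in the 45-deg bin: plant weight
        # only between those orientations and check it appears there
        ori = bank.preferred_orientation
        W = np.zeros((18, 18, 3, 3))
        j = int(np.flatnonzero(ori == 0.0)[0])
        k = int(np.flatnonzero(ori == 135.0)[0])
        W[j, k] = 1.0
        bins = orientation_dependence(W, bank, sign="positive")
        assert bins[45.0] > 0
        assert bins[0.0] == 0 and bins[90.0] == 0

    def test_like_to_like_planted_tensor(self, bank):
        ori = bank.preferred_orientation
        W = np.zeros((18, 18, 3, 3))
        for j in _oriented_indices(bank):
            for k in _oriented_indices(bank):
                if ori[j] == ori[k]:
                    W[j, k] = 1.0
        bins = orientation_dependence(W, bank, sign="positive")
        assert bins[0.0] == pytest.approx(1.0)
        assert bins[45.0] == 0.0 and bins[90.0] == 0.0

    def test_unoriented_bank_rejected(self, bank):
        from latnet.filterbank import FilterBank
        flat = FilterBank(
            filters=bank.filters[:2], classes=bank.classes[:2],
            relative_orientation=np.full(2, np.nan),
            preferred_orientation=np.full(2, np.nan),
            deg_per_px=1.0,
        )
        with pytest.raises(ValueError):
            orientation_dependence(np.zeros((2, 2, 3, 3)), flat)


class TestDistanceProfile:
    def test_constant_tensor_flat_profile(self):
        prof = distance_profile(np.full((3, 3, 9, 9), 0.4), sign="positive")
        assert np.allclose(prof["mean_weight"], 0.4, atol=1e-12)

    def test_first_ring_has_eight_offsets(self):
        W = np.zeros((1, 1, 9, 9))
        W[0, 0, 3:6, 3:6] = 1.0
        W[0, 0, 4, 4] = 0.0  # ring r=1 only
        prof = distance_profile(W, sign="positive")
        assert prof["mean_weight"][0] == pytest.approx(1.0)  # 8/8 offsets
        assert prof["mean_weight"][1] == 0.0

    def test_ring_means_match_brute_force(self):
        s = 3.0
        d = np.arange(-10, 11)
        g = np.exp(-(d[:, None] ** 2 + d[None, :] ** 2) / (2 * s * s))
        W = g[None, None]
        prof = distance_profile(W, sign="positive")
        for i, r in enumerate(prof["r_px"].astype(int)):
            vals = [g[y + 10, x + 10]
                    for y in range(-10, 11) for x in range(-10, 11)
                    if max(abs(y), abs(x)) == r]
            assert prof["mean_weight"][i] == pytest.approx(np.mean(vals),
                                                           abs=1e-12)

    def test_rf_size_units(self):
        prof = distance_profile(np.ones((1, 1, 9, 9)), rf_size=4.0)
        assert np.allclose(prof["r_rf"], prof["r_px"] / 4.0)

    def test_mean_conservation_over_rings(self, contour_weights):
        """Ring averages, reweighted by ring sizes, recover the global
        mean over nonzero-distance offsets."""
        pos = np.maximum(contour_weights.W, 0.0)
        prof = distance_profile(contour_weights.W, sign="positive")
        ring_sizes = 8 * prof["r_px"]
        total = float((prof["mean_weight"] * ring_sizes).sum())
        mean_map = pos.mean(axis=(0, 1))
        mean_map[21, 21] = 0.0
        assert total == pytest.approx(mean_map.sum(), rel=1e-10)


class TestGaussianFit:
    def test_noiseless_recovery(self):
        r = np.arange(1, 22, dtype=float)
        w = 1.0 * np.exp(-r**2 / (2 * 2.0**2)) + 0.1
        fit = fit_gaussian_profile(r, w)
        assert fit.wm == pytest.approx(1.0, abs=1e-6)
        assert fit.w0 == pytest.approx(0.1, abs=1e-6)
        assert fit.sigma == pytest.approx(2.0, abs=1e-6)
        assert not fit.degenerate

    def test_noisy_sigma_within_five_percent(self):
        rng = np.random.default_rng(12)
        r = np.arange(1, 22, dtype=float)
        true = 1.0 * np.exp(-r**2 / (2 * 4.0**2)) + 0.05
        fit = fit_gaussian_profile(r, true + rng.normal(0, 0.01, r.size))
        assert abs(fit.sigma - 4.0) / 4.0 < 0.05

    def test_constant_profile_flagged_degenerate(self):
        fit = fit_gaussian_profile(np.arange(1, 10.0), np.full(9, 0.3))
        assert fit.degenerate
        assert abs(fit.wm) < 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_profile(np.arange(3.0), np.zeros(3))


class TestUnitConversion:
    @pytest.mark.parametrize("deg,um", [(3.0, 100.0), (4.65, 155.0), (0.0, 0.0)])
    def test_cortical_magnification(self, deg, um):
        assert sigma_to_microns(deg, 30.0) == pytest.approx(um, abs=1e-9)

    def test_invalid_magnification(self):
        with pytest.raises(ValueError):
            sigma_to_microns(1.0, 0.0)
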