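"""Paired metrics against independently coded brute-force oracles."""

import math

import numpy as np
import pytest

from phantomforge.metrics import paired as pm
from phantomforge.metrics.fsim import fsim as fsim_fast
from phantomforge.volumes import Modality, Volume


# ---------------------------------------------------------------------------
# Brute-force oracles (loop-based, independent of the library implementations)
# ---------------------------------------------------------------------------

def brute_mae(a, b):
    total = 0.0
    for x, y in zip(a.ravel(), b.ravel()):
        total += abs(x - y)
    return total / a.size


def brute_rmse(a, b):
    total = 0.0
    for x, y in zip(a.ravel(), b.ravel()):
        total += (x - y) ** 2
    return math.sqrt(total / a.size)


def brute_ncc(a, b):
    a, b = a.ravel().astype(float), b.ravel().astype(float)
    ma, mb = sum(a) / len(a), sum(b) / len(b)
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.sqrt(sum((x - ma) ** 2 for x in a))
    db = math.sqrt(sum((y - mb) ** 2 for y in b))
    return num / (da * db)


def brute_psnr(a, b, data_range):
    mse = sum((x - y) ** 2 for x, y in zip(a.ravel(), b.ravel())) / a.size
    return 20 * math.log10(data_range) - 10 * math.log10(mse)


def _gaussian_kernel(sigma=1.5, radius=5):
    g = np.array([math.exp(-0.5 * (i / sigma) ** 2) for i in range(-radius, radius + 1)])
    g /= g.sum()
    return np.outer(g, g)


def brute_ssim(a, b, data_range):
    """Windowed SSIM computed pixel-by-pixel on the interior (the region the
    standard implementation averages after cropping the filter pad)."""
    w = _gaussian_kernel()
    rad = 5
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    h, wd = a.shape
    vals = []
    for r in range(rad, h - rad):
        for c in range(rad, wd - rad):
            pa = a[r - rad : r + rad + 1, c - rad : c + rad + 1].astype(float)
            pb = b[r - rad : r + rad + 1, c - rad : c + rad + 1].astype(float)
            ux, uy = (w * pa).sum(), (w * pb).sum()
            vx = (w * (pa - ux) ** 2).sum()
            vy = (w * (pb - uy) ** 2).sum()
            cov = (w * (pa - ux) * (pb - uy)).sum()
            vals.append(((2 * ux * uy + c1) * (2 * cov + c2))
                        / ((ux**2 + uy**2 + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


def brute_epr_egr(em_orig, em_gen):
    n_orig = n_gen = n_both = 0
    for o, g in zip(em_orig.ravel(), em_gen.ravel()):
        n_orig += bool(o)
        n_gen += bool(g)
        n_both += bool(o) and bool(g)
    return n_both / n_orig, n_gen / n_orig


def brute_fsim(a, b):
    """Loop-based FSIM: per-pixel similarity pooling with phase congruency and
    gradient maps recomputed here from their definitions."""
    from phantomforge.metrics.fsim import gradient_magnitude, phase_congruency

    scale = 255.0 / (max(a.max(), b.max()) - min(a.min(), b.min()))
    lo = min(a.min(), b.min())
    a = (a - lo) * scale
    b = (b - lo) * scale
    pc1, pc2 = phase_congruency(a), phase_congruency(b)
    g1, g2 = gradient_magnitude(a), gradient_magnitude(b)
    t1, t2 = 0.85, 160.0
    num = den = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            s_pc = (2 * pc1[i, j] * pc2[i, j] + t1) / (pc1[i, j] ** 2 + pc2[i, j] ** 2 + t1)
            s_g = (2 * g1[i, j] * g2[i, j] + t2) / (g1[i, j] ** 2 + g2[i, j] ** 2 + t2)
            pcm = max(pc1[i, j], pc2[i, j])
            num += s_pc * s_g * pcm
            den += pcm
    return num / den


@pytest.fixture(scope="module")
def random_pairs():
    rng = np.random.default_rng(42)
    return [(rng.normal(size=(32, 32)), rng.normal(size=(32, 32))) for _ in range(5)]


class TestScalarMetricOracles:
    def test_mae_rmse_ncc_psnr_match_brute_force(self, random_pairs):
        for a, b in random_pairs:
            assert pm.mae(a, b) == pytest.approx(brute_mae(a, b), abs=1e-6)
            assert pm.rmse(a, b) == pytest.approx(brute_rmse(a, b), abs=1e-6)
            assert pm.ncc(a, b) == pytest.approx(brute_ncc(a, b), abs=1e-6)
            assert pm.psnr(a, b, 4.0) == pytest.approx(brute_psnr(a, b, 4.0), abs=1e-6)

    def test_ssim_matches_windowed_brute_force(self, random_pairs):
        a, b = random_pairs[0]
        assert pm.ssim(a, b, data_range=4.0) == pytest.approx(
            brute_ssim(a, b, 4.0), abs=1e-6)

    def test_fsim_matches_pooling_brute_force(self, random_pairs):
        for a, b in random_pairs[:3]:
            assert fsim_fast(a, b) == pytest.approx(brute_fsim(a, b), abs=1e-3)


class TestClosedForms:
    def test_identity_values(self, rng):
        a = rng.normal(size=(32, 32))
        assert pm.mae(a, a) == 0.0
        assert pm.rmse(a, a) == 0.0
        assert pm.ssim(a, a, data_range=4.0) == pytest.approx(1.0)
        assert pm.ncc(a, a) == pytest.approx(1.0)
        assert pm.psnr(a, a, 4.0) == math.inf

    def test_offset_values(self, rng):
        a = rng.normal(size=(16, 16))
        assert pm.mae(a, a + 5) == pytest.approx(5.0)
        assert pm.rmse(a, a + 3) == pytest.approx(3.0)
        assert pm.ncc(a, a + 7) == pytest.approx(1.0)

    def test_ncc_affine_invariance_and_sign(self, rng):
        a = rng.normal(size=(16, 16))
        assert pm.ncc(a, 2 * a + 3) == pytest.approx(1.0)
        assert pm.ncc(a, -a) == pytest.approx(-1.0)

    def test_ncc_undefined_for_constant(self):
        with pytest.raises(ValueError):
            pm.ncc(np.ones((4, 4)), np.zeros((4, 4)) + np.arange(4))

    def test_ssim_negative_for_anticorrelated_structure(self, rng):
        # equal local luminance but inverted structure drives SSIM below zero
        a = rng.normal(100.0, 1.0, size=(32, 32))
        b = 2 * a.mean() - a
        assert pm.ssim(a, b, data_range=8.0) < 0

    def test_ssim_decreasing_in_constant_offset(self):
        a = np.full((32, 32), 10.0)
        vals = [pm.ssim(a, a + d, data_range=100.0) for d in (0.0, 5.0, 20.0)]
        assert vals[0] == pytest.approx(1.0)
        assert vals[0] > vals[1] > vals[2]

    def test_symmetry_of_symmetric_metrics(self, rng):
        a, b = rng.normal(size=(32, 32)), rng.normal(size=(32, 32))
        assert pm.mae(a, b) == pm.mae(b, a)
        assert pm.rmse(a, b) == pm.rmse(b, a)
        assert pm.ncc(a, b) == pytest.approx(pm.ncc(b, a))
        assert pm.ssim(a, b, 4.0) == pytest.approx(pm.ssim(b, a, 4.0))

    def test_fsim_identity_is_one(self, rng):
        a = rng.normal(size=(32, 32))
        assert fsim_fast(a, a) == pytest.approx(1.0, abs=1e-9)
        b = rng.normal(size=(32, 32))
        assert fsim_fast(a, b) < 1.0


class TestEdges:
    def _step_image(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 100.0
        return img

    def test_constant_image_has_empty_edge_map(self):
        maps = pm.edge_maps(np.full((32, 32), 5.0), self._step_image())
        assert maps.original.sum() == 0

    def test_step_edge_localized_at_step(self):
        # the detector marks the two pixels flanking an ideal step; the edge
        # must be a thin vertical band exactly at the transition
        maps = pm.edge_maps(self._step_image(), self._step_image())
        cols = set(np.unique(np.nonzero(maps.original)[1]))
        assert cols and cols <= {15, 16}

    def test_epr_egr_counts(self):
        em_o = np.zeros((5, 5), bool)
        em_o[2, :4] = True  # 4 original edge pixels
        em_g = np.zeros((5, 5), bool)
        em_g[2, :2] = True  # 2 preserved
        em_g[4, :4] = True  # 4 new
        maps = pm.EdgeMaps(em_o, em_g, pm.CannyParams())
        assert pm.epr(maps) == pytest.approx(0.5)
        assert pm.egr(maps) == pytest.approx(6 / 4)
        brute_p, brute_g = brute_epr_egr(em_o, em_g)
        assert pm.epr(maps) == pytest.approx(brute_p)
        assert pm.egr(maps) == pytest.approx(brute_g)

    def test_identical_maps_give_unity(self):
        em = np.zeros((6, 6), bool)
        em[3] = True
        maps = pm.EdgeMaps(em, em.copy(), pm.CannyParams())
        assert pm.epr(maps) == 1.0 and pm.egr(maps) == 1.0

    def test_disjoint_maps_give_zero_epr(self):
        em_o = np.zeros((6, 6), bool)
        em_o[1] = True
        em_g = np.zeros((6, 6), bool)
        em_g[4] = True
        maps = pm.EdgeMaps(em_o, em_g, pm.CannyParams())
        assert pm.epr(maps) == 0.0

    def test_empty_original_map_is_undefined_not_zero(self):
        maps = pm.EdgeMaps(np.zeros((4, 4), bool), np.ones((4, 4), bool), pm.CannyParams())
        with pytest.raises(pm.UndefinedMetricError):
            pm.epr(maps)
        with pytest.raises(pm.UndefinedMetricError):
            pm.egr(maps)

    def test_epr_egr_asymmetric_on_asymmetric_fixture(self):
        em_a = np.zeros((6, 6), bool)
        em_a[2, :3] = True
        em_b = np.zeros((6, 6), bool)
        em_b[2, :6] = True
        fwd = pm.EdgeMaps(em_a, em_b, pm.CannyParams())
        rev = pm.EdgeMaps(em_b, em_a, pm.CannyParams())
        assert pm.egr(fwd) != pm.egr(rev)


class TestLpips:
    def test_missing_backend_reports_unavailable(self, rng):
        assert pm.lpips_center(rng.normal(size=(300, 300)),
                               rng.normal(size=(300, 300)), backend=None) is None

    def test_mock_backend_reduces_to_normalized_mse(self, rng):
        def mock_backend(pa, pb):  # unit-norm pixel features -> normalized MSE
            na = pa / (np.abs(pa).max() or 1.0)
            nb = pb / (np.abs(pb).max() or 1.0)
            return float(np.mean((na - nb) ** 2))

        a = rng.normal(size=(300, 300))
        b = a + rng.normal(0, 0.1, size=(300, 300))
        got = pm.lpips_center(a, b, backend=mock_backend)
        ca = a[22:278, 22:278]
        cb = b[22:278, 22:278]
        expect = np.mean((ca / np.abs(ca).max() - cb / np.abs(cb).max()) ** 2)
        assert got == pytest.approx(expect, abs=1e-12)
        assert pm.lpips_center(a, a, backend=mock_backend) == 0.0

    def test_small_slices_are_center_padded(self, rng):
        a = rng.normal(size=(100, 100))
        got = pm.lpips_center(a, a, backend=lambda x, y: float(np.mean((x - y) ** 2)))
        assert got == 0.0


class TestChannelMae:
    def test_identical_volumes_all_zero(self, phantom_ct):
        out = pm.channel_mae(phantom_ct, phantom_ct)
        assert all(v == 0.0 for v in out.values() if v is not None)

    def test_offset_inside_bone_only(self, phantom_ct):
        lab = pm.threshold_channels(phantom_ct.data)
        shifted = phantom_ct.data.copy()
        shifted[lab == 3] += 50.0
        out = pm.channel_mae(shifted, phantom_ct.data)
        assert out["bone"] == pytest.approx(50.0)
        assert out["air"] == 0.0 and out["soft"] == 0.0

    def test_empty_channel_reported_missing(self):
        soft = np.zeros((1, 8, 8))  # no voxels below -200 or above +200
        out = pm.channel_mae(soft, soft)
        assert out["air"] is None and out["bone"] is None and out["soft"] == 0.0


class TestVolumeAggregation:
    def test_summary_is_mean_of_slices(self, phantom_ct, patientlike_ct):
        report = pm.evaluate_paired_volumes(patientlike_ct, phantom_ct)
        assert report.summary["mae"]["mean"] == pytest.approx(
            np.mean(report.per_slice["mae"]))
        assert 0 <= report.summary["epr"]["mean"] <= 1
        assert report.summary["ssim"]["mean"] <= 1

    def test_geometry_mismatch_rejected(self, phantom_ct):
        other = Volume(np.zeros((2, 8, 8)), (1, 1, 1), modality=Modality.CT)
        with pytest.raises(ValueError):
            pm.evaluate_paired_volumes(other, phantom_ct)
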