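"""Image statistics: missorting MFI, cluster segmentation, nuclei, tangles."""

import numpy as np
import pytest
from skimage.draw import disk

from iglonquant import (
    RoiSet,
    count_nuclei,
    missorting_mfi,
    segment_clusters,
    synthesize_cluster_image,
    tangle_fraction,
)
from iglonquant.exceptions import (
    DegenerateRoiError,
    EmptyMaskError,
    InvalidParameterError,
    InvalidRoiError,
)


def disk_rois(shape=(100, 100), soma_r=30, nuc_r=10):
    center = (shape[0] // 2, shape[1] // 2)
    soma = np.zeros(shape, dtype=bool)
    soma[disk(center, soma_r, shape=shape)] = True
    nuc = np.zeros(shape, dtype=bool)
    nuc[disk(center, nuc_r, shape=shape)] = True
    return RoiSet(soma_mask=soma, nucleus_mask=nuc)


class TestMissorting:
    def test_printed_equation_arithmetic(self):
        """RawIntDen soma 1000/area 100, nucleus 400/area 50 → MFI 12."""
        soma = np.zeros((20, 20), dtype=bool)
        soma[:10, :10] = True  # 100 px
        nuc = np.zeros((20, 20), dtype=bool)
        nuc[:5, :10] = True  # 50 px
        tau = np.zeros((20, 20))
        tau[nuc] = 8.0  # nucleus RawIntDen 400
        tau[soma & ~nuc] = 12.0  # soma RawIntDen 1000 total
        res = missorting_mfi(tau, RoiSet(soma_mask=soma, nucleus_mask=nuc))
        assert res.rawintden_soma == 1000.0
        assert res.rawintden_nucleus == 400.0
        assert res.mfi == pytest.approx(12.0, abs=0)

    def test_uniform_image_identity(self):
        tau = np.full((100, 100), 7.0)
        assert missorting_mfi(tau, disk_rois()).mfi == pytest.approx(7.0, abs=0)

    def test_equals_pixelwise_oracle(self):
        rng = np.random.default_rng(0)
        tau = rng.uniform(0, 255, (100, 100))
        rois = disk_rois()
        res = missorting_mfi(tau, rois)
        oracle = tau[rois.soma_mask & ~rois.nucleus_mask].mean()
        assert res.mfi == pytest.approx(oracle, rel=1e-14)

    def test_invariant_to_outside_intensity(self):
        rng = np.random.default_rng(1)
        tau = rng.uniform(0, 100, (100, 100))
        rois = disk_rois()
        a = missorting_mfi(tau, rois).mfi
        tau2 = tau.copy()
        tau2[~rois.soma_mask] += 500.0
        assert missorting_mfi(tau2, rois).mfi == a

    def test_scales_with_gain(self):
        rng = np.random.default_rng(2)
        tau = rng.uniform(0, 100, (100, 100))
        rois = disk_rois()
        assert missorting_mfi(3.0 * tau, rois).mfi == pytest.approx(
            3.0 * missorting_mfi(tau, rois).mfi, rel=1e-12
        )

    def test_nucleus_outside_soma_rejected(self):
        soma = np.zeros((20, 20), dtype=bool)
        soma[:10, :10] = True
        nuc = np.zeros((20, 20), dtype=bool)
        nuc[12:18, 12:18] = True
        with pytest.raises(InvalidRoiError):
            RoiSet(soma_mask=soma, nucleus_mask=nuc)

    def test_equal_areas_rejected(self):
        soma = np.zeros((10, 10), dtype=bool)
        soma[:5, :5] = True
        with pytest.raises(DegenerateRoiError):
            RoiSet(soma_mask=soma, nucleus_mask=soma.copy())


class TestClusters:
    def test_disjoint_blobs_counted(self):
        """3 disjoint 5-px blobs on a 1000-px dendrite: density 0.003/px."""
        map2 = np.zeros((50, 50))
        map2[10:30, 10:60] = 0  # keep explicit zeros elsewhere
        map2[10:30, 0:50] = 100.0
        map2_area = int((map2 > 0).sum())
        ig = np.zeros((50, 50))
        for c in (5, 20, 35):
            ig[15, c : c + 5] = 200.0
        stats = segment_clusters(ig, map2, smoothing_sigma=0.0, min_area_px=2)
        assert stats.n_clusters == 3
        assert stats.density == pytest.approx(3 / map2_area)

    def test_blank_channel_zero_clusters(self):
        map2 = np.full((40, 40), 50.0)
        stats = segment_clusters(np.zeros((40, 40)), map2)
        assert stats.n_clusters == 0
        assert stats.density == 0.0

    def test_min_area_filter(self):
        map2 = np.full((40, 40), 50.0)
        ig = np.zeros((40, 40))
        ig[10, 10] = 200.0  # single pixel
        stats = segment_clusters(ig, map2, smoothing_sigma=0.0, min_area_px=2)
        assert stats.n_clusters == 0

    def test_empty_map2_rejected(self):
        with pytest.raises(EmptyMaskError):
            segment_clusters(np.zeros((20, 20)), np.zeros((20, 20)))

    @pytest.mark.parametrize("n", range(0, 21, 4))
    def test_recovery_on_synthetic_fixtures(self, n):
        img, truth = synthesize_cluster_image(n, seed=50 + n)
        stats = segment_clusters(img.channel("IgLON5"), img.channel("MAP2"))
        assert stats.n_clusters == n == truth.true_cluster_count
        assert stats.mean_area == truth.true_cluster_mean_area

    def test_density_invariant_to_background_padding(self):
        img, _ = synthesize_cluster_image(5, seed=7)
        ig, m2 = img.channel("IgLON5"), img.channel("MAP2")
        a = segment_clusters(ig, m2)
        pad = ((20, 20), (20, 20))
        b = segment_clusters(np.pad(ig, pad), np.pad(m2, pad))
        assert b.n_clusters == a.n_clusters
        assert b.density == pytest.approx(a.density)

    def test_equivalent_radius(self):
        map2 = np.full((60, 60), 50.0)
        ig = np.zeros((60, 60))
        ig[disk((30, 30), 5, shape=(60, 60))] = 200.0
        stats = segment_clusters(ig, map2, smoothing_sigma=0.0)
        assert stats.radii[0] == pytest.approx(np.sqrt(stats.cluster_areas[0] / np.pi))


class TestNuclei:
    def test_disjoint_nuclei_counted(self):
        dapi = np.zeros((120, 120))
        centers = [(20, 20), (20, 60), (20, 100), (60, 20), (60, 60),
                   (60, 100), (100, 20), (100, 60), (100, 100), (40, 40)]
        for c in centers:
            dapi[disk(c, 6, shape=(120, 120))] = 150.0
        assert count_nuclei(dapi) == 10

    def test_blank_image_zero(self):
        assert count_nuclei(np.zeros((50, 50))) == 0

    def test_touching_nuclei_merge(self):
        """Adjacent components merge (documented limitation: no watershed)."""
        dapi = np.zeros((60, 60))
        dapi[disk((30, 25), 6, shape=(60, 60))] = 150.0
        dapi[disk((30, 35), 6, shape=(60, 60))] = 150.0
        assert count_nuclei(dapi) == 1

    def test_empty_channel_rejected(self):
        with pytest.raises(InvalidParameterError):
            count_nuclei(np.zeros((0, 0)))


class TestTangleFraction:
    @pytest.mark.parametrize("tangles,nuclei,expected", [(5, 100, 5.0), (0, 50, 0.0),
                                                         (2, 100, 2.0)])
    def test_percentage(self, tangles, nuclei, expected):
        assert tangle_fraction(tangles, nuclei) == pytest.approx(expected)

    def test_zero_nuclei_rejected(self):
        with pytest.raises(InvalidParameterError):
            tangle_fraction(3, 0)

    def test_more_tangles_than_nuclei_rejected(self):
        with pytest.raises(InvalidParameterError):
            tangle_fraction(5, 4)
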