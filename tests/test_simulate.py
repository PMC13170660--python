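"""Synthetic-data generators: Poisson spikes, rendering, fixtures, binding."""

import numpy as np
import pytest
from scipy import stats

from iglonquant import (
    GroupDesign,
    IndicatorKernel,
    PopulationDesign,
    missorting_mfi,
    render_fluorescence,
    segment_clusters,
    simulate_binding,
    simulate_population,
    simulate_spike_trains,
    synthesize_cluster_image,
    synthesize_missorting_image,
)
from iglonquant.binding import one_site
from iglonquant.exceptions import GenerationError, InvalidParameterError
from iglonquant.simulate import SpikeTrainSet


class TestSpikeTrains:
    def test_zero_rate_is_empty(self):
        st = simulate_spike_trains([0.0], 180.0, seed=0)
        assert st.counts().tolist() == [0]

    def test_poisson_mean_count(self):
        """1000 neurons at 2 ev/s for 180 s: mean count within 3 SE of 360."""
        st = simulate_spike_trains([2.0] * 1000, 180.0, seed=42)
        se = np.sqrt(2.0 * 180.0 / 1000)
        assert abs(st.counts().mean() - 360.0) < 3 * se

    def test_times_sorted_and_in_range(self):
        st = simulate_spike_trains([1.0] * 20, 60.0, seed=7)
        for times in st.spike_times:
            assert np.all(np.diff(times) >= 0)
            assert np.all((times >= 0) & (times < 60.0))

    def test_determinism(self):
        a = simulate_spike_trains([0.5] * 10, 180.0, seed=5)
        b = simulate_spike_trains([0.5] * 10, 180.0, seed=5)
        for x, y in zip(a.spike_times, b.spike_times):
            np.testing.assert_array_equal(x, y)

    @pytest.mark.parametrize("rates,duration", [([-1.0], 10.0), ([1.0], -5.0)])
    def test_invalid_parameters(self, rates, duration):
        with pytest.raises(InvalidParameterError):
            simulate_spike_trains(rates, duration, seed=0)


class TestKernelAndRendering:
    def test_kernel_peak_equals_amplitude(self):
        k = IndicatorKernel(amplitude=0.37)
        assert k.render().max() == pytest.approx(0.37, abs=0)

    def test_invalid_taus(self):
        with pytest.raises(InvalidParameterError):
            IndicatorKernel(rise_tau=0.5, decay_tau=0.1)

    def test_no_spikes_constant_trace(self):
        st = SpikeTrainSet(["a"], [np.array([])], 180.0, np.array([0.0]))
        fl = render_fluorescence(st, baseline_F=100.0, noise_sd=0.0)
        assert np.all(fl.F == 100.0)

    def test_single_spike_peak(self):
        """Max − baseline equals kernel amplitude × baseline (grid-aligned spike)."""
        st = SpikeTrainSet(["a"], [np.array([10.0])], 180.0, np.array([1 / 180]))
        k = IndicatorKernel(amplitude=0.5)
        fl = render_fluorescence(st, kernel=k, baseline_F=100.0, noise_sd=0.0)
        assert fl.F.max() - 100.0 == pytest.approx(0.5 * 100.0, rel=1e-12)

    def test_coincident_spikes_double(self):
        one = SpikeTrainSet(["a"], [np.array([10.0])], 60.0, np.array([1 / 60]))
        two = SpikeTrainSet(["a"], [np.array([10.0, 10.0])], 60.0, np.array([2 / 60]))
        f1 = render_fluorescence(one, baseline_F=100.0, noise_sd=0.0)
        f2 = render_fluorescence(two, baseline_F=100.0, noise_sd=0.0)
        assert f2.F.max() - 100.0 == pytest.approx(2 * (f1.F.max() - 100.0), rel=1e-12)

    def test_superposition_linearity(self):
        """Rendering a merged spike train equals the sum of responses."""
        a = np.array([5.0, 20.0])
        b = np.array([12.0, 40.0])
        mk = lambda t: SpikeTrainSet(["x"], [t], 60.0, np.array([len(t) / 60]))
        fa = render_fluorescence(mk(a), baseline_F=1.0, noise_sd=0.0).F
        fb = render_fluorescence(mk(b), baseline_F=1.0, noise_sd=0.0).F
        fab = render_fluorescence(mk(np.sort(np.concatenate([a, b]))),
                                  baseline_F=1.0, noise_sd=0.0).F
        np.testing.assert_allclose(fab - 1.0, (fa - 1.0) + (fb - 1.0), atol=1e-12)

    def test_bad_sampling_rate(self):
        st = SpikeTrainSet(["a"], [np.array([])], 10.0, np.array([0.0]))
        with pytest.raises(InvalidParameterError):
            render_fluorescence(st, kernel=IndicatorKernel(sampling_rate=8.0),
                                sampling_rate=-1.0)


class TestPopulation:
    def test_labels_and_rates_present(self):
        design = PopulationDesign(
            groups=[GroupDesign("pCtrl", n_neurons=5), GroupDesign("trt", n_neurons=4)],
            seed=1,
        )
        sets, truth = simulate_population(design)
        assert len(sets) == 4  # 2 groups x 2 default timepoints
        assert set(truth["group"]) == {"pCtrl", "trt"}
        assert truth["true_rate"].notna().all()
        assert len(truth) == (5 + 4) * 2

    def test_multiplier_scales_mean_exactly(self):
        """Paired design: 60-min multiplier 3 → exactly 3x the 0-min mean rate."""
        g = GroupDesign("trt", n_neurons=30,
                        timepoint_multipliers={"0min": 1.0, "60min": 3.0})
        _, truth = simulate_population(PopulationDesign(groups=[g], seed=3))
        m0 = truth[truth["timepoint"] == "0min"]["true_rate"].mean()
        m60 = truth[truth["timepoint"] == "60min"]["true_rate"].mean()
        assert m60 == pytest.approx(3.0 * m0, rel=1e-12)

    def test_null_groups_indistinguishable(self):
        """Equal-multiplier groups: realized rates pass a two-sample test."""
        pvals = []
        for s in range(20):
            design = PopulationDesign(
                groups=[GroupDesign("a", n_neurons=30), GroupDesign("b", n_neurons=30)],
                noise_sd=0.0, seed=100 + s,
            )
            _, truth = simulate_population(design)
            a = truth[(truth["group"] == "a") & (truth["timepoint"] == "0min")]["realized_rate_spm"]
            b = truth[(truth["group"] == "b") & (truth["timepoint"] == "0min")]["realized_rate_spm"]
            pvals.append(stats.mannwhitneyu(a, b).pvalue)
        assert np.median(pvals) > 0.01

    def test_empty_groups_rejected(self):
        with pytest.raises(InvalidParameterError):
            PopulationDesign(groups=[])

    def test_determinism(self):
        design = PopulationDesign(groups=[GroupDesign("g", n_neurons=3)], seed=9)
        a, _ = simulate_population(design)
        b, _ = simulate_population(design)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.F, y.F)


class TestMissortingFixture:
    def test_truth_round_trip_noiseless(self):
        img, rois, truth = synthesize_missorting_image(allocation_somatic=0.7, seed=0)
        got = missorting_mfi(img.channel("Tau"), rois).mfi
        assert got == truth.true_missorting_mfi

    def test_allocation_zero_gives_background(self):
        img, rois, _ = synthesize_missorting_image(
            allocation_somatic=0.0, background=10.0, seed=1
        )
        assert missorting_mfi(img.channel("Tau"), rois).mfi == pytest.approx(10.0)

    def test_determinism(self):
        a = synthesize_missorting_image(seed=4, noise_sd=3.0)
        b = synthesize_missorting_image(seed=4, noise_sd=3.0)
        for role in a[0].channels:
            np.testing.assert_array_equal(a[0].channels[role], b[0].channels[role])

    def test_nucleus_outside_soma_rejected(self):
        with pytest.raises(GenerationError):
            synthesize_missorting_image(soma_radius=10, nucleus_radius=12)

    def test_bad_allocation_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthesize_missorting_image(allocation_somatic=1.5)


class TestClusterFixture:
    def test_zero_clusters_blank(self):
        img, truth = synthesize_cluster_image(0, seed=0)
        assert truth.true_cluster_count == 0
        assert np.all(img.channel("IgLON5") == 0)

    def test_three_clusters_segmented(self):
        img, truth = synthesize_cluster_image(3, seed=1)
        stats_ = segment_clusters(img.channel("IgLON5"), img.channel("MAP2"))
        assert stats_.n_clusters == 3 == truth.true_cluster_count

    def test_determinism(self):
        a, _ = synthesize_cluster_image(8, seed=2)
        b, _ = synthesize_cluster_image(8, seed=2)
        np.testing.assert_array_equal(a.channel("IgLON5"), b.channel("IgLON5"))

    def test_overcrowded_placement_fails(self):
        with pytest.raises(GenerationError):
            synthesize_cluster_image(500, shape=(64, 64), max_tries=300)


class TestBindingSimulation:
    def test_noiseless_points_on_curve(self):
        c = simulate_binding(kd=0.5, mfi_max=1000.0, noise_cv=0.0)
        np.testing.assert_allclose(c.mfi, one_site(c.concentrations, 1000.0, 0.5))

    def test_half_max_at_kd(self):
        c = simulate_binding(kd=1.0, mfi_max=800.0, concentrations=[1.0], noise_cv=0.0)
        assert c.mfi[0] == pytest.approx(400.0)

    def test_determinism(self):
        a = simulate_binding(kd=0.5, mfi_max=1000.0, noise_cv=0.1, seed=3)
        b = simulate_binding(kd=0.5, mfi_max=1000.0, noise_cv=0.1, seed=3)
        np.testing.assert_array_equal(a.mfi, b.mfi)

    def test_invalid_kd(self):
        with pytest.raises(InvalidParameterError):
            simulate_binding(kd=-1.0, mfi_max=100.0)
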