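"""Ground-truth recovery benchmarks for the whole pipeline.

Each function simulates data with the :mod:`~iglonquant.simulate` generators
under stated conditions, runs the corresponding quantification stage, and
scores the result against the known truth.  They back both the test suite
and the reproducibility script, so the numbers they return are always
recomputed, never stored.
"""

from __future__ import annotations

import numpy as np

from . import activity, binding, events, images, simulate, traces

__all__ = [
    "separated_spike_trains",
    "detection_benchmark",
    "null_hyperactivity_calibration",
    "effect_sensitivity",
    "missorting_recovery",
    "cluster_recovery",
    "binding_noise_recovery",
]


def separated_spike_trains(
    n_neurons: int,
    duration: float = 180.0,
    min_gap: float = 4.0,
    max_gap: float = 12.0,
    seed: int = 0,
) -> simulate.SpikeTrainSet:
    """Spike trains with guaranteed inter-event gaps (> template length).

    Used for the perfect-recall regime: every transient is isolated, so a
    correct detector must find each one exactly once.
    """
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n_neurons):
        t = rng.uniform(1.0, min_gap)
        times = []
        while t < duration - min_gap:
            times.append(t)
            t += rng.uniform(min_gap, max_gap)
        trains.append(np.asarray(times))
    rates = np.array([len(t) / duration for t in trains])
    ids = [f"roi{i:04d}" for i in range(n_neurons)]
    return simulate.SpikeTrainSet(ids, trains, duration, rates)


def detection_benchmark(
    n_neurons: int = 100,
    amplitude: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
    match_tol_s: float = 1.0,
    similarity_threshold: float = events.SIMILARITY_THRESHOLD,
    min_amplitude: float = events.MIN_AMPLITUDE,
) -> dict:
    """Recall/precision of event detection on injected isolated transients.

    ``noise_sd`` is additive Gaussian noise on F with baseline 1, i.e. it is
    expressed directly in ΔF/F0 units.
    """
    st = separated_spike_trains(n_neurons, seed=seed)
    kernel = simulate.IndicatorKernel(amplitude=amplitude)
    fl = simulate.render_fluorescence(
        st, kernel=kernel, baseline_F=1.0, noise_sd=noise_sd, seed=seed + 1
    )
    dff = traces.compute_dff(fl)
    evs = events.detect_events(
        dff, similarity_threshold=similarity_threshold, min_amplitude=min_amplitude
    )
    fs = fl.sampling_rate
    by_roi: dict[str, list[float]] = {r: [] for r in st.neuron_ids}
    for e in evs:
        by_roi[e.roi_id].append(e.onset_frame / fs)
    tp = fp = fn = 0
    for i, roi in enumerate(st.neuron_ids):
        det = np.asarray(by_roi[roi])
        used = np.zeros(det.size, dtype=bool)
        for s in st.spike_times[i]:
            hits = np.flatnonzero(~used & (np.abs(det - s) < match_tol_s))
            if hits.size:
                used[hits[0]] = True
                tp += 1
            else:
                fn += 1
        fp += int((~used).sum())
    recall = tp / (tp + fn) if tp + fn else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    return {"recall": recall, "precision": precision, "tp": tp, "fp": fp, "fn": fn,
            "n_true": tp + fn}


def null_hyperactivity_calibration(
    n_per_group: int = 300,
    n_seeds: int = 200,
    mean_spm: float = 2.0,
    sd_spm: float = 1.0,
    seed: int = 0,
) -> dict:
    """Hyperactive fraction when 'treated' rates equal the control law.

    Control and treated spikes/min are drawn from the same Gaussian (clipped
    at 0); the treated group is classified against the control mean + 2·SD
    threshold.  Under the null the expected hyperactive fraction is the
    one-sided ~2.3% 2σ tail plus sampling error.
    """
    fracs = []
    for s in range(n_seeds):
        rng = np.random.default_rng(simulate.derive_seed(seed, f"null/{s}"))
        control = np.clip(rng.normal(mean_spm, sd_spm, n_per_group), 0.0, None)
        treated = np.clip(rng.normal(mean_spm, sd_spm, n_per_group), 0.0, None)
        thr = activity.control_threshold(control, timepoint_label="t")
        fracs.append(float(np.mean(treated > thr.threshold)))
    fracs = np.asarray(fracs)
    return {"median_hyperactive_fraction": float(np.median(fracs)),
            "mean_hyperactive_fraction": float(fracs.mean()),
            "n_seeds": n_seeds, "n_per_group": n_per_group}


def effect_sensitivity(
    multiplier: float = 3.0,
    n_seeds: int = 100,
    n_neurons: int = 40,
    rate_mean: float = 1.0 / 30.0,
    seed: int = 0,
) -> dict:
    """Fraction of seeds where a rate-multiplied group looks hyperactive.

    Simulates paired control/treated populations (treated base rates scaled
    by ``multiplier``), classifies realized spikes/min of both groups against
    the control threshold, and counts the seeds in which the treated
    hyperactive fraction strictly exceeds the control's.
    """
    wins = 0
    for s in range(n_seeds):
        design = simulate.PopulationDesign(
            groups=[
                simulate.GroupDesign("pCtrl", n_neurons=n_neurons, rate_mean=rate_mean,
                                     timepoint_multipliers={"60min": 1.0}),
                simulate.GroupDesign("treated", n_neurons=n_neurons, rate_mean=rate_mean,
                                     timepoint_multipliers={"60min": multiplier}),
            ],
            noise_sd=0.0,
            seed=simulate.derive_seed(seed, f"effect/{s}"),
        )
        _, truth = simulate.simulate_population(design)
        ctrl = truth[truth["group"] == "pCtrl"]["realized_rate_spm"].to_numpy()
        trt = truth[truth["group"] == "treated"]["realized_rate_spm"].to_numpy()
        thr = activity.control_threshold(ctrl, timepoint_label="60min").threshold
        if float(np.mean(trt > thr)) > float(np.mean(ctrl > thr)):
            wins += 1
    return {"fraction_exceeding": wins / n_seeds, "n_seeds": n_seeds,
            "n_neurons": n_neurons, "multiplier": multiplier}


def missorting_recovery(n_images: int = 50, seed: int = 0) -> dict:
    """Missorting formula vs brute-force pixelwise oracle, plus truth round trip.

    For each random geometry the RawIntDen-based statistic is compared with
    the direct pixel mean of the Tau channel over (soma AND NOT nucleus), and
    with the fixture's stored noiseless truth.
    """
    rng = np.random.default_rng(seed)
    max_err_oracle = 0.0
    max_err_truth = 0.0
    for i in range(n_images):
        img, rois, truth = simulate.synthesize_missorting_image(
            soma_radius=int(rng.integers(20, 36)),
            nucleus_radius=int(rng.integers(8, 16)),
            allocation_somatic=float(rng.uniform(0, 1)),
            tau_amplitude=float(rng.uniform(50, 400)),
            background=float(rng.uniform(0, 30)),
            noise_sd=0.0,
            seed=simulate.derive_seed(seed, f"missorting/{i}"),
        )
        tau = img.channel("Tau")
        res = images.missorting_mfi(tau, rois)
        oracle = float(tau[rois.soma_mask & ~rois.nucleus_mask].mean())
        max_err_oracle = max(max_err_oracle, abs(res.mfi - oracle))
        max_err_truth = max(max_err_truth, abs(res.mfi - truth.true_missorting_mfi))
    return {"max_abs_err_vs_pixel_oracle": max_err_oracle,
            "max_abs_err_vs_truth": max_err_truth, "n_images": n_images}


def cluster_recovery(max_n: int = 20, seed: int = 0) -> dict:
    """Exact count/density recovery on noiseless cluster images, n = 0..max_n."""
    count_errors = 0
    density_errors = 0
    for n in range(max_n + 1):
        img, truth = simulate.synthesize_cluster_image(
            n, noise_sd=0.0, seed=simulate.derive_seed(seed, f"cluster/{n}")
        )
        stats = images.segment_clusters(img.channel("IgLON5"), img.channel("MAP2"))
        if stats.n_clusters != n or stats.n_clusters != truth.true_cluster_count:
            count_errors += 1
        if stats.map2_area > 0 and stats.density != stats.n_clusters / stats.map2_area:
            density_errors += 1
    return {"count_errors": count_errors, "density_errors": density_errors,
            "n_cases": max_n + 1}


def binding_noise_recovery(
    n_seeds: int = 100,
    noise_cv: float = 0.05,
    kd: float = 0.5,
    mfi_max: float = 1000.0,
    seed: int = 0,
) -> dict:
    """Median relative Kd error under multiplicative noise on the 4-point grid."""
    errs = []
    for s in range(n_seeds):
        curve = simulate.simulate_binding(
            kd=kd, mfi_max=mfi_max, noise_cv=noise_cv,
            seed=simulate.derive_seed(seed, f"binding/{s}"),
        )
        res = binding.fit_binding(curve)
        if res.converged:
            errs.append(abs(res.kd - kd) / kd)
        else:
            errs.append(np.inf)
    return {"median_rel_kd_error": float(np.median(errs)), "n_seeds": n_seeds,
            "noise_cv": noise_cv, "true_kd": kd}
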