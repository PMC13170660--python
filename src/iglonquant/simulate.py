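"""Synthetic data with known ground truth for every pipeline stage.

Emulated acquisition regimes:

* **Calcium traces** — 180-s recordings at 8 Hz of a fast genetically encoded
  indicator.  Spontaneous activity is a homogeneous Poisson process per
  neuron; rate heterogeneity across a population is log-normal.  Each spike
  contributes a difference-of-exponentials transient (rise 0.1 s, decay
  0.6 s by default), transients superpose linearly, and the fluorescence is
  F(t) = baseline_F · exp(−bleach_rate·t) · (1 + Σ responses) + Gaussian
  noise.  Shot noise is not modelled.

* **Missorting images** — DAPI/MAP2/Tau channels of a single neuron with a
  circular nucleus strictly inside a circular soma and straight neurites.  A
  fraction ``allocation_somatic`` of the Tau signal is placed in the
  cytoplasm (soma minus nucleus), the rest along the neurites, emulating the
  axonal-to-somatodendritic redistribution being quantified.

* **Cluster images** — disjoint circular puncta on a dendrite-band mask, for
  surface-cluster counting.

* **Binding curves** — one-site responses on the 0.01/0.1/1/10 µg/ml dose
  grid with multiplicative Gaussian noise.

Every generator is a pure function of (parameters, seed), and each image
fixture stores ground truth recomputed from its own noiseless rendering by
the matching quantification routine, so round-trip tests are exact.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk, line

from . import images as _images
from .binding import DEFAULT_CONCENTRATIONS, BindingCurve, one_site
from .events import kernel_waveform
from .exceptions import GenerationError, InvalidParameterError
from .images import LabeledImage, RoiSet
from .traces import FluorescenceTraceSet

__all__ = [
    "SpikeTrainSet",
    "IndicatorKernel",
    "GroupDesign",
    "PopulationDesign",
    "SyntheticImageTruth",
    "derive_seed",
    "simulate_spike_trains",
    "render_fluorescence",
    "simulate_population",
    "synthesize_missorting_image",
    "synthesize_cluster_image",
    "simulate_binding",
]

DEFAULT_DURATION_S = 180.0
DEFAULT_SAMPLING_RATE = 8.0


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic per-operation seed from a run-level master seed."""
    return int(np.random.SeedSequence([int(master_seed) % (2**31), zlib.crc32(label.encode())]).generate_state(1)[0] % (2**31))


@dataclass
class SpikeTrainSet:
    """Ground-truth spike times per neuron (homogeneous Poisson)."""

    neuron_ids: list[str]
    spike_times: list[np.ndarray]  # seconds, strictly increasing, in [0, duration)
    duration: float
    true_rates: np.ndarray  # events/s per neuron

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    def counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.spike_times])


@dataclass
class IndicatorKernel:
    """Difference-of-exponentials transient waveform of a calcium indicator.

    The rendered waveform is peak-normalized on the sampling grid and scaled
    by ``amplitude`` (ΔF/F0 units), so its maximum equals ``amplitude``
    exactly.
    """

    rise_tau: float = 0.1
    decay_tau: float = 0.6
    amplitude: float = 0.5
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        if not (self.decay_tau > self.rise_tau > 0):
            raise InvalidParameterError("need decay_tau > rise_tau > 0")
        if self.amplitude <= 0 or self.sampling_rate <= 0:
            raise InvalidParameterError("amplitude and sampling_rate must be positive")

    def render(self, length_s: float = 6.0) -> np.ndarray:
        n = int(round(length_s * self.sampling_rate))
        return self.amplitude * kernel_waveform(self.rise_tau, self.decay_tau, self.sampling_rate, n)


@dataclass
class GroupDesign:
    """One treatment group: log-normal rate heterogeneity across neurons.

    ``rate_mean`` is the population mean spontaneous rate in events/s;
    ``rate_sigma`` the log-normal shape parameter.  ``timepoint_multipliers``
    scale each neuron's base rate per timepoint (paired design: the same
    neurons are recorded before and after treatment).
    """

    label: str
    n_neurons: int = 50
    rate_mean: float = 1.0 / 30.0  # 2 spikes/min
    rate_sigma: float = 0.5
    timepoint_multipliers: dict[str, float] = field(default_factory=lambda: {"0min": 1.0, "60min": 1.0})

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise InvalidParameterError("n_neurons must be >= 1")
        if self.rate_mean < 0 or self.rate_sigma < 0:
            raise InvalidParameterError("rate parameters must be non-negative")
        if any(m < 0 for m in self.timepoint_multipliers.values()):
            raise InvalidParameterError("effect multipliers must be non-negative")


@dataclass
class PopulationDesign:
    """Full population experiment: groups, acquisition, noise, and seed."""

    groups: list[GroupDesign]
    duration: float = DEFAULT_DURATION_S
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    kernel: IndicatorKernel = field(default_factory=IndicatorKernel)
    baseline_F: float = 100.0
    noise_sd: float = 2.0  # a.u. on F; ~0.02 in ΔF/F0 at baseline 100
    bleach_rate: float = 0.0  # fraction/s
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise InvalidParameterError("population design needs at least one group")
        if self.baseline_F <= 0:
            raise InvalidParameterError("baseline_F must be positive")


@dataclass
class SyntheticImageTruth:
    """Ground truth stored with each synthetic image fixture.

    Values are recomputed from the noiseless rendering by the matching
    quantification routine, so noise-free round trips are exact.
    """

    true_missorting_mfi: float | None = None
    true_cluster_count: int | None = None
    true_cluster_mean_area: float | None = None
    allocation_somatic: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def simulate_spike_trains(rates, duration: float, seed: int) -> SpikeTrainSet:
    """Homogeneous Poisson spike trains, one per entry of ``rates``.

    Counts are Poisson(rate × duration); times are sorted uniforms on
    [0, duration).
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates < 0):
        raise InvalidParameterError("spike rates must be non-negative")
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    rng = np.random.default_rng(seed)
    trains = []
    for r in rates:
        n = rng.poisson(r * duration)
        trains.append(np.sort(rng.uniform(0.0, duration, size=n)))
    ids = [f"roi{i:04d}" for i in range(len(rates))]
    return SpikeTrainSet(neuron_ids=ids, spike_times=trains, duration=duration, true_rates=rates)


def render_fluorescence(
    spikes: SpikeTrainSet,
    kernel: IndicatorKernel | None = None,
    baseline_F: float = 100.0,
    noise_sd: float = 0.0,
    bleach_rate: float = 0.0,
    sampling_rate: float | None = None,
    seed: int = 0,
    group_label: str = "",
    timepoint_label: str = "",
) -> FluorescenceTraceSet:
    """Render spike trains into raw fluorescence traces.

    F(t) = baseline_F · exp(−bleach_rate·t) · (1 + Σ transients) + N(0, noise_sd).
    Transients superpose linearly; each spike is quantized to the sample grid.
    """
    if kernel is None:
        kernel = IndicatorKernel(sampling_rate=sampling_rate or DEFAULT_SAMPLING_RATE)
    fs = sampling_rate if sampling_rate is not None else kernel.sampling_rate
    if fs <= 0:
        raise InvalidParameterError("sampling_rate must be positive")
    if not np.isclose(fs, kernel.sampling_rate):
        raise InvalidParameterError("kernel and requested sampling rates differ")
    if baseline_F <= 0:
        raise InvalidParameterError("baseline_F must be positive")
    if noise_sd < 0 or bleach_rate < 0:
        raise InvalidParameterError("noise_sd and bleach_rate must be non-negative")
    n_frames = int(np.floor(spikes.duration * fs))
    k = kernel.render(length_s=min(10 * kernel.decay_tau, spikes.duration))
    t = np.arange(n_frames) / fs
    rng = np.random.default_rng(seed)
    F = np.empty((spikes.n_neurons, n_frames))
    for i, st in enumerate(spikes.spike_times):
        sig = np.zeros(n_frames)
        for s in st:
            j = int(np.floor(s * fs))
            if j >= n_frames:
                continue
            m = min(len(k), n_frames - j)
            sig[j : j + m] += k[:m]
        F[i] = baseline_F * np.exp(-bleach_rate * t) * (1.0 + sig)
    if noise_sd > 0:
        F += rng.normal(0.0, noise_sd, size=F.shape)
    return FluorescenceTraceSet(
        F=F, sampling_rate=fs, roi_ids=list(spikes.neuron_ids),
        group_label=group_label, timepoint_label=timepoint_label,
    )


def _lognormal_rates(rng: np.random.Generator, mean: float, sigma: float, n: int) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean."""
    if mean == 0:
        return np.zeros(n)
    mu = np.log(mean) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, size=n)


def simulate_population(design: PopulationDesign) -> tuple[list[FluorescenceTraceSet], pd.DataFrame]:
    """Simulate a multi-group, multi-timepoint population experiment.

    Each neuron draws one base rate from its group's log-normal distribution;
    the timepoint multiplier scales that base rate, so within a group the
    true mean rate across timepoints follows the multipliers exactly (paired
    before/after design).

    Returns one :class:`~iglonquant.traces.FluorescenceTraceSet` per
    (group, timepoint) and a truth table with columns roi_id, group,
    timepoint, true_rate (events/s), true_rate_spm (spikes/min), n_spikes.
    """
    trace_sets: list[FluorescenceTraceSet] = []
    rows = []
    for g_idx, g in enumerate(design.groups):
        rng = np.random.default_rng(derive_seed(design.seed, f"rates/{g.label}/{g_idx}"))
        base = _lognormal_rates(rng, g.rate_mean, g.rate_sigma, g.n_neurons)
        for tp, mult in g.timepoint_multipliers.items():
            rates = base * mult
            sseed = derive_seed(design.seed, f"spikes/{g.label}/{g_idx}/{tp}")
            trains = simulate_spike_trains(rates, design.duration, seed=sseed)
            trains.neuron_ids = [f"{g.label}_{tp}_{i:04d}" for i in range(g.n_neurons)]
            traces = render_fluorescence(
                trains,
                kernel=design.kernel,
                baseline_F=design.baseline_F,
                noise_sd=design.noise_sd,
                bleach_rate=design.bleach_rate,
                sampling_rate=design.sampling_rate,
                seed=derive_seed(design.seed, f"noise/{g.label}/{g_idx}/{tp}"),
                group_label=g.label,
                timepoint_label=tp,
            )
            trace_sets.append(traces)
            counts = trains.counts()
            for i, roi in enumerate(trains.neuron_ids):
                rows.append(
                    {
                        "roi_id": roi,
                        "group": g.label,
                        "timepoint": tp,
                        "true_rate": rates[i],
                        "true_rate_spm": rates[i] * 60.0,
                        "n_spikes": int(counts[i]),
                        "realized_rate_spm": counts[i] / (design.duration / 60.0),
                    }
                )
    return trace_sets, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# image fixtures
# ---------------------------------------------------------------------------

def _neurite_mask(shape, center, soma_radius, n_neurites, length, width, rng) -> np.ndarray:
    """Straight neurites radiating from the soma edge at random angles."""
    mask = np.zeros(shape, dtype=bool)
    angles = rng.uniform(0, 2 * np.pi, size=n_neurites)
    for a in angles:
        r0 = np.array(center) + soma_radius * np.array([np.sin(a), np.cos(a)])
        r1 = np.array(center) + (soma_radius + length) * np.array([np.sin(a), np.cos(a)])
        rr, cc = line(int(r0[0]), int(r0[1]), int(r1[0]), int(r1[1]))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        for dr in range(-(width // 2), width // 2 + 1):
            for dc in range(-(width // 2), width // 2 + 1):
                r2, c2 = rr[keep] + dr, cc[keep] + dc
                ok = (r2 >= 0) & (r2 < shape[0]) & (c2 >= 0) & (c2 < shape[1])
                mask[r2[ok], c2[ok]] = True
    return mask


def synthesize_missorting_image(
    shape: tuple[int, int] = (192, 192),
    soma_radius: int = 30,
    nucleus_radius: int = 14,
    n_neurites: int = 4,
    neurite_length: int = 60,
    neurite_width: int = 3,
    allocation_somatic: float = 0.5,
    tau_amplitude: float = 200.0,
    background: float = 10.0,
    dapi_amplitude: float = 150.0,
    map2_amplitude: float = 120.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[LabeledImage, RoiSet, SyntheticImageTruth]:
    """Render a single-neuron DAPI/MAP2/Tau image with known missorting truth.

    A fraction ``allocation_somatic`` of the Tau amplitude goes to the
    cytoplasm (soma minus nucleus), the rest to the neurites; at allocation 0
    the cytoplasmic Tau mean equals the background level.  Ground truth is
    the missorting MFI recomputed from the noiseless Tau channel.
    """
    if not 0.0 <= allocation_somatic <= 1.0:
        raise InvalidParameterError("allocation_somatic must lie in [0, 1]")
    if nucleus_radius >= soma_radius:
        raise GenerationError("nucleus mask must be strictly inside the soma mask")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    center = (shape[0] // 2, shape[1] // 2)
    if center[0] - soma_radius < 0 or center[0] + soma_radius >= shape[0]:
        raise GenerationError("soma does not fit in the image")
    rng = np.random.default_rng(seed)

    soma = np.zeros(shape, dtype=bool)
    soma[disk(center, soma_radius, shape=shape)] = True
    nucleus = np.zeros(shape, dtype=bool)
    nucleus[disk(center, nucleus_radius, shape=shape)] = True
    if np.any(nucleus & ~soma) or nucleus.sum() >= soma.sum():
        raise GenerationError("nucleus mask must be strictly inside the soma mask")
    neurites = _neurite_mask(shape, center, soma_radius, n_neurites, neurite_length, neurite_width, rng)
    neurites &= ~soma

    cyto = soma & ~nucleus
    tau = np.full(shape, background, dtype=float)
    tau[cyto] = background + allocation_somatic * tau_amplitude
    tau[neurites] = background + (1.0 - allocation_somatic) * tau_amplitude
    dapi = np.zeros(shape, dtype=float)
    dapi[nucleus] = dapi_amplitude
    map2 = np.zeros(shape, dtype=float)
    map2[soma | neurites] = map2_amplitude

    rois = RoiSet(soma_mask=soma, nucleus_mask=nucleus, provenance="synthetic")
    truth = SyntheticImageTruth(
        true_missorting_mfi=_images.missorting_mfi(tau, rois).mfi,
        allocation_somatic=allocation_somatic,
    )
    channels = {"DAPI": dapi, "MAP2": map2, "Tau": tau}
    if noise_sd > 0:
        for role in channels:
            channels[role] = np.clip(
                channels[role] + rng.normal(0.0, noise_sd, size=shape), 0.0, None
            )
    return LabeledImage(channels=channels), rois, truth


def synthesize_cluster_image(
    n_clusters: int,
    shape: tuple[int, int] = (192, 192),
    radius_range: tuple[float, float] = (2.0, 4.0),
    n_bands: int = 3,
    band_width: int = 12,
    cluster_amplitude: float = 200.0,
    map2_amplitude: float = 120.0,
    min_separation: float = 6.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    max_tries: int = 2000,
) -> tuple[LabeledImage, SyntheticImageTruth]:
    """Disjoint circular surface puncta on horizontal dendrite bands.

    Cluster centres keep at least ``min_separation`` px edge-to-edge so that
    smoothing during segmentation cannot merge them.  Ground-truth count and
    mean area are recomputed from the noiseless rendering by
    :func:`iglonquant.images.segment_clusters`.
    """
    if n_clusters < 0:
        raise InvalidParameterError("n_clusters must be non-negative")
    if radius_range[0] <= 0 or radius_range[1] < radius_range[0]:
        raise InvalidParameterError("invalid radius range")
    rng = np.random.default_rng(seed)

    map2 = np.zeros(shape, dtype=float)
    band_rows = np.linspace(shape[0] * 0.2, shape[0] * 0.8, n_bands).astype(int)
    for r0 in band_rows:
        map2[max(r0 - band_width // 2, 0) : r0 + band_width // 2, :] = map2_amplitude
    dendrite = map2 > 0

    rmax = radius_range[1]
    placements: list[tuple[int, int, float]] = []
    tries = 0
    while len(placements) < n_clusters:
        if tries >= max_tries:
            raise GenerationError(
                f"could not place {n_clusters} non-overlapping clusters in {max_tries} tries"
            )
        tries += 1
        r0 = int(rng.choice(band_rows))
        row = r0 + rng.integers(-(band_width // 2) + int(np.ceil(rmax)), band_width // 2 - int(np.ceil(rmax)) + 1)
        col = int(rng.integers(int(np.ceil(rmax)), shape[1] - int(np.ceil(rmax))))
        rad = float(rng.uniform(*radius_range))
        if all(
            np.hypot(row - pr, col - pc) >= rad + prad + min_separation
            for pr, pc, prad in placements
        ):
            placements.append((int(row), col, rad))

    iglon5 = np.zeros(shape, dtype=float)
    for row, col, rad in placements:
        iglon5[disk((row, col), rad, shape=shape)] = cluster_amplitude

    stats = _images.segment_clusters(iglon5, map2)
    truth = SyntheticImageTruth(
        true_cluster_count=stats.n_clusters,
        true_cluster_mean_area=stats.mean_area,
    )
    channels = {"MAP2": map2, "IgLON5": iglon5}
    if noise_sd > 0:
        for role in channels:
            channels[role] = np.clip(
                channels[role] + rng.normal(0.0, noise_sd, size=shape), 0.0, None
            )
    return LabeledImage(channels=channels), truth


def simulate_binding(
    kd: float,
    mfi_max: float,
    concentrations=DEFAULT_CONCENTRATIONS,
    noise_cv: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    concentration_unit: str = "ug/ml",
) -> BindingCurve:
    """One-site dose–response points with multiplicative Gaussian noise.

    MFI_i = mfi_max · c_i / (kd + c_i) · (1 + ε_i), ε_i ~ N(0, noise_cv).
    """
    if kd <= 0 or mfi_max <= 0:
        raise InvalidParameterError("kd and mfi_max must be positive")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise InvalidParameterError("concentrations must be non-negative")
    if noise_cv < 0 or n_replicates < 1:
        raise InvalidParameterError("invalid noise_cv or n_replicates")
    rng = np.random.default_rng(seed)
    conc_full = np.tile(conc, n_replicates)
    rep = np.repeat(np.arange(n_replicates), len(conc))
    clean = one_site(conc_full, mfi_max, kd)
    eps = rng.normal(0.0, noise_cv, size=conc_full.shape) if noise_cv > 0 else 0.0
    return BindingCurve(
        concentrations=conc_full,
        mfi=clean * (1.0 + eps),
        replicate=rep,
        concentration_unit=concentration_unit,
    )
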