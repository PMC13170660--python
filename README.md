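# iglonquant

Quantification stack for cell-level readouts of anti-IgLON5 autoantibody
experiments in cultured neurons.  Patient-derived autoantibodies against the
neuronal surface protein IgLON5 induce hyperactivity and somatodendritic Tau
missorting; this package implements the measurements used to show that, as a
tested, reusable pipeline:

* **Calcium traces → events → hyperactivity.**  Raw per-ROI fluorescence is
  converted to ΔF/F0 with a percentile baseline (F0 = average of the 50th
  percentile over 60-s windows), transients are detected by template matching
  (similarity ≥ 0.75, minimum amplitude 0.01 ΔF/F0), and neurons are
  classified per timepoint against the control group: *silent* (no spikes),
  *active* (0 < spikes/min ≤ mean + 2·SD of control), *hyperactive*
  (spikes/min > mean + 2·SD of control).
* **Tau missorting.**  Mean Tau intensity over the cytoplasmic compartment,
  MFI = (RawIntDen_soma − RawIntDen_nucleus) / (Area_soma − Area_nucleus).
* **Surface clusters.**  Antibody-induced antigen puncta segmented on the
  dendrite (MAP2+) mask; density = # clusters / MAP2+ area, size, and
  equivalent-circle radius.
* **Tangle fraction.**  Tangle-bearing neurons per DAPI+ nucleus, in percent.
* **One-site binding.**  Dose–response fits MFI(c) = MFI_max·c/(Kd + c),
  statsmodels-style: `OneSiteBinding(...).fit()` returns a results object
  with estimates, standard errors, `summary()`, `predict()`, and `plot()`.

Because no raw imaging data are deposited for these assays, the package
ships a first-class synthetic-data module (`iglonquant.simulate`) that
generates 180-s / 8-Hz indicator traces from Poisson spike trains,
multi-channel soma/nucleus/dendrite images with a controllable
axonal-vs-somatic Tau allocation, disjoint surface puncta, and binding
curves on the 0.01/0.1/1/10 µg/ml dose grid — all with known ground truth,
so every stage is validated by parameter recovery.

## Worked example

```python
import numpy as np
import iglonquant as iq

# simulate a 180-s, 8-Hz recording of 20 neurons firing at 2 spikes/min
trains = iq.simulate_spike_trains([1/30] * 20, duration=180.0, seed=1)
raw = iq.render_fluorescence(trains, baseline_F=100.0, noise_sd=2.0, seed=2)

dff = iq.compute_dff(raw)                      # percentile-window baseline
events = iq.detect_events(dff)                 # template matching
rates = iq.spike_rates(events, raw.duration, raw.roi_ids)
print(rates["rate"].mean())                    # 1.883... spikes/min

thr = iq.control_threshold(rates["rate"], "")  # mean + 2*SD of this pool
cls = iq.classify_neurons(rates, thr)
print(iq.class_fractions(cls))
# {'silent': 0.0, 'active': 0.95, 'hyperactive': 0.05}

# one-site binding fit on the standard dose grid
curve = iq.simulate_binding(kd=0.5, mfi_max=1000.0, noise_cv=0.05, seed=3)
res = iq.OneSiteBinding(curve).fit()
print(res.summary())
# One-site specific binding: MFI(c) = MFI_max * c / (Kd + c)
#   ...
#   MFI_max:    977.799 (SE 25.7)
#   Kd:         0.475041 ug/ml (SE 0.0557)
print(iq.mass_to_molar(0.1))                   # 0.667 nM for 0.1 µg/ml IgG
```

The mean detected rate (~1.9 spikes/min) recovers the simulated 2 spikes/min;
the fitted Kd recovers the simulated 0.5 µg/ml within the noise level; and
the mass-to-molar conversion shows 0.1 µg/ml of a 150-kDa IgG ≈ 0.67 nM.

The same chain is available from the shell:

```bash
iglonquant simulate-traces --out traces.csv --seed 1
iglonquant dff --traces traces.csv --out dff.csv
iglonquant detect --dff dff.csv --out events.csv
iglonquant classify --rates events.rates.csv --out classes.csv
```

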