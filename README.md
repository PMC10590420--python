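# atckit

Analysis toolkit for **acoustic tweezing cytometry (ATC)** experiments, in
which ultrasound pulses displace integrin-bound microbubbles to apply cyclic
mechanical strain to cells (here, human pluripotent stem cell colonies).
The package provides, as tested library code plus numbered analysis drivers:

- **Acoustics** — the first-order primary acoustic radiation force on a
  bubble, secondary Bjerknes bubble–bubble coupling, and pulse-train
  scheduling (PRF, duty cycle, ramped pressure segments).
- **Viscoelastic simulation** — the bubble–integrin–cytoskeleton linkage as
  a linear Kelvin–Voigt element driven by pulsed step forces, with optional
  secondary-creep and plasticity terms; exact closed-form trajectories.
- **Tracking** — subpixel blob detection (band-pass + iterated
  intensity-weighted centroids) and minimum-cost trajectory linking for
  bright-field bubble videos.
- **Pulse metrics** — per-pulse peak, residual, and relative displacement,
  the displacement integral (AUC), and first-five-pulse summaries.
- **Image quantification** — DAPI-based nuclear masking, DAPI-normalized
  nuclear marker intensity (OCT4-style), and nuclear/cytoplasmic positivity
  classification (YAP-style, threshold ratio ≥ 1.1).
- **Statistics** — normality-gated two-sample tests (Welch t /
  Mann–Whitney), box-plot summaries (25–75%, median, 1%/99% whiskers), and
  per-condition metric–marker correlations.
- **Synthetic data** — seeded generators for trajectories, rendered bubble
  image stacks, and two-channel nuclei images, each with ground truth, so
  the whole pipeline is testable without microscope data.

## Core model

A bubble pushed by the radiation force of an ultrasound pulse displaces as a
Kelvin–Voigt element (spring *k* ∥ dashpot *η*): during a pulse

x(t) = x∞ (1 − e^(−t/τ)),  τ = η/k,  x∞ = F/k,

and recovers exponentially with the same retardation time τ when the pulse
ends. Under a pulse train with on-time t_on and off-time t_off the per-pulse
peaks obey the recursion p_{n+1} = x∞(1 − a) + a·b·p_n with
a = e^(−t_on/τ), b = e^(−t_off/τ), and residuals r_n = b·p_n. Inverting this
recursion against measured five-pulse mean peak/residual displacements
yields the built-in calibrations:

| duty cycle | τ (s) | x∞ (µm) |
|-----------:|------:|--------:|
| 5%         | 0.578 | 15.04   |
| 50%        | 1.070 | 8.84    |

The primary radiation force is F ≅ 2π P_A² R₀ / (δ_tot ρ₀ c ω₀) for a
bubble of radius R₀ in a field of pressure amplitude P_A and angular
frequency ω₀ (δ_tot ≈ 0.16, ρ₀ = 1000 kg·m⁻³, c = 1500 m·s⁻¹); the
secondary Bjerknes coupling between bubbles scales as R₁³R₂³/d² along the
line of centers, which makes nearby bubbles deviate from the primary push
direction.

## Worked example

```python
from atckit.acoustics import PulseTrain
from atckit.pulse_metrics import per_pulse_metrics
from atckit.synthetic import default_calibration, kv_trajectory

kv = default_calibration(0.05)              # 5% duty cycle
train = PulseTrain.constant(prf=1.0, duty=0.05, n_pulses=5)
traj = kv_trajectory(kv, train, duration=5.0, sample_rate=1000.0)
ms = per_pulse_metrics(traj.x, traj.t, train)
print(f"tau={kv.tau:.4f} s  x_inf={kv.x_inf:.3f} um")
print(f"mean peak={ms.peak.mean():.3f} um  "
      f"mean residual={ms.residual.mean():.3f} um")
```

prints

```
tau=0.5777 s  x_inf=15.038 um
mean peak=1.450 um  mean residual=0.280 um
```

i.e. the calibrated model, pushed through the same metrics extraction used
for tracked videos, returns a five-pulse mean peak displacement of 1.45 µm
and mean residual of 0.28 µm for the 5% duty-cycle condition (4.74 / 2.97 µm
for 50%).

The numbered drivers under `analysis/` run the full story — calibration,
metric extraction, viscoelastic fitting on noisy data, end-to-end
render-and-track validation, nuclei quantification, and statistics — and
write their tables under `results/`. The full pipeline is also available as
a CLI: `atckit run --config configs/demo.yaml --out out/`.

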