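# glintloc

Simulation and inference tools for **glint-based sound-source localization
in constant-frequency (CF) echolocating bats**, in the style of horseshoe
bats (*Rhinolophus*).

## The scientific problem

CF bats such as *Rhinolophus rouxii* emit long (~50 ms) narrowband calls
near 75 kHz and hunt fluttering insects. Because their call carries almost
no spectral bandwidth, the classic spectral-cue route to localization is
closed to them. Instead, they move their pinnae during echo reception: as
each ear sweeps through an oblique ±15° arc (one ear up while the other
goes down), the gain of the combined emission/hearing directionality
toward a fixed target changes, imposing a direction-specific **amplitude
modulation** on the received echo at each ear. The expected binaural
modulation pattern for a target direction θ is a *template* T<sub>θ</sub>;
localization is matching the received level vector against the stored
template set.

A fluttering insect returns one amplitude-stable **dominant glint** per
wingbeat (the moment its wings stand perpendicular to the wavefront), so a
receiver that listens only in the Doppler-shifted frequency channels
observes the modulation at discrete glint times: a flutter rate *f* during
a call of duration *D* yields *k = fD* samples per ear (1–10 for
20–200 Hz at 50 ms). Sampling discards information, but dominant glints
are far less noisy than the rest of the echo. This package quantifies that
trade-off as an ideal-observer calculation.

## The model

Received levels are modelled in the log (dB) domain. For a target at
direction θ with unknown echo strength *A* (interpretable as SNR when the
detection floor is 0 dB), the measurement vector *s* (k left-ear then k
right-ear samples) is

> s = max(n₀, T<sub>θ</sub> + A + ν),  ν ~ N(0, Σ)

where n₀ is the detection floor and Σ has per-sample variance σ², zero
correlation across glints, and correlation ρ between simultaneous
left/right samples. The observer evaluates the Gaussian likelihood
p(s | θ, A) about the floor-censored mean max(n₀, T<sub>θ</sub> + A),
marginalizes *A* over a uniform discrete prior (it is a nuisance
parameter), and applies Bayes' theorem over a grid of candidate directions
uniformly distributed on the frontal hemisphere. The **Shannon entropy of
the posterior** (bits) measures the remaining ambiguity about target
direction: 0 bits = pinned down, log₂ n = chance (≈11.7 bits for the
full 3252-direction grid). Cell means are estimated by Monte Carlo
(default 20 measurement realizations per direction × flutter × strength
cell, each with a fresh glint-phase and noise draw).

Because the numerically simulated head model behind the original
directionality patterns is not distributable, the package generates
**synthetic directivity patterns** (smooth Gaussian lobes with optional
side lobes, laterally offset ear boresights) and can also load measured or
simulated directivity grids from CSV.

## Worked example

```python
import numpy as np
from glintloc import (ExperimentConfig, simulate_entropy_surface,
                      performance_curve, nyquist_limit)
from glintloc.experiments import build_default_templates

cfg = ExperimentConfig(grid_size=300, seed=0)
templates = build_default_templates(cfg)

surface = simulate_entropy_surface(
    templates, [20.0, 60.0, 100.0, 200.0], cfg.echo_strengths_db,
    cfg.noise(cfg.low_sigma_db), n_realizations=10, seed=cfg.seed)

hbar = surface.direction_mean().mean(axis=1)
for f, h in zip(surface.flutter_rates_hz, hbar):
    k = int(f * cfg.call_duration_s)
    print(f"{f:5.0f} Hz ({k:2d} glints): {h:5.2f} bits   "
          f"(Nyquist {nyquist_limit(f, 0.05):.2f} cycles/stroke)")
print("chance level:", round(surface.chance_entropy_bits(), 2), "bits")
print(performance_curve(surface, 200.0).to_string(index=False))
```

prints

```
   20 Hz ( 1 glints):  4.57 bits   (Nyquist 0.50 cycles/stroke)
   60 Hz ( 3 glints):  0.66 bits   (Nyquist 1.50 cycles/stroke)
  100 Hz ( 5 glints):  0.32 bits   (Nyquist 2.50 cycles/stroke)
  200 Hz (10 glints):  0.13 bits   (Nyquist 5.00 cycles/stroke)
chance level: 8.23 bits
 flutter_hz  performance_pct
       20.0        45.134404
       60.0        93.355919
      100.0        97.570866
      200.0       100.000000
```

Reading: even a single glint per call (20 Hz) cuts the ambiguity from the
8.2-bit chance level to 4.6 bits, and from three glints upward (≥60 Hz)
the observer loses less than a bit relative to the 200 Hz baseline — in
the low-noise dominant-glint channel, sampling is nearly free. The
performance column is the normalized information gain
P(f) = 100 · Σ_A(H_max − H̄(f,A)) / Σ_A(H_max − H̄(200 Hz,A)).

## Command line

```sh
glintloc maps     --seed 1 --out out/       # entropy maps per flutter rate
glintloc sweep    --seed 1 --out out/       # flutter/strength sweep + performance
glintloc channels --seed 1 --out out/       # dominant-glint vs whole-echo channel
glintloc templates --out out/               # dynamic range, spectrum, Nyquist
glintloc tradeoff --seed 1 --out out/       # entropy maps vs echo strength
```

All outputs are CSV plus a JSON run manifest; `--full` switches to the
full 3252-direction grid, `--config cfg.yaml` overrides any parameter and
`--plot` renders PNG maps/curves.

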