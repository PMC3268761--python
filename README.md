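# polarsim

Stochastic reaction–diffusion simulation of spatial gradient sensing
and cell polarization under gradient noise.

Cells such as budding yeast read a shallow spatial gradient of a
chemical cue and polarize toward its source.  Fluctuations in the
local cue concentration corrupt this measurement: noise inhibits the
*extent* of polarization, degrades its *directional accuracy*
(cos θ between the polarization site and the gradient), and makes the
output *rough* (temporal variance of the front signal).  `polarsim` is
a small library for studying these effects and the filtering
strategies — positive feedback, multi-stage cascades, time-averaging,
diffusive smoothing — that signalling networks use against them, along
with the central trade-off: every filter slows the response.

It is aimed at systems-biology modellers who want reproducible,
scriptable versions of these simulation experiments.

## Models

**Generic polarity stage** — membrane marker a(x, t) with global
integral-feedback inhibitor b(t):

    ∂a/∂t = Ds ∇²a + k0·u^q/(1+u^q) + k1·(pa)^h/(1+(pa)^h) − k2 a − k3 b a
    db/dt  = k4 (ā − k_ss) b,          p = (βu)^q / (1 + (βu)^q)

Amplification comes either from input ultrasensitivity (`NPF` preset,
k0 = 10, k1 = 0) or a ligand-gated positive feedback loop (`PF`,
k0 = 1, k1 = 10); stages chain into filter–amplifier cascades
(`NPF+PF`).  The input is a linear gradient plus spatio-temporal white
noise, u = u′ + η, with σ the per-node noise standard deviation.

**Yeast mechanistic model** — the pheromone pathway as a two-stage
filter–amplifier: a receptor/heterotrimeric G-protein cycle
(slow filter) feeding the Cdc42 GTPase cycle (fast amplifier) with an
inner Bem1–Cdc24–Cdc42 positive feedback loop, Cla4 global negative
feedback, and a slow outer loop of polarized receptor delivery.
Mutant lesions (`bem1_delta`, `bni1_delta`) and G-protein-cycle speed
scaling are first-class operations.

## Worked example

Settling times of the three architectures after gradient onset and a
180° reversal (noise-free, L_mid = 1, L_slp = 0.01 /μm):

```python
from polarsim.geometry import make_grid
from polarsim.inputs import GradientSpec
from polarsim.generic import make_preset
from polarsim.metrics import settling_time

grid = make_grid("axisymmetric_sphere", 200, 2.0)
grad = GradientSpec(L_mid=1.0, L_slp=0.01)
for name in ("NPF", "PF", "NPF+PF"):
    r = settling_time(make_preset(name), grad, grid=grid)
    print(f"{name:7s} t_s = {r.t_s:5.2f} s "
          f"(onset {r.t_initial:5.2f} s, reversal {r.t_switch:5.2f} s)")
```

prints

```
NPF     t_s =  2.41 s (onset  4.23 s, reversal  0.59 s)
PF      t_s = 25.12 s (onset 24.81 s, reversal 25.43 s)
NPF+PF  t_s = 29.41 s (onset 32.15 s, reversal 26.68 s)
```

The ultrasensitive model (NPF) responds in seconds; adding positive
feedback (PF) buys far stronger, noise-tolerant polarization at a
~10× cost in response time, and putting a non-amplifying filter stage
in front (NPF+PF) improves noise handling again for only a few extra
seconds.

The same experiments are exposed as one-command runs:

```
polarsim list-experiments
polarsim run fig3AB --out results/
polarsim run fig3C --seed 7 --n-reps 20 --out results/
polarsim sweep snr_sweep --param sigmas=0.2,0.5,1.0 --out results/
```

Each writes a long-format CSV (one row per replicate and metric, with
seed and config hash) plus a JSON mean ± SEM summary.

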