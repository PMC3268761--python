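# Methods

`polarsim` simulates how noise in an external chemical gradient degrades
cell polarization, and how filter–amplifier signalling architectures
trade noise tolerance against response speed.  Two models share one
numerical core: a coarse-grained generic polarity model and a
mechanistic model of yeast pheromone-induced polarization.

## Geometry and discretization

Cells are closed surfaces of radius r = 2 μm, discretized either as a
ring of `k_x` uniformly spaced nodes (2-D simulations, arc angle θ) or
as an axisymmetric sphere (1-D simulations, axial coordinate
z = cos φ ∈ [−1, 1], front at z = 1).  The axisymmetric grid is a
cell-centred finite-volume mesh in z with equal-width (hence
equal-area) bands; interface conductances (1 − z²) vanish identically
at the poles, so the discrete Laplace–Beltrami operator needs no pole
regularization, conserves mass to round-off, and reproduces the
degree-1 Legendre eigenmode exactly.  The circle uses the standard
periodic three-point stencil.  Default resolution is `k_x = 200` for
1-D stationary statistics; the 2-D Monte Carlo panels run at
`k_x = 60` (resolutions between 40 and 200 give closely similar
statistics; the resolution used is always recorded in run metadata).

Time stepping is first-order IMEX: reactions and noise explicit,
diffusion implicit via a precomputed dense factorization of
(I − Δt·D·L), with Δt = 0.01 s matching the noise refresh step.  A
plain forward-Euler scheme is kept as an independent reference; the two
agree to <10⁻³ relative on 1-s benchmark runs.  When speed-scaled
variants make the reaction terms stiff (rates approaching 1/Δt), the
reaction half of the step is sub-stepped automatically; the noise field
is still held frozen across the full Δt so the noise model is
unchanged.  All simulators advance an optional leading replicate axis,
so a Monte Carlo batch costs little more than a single run.

## Input model

The ligand input is u(x, t) = u′(x) + η(x, t): a static linear gradient
u′ = L_mid + L_slp·d(x) (d = signed distance from the cell midplane
along the gradient axis) plus spatially and temporally uncorrelated
noise, redrawn independently at every node each noise step
k_t = 0.01 s.  σ is the literal per-node standard deviation at this
discretization — draws are *not* rescaled by 1/√(k_t Δx), so σ is tied
to the default k_x/k_t.  Noise is normal, or for σ large compared with
L_mid a shifted log-normal: a log-normal with variance σ² and mean
equal to the minimum of u′ over the cell, minus that mean — giving mean
0, standard deviation σ, and support bounded below so that u never goes
negative.  Negative u under normal noise is passed through unmodified
and clamped to zero only inside Hill-term evaluations.  Every
realization is reproducible from its seed (counter-based generators,
one stream per replicate).  Gradient reversal is an instantaneous 180°
direction switch.

What the generator does *not* emulate: receptor–ligand binding noise,
internal (molecular) reaction noise, spatially correlated fluctuations,
and cell-shape change.  Passing tests therefore speak to the response
of these models to idealized external field noise, not to the full
stochasticity of a real cell.

## Generic model

Each stage evolves a membrane marker a(x, t) and a global inhibitor
b(t):

    ∂a/∂t = Ds ∇²a + k0·H_q(u) + k1·H_h(p·a) − k2·a − k3·b·a
    db/dt  = k4·(ā − k_ss)·b,       p = H_q(β·u)

with H_n(x) = xⁿ/(1 + xⁿ) (evaluated as expit(n·log x), safe up to
n = 1000; H₀ ≡ 1/2 by convention) and ā the surface average.  b
integrates the deviation of ā from the set point k_ss = 1: whatever the
input level (above the sensing threshold), the mean marker level
adapts back to k_ss.  Because b only *adds* decay, adaptation is
one-sided: inputs so small that k0·H_q(u) < k2·k_ss leave nothing to
regulate.  The input gate p prevents the positive feedback loop from
locking in without ligand.

Presets: NPF (k0 = 10, k1 = 0; ultrasensitive amplification), PF
(k0 = 1, k1 = 10; positive-feedback amplification), low/high feedback
gain (h = 2 / 8), and serial cascades (`NPF+PF`, `NPF+NPF`, …) where
stage i+1 reads stage i's marker field as its input, each stage with
its own integral controller.  Speed variants multiply k0…k4 by 10 or
0.1, leaving Ds fixed (a co-scaled-diffusion flag exists for the pure
time-rescaling oracle used in tests).

### Calibrated constants

k0…k4 are fixed by the study conditions; the remaining constants are
calibrated once against the published operating points and then frozen
(runs embed a `calibrated` marker in metadata):

| parameter | value | why |
|---|---|---|
| Ds | 0.05 μm²/s | noise-free NPF a_f ≈ 2 at L_slp = 0.1/μm; enough smoothing for stable two-stage amplification |
| q | 50 | ultrasensitive regime; any q ≳ 30 gives the same noise-free extent, q = 50 also reproduces the settling-time scale |
| h | 8 (PF default) | high-gain feedback; h = 2 kept as the low-gain preset |
| β | 1 | gate threshold at the mid-cell concentration |
| filter-stage q | 2 | non-final cascade stages are unity-log-gain low-pass filters: the logarithmic slope of H_q at u = 1 is q/2, so q = 2 passes the relative front–back contrast unchanged while time-averaging the noise.  An amplifying (high-q) first stage saturates into a hemisphere and destroys both the cascade's response-time summation and its filtering benefit. |

With these values: settling times (protocol below) t_s = 2.4 s (NPF),
25.1 s (PF), 29.4 s (NPF+PF); stationary output noise σ_out = 0.135 at
σ = 1 and 0.187 at σ = 10 (published: 3.2 / 26.1 / 28.8 s and
0.18 / 0.23).  The σ_out shortfall (~0.04) is a genuine limit: at the
pinned decay constants the front value is an Ornstein–Uhlenbeck-type
average whose variance saturates ≈ 0.16 as Ds → 0, and smaller Ds
destabilizes the cascades.  We kept the physical parameters rather than
distorting them to close the gap.

### Protocols

*Stationary statistics* — runs start from a = k_ss, b = 1, equilibrate
noise-free under the deterministic gradient (50–150 s), then run 100 s
with noise; means/standard deviations use 10 000 samples over that
100-s window at every node.  *Settling time* — noise-free; from the
unstimulated state the gradient is applied at t = 0 and t_initial is
the last time the front value leaves a 5% band (of the transition
magnitude, the standard control-theory definition; a steady-level band
is available behind a flag) around its new steady value; the gradient
is then reversed 180° and t_switch measured at the new front;
t_s = (t_initial + t_switch)/2.  Starting from the unstimulated state,
rather than a pre-equilibrated uniform-ligand state, is what gives the
architectures their distinct second-scale to half-minute-scale
responses — from a pre-adapted state every architecture relaxes within
a second, which would make the comparison vacuous.

## Yeast model

Eleven species on the membrane plus well-mixed scalars implement the
two-stage filter–amplifier: receptor/G-protein cycle (R, RL, G, Ga,
Gbg, Gd) feeding the Cdc42 cycle (C24m, C42, C42a, B1m, Cla4a), with
Cdc24 and Bem1 exchanging with conserved cytoplasmic pools and three
strict conservation laws (Gα, Gβγ, total Cdc42; drift < 10⁻⁶ per
simulated minute is enforced in tests).  Regulatory saturating
functions f_Gbg (Cdc24 recruitment by free Gβγ, via normalized
Gbg/G_total), f_Bem1 (scaffold-mediated recruitment) and f_Cla4
(global negative feedback on the Cdc42 activity average) are Hill
forms whose constants live in one parameter block, so substituting
externally derived values requires no code change.  Polarized receptor
delivery p_s = C42a/⟨C42a⟩ is the slow outer feedback loop.

The numeric constants are a calibrated set (the published source keeps
its constants in supplementary material not vendored here).  The
calibration strategy, in order:

1. **Scale anchors.** ~10 000 receptors and 10 000 G proteins on the
   cell at rest (kRs/kRd0 = 200/μm²); α-factor Kd = 5 nM; membrane
   diffusion D = 0.01 μm²/s; receptor turnover in minutes (the outer
   loop's timescale); G-cycle turnover ~seconds at normal speed;
   Cdc42-cycle turnover ~1 s (the fast inner loop).
2. **Near-critical operating point.** The uniform steady state is
   solved as an ODE and the growth rate λ of non-uniform perturbations
   computed from the local Jacobian (global pools and Cla4 frozen —
   they respond only to the uniform mode).  f_Cla4's threshold is set
   so the clamped activity level sits just *below* the onset of the
   inner-loop instability (λ ≈ −0.05/s).  Polarization is then an
   ignition race: the gradient tips the front locally supercritical,
   while noise can ignite elsewhere first.
3. **Directional-accuracy targets.** The steep f_Gbg (n = 40) makes the
   Gβγ readout switch-like, so large pass-through noise (fast G-cycle)
   saturates it and crushes the front–back bias, while a slow G-cycle
   filters the noise into the readout's linear range.  This yields the
   strict accuracy ordering fast < normal < slow at σ = 1,
   L_slp = 0.01 nM/μm.

Mutants: `bem1_delta` removes the Bem1-dependent Cdc24 recruitment term
(the truncation allele cannot bind Cdc24); the literal
zeroed-Hill-exponent variant (constant half-maximal recruitment) is
kept behind a flag but, at this operating point (f_Bem1 ≈ 0 at rest),
it *raises* baseline recruitment ~25-fold and produces more membrane
Cdc42 than wild type — the opposite of the mutant's phenotype — so it
is not the default.  `bni1_delta` makes receptor delivery isotropic
(p_s ≡ 1): delivery continues through the second formin pathway, only
its polarized component is lost; zeroing the synthesis term outright
would strip the cell of receptors entirely and no polarization of any
kind could occur.

Monte Carlo protocol: noise is on from t = 0 (the direction is decided
during noisy establishment — equilibrating noise-free first would
pre-polarize the cell up the gradient and make every run perfectly
accurate); each replicate runs 600 s and the polarization direction is
the circular centre of mass of the time-averaged active-Cdc42 field
over the final 300 s; cos(θ) against the gradient direction is averaged
over ≥ 20 seeded replicates (mean ± SEM).

## Known limitations

* At the fixed per-step noise convention (σ per node per k_t = 0.01 s),
  the low-frequency content of the input noise is small: any decision
  mechanism that integrates ≳ 1 s of input averages ≥ 100 independent
  draws across ~60–200 nodes.  This bounds how *inaccurate* the model
  can be made: the calibrated accuracies under speed scaling are
  ~0.83 / 0.91 / 0.96 (fast/normal/slow) versus the published
  0.06 / 0.62 / 0.99.  The ordering and the slope-sweep degradation are
  reproduced; the published magnitude of the fast- and normal-variant
  inaccuracy is not reachable in this noise model.
* Established polarization peaks are winner-take-all states pinned by
  pool depletion; under this noise model they essentially do not
  wander.  The bni1Δ "shifting peaks" phenotype therefore appears only
  weakly (reduced anchoring), not as the published multi-peak drift.
* PF-regime adaptation is conditional: the bistable amplifier adapts
  only once its feedback is ignited; its collapsed uniform state sits
  below the set point.
* One cell, fixed shape; no MAPK branch; no internal molecular noise.
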